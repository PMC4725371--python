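"""In-scope preprocessing: equilibrium-volume removal, detrending,
per-block normalization, and trial pattern extraction.

Spatial preprocessing (motion correction, slice timing, co-registration,
normalization) is not needed for the synthetic data, which is generated
aligned; only the temporal steps the multivariate analysis depends on are
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import RunDesign, trial_volume_window
from .simulate import VolumeSeries

EPS_VAR = 1e-12


class PreprocessError(ValueError):
    pass


@dataclass
class TrialPatternSet:
    """Trial x voxel activity patterns with labels and fold assignment.

    ``fold_assignment`` partitions the trials into 10 non-overlapping sets;
    the folds are the design blocks, so each fold holds 8 trials balanced
    4/4 in both label dimensions.  ``voxel_index`` maps pattern columns to
    3-D mask coordinates.
    """

    patterns: np.ndarray  # (n_trials, V)
    gender_labels: np.ndarray
    emotion_labels: np.ndarray
    fold_assignment: np.ndarray
    voxel_index: np.ndarray  # (V, 3)
    mask_shape: tuple[int, int, int]

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def labels(self, feature: str) -> np.ndarray:
        if feature == "gender":
            return self.gender_labels
        if feature == "emotion":
            return self.emotion_labels
        raise KeyError(feature)

    def select(self, columns: np.ndarray) -> "TrialPatternSet":
        """Restrict to a voxel subset (columns into ``patterns``)."""
        return replace(
            self,
            patterns=self.patterns[:, columns],
            voxel_index=self.voxel_index[columns],
        )

    def columns_of(self, coords: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel coordinates to pattern columns."""
        flat = np.ravel_multi_index(self.voxel_index.T, self.mask_shape)
        lookup = {f: i for i, f in enumerate(flat)}
        want = np.ravel_multi_index(np.asarray(coords).T, self.mask_shape)
        try:
            return np.array([lookup[f] for f in want])
        except KeyError:
            raise PreprocessError("some coordinates are outside the pattern voxel set")

    def to_label_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "fold": self.fold_assignment,
                "gender": self.gender_labels,
                "emotion": self.emotion_labels,
            }
        )

    def save(self, stem) -> None:
        """Write <stem>_patterns.tsv (trial x voxel matrix),
        <stem>_labels.tsv and <stem>_voxels.tsv."""
        from pathlib import Path

        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        np.savetxt(stem.with_name(stem.name + "_patterns.tsv"),
                   self.patterns, delimiter="\t")
        self.to_label_table().to_csv(
            stem.with_name(stem.name + "_labels.tsv"), sep="\t", index=False)
        header = "\t".join(map(str, self.mask_shape))
        np.savetxt(stem.with_name(stem.name + "_voxels.tsv"),
                   self.voxel_index, fmt="%d", delimiter="\t", header=header)

    @classmethod
    def load(cls, stem) -> "TrialPatternSet":
        from pathlib import Path

        stem = Path(stem)
        patterns = np.loadtxt(stem.with_name(stem.name + "_patterns.tsv"),
                              delimiter="\t", ndmin=2)
        labels = pd.read_csv(stem.with_name(stem.name + "_labels.tsv"), sep="\t")
        vox_path = stem.with_name(stem.name + "_voxels.tsv")
        with open(vox_path) as fh:
            mask_shape = tuple(int(v) for v in fh.readline().lstrip("# ").split())
        voxels = np.loadtxt(vox_path, dtype=int, delimiter="\t", ndmin=2)
        return cls(
            patterns=patterns,
            gender_labels=labels["gender"].to_numpy(),
            emotion_labels=labels["emotion"].to_numpy(),
            fold_assignment=labels["fold"].to_numpy(),
            voxel_index=voxels,
            mask_shape=mask_shape,
        )


def drop_equilibrium(series: VolumeSeries, n_volumes: int = 5) -> VolumeSeries:
    """Discard the pre-equilibrium volumes and re-reference onsets to 0.

    The discarded volumes correspond to the 10 s pre-stimulation baseline.
    Guarded against double application.
    """
    if series.equilibrium_dropped:
        raise PreprocessError("equilibrium volumes were already dropped")
    if series.n_volumes <= n_volumes:
        raise PreprocessError("series too short to drop equilibrium volumes")
    dt = n_volumes * series.tr_s
    return replace(
        series,
        data=series.data[..., n_volumes:],
        design=series.design.shifted(-dt),
        equilibrium_dropped=True,
    )


def detrend_and_blocknorm(series: VolumeSeries) -> VolumeSeries:
    """Remove each voxel's linear trend over the run, then z-score each
    voxel's series within every block's time span (mean 0, variance 1).

    Volumes outside block spans (inter-block blanks) are left detrended but
    un-normalized; they are not used downstream.  Voxels constant within a
    block are set to zero there and flagged rather than treated as fatal.
    """
    X = series.masked().astype(np.float64)  # (T, V)
    T = X.shape[0]
    t = np.arange(T, dtype=np.float64)
    t = (t - t.mean()) / (t.std() or 1.0)
    # least-squares linear detrend, all voxels at once
    beta = (t @ X) / (t @ t)
    X = X - X.mean(axis=0) - np.outer(t, beta)

    flagged = np.zeros(X.shape[1], dtype=bool)
    for start_s, end_s in series.design.block_spans_s():
        i0 = int(round(start_s / series.tr_s))
        i1 = int(round(end_s / series.tr_s))
        i0, i1 = max(i0, 0), min(i1, T)
        if i1 <= i0:
            raise PreprocessError("block span outside the series; was the "
                                  "equilibrium period dropped twice?")
        blk = X[i0:i1]
        mu = blk.mean(axis=0)
        sd = blk.std(axis=0)
        const = sd < np.sqrt(EPS_VAR)
        flagged |= const
        X[i0:i1] = (blk - mu) / np.sqrt(sd**2 + EPS_VAR)
        X[i0:i1, const] = 0.0
    out = np.zeros_like(series.data)
    out[series.mask] = X.T.astype(series.data.dtype)
    flags = dict(series.flags)
    flags["constant_voxels"] = np.flatnonzero(flagged)
    return replace(series, data=out, flags=flags)


def preprocess_run(series: VolumeSeries) -> VolumeSeries:
    """Standard temporal pipeline: equilibrium drop, detrend, block z-score."""
    return detrend_and_blocknorm(drop_equilibrium(series))


def extract_patterns(
    series: VolumeSeries, voxel_subset: np.ndarray | None = None
) -> TrialPatternSet:
    """Average the last four volumes of each trial into a pattern vector.

    Each pattern element is the mean BOLD response of one voxel over the
    6th-to-14th-second window of the trial.  ``voxel_subset`` is an optional
    (n, 3) coordinate array; default is the full mask.
    """
    X = series.masked()  # (T, V)
    coords = series.mask_coords()
    if voxel_subset is not None:
        flat = np.ravel_multi_index(coords.T, series.mask.shape)
        lookup = {f: i for i, f in enumerate(flat)}
        cols = np.array(
            [lookup[f] for f in np.ravel_multi_index(np.asarray(voxel_subset).T, series.mask.shape)]
        )
        X = X[:, cols]
        coords = coords[cols]
    design = series.design
    rows = []
    for trial in design.trials:
        win = trial_volume_window(trial, series.tr_s, n_volumes=series.n_volumes)
        rows.append(X[win].mean(axis=0))
    return TrialPatternSet(
        patterns=np.asarray(rows, dtype=np.float64),
        gender_labels=design.labels("gender"),
        emotion_labels=design.labels("emotion"),
        fold_assignment=design.block_index(),
        voxel_index=coords,
        mask_shape=series.mask.shape,
    )
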
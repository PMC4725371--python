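"""Group-level informative-voxel localization.

Per-fold linear-SVM weight maps (unselected voxels = 0) are averaged across
all folds and subjects into a group weight map.  A family-wise-error
threshold is built by rerunning the full fold-wise selection-and-training
pipeline under trial-label permutations (balanced within each fold so the
fold machinery stays valid), recording the maximum group-map voxel weight
per permutation, and taking the empirical 95th percentile of the resulting
max-weight null (1,000 permutations at full fidelity).  Suprathreshold
voxels form the informative voxel set, reported as 26-connected clusters.

Cross-reproducibility evaluates the same fold-wise reproducibility ratio on
an externally fixed voxel set (no per-fold selection), testing whether the
set generalizes across runs and tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .mvpa import (
    CvEngine,
    DecodingResult,
    ReproducibilityResult,
    SearchlightSpec,
    reproducibility,
    summarize_folds,
)
from .preprocess import TrialPatternSet


class LocalizeError(ValueError):
    pass


@dataclass
class GroupWeightMap:
    values: np.ndarray  # (V,) mean |w| across folds and subjects
    voxel_index: np.ndarray
    n_subjects: int
    n_folds: int


@dataclass
class PermutationNull:
    max_weights: np.ndarray
    alpha: float

    @property
    def threshold(self) -> float:
        """Nearest-rank (1 - alpha) percentile: sorted index ceil(q*n)."""
        s = np.sort(self.max_weights)
        k = int(np.ceil((1.0 - self.alpha) * len(s)))
        return float(s[max(k - 1, 0)])


@dataclass
class InformativeVoxelSet:
    columns: np.ndarray  # suprathreshold pattern columns
    voxel_index: np.ndarray  # their 3-D coordinates
    clusters: pd.DataFrame
    threshold: float


def group_weight_map(
    per_subject_decoding: list[DecodingResult],
    voxel_index: np.ndarray,
    mode: str = "abs",
    normalize: bool = True,
) -> GroupWeightMap:
    """Voxel-wise mean of per-fold SVM weights across folds and subjects.

    ``mode="abs"`` (default) averages magnitudes, making the importance
    measure sign-invariant across subjects; ``mode="signed"`` averages raw
    weights.  With ``normalize`` each fold map is scaled to unit L2 norm
    before averaging: the SVM weight norm is inversely tied to the margin,
    so un-normalized maps from poorly separable (e.g. label-permuted) data
    would dominate the average purely through scale.
    """
    if not per_subject_decoding:
        raise LocalizeError("need at least one subject")
    maps = [d.weight_maps for d in per_subject_decoding]
    shape0 = maps[0].shape
    if any(m.shape != shape0 for m in maps):
        raise LocalizeError("weight-map shapes differ across subjects")
    stacked = np.concatenate(maps, axis=0)  # (subjects*folds, V)
    if normalize:
        norms = np.linalg.norm(stacked, axis=1, keepdims=True)
        stacked = stacked / np.maximum(norms, 1e-30)
    if mode == "abs":
        stacked = np.abs(stacked)
    elif mode != "signed":
        raise LocalizeError("mode must be 'abs' or 'signed'")
    return GroupWeightMap(
        values=stacked.mean(axis=0),
        voxel_index=voxel_index,
        n_subjects=len(maps),
        n_folds=shape0[0],
    )


def _balanced_relabel(labels: np.ndarray, folds: np.ndarray, rng) -> np.ndarray:
    """Randomly permute labels within each fold (4/4 balance preserved)."""
    out = labels.copy()
    for k in np.unique(folds):
        rows = np.flatnonzero(folds == k)
        out[rows] = out[rows][rng.permutation(len(rows))]
    return out


def permutation_threshold(
    pattern_sets: list[TrialPatternSet],
    feature: str,
    K: int,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    spec: SearchlightSpec | None = None,
    mode: str = "abs",
    engines: list[CvEngine] | None = None,
) -> PermutationNull:
    """Max-weight null distribution over balanced trial relabelings.

    Each permutation independently relabels every subject's trials, reruns
    the complete fold-wise voxel selection and SVM training, and records
    the maximum voxel of the resulting group weight map.
    """
    if n_perm < 100:
        raise LocalizeError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    if engines is None:
        engines = [CvEngine(ps, K=K, spec=spec) for ps in pattern_sets]
    maxima = np.empty(n_perm)
    vi = pattern_sets[0].voxel_index
    for p in range(n_perm):
        decs = []
        for ps, eng in zip(pattern_sets, engines):
            perm = _balanced_relabel(ps.labels(feature), ps.fold_assignment, rng)
            _, dec = eng.run(perm, compute_repro=False)
            decs.append(dec)
        gmap = group_weight_map(decs, vi, mode=mode)
        maxima[p] = gmap.values.max()
    return PermutationNull(max_weights=maxima, alpha=alpha)


def extract_clusters(coords: np.ndarray, mask_shape,
                     weights: np.ndarray | None = None) -> pd.DataFrame:
    """26-connected components of a voxel set with size and center of mass."""
    cols = ["cluster", "size", "com_x", "com_y", "com_z", "max_weight"]
    if len(coords) == 0:
        return pd.DataFrame(columns=cols)
    vol = np.zeros(mask_shape, dtype=bool)
    vol[tuple(np.asarray(coords).T)] = True
    labeled, n = ndimage.label(vol, structure=np.ones((3, 3, 3), dtype=int))
    wvol = None
    if weights is not None:
        wvol = np.zeros(mask_shape)
        wvol[tuple(np.asarray(coords).T)] = weights
    rows = []
    for c in range(1, n + 1):
        cv = np.argwhere(labeled == c)
        com = cv.mean(axis=0)
        mw = float(wvol[tuple(cv.T)].max()) if wvol is not None else np.nan
        rows.append([c, len(cv), com[0], com[1], com[2], mw])
    return pd.DataFrame(rows, columns=cols)


def localize_informative_voxels(
    gmap: GroupWeightMap, null: PermutationNull, mask_shape
) -> InformativeVoxelSet:
    """Threshold the actual group map at the null's 95th percentile."""
    thr = null.threshold
    cols = np.flatnonzero(gmap.values > thr)
    coords = gmap.voxel_index[cols]
    clusters = extract_clusters(coords, mask_shape, weights=gmap.values[cols])
    return InformativeVoxelSet(
        columns=cols, voxel_index=coords, clusters=clusters, threshold=thr
    )


def cross_reproducibility(
    run_patterns: TrialPatternSet,
    fixed_voxels: InformativeVoxelSet | np.ndarray,
    feature: str,
    ratio_form: str = "ratio",
) -> ReproducibilityResult:
    """Fold-wise reproducibility ratio on an externally fixed voxel set.

    ``fixed_voxels`` may be an InformativeVoxelSet (matched by coordinates)
    or an array of pattern columns.  No per-fold selection is performed.
    """
    if isinstance(fixed_voxels, InformativeVoxelSet):
        cols = run_patterns.columns_of(fixed_voxels.voxel_index)
    else:
        cols = np.asarray(fixed_voxels)
    if len(cols) == 0:
        raise LocalizeError("fixed voxel set is empty")
    labels = run_patterns.labels(feature)
    per_fold = []
    for k in np.unique(run_patterns.fold_assignment):
        test = np.flatnonzero(run_patterns.fold_assignment == k)
        per_fold.append(
            reproducibility(
                run_patterns.patterns[np.ix_(test, cols)], labels[test], form=ratio_form
            )
        )
    return summarize_folds(per_fold)
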
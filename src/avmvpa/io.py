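"""NIfTI / TSV / JSON serialization for runs, masks and voxel maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import (
    Condition,
    RunDesign,
    StimulusCondition,
    Task,
    TaskSpec,
    TrialEvent,
)
from .simulate import VolumeSeries

# EPI voxel size of the emulated acquisition (mm)
VOXEL_MM = (4.375, 4.375, 5.5)


def _affine() -> np.ndarray:
    return np.diag(list(VOXEL_MM) + [1.0])


def write_run(series: VolumeSeries, stem: Path | str) -> dict[str, Path]:
    """Write a run as <stem>_bold.nii.gz, <stem>_mask.nii.gz,
    <stem>_events.tsv and <stem>_design.json."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "bold": stem.with_name(stem.name + "_bold.nii.gz"),
        "mask": stem.with_name(stem.name + "_mask.nii.gz"),
        "events": stem.with_name(stem.name + "_events.tsv"),
        "design": stem.with_name(stem.name + "_design.json"),
    }
    nib.save(nib.Nifti1Image(series.data, _affine()), paths["bold"])
    nib.save(nib.Nifti1Image(series.mask.astype(np.uint8), _affine()), paths["mask"])
    series.design.to_table().to_csv(paths["events"], sep="\t", index=False)
    paths["design"].write_text(series.design.to_json())
    return paths


def read_run(stem: Path | str) -> VolumeSeries:
    """Read a run written by :func:`write_run` (or any 4-D NIfTI volume plus
    a tabular trial table and design header)."""
    stem = Path(stem)
    data = np.asarray(
        nib.load(stem.with_name(stem.name + "_bold.nii.gz")).dataobj, dtype=np.float32
    )
    mask = (
        np.asarray(nib.load(stem.with_name(stem.name + "_mask.nii.gz")).dataobj) > 0
    )
    header = json.loads(stem.with_name(stem.name + "_design.json").read_text())
    events = pd.read_csv(stem.with_name(stem.name + "_events.tsv"), sep="\t")
    trials = tuple(
        TrialEvent(
            onset_s=float(r.onset),
            duration_s=float(r.duration),
            gender_label=str(r.gender),
            emotion_label=str(r.emotion),
            block_index=int(r.block),
            trial_index_in_run=i,
        )
        for i, r in enumerate(events.itertuples())
    )
    design = RunDesign(
        task=TaskSpec(Task(header["task"])),
        condition=StimulusCondition(Condition(header["condition"])),
        trials=trials,
        n_blocks=int(header["n_blocks"]),
        trials_per_block=int(header["trials_per_block"]),
        baseline_s=float(header["baseline_s"]),
        instruction_s=float(header["instruction_s"]),
        interblock_blank_s=float(header["interblock_blank_s"]),
        tr_s=float(header["tr_s"]),
        rng_seed=int(header["rng_seed"]),
    )
    return VolumeSeries(data=data, mask=mask, design=design, tr_s=design.tr_s)


def write_voxel_map(
    values: np.ndarray, voxel_index: np.ndarray, mask_shape, path: Path | str
) -> Path:
    """Scatter a per-voxel vector into the grid and save as NIfTI-1."""
    vol = np.zeros(mask_shape, dtype=np.float32)
    vol[tuple(np.asarray(voxel_index).T)] = values
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol, _affine()), path)
    return path
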
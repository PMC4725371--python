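"""Pipeline configuration: every tunable parameter with its default.

Defaults equal the study's printed values where one exists (K = 1500,
n_perm = 1000, alpha = 0.05, 9 subjects, 80 trials per run, TR = 2 s);
generator effect sizes default to the calibration choices documented in
docs/methods.md.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .simulate import DEFAULT_GRID


class ModelConfig(BaseModel):
    base_amplitude: float = 1.5
    class_contrast: float = 0.2
    attention_gain: float = Field(1.5, ge=1.0)
    av_congruent_gain: float = Field(1.4, ge=1.0)
    heteromodal_sensory_gain: float = 1.5
    coupling_strength: float = 0.8
    noise_sigma: float = Field(1.0, gt=0.0)
    global_noise_sigma: float = 0.5
    ar1_rho: float = Field(0.3, ge=0.0, lt=1.0)
    baseline: float = 100.0
    subject_sigma: float = 0.1


class PipelineConfig(BaseModel):
    seed: int = 0
    n_subjects: int = Field(9, ge=1)
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    roi_sizes: dict[str, int] | None = None
    K: int = Field(1500, ge=1)
    searchlight_radius: float = 2.0**0.5
    n_perm: int = Field(1000, ge=100)
    alpha_fwe: float = 0.05
    alpha_unc: float = 0.05
    fdr_alpha: float = 0.05
    max_order: int = 3
    svm_C: float = 1.0
    ratio_form: str = "ratio"
    outdir: str = "avmvpa_out"
    model: ModelConfig = ModelConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def neural_model(self):
        from .simulate import NeuralModel

        return NeuralModel(**self.model.model_dump())
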
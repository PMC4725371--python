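"""Two-level GLM test for audiovisual sensory integration.

The first level fits, per condition run (V, A, AV of one task), a design of
the HRF-convolved stimulation boxcar plus linear drift and intercept, by
voxel-wise least squares.  The second level declares audiovisual
integration at voxels satisfying the max criterion

    [AV > max(A, V)  (p < 0.05, FWE-corrected)]
      intersect  [V > 0 or A > 0  (p < 0.05, uncorrected)]

operationalized as the minimum-statistic conjunction of the one-sided
one-sample tests on the subject contrasts AV-A and AV-V, with family-wise
error control by sign-flip permutation of the subject contrast maps
(max of the min-t statistic under the null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import RunDesign
from .simulate import VolumeSeries, canonical_hrf, _boxcar


class GlmError(ValueError):
    pass


@dataclass
class GlmFit:
    betas: dict[str, np.ndarray]  # condition -> (V,) event-response betas
    residual_variance: dict[str, np.ndarray]
    dof: dict[str, int]
    voxel_index: np.ndarray
    mask_shape: tuple[int, int, int]


@dataclass
class IntegrationMap:
    columns: np.ndarray  # passing pattern columns
    voxel_index: np.ndarray
    t_conjunction: np.ndarray
    threshold: float
    t_av_a: np.ndarray
    t_av_v: np.ndarray
    unimodal_mask: np.ndarray


def event_regressor(design: RunDesign, n_volumes: int | None = None) -> np.ndarray:
    """HRF-convolved stimulation boxcar sampled at TR."""
    T = n_volumes or design.n_volumes
    box = _boxcar(design, np.ones(design.n_trials))[:T]
    return np.convolve(box, canonical_hrf(design.tr_s))[:T]


def design_matrix(design: RunDesign, n_volumes: int) -> np.ndarray:
    ev = event_regressor(design, n_volumes)
    drift = np.linspace(-1, 1, n_volumes)
    return np.column_stack([ev, drift, np.ones(n_volumes)])


def _fit_run(series: VolumeSeries):
    X = design_matrix(series.design, series.n_volumes)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise GlmError("rank-deficient GLM design matrix")
    Y = series.masked()  # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    return beta, (resid**2).sum(axis=0) / dof, dof


def first_level_glm(series_by_condition: dict[str, VolumeSeries]) -> GlmFit:
    """Per-voxel event-response betas for one task's V/A/AV run triplet."""
    betas, rvar, dofs = {}, {}, {}
    vi = None
    for cond, series in series_by_condition.items():
        cond = str(getattr(cond, "value", cond))
        beta, rv, dof = _fit_run(series)
        betas[cond] = beta[0]
        rvar[cond] = rv
        dofs[cond] = dof
        if vi is None:
            vi = series.mask_coords()
            shape = series.mask.shape
    return GlmFit(betas=betas, residual_variance=rvar, dof=dofs,
                  voxel_index=vi, mask_shape=shape)


def _one_sample_t(D: np.ndarray) -> np.ndarray:
    """One-sample t across subjects (rows), per voxel."""
    S = D.shape[0]
    sd = D.std(axis=0, ddof=1)
    return D.mean(axis=0) / np.maximum(sd, 1e-30) * np.sqrt(S)


def _sign_flips(n_subjects: int, n_perm: int, rng) -> np.ndarray:
    if 2**n_subjects <= max(n_perm, 2**n_subjects if n_subjects <= 14 else 0):
        bits = np.arange(2**n_subjects)
        return 1 - 2 * ((bits[:, None] >> np.arange(n_subjects)) & 1)
    return rng.choice([-1, 1], size=(n_perm, n_subjects))


def max_criterion_map(
    group_fits: list[GlmFit],
    alpha_fwe: float = 0.05,
    alpha_unc: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> IntegrationMap:
    """Second-level max-criterion conjunction with sign-flip FWE control.

    All 2^S sign flips are enumerated when S <= 14 (exact test); otherwise
    ``n_perm`` random flips are drawn.  Needs >= 2 subjects.
    """
    S = len(group_fits)
    if S < 2:
        raise GlmError("second-level test needs >= 2 subjects")
    d_a = np.stack([f.betas["AV"] - f.betas["A"] for f in group_fits])
    d_v = np.stack([f.betas["AV"] - f.betas["V"] for f in group_fits])
    b_v = np.stack([f.betas["V"] for f in group_fits])
    b_a = np.stack([f.betas["A"] for f in group_fits])

    t1, t2 = _one_sample_t(d_a), _one_sample_t(d_v)
    t_conj = np.minimum(t1, t2)

    rng = np.random.default_rng(seed)
    flips = _sign_flips(S, n_perm, rng)
    null = np.empty(len(flips))
    for i, eps in enumerate(flips):
        null[i] = np.minimum(
            _one_sample_t(eps[:, None] * d_a), _one_sample_t(eps[:, None] * d_v)
        ).max()
    k = int(np.ceil((1.0 - alpha_fwe) * len(null)))
    thr = float(np.sort(null)[max(k - 1, 0)])

    t_crit = stats.t.ppf(1.0 - alpha_unc, S - 1)
    unimodal = (_one_sample_t(b_v) > t_crit) | (_one_sample_t(b_a) > t_crit)

    passing = np.flatnonzero((t_conj > thr) & unimodal)
    vi = group_fits[0].voxel_index
    return IntegrationMap(
        columns=passing,
        voxel_index=vi[passing],
        t_conjunction=t_conj,
        threshold=thr,
        t_av_a=t1,
        t_av_v=t2,
        unimodal_mask=unimodal,
    )


def percent_signal_change(
    series: VolumeSeries, roi: np.ndarray, design: RunDesign | None = None
) -> float:
    """Peak fitted event response as a percentage of the ROI baseline.

    Fits the run GLM to the ROI-mean series; PSC = 100 * max_t(beta_event *
    event regressor) / baseline(intercept).  Returns NaN when the baseline
    is non-positive (undefined).
    """
    roi = np.asarray(roi)
    if roi.size == 0:
        raise GlmError("empty ROI")
    design = design or series.design
    y = series.data[tuple(roi.T)].mean(axis=0).astype(np.float64)
    X = design_matrix(design, len(y))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    baseline = beta[-1]
    if baseline <= 0:
        return float("nan")
    fitted_event = beta[0] * X[:, 0]
    return float(100.0 * fitted_event.max() / baseline)
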
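import numpy as np
import pytest

import avmvpa as m
from avmvpa.glm import (
    GlmError,
    GlmFit,
    design_matrix,
    event_regressor,
    first_level_glm,
    max_criterion_map,
    percent_signal_change,
)
from avmvpa.preprocess import drop_equilibrium
from avmvpa.simulate import VolumeSeries


def _series(X, design, grid=(4, 4, 2)):
    mask = np.zeros(grid, bool)
    coords = np.argwhere(np.ones(grid, bool))[: X.shape[1]]
    mask[tuple(coords.T)] = True
    data = np.zeros(grid + (X.shape[0],))
    data[mask] = X.T
    return VolumeSeries(data=data, mask=mask, design=design, tr_s=design.tr_s)


@pytest.fixture(scope="module")
def short_design():
    return m.build_run_design("number", "AV", seed=0, n_blocks=2,
                              trials_per_block=4)


class TestFirstLevel:
    def test_betas_match_normal_equations_oracle(self, short_design):
        X = design_matrix(short_design, short_design.n_volumes)
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((short_design.n_volumes, 1))
        fit = first_level_glm({"AV": _series(Y, short_design)})
        beta_ref = np.linalg.inv(X.T @ X) @ X.T @ Y[:, 0]
        assert fit.betas["AV"][0] == pytest.approx(beta_ref[0], abs=1e-10)
        resid = Y[:, 0] - X @ beta_ref
        dof = len(Y) - 3
        assert fit.residual_variance["AV"][0] == pytest.approx(
            resid @ resid / dof, rel=1e-10)
        assert fit.dof["AV"] == dof

    def test_noiseless_self_consistency(self, tiny_phantom):
        """Betas recover the generating per-voxel evoked amplitudes."""
        model = m.NeuralModel(noise_sigma=1e-9, class_contrast=0.0,
                              global_noise_sigma=0.0, coupling_strength=0.0)
        triplet = {}
        for cond in ("V", "A", "AV"):
            d = m.build_run_design("gender", cond, seed=1)
            triplet[cond] = drop_equilibrium(
                m.simulate_run(d, tiny_phantom, model, seed=2))
        fit = first_level_glm(triplet)
        bg_col = 0  # first mask voxel; evoked amplitude from the phantom
        want = model.base_amplitude * tiny_phantom.evoked
        het_cols = triplet["AV"].design  # noqa: F841  (readability)
        assert np.allclose(fit.betas["V"], fit.betas["A"], atol=1e-4)
        # heteromodal voxels gain 1.5 in AV; all others do not
        ratio = fit.betas["AV"] / np.maximum(fit.betas["V"], 1e-12)
        coords = np.argwhere(tiny_phantom.mask)
        het = {tuple(v) for v in tiny_phantom.roi_voxels(
            ("het_left_stg", "het_right_stg", "het_left_prc", "het_right_prc"))}
        is_het = np.array([tuple(c) in het for c in coords])
        assert np.allclose(ratio[is_het], model.heteromodal_sensory_gain, atol=1e-3)
        assert np.allclose(ratio[~is_het], 1.0, atol=1e-3)
        assert np.allclose(fit.betas["V"], want, atol=1e-4)

    def test_all_zero_data(self, short_design):
        Y = np.zeros((short_design.n_volumes, 3))
        fit = first_level_glm({"V": _series(Y, short_design)})
        assert np.allclose(fit.betas["V"], 0.0)


def _fits_from_betas(av, a, v, n_subjects, noise, rng, n_vox=6):
    av, a, v = (np.broadcast_to(np.asarray(x, float), n_vox) for x in (av, a, v))
    fits = []
    coords = np.argwhere(np.ones((n_vox, 1, 1), bool))
    for _ in range(n_subjects):
        fits.append(GlmFit(
            betas={
                "AV": av + noise * rng.standard_normal(n_vox),
                "A": a + noise * rng.standard_normal(n_vox),
                "V": v + noise * rng.standard_normal(n_vox),
            },
            residual_variance={}, dof={}, voxel_index=coords,
            mask_shape=(n_vox, 1, 1),
        ))
    return fits


class TestMaxCriterion:
    def test_additive_positive_case_passes(self):
        rng = np.random.default_rng(0)
        fits = _fits_from_betas(2.0, 1.0, 1.0, 8, 1e-3, rng)
        imap = max_criterion_map(fits, seed=1)
        assert len(imap.columns) == 6

    def test_av_not_exceeding_max_fails(self):
        rng = np.random.default_rng(1)
        # AV equals A: no superadditive direction, V positive
        fits = _fits_from_betas(1.0, 1.0, 0.5, 8, 1e-3, rng)
        imap = max_criterion_map(fits, seed=1)
        assert len(imap.columns) == 0

    def test_conjunction_never_laxer_than_components(self):
        rng = np.random.default_rng(2)
        av = rng.normal(1.0, 0.5, 6)
        fits = _fits_from_betas(av, 0.8, 0.9, 8, 0.3, rng)
        imap = max_criterion_map(fits, seed=3)
        passing = set(imap.columns.tolist())
        comp1 = set(np.flatnonzero(imap.t_av_a > imap.threshold).tolist())
        comp2 = set(np.flatnonzero(imap.t_av_v > imap.threshold).tolist())
        assert passing <= comp1 and passing <= comp2

    def test_requires_two_subjects(self):
        rng = np.random.default_rng(3)
        fits = _fits_from_betas(1.0, 1.0, 1.0, 1, 0.1, rng, n_vox=4)
        with pytest.raises(GlmError):
            max_criterion_map(fits)

    def test_signflip_fwe_control_under_null(self):
        """Zero-mean subject contrasts: family-wise positive rate <= alpha
        plus Monte-Carlo error."""
        rng = np.random.default_rng(4)
        hits = 0
        n_data = 150
        for i in range(n_data):
            fits = _fits_from_betas(0.0, 0.0, 0.0, 8, 1.0, rng, n_vox=8)
            imap = max_criterion_map(fits, alpha_unc=0.5, seed=i)
            hits += len(imap.columns) > 0
        rate = hits / n_data
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_data)


class TestPercentSignalChange:
    def test_flat_series_is_zero(self, short_design):
        Y = np.full((short_design.n_volumes, 1), 50.0)
        s = _series(Y, short_design)
        assert percent_signal_change(s, s.mask_coords()[:1]) == pytest.approx(0.0, abs=1e-9)

    def test_definition_peak_over_baseline(self, short_design):
        ev = event_regressor(short_design)
        y = 100.0 + 2.0 * ev / ev.max()  # fitted event peak 2, baseline 100
        s = _series(y[:, None], short_design)
        assert percent_signal_change(s, s.mask_coords()[:1]) == pytest.approx(2.0)

    def test_doubling_baseline_halves_psc(self, short_design):
        ev = event_regressor(short_design)
        for base, want in ((100.0, 2.0), (200.0, 1.0)):
            y = base + 2.0 * ev / ev.max()
            s = _series(y[:, None], short_design)
            assert percent_signal_change(s, s.mask_coords()[:1]) == pytest.approx(want)

    def test_nonpositive_baseline_undefined(self, short_design):
        Y = np.zeros((short_design.n_volumes, 1))
        s = _series(Y, short_design)
        assert np.isnan(percent_signal_change(s, s.mask_coords()[:1]))

    def test_generative_recovery_within_ten_percent(self, tiny_phantom):
        model = m.NeuralModel(class_contrast=0.0, coupling_strength=0.0)
        d = m.build_run_design("number", "V", seed=5)
        run = drop_equilibrium(m.simulate_run(d, tiny_phantom, model, seed=6))
        roi = tiny_phantom.roi_map["het_left_stg"]
        coords = np.argwhere(tiny_phantom.mask)
        idx = {tuple(c): i for i, c in enumerate(coords)}
        amp = tiny_phantom.evoked[[idx[tuple(v)] for v in roi]].mean()
        ev = event_regressor(run.design, run.n_volumes)
        want = 100.0 * amp * model.base_amplitude * ev.max() / model.baseline
        got = percent_signal_change(run, roi)
        assert got == pytest.approx(want, rel=0.10)

    def test_empty_roi_errors(self, short_design):
        Y = np.zeros((short_design.n_volumes, 1))
        with pytest.raises(GlmError):
            percent_signal_change(_series(Y, short_design), np.empty((0, 3), int))
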
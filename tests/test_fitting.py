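"""One-step and two-step fitting: oracles, recovery and invariances."""

import math

import numpy as np
import pytest

from cordivim import (
    BValueScheme,
    FitConfig,
    IVIMFitter,
    IVIMParams,
    SignalDecay,
    estimate_D_monoexp,
    fit_one_step,
    fit_roiwise,
    fit_two_step,
    fit_voxelwise,
    forward_signal,
    roi_average_decay,
)
from cordivim.exceptions import (
    EmptyMaskError,
    EmptyROIError,
    InsufficientDataError,
    InvalidSignalError,
    LogDomainError,
)
from cordivim.model import D_BOUNDS, DSTAR_BOUNDS, F_BOUNDS, ivim_signal
from conftest import GM_TRUTH, WM_TRUTH


class TestMonoexpPrior:
    def test_exact_monoexponential_recovered_to_machine_precision(self, scheme):
        decay = SignalDecay(scheme, tuple(np.exp(-scheme.b * 4e-4)))
        d, s0 = estimate_D_monoexp(decay)
        assert d == pytest.approx(4e-4, rel=1e-12)
        assert s0 == pytest.approx(1.0, rel=1e-12)

    def test_two_point_closed_form_slope(self):
        # only b=450 and b=650 lie above the cut-off: D = ln(0.9/0.8) / 200
        sch = BValueScheme(bvalues=(0.0, 200.0, 450.0, 650.0), cutoff=400.0)
        decay = SignalDecay(sch, (1.0, 0.95, 0.9, 0.8))
        d, _ = estimate_D_monoexp(decay)
        assert d == pytest.approx(math.log(0.9 / 0.8) / 200.0, rel=1e-12)

    def test_constant_decay_clips_to_lower_bound(self, scheme):
        decay = SignalDecay(scheme, tuple(np.ones(len(scheme))))
        d, _ = estimate_D_monoexp(decay)
        assert d == D_BOUNDS[0]

    def test_insufficient_high_b_points(self, scheme):
        decay = SignalDecay(scheme, tuple(np.exp(-scheme.b * 4e-4)))
        with pytest.raises(InsufficientDataError):
            estimate_D_monoexp(decay, cutoff_b=649.0)

    def test_nonpositive_signal_rejected(self, scheme):
        vals = np.exp(-scheme.b * 4e-4)
        vals[-1] = 0.0
        with pytest.raises(LogDomainError):
            estimate_D_monoexp(SignalDecay(scheme, tuple(vals)))


class TestOneStep:
    @pytest.mark.parametrize("truth", [WM_TRUTH, GM_TRUTH], ids=["WM", "GM"])
    def test_noiseless_recovery_within_one_percent(self, truth, scheme):
        decay = forward_signal(IVIMParams(**truth), scheme)
        res = fit_one_step(decay)
        assert res.params.F == pytest.approx(truth["F"], rel=0.01)
        assert res.params.Dstar == pytest.approx(truth["Dstar"], rel=0.01)
        assert res.params.D == pytest.approx(truth["D"], rel=0.01)
        assert res.r2 > 0.999999

    def test_monoexponential_input_pins_f_at_lower_bound(self, scheme):
        decay = SignalDecay(scheme, tuple(np.exp(-scheme.b * 4e-4)))
        res = fit_one_step(decay)
        assert res.params.D == pytest.approx(4e-4, rel=0.01)
        assert res.params.F <= 0.005

    def test_fixed_seed_is_bit_reproducible(self, wm_decay):
        r1 = fit_one_step(wm_decay, FitConfig(seed=7))
        r2 = fit_one_step(wm_decay, FitConfig(seed=7))
        assert r1.params == r2.params
        assert r1.r2 == r2.r2

    def test_scale_invariance_changes_only_s0(self, wm_decay, scheme):
        res1 = fit_one_step(wm_decay)
        scaled = SignalDecay(scheme, tuple(3.0 * wm_decay.y))
        res2 = fit_one_step(scaled)
        assert res2.params.S0 == pytest.approx(3.0 * res1.params.S0, rel=1e-3)
        assert res2.params.F == pytest.approx(res1.params.F, rel=1e-3)
        assert res2.params.Dstar == pytest.approx(res1.params.Dstar, rel=1e-3)
        assert res2.params.D == pytest.approx(res1.params.D, rel=1e-3)

    def test_noisy_fits_respect_bounds(self, wm_decay, scheme, rng):
        for _ in range(5):
            noisy = np.abs(wm_decay.y + 0.02 * rng.standard_normal(len(scheme)))
            res = fit_one_step(SignalDecay(scheme, tuple(noisy)))
            p = res.params
            assert F_BOUNDS[0] <= p.F <= F_BOUNDS[1] + 1e-12
            assert DSTAR_BOUNDS[0] - 1e-12 <= p.Dstar <= DSTAR_BOUNDS[1] + 1e-12
            assert D_BOUNDS[0] - 1e-12 <= p.D <= D_BOUNDS[1] + 1e-12

    def test_median_d_matches_grid_search_oracle_on_same_noise(self, scheme, wm_decay):
        """DE fits agree with an exhaustive grid-search minimizer on identical
        Rician draws at the repetition-averaged SNR ~ 120 regime."""
        rng = np.random.default_rng(42)
        b = scheme.b
        clean = wm_decay.y
        sigma, nrep, n = 1.0 / 27.0, 20, 30
        re = clean[None, :, None] + sigma * rng.standard_normal((n, b.size, nrep))
        im = sigma * rng.standard_normal((n, b.size, nrep))
        decays = np.hypot(re, im).mean(axis=2)

        f_g = np.linspace(*F_BOUNDS, 41)
        ds_g = np.geomspace(*DSTAR_BOUNDS, 40)
        d_g = np.linspace(*D_BOUNDS, 106)
        ff, ss, dd = np.meshgrid(f_g, ds_g, d_g, indexing="ij")
        model = np.exp(-b * dd[..., None]) * (
            ff[..., None] * np.exp(-b * ss[..., None]) + 1 - ff[..., None]
        )
        grid_d = []
        for y in decays:
            ssr = np.sum((y - y[0] * model) ** 2, axis=-1)
            grid_d.append(d_g[np.unravel_index(np.argmin(ssr), ssr.shape)[2]])

        fitter = IVIMFitter(scheme, config=FitConfig(seed=0)).fit(decays)
        step = d_g[1] - d_g[0]
        assert abs(np.median(fitter.params_[:, 3]) - np.median(grid_d)) <= step

    def test_all_zero_decay_rejected(self, scheme):
        fitter = IVIMFitter(scheme)
        with pytest.raises(InvalidSignalError):
            fitter.fit(np.zeros((1, len(scheme))))


class TestTwoStep:
    def test_d_equals_closed_form_high_b_slope_exactly(self, wm_decay):
        res = fit_two_step(wm_decay)
        d_prior, _ = estimate_D_monoexp(wm_decay)
        assert res.params.D == d_prior  # held fixed, bitwise

    def test_noiseless_wm_recovery(self, wm_decay):
        # perfusion contamination above the cut-off is ~1e-6 of the signal at
        # these parameters, so F and D* recover within 2 % relative
        assert WM_TRUTH["F"] * math.exp(-450 * WM_TRUTH["Dstar"]) < 1e-5
        res = fit_two_step(wm_decay)
        assert res.params.D == pytest.approx(WM_TRUTH["D"], rel=0.01)
        assert res.params.F == pytest.approx(WM_TRUTH["F"], rel=0.02)
        assert res.params.Dstar == pytest.approx(WM_TRUTH["Dstar"], rel=0.02)

    def test_zero_perfusion_flags_dstar_unidentifiable(self, scheme):
        decay = SignalDecay(scheme, tuple(np.exp(-scheme.b * 4e-4)))
        res = fit_two_step(decay)
        assert res.converged
        assert res.params.F <= 0.005
        if res.provenance["Dstar_unidentifiable"]:
            assert res.params.Dstar == DSTAR_BOUNDS[0]

    def test_one_and_two_step_agree_on_noiseless_data(self, wm_decay):
        r1 = fit_one_step(wm_decay)
        r2 = fit_two_step(wm_decay)
        assert abs(r1.params.D - r2.params.D) / r1.params.D < 0.01


class TestVoxelwise:
    def _volume(self, decays, shape):
        vol = np.zeros(shape + (len(decays[0]),))
        vol[..., :] = decays[0]
        return vol

    def test_homogeneous_phantom_gives_identical_maps(self, wm_decay, scheme):
        vol = np.broadcast_to(wm_decay.y, (3, 3, 2, len(scheme))).copy()
        mask = np.ones((3, 3, 2), dtype=bool)
        maps = fit_voxelwise(vol, mask, scheme)
        for name in ("F", "Dstar", "D"):
            vals = maps[name][mask]
            assert np.ptp(vals) <= 0.01 * abs(np.mean(vals))

    def test_single_voxel_mask_reduces_to_scalar_fit(self, wm_decay, scheme):
        vol = np.broadcast_to(wm_decay.y, (3, 3, 1, len(scheme))).copy()
        mask = np.zeros((3, 3, 1), dtype=bool)
        mask[1, 2, 0] = True
        maps = fit_voxelwise(vol, mask, scheme)
        scalar = fit_one_step(wm_decay)
        assert maps["D"][1, 2, 0] == pytest.approx(scalar.params.D, rel=1e-12)
        assert np.isnan(maps["D"][0, 0, 0])

    def test_two_tissue_phantom_recovers_both_truths(self, scheme, wm_decay, gm_decay):
        vol = np.zeros((4, 2, 1, len(scheme)))
        vol[:2, :, 0, :] = wm_decay.y
        vol[2:, :, 0, :] = gm_decay.y
        mask = np.ones((4, 2, 1), dtype=bool)
        maps = fit_voxelwise(vol, mask, scheme)
        assert np.nanmean(maps["F"][:2]) == pytest.approx(WM_TRUTH["F"], rel=0.01)
        assert np.nanmean(maps["F"][2:]) == pytest.approx(GM_TRUTH["F"], rel=0.01)
        assert np.nanmean(maps["D"][:2]) == pytest.approx(WM_TRUTH["D"], rel=0.01)
        assert np.nanmean(maps["D"][2:]) == pytest.approx(GM_TRUTH["D"], rel=0.01)

    def test_empty_mask_raises(self, wm_decay, scheme):
        vol = np.broadcast_to(wm_decay.y, (2, 2, 1, len(scheme))).copy()
        with pytest.raises(EmptyMaskError):
            fit_voxelwise(vol, np.zeros((2, 2, 1), dtype=bool), scheme)


class TestROIAverage:
    def test_uniform_probabilities_give_arithmetic_mean(self, scheme, rng):
        vol = rng.random((3, 2, 1, len(scheme))) + 0.5
        prob = np.full((3, 2, 1), 0.4)
        decay = roi_average_decay(vol, prob, 0, scheme)
        np.testing.assert_allclose(decay.y, vol[:, :, 0, :].mean(axis=(0, 1)), rtol=1e-12)

    def test_hand_computed_weighted_mean(self, scheme):
        vol = np.zeros((2, 1, 1, len(scheme)))
        vol[0, 0, 0, :] = 1.0
        vol[1, 0, 0, :] = 2.0
        prob = np.zeros((2, 1, 1))
        prob[0, 0, 0], prob[1, 0, 0] = 0.25, 0.75
        decay = roi_average_decay(vol, prob, 0, scheme)
        assert decay.values[0] == pytest.approx(1.75)

    def test_single_voxel_roi_is_identity(self, wm_decay, scheme):
        vol = np.zeros((2, 2, 1, len(scheme)))
        vol[1, 1, 0, :] = wm_decay.y
        prob = np.zeros((2, 2, 1))
        prob[1, 1, 0] = 0.8
        decay = roi_average_decay(vol, prob, 0, scheme)
        np.testing.assert_allclose(decay.y, wm_decay.y, rtol=1e-12)

    def test_all_zero_probability_slice_raises(self, wm_decay, scheme):
        vol = np.broadcast_to(wm_decay.y, (2, 2, 2, len(scheme))).copy()
        prob = np.zeros((2, 2, 2))
        prob[:, :, 0] = 0.5
        with pytest.raises(EmptyROIError):
            roi_average_decay(vol, prob, 1, scheme)


class TestROIwise:
    def test_homogeneous_phantom_roi_equals_voxel_mean(self, wm_decay, scheme):
        vol = np.broadcast_to(wm_decay.y, (3, 3, 2, len(scheme))).copy()
        prob = np.full((3, 3, 2), 0.7)
        mask = np.ones((3, 3, 2), dtype=bool)
        roi = fit_roiwise(vol, prob, scheme)
        maps = fit_voxelwise(vol, mask, scheme)
        assert set(roi) == {0, 1}
        for k in roi:
            assert roi[k].params.D == pytest.approx(np.nanmean(maps["D"]), rel=0.01)
            assert roi[k].params.F == pytest.approx(np.nanmean(maps["F"]), rel=0.01)

    def test_mixed_population_d_is_bracketed(self, scheme):
        lo = forward_signal(IVIMParams(S0=1.0, F=0.05, Dstar=20e-3, D=3e-4), scheme)
        hi = forward_signal(IVIMParams(S0=1.0, F=0.05, Dstar=20e-3, D=5e-4), scheme)
        vol = np.zeros((2, 1, 1, len(scheme)))
        vol[0, 0, 0, :] = lo.y
        vol[1, 0, 0, :] = hi.y
        prob = np.full((2, 1, 1), 1.0)
        roi = fit_roiwise(vol, prob, scheme)
        assert 3e-4 < roi[0].params.D < 5e-4

    def test_empty_slices_are_absent_not_zero_filled(self, wm_decay, scheme):
        vol = np.broadcast_to(wm_decay.y, (2, 2, 3, len(scheme))).copy()
        prob = np.zeros((2, 2, 3))
        prob[:, :, 1] = 0.5
        roi = fit_roiwise(vol, prob, scheme)
        assert set(roi) == {1}
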
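"""Phantom generator: bolus model, recirculation, tissue curves, assembly."""

import numpy as np
import pytest
from scipy.optimize import brentq

from aifdetect import (GammaVariateParams, PhantomSpec, RecirculationParams,
                       SamplingGrid, TissueParams, add_recirculation,
                       build_phantom, gamma_variate, mix_pve,
                       tissue_concentration)

AIF = GammaVariateParams(t0=26.0, alpha=3.0, beta=1.5, scale=1.0)


class TestGammaVariate:
    def test_zero_before_arrival(self, grid):
        c = gamma_variate(grid, AIF)
        assert np.all(c[grid.times <= AIF.t0] == 0.0)
        assert np.all(c[grid.times > AIF.t0] > 0.0)

    def test_peak_matches_calculus(self):
        # continuous maximum at t0 + alpha*beta with value (alpha*beta)^alpha e^-alpha
        t = np.linspace(20, 50, 30001)
        c = gamma_variate(t, AIF)
        assert t[c.argmax()] == pytest.approx(26 + 3.0 * 1.5, abs=2e-3)
        assert c.max() == pytest.approx((4.5**3) * np.exp(-3.0), rel=1e-6)
        assert c.max() == pytest.approx(4.5368, abs=5e-4)

    def test_fwhm_matches_bisection_oracle(self):
        # the two half-maximum crossings of the analytic curve, by root finding
        half = AIF.peak_value / 2.0
        f = lambda t: (t - 26.0) ** 3 * np.exp(-(t - 26.0) / 1.5) - half
        left = brentq(f, 26.01, 30.5)
        right = brentq(f, 30.5, 45.0)
        assert right - left == pytest.approx(6.19, abs=0.01)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            GammaVariateParams(alpha=-1.0)
        with pytest.raises(ValueError):
            GammaVariateParams(beta=np.nan)


class TestRecirculation:
    RC = RecirculationParams(tau_d=8.0, tau_r=30.0)

    def test_zero_amplitude_is_identity(self, grid):
        fp = gamma_variate(grid, AIF)
        out = add_recirculation(fp, RecirculationParams(amplitude=0.0), grid)
        np.testing.assert_array_equal(out, fp)

    def test_no_contribution_before_delayed_arrival(self, grid):
        fp = gamma_variate(grid, AIF)
        out = add_recirculation(fp, self.RC, grid, onset=AIF.t0)
        contribution = out - fp
        early = grid.times <= AIF.t0 + self.RC.tau_d
        assert np.all(contribution[early] == 0.0)
        assert np.all(contribution >= 0.0)
        assert contribution.max() > 0.0

    def test_area_identity_on_fine_grid(self):
        # normalized kernel: recirculation area = amplitude * first-passage area
        t = np.arange(1, 60001) * 0.01
        fp = gamma_variate(t, AIF)
        for amp in (1.0, 0.7):
            out = add_recirculation(fp, RecirculationParams(amplitude=amp), t,
                                    onset=AIF.t0)
            area_fp = np.trapezoid(fp, t)
            area_rc = np.trapezoid(out - fp, t)
            assert area_rc == pytest.approx(amp * area_fp, rel=1e-3)

    def test_grid_mismatch_rejected(self, grid):
        with pytest.raises(ValueError):
            add_recirculation(np.zeros(10), self.RC, grid)


class TestTissueConcentration:
    def test_cbf_follows_central_volume_principle(self):
        gm = TissueParams(cbv=4.0, mtt_mean=4.0, mtt_sd=0.33)
        assert gm.cbf == pytest.approx(1.0)  # ml/100 g/s
        assert TissueParams(cbv=2.0, mtt_mean=5.45).cbf == pytest.approx(0.367, abs=1e-3)

    def test_impulse_aif_gives_scaled_residue(self, grid):
        # unit impulse at the first sample -> tissue_scale*CBF*exp(-t/MTT)*dt
        impulse = np.zeros(grid.n_frames)
        impulse[0] = 1.0
        gm = TissueParams(cbv=4.0, mtt_mean=4.0)
        c = tissue_concentration(impulse, gm, grid, tissue_scale=0.1, mtt=4.0)
        expected = 0.1 * 1.0 * np.exp(-(grid.times - grid.times[0]) / 4.0) * grid.tr
        np.testing.assert_allclose(c, expected, rtol=1e-12)

    def test_mtt_draws_are_reproducible(self, grid):
        gm = TissueParams(cbv=4.0, mtt_mean=4.0, mtt_sd=0.33)
        aif = gamma_variate(grid, AIF)
        a = tissue_concentration(aif, gm, grid, np.random.default_rng(5))
        b = tissue_concentration(aif, gm, grid, np.random.default_rng(5))
        c = tissue_concentration(aif, gm, grid, np.random.default_rng(6))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_nonpositive_mtt_rejected(self, grid):
        gm = TissueParams(cbv=4.0, mtt_mean=4.0)
        with pytest.raises(ValueError):
            tissue_concentration(np.ones(grid.n_frames), gm, grid, mtt=-1.0)


class TestMixPve:
    def test_endpoint_weights(self, rng):
        a, b = np.full(10, 3.0), np.full(10, 1.0)
        np.testing.assert_array_equal(mix_pve(a, b, w=1.0), a)
        np.testing.assert_array_equal(mix_pve(a, b, w=0.0), b)
        np.testing.assert_allclose(mix_pve(a, b, w=0.5), np.full(10, 2.0))

    def test_random_weight_within_hull(self, rng):
        a, b = np.full(10, 3.0), np.full(10, 1.0)
        m = mix_pve(a, b, rng)
        assert np.all((m >= 1.0) & (m <= 3.0))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mix_pve(np.ones(5), np.ones(6), rng)


class TestBuildPhantom:
    def test_default_composition_counts(self):
        spec = PhantomSpec()
        assert spec.composition == {"arterial": 6, "false_arterial": 16,
                                    "gm": 440, "gm_path": 440, "wm": 600,
                                    "pve": 400}
        assert len(spec.false_arterial_grid()) == 16
        t0s = sorted({a for a, _ in spec.false_arterial_grid()})
        tds = sorted({b for _, b in spec.false_arterial_grid()})
        assert t0s == [27.0, 28.0, 29.0, 30.0]
        assert tds == [9.0, 10.0, 11.0, 12.0]

    def test_noise_sigma_from_snr(self):
        spec = PhantomSpec()
        assert spec.s0 / spec.snr == pytest.approx(5.0)

    def test_total_count_and_labels(self, small_phantom):
        curves = small_phantom.curves
        assert curves.n_curves == sum(small_phantom.spec.composition.values())
        counts = {c: int((curves.labels == c).sum())
                  for c in np.unique(curves.labels)}
        assert counts == small_phantom.spec.composition

    def test_same_seed_bit_identical_different_seed_differs(self):
        comp = dict(arterial=6, false_arterial=16, gm=10, gm_path=10, wm=10, pve=10)
        a = build_phantom(PhantomSpec(composition=comp, seed=11))
        b = build_phantom(PhantomSpec(composition=comp, seed=11))
        c = build_phantom(PhantomSpec(composition=comp, seed=12))
        np.testing.assert_array_equal(a.curves.values, b.curves.values)
        assert not np.array_equal(a.curves.values, c.curves.values)

    def test_true_aif_consistent_with_pipeline(self, small_phantom):
        spec = small_phantom.spec
        fp = gamma_variate(spec.grid, spec.aif_params)
        expected = add_recirculation(fp, spec.recirc, spec.grid,
                                     onset=spec.aif_params.t0)
        np.testing.assert_array_equal(small_phantom.true_aif, expected)

    def test_noiseless_tissue_peaks_below_and_after_aif(self, noiseless_phantom):
        ph = noiseless_phantom
        from aifdetect import concentration_from_signal

        conc = concentration_from_signal(ph.curves.values, ph.signal_params,
                                         grid=ph.curves.grid)
        aif_peak = ph.true_aif.max()
        aif_argmax = ph.true_aif.argmax()
        tissue = np.isin(ph.curves.labels, ["gm", "gm_path", "wm"])
        assert np.all(conc[tissue].max(axis=1) < aif_peak)
        assert np.all(conc[tissue].argmax(axis=1) > aif_argmax)

    def test_inconsistent_false_grid_rejected(self):
        comp = dict(arterial=6, false_arterial=7, gm=5, gm_path=5, wm=5, pve=5)
        with pytest.raises(ValueError, match="inconsistent"):
            build_phantom(PhantomSpec(composition=comp))

    def test_sampling_grid_spans_scan_time(self, grid):
        assert grid.times[0] == pytest.approx(1.5)
        assert grid.times[-1] == pytest.approx(90.0)
        assert np.allclose(np.diff(grid.times), 1.5)
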
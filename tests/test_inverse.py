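"""Inverse fit: error function contract, recovery, determinism, gating."""

import numpy as np
import pytest

from mcdrs.chromophores import build_solid_saturated_table
from mcdrs.forward import Spectrum, default_wavelength_grid, forward_spectra
from mcdrs.inverse import FitConfig, QualityError, error_function, fit, fit_batch
from mcdrs.phantoms import (
    SolidPhantomScenario,
    damped_hemoglobin,
    solid_truth_stack,
)
from mcdrs.tissue import SkinModelParams, build_layer_stack


def _liquid_spectrum(lut, so2=0.6, cheme=0.248, musp=2.0):
    params = SkinModelParams(tepi=0.0, alpha=musp, beta=0.0, gamma=0.0,
                             cheme1=cheme, cheme2=cheme, so2=so2, d_vessel=0.0,
                             fmel=0.0, gamma_mel=3.0)
    return forward_spectra(build_layer_stack(params, "liquid-phantom"), lut,
                           default_wavelength_grid())


class TestErrorFunction:
    def test_perfect_match_gives_zero(self, lut):
        sp = _liquid_spectrum(lut)
        assert np.allclose(error_function(sp, sp), 0.0)

    def test_uniform_scaling_is_invisible(self, lut):
        sp = _liquid_spectrum(lut)
        doubled = Spectrum(sp.wavelengths, 2.0 * sp.values, channels=sp.channels)
        assert np.allclose(error_function(sp, doubled), 0.0, atol=1e-12)

    def test_heme_band_perturbation_weighs_more(self, lut):
        sp = _liquid_spectrum(lut)
        lam = sp.wavelengths

        def perturbed(center):
            v = sp.values.copy()
            idx = np.argmin(np.abs(lam - center))
            v[:, idx] *= 1.05
            return Spectrum(lam, v, channels=sp.channels)

        r550 = np.linalg.norm(error_function(sp, perturbed(550.0)))
        r700 = np.linalg.norm(error_function(sp, perturbed(700.0)))
        assert r550 > r700

    def test_grid_mismatch_rejected(self, lut):
        sp = _liquid_spectrum(lut)
        other = Spectrum(sp.wavelengths + 1.0, sp.values, channels=sp.channels)
        with pytest.raises(ValueError):
            error_function(sp, other)


class TestFit:
    def test_noiseless_solid_self_consistency(self, lut):
        """Forward spectra of known solid-phantom parameters are inverted to
        SO2 within 1 %-unit and cheme within 3% relative."""
        hb_solid = damped_hemoglobin(damping=0.7)
        hbo2_solid = build_solid_saturated_table(hb_solid)
        sc = SolidPhantomScenario(dermis_level="high", coffee_level="no coffee",
                                  tepi_um=155.0)
        clean = forward_spectra(solid_truth_stack(sc, hb_solid), lut,
                                default_wavelength_grid())
        config = FitConfig(seed=2, hb=hb_solid, hbo2=hbo2_solid, normalize=False)
        res = fit(clean, lut, config, mode="solid-phantom")
        assert res.success
        assert abs(res.so2_percent - 0.0) < 1.0
        assert abs(res.params.cheme1 - sc.cheme) / sc.cheme < 0.03

    def test_liquid_fit_finds_no_vessels(self, lut):
        """A homogeneous medium has no vessels: D must come back ~0."""
        sp = _liquid_spectrum(lut, so2=0.8)
        res = fit(sp, lut, FitConfig(seed=2), mode="liquid-phantom")
        assert res.success
        assert res.d_um <= 2.0
        assert abs(res.so2_percent - 80.0) < 1.0

    def test_low_heme_area_input_flagged_excluded(self, lut):
        lam = default_wavelength_grid()
        # nearly flat long-separation channel: tiny heme signature
        sp = _liquid_spectrum(lut, so2=0.5, cheme=0.001)
        res = fit(sp, lut, FitConfig(seed=2, n_starts=4, refine_top=1,
                                     max_nfev_refine=30, max_nfev_polish=10),
                  mode="liquid-phantom")
        assert res.heme is not None and res.heme.heme_area < 1.5
        assert not res.included

    def test_invariant_to_per_channel_rescaling(self, lut):
        sp = _liquid_spectrum(lut, so2=0.4)
        gains = np.array([[2.0], [0.5]])
        rescaled = Spectrum(sp.wavelengths, sp.values * gains, channels=sp.channels)
        cfg = FitConfig(seed=2, n_starts=8, refine_top=1)
        a = fit(sp, lut, cfg, mode="liquid-phantom")
        b = fit(rescaled, lut, cfg, mode="liquid-phantom")
        assert a.params == b.params

    def test_degenerate_flat_spectrum_rejected(self, lut):
        lam = default_wavelength_grid()
        flat = Spectrum(lam, np.ones((2, lam.size)))
        with pytest.raises(QualityError):
            fit(flat, lut, FitConfig(seed=2), mode="liquid-phantom")

    def test_unknown_mode_rejected(self, lut):
        sp = _liquid_spectrum(lut)
        with pytest.raises(ValueError):
            fit(sp, lut, FitConfig(seed=2), mode="two-layer")


class TestFitBatch:
    def test_singleton_equals_single_fit(self, lut):
        sp = _liquid_spectrum(lut, so2=0.7)
        cfg = FitConfig(seed=2, n_starts=8, refine_top=1)
        single = fit(sp, lut, cfg, mode="liquid-phantom")
        batch = fit_batch([sp], lut, cfg, mode="liquid-phantom")
        assert len(batch) == 1
        assert batch[0].params == single.params

    def test_identical_inputs_give_identical_results(self, lut):
        sp = _liquid_spectrum(lut, so2=0.7)
        cfg = FitConfig(seed=2, n_starts=8, refine_top=1)
        batch = fit_batch([sp, sp], lut, cfg, mode="liquid-phantom")
        assert batch[0].params == batch[1].params

    def test_failures_are_isolated(self, lut):
        lam = default_wavelength_grid()
        good = _liquid_spectrum(lut, so2=0.7)
        flat = Spectrum(lam, np.ones((2, lam.size)))
        cfg = FitConfig(seed=2, n_starts=8, refine_top=1)
        batch = fit_batch([flat, good], lut, cfg, mode="liquid-phantom")
        assert not batch[0].success and "fit failed" in batch[0].message
        assert batch[1].success

    def test_empty_series_rejected(self, lut):
        with pytest.raises(ValueError):
            fit_batch([], lut, FitConfig(seed=2), mode="liquid-phantom")


class TestRecoveryOnTimeSeries:
    def test_monotone_deoxygenation_is_tracked(self, liquid_eval):
        """The yeast scenario's SO2 decays monotonically; the recovered
        trace must follow within a small noise allowance."""
        t = liquid_eval.table
        est = t["so2_est_pct"].to_numpy()
        assert np.all(np.diff(est) < 2.0)  # non-increasing up to noise
        assert est[0] > 90.0 and est[-1] < 10.0

    def test_noisy_recovery_degrades_gracefully(self, solid_eval,
                                                solid_eval_noiseless):
        """Median errors under 1% noise stay within 3x the noiseless medians
        plus the per-measurement noise floor."""
        noisy = solid_eval.table
        clean = solid_eval_noiseless.table
        med_noisy = noisy["so2_est_pct"].abs().median()
        med_clean = clean["so2_est_pct"].abs().median()
        assert med_noisy <= 3.0 * max(med_clean, 1.0)

    def test_noiseless_solid_medians(self, solid_eval_noiseless):
        """Across the included solid matrix (no noise): median SO2 error
        < 1 %-unit, median cheme error < 5%, median mus' deviation < 5%."""
        t = solid_eval_noiseless.table
        ok = [bool(v) if v == v else False for v in t["success"]]
        f = t[np.array(ok)]
        assert f["so2_est_pct"].abs().median() < 1.0
        cheme_rel = ((f["cheme_est"] - f["cheme_truth"]) / f["cheme_truth"]).abs()
        assert cheme_rel.median() < 0.05
        assert f["musp_rel_rms_pct"].median() < 5.0
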
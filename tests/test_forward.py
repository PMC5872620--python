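"""Forward Beer-Lambert spectra and sampling-volume summaries."""

import copy

import numpy as np
import pytest

from mcdrs.forward import (
    Spectrum,
    default_wavelength_grid,
    forward_spectra,
    included_mask,
    layer_sampling_fractions,
    weighted_expected_property,
)
from mcdrs.tissue import SkinModelParams, build_layer_stack


def _stack(tepi=0.0, musp=2.0, cheme=0.3, so2=0.5, mode="in-vivo", **kw):
    """Constant-scattering stack (beta = gamma = 0 gives mus' = alpha)."""
    base = dict(tepi=tepi, alpha=musp, beta=0.0, gamma=0.0, cheme1=cheme,
                cheme2=cheme, so2=so2, d_vessel=0.0, fmel=0.0, gamma_mel=3.0)
    base.update(kw)
    return build_layer_stack(SkinModelParams(**base), mode)


class TestForwardSpectra:
    def test_zero_absorption_reduces_to_weight_sum(self, lut):
        stack = _stack(cheme=0.0)
        lam = np.array([500.0, 600.0, 700.0])
        sp = forward_spectra(stack, lut, lam)
        for c in range(2):
            S, Z, W, offsets, scale = lut.flat_arrays(c)
            a, b = offsets[0, 2]  # tepi = 0 node, musp = 2 node
            expected = W[a:b].sum() * scale[0, 2]
            assert np.allclose(sp.values[c], expected, rtol=1e-12)

    def test_identical_layer_absorption_merges_to_total_path(self, lut):
        from mcdrs.tissue import LayerStack

        mua = 0.21
        lam = np.array([550.0])
        f = lambda l, m=mua: np.full(np.atleast_1d(l).shape, m)  # noqa: E731
        st = LayerStack(
            thicknesses_mm=(0.0, 0.2, np.inf),
            mua_funcs=(f, f, f),
            musp_func=lambda l: np.full(np.atleast_1d(l).shape, 2.0),
        )
        got = forward_spectra(st, lut, lam)
        # brute force on total path length at the (tepi=0, musp=2) node
        for c in range(2):
            S, Z, W, offsets, scale = lut.flat_arrays(c)
            a, b = offsets[0, 2]
            total = S[a:b].sum(axis=1)
            expected = (W[a:b] * np.exp(-mua * total)).sum() * scale[0, 2]
            assert got.values[c][0] == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_record_loop(self, lut):
        rng = np.random.default_rng(4)
        lam = np.array([500.0, 575.0, 700.0, 840.0])
        for _ in range(10):
            tepi = rng.uniform(0.0, 600.0)
            musp = rng.uniform(0.6, 3.8)
            mua123 = rng.uniform(0.0, 0.5, 3)
            from mcdrs.tissue import LayerStack

            stack = LayerStack(
                thicknesses_mm=(tepi * 1e-3, 0.2, np.inf),
                mua_funcs=tuple(
                    (lambda l, m=m: np.full(np.atleast_1d(l).shape, m))
                    for m in mua123
                ),
                musp_func=lambda l, m=musp: np.full(np.atleast_1d(l).shape, m),
            )
            got = forward_spectra(stack, lut, lam)
            # independent plain-python accumulation
            i_lo, i_hi, wi = lut.tepi_bracket(tepi)
            j_lo, j_hi, wj = lut.musp_bracket(musp)
            for c in range(2):
                S, Z, W, offsets, scale = lut.flat_arrays(c)
                total = 0.0
                for i, w_i in ((i_lo, wi), (i_hi, 1.0 - wi)):
                    for j, w_j in ((j_lo, wj), (j_hi, 1.0 - wj)):
                        if w_i == 0.0 or w_j == 0.0:
                            continue
                        a, b = offsets[i, j]
                        acc = 0.0
                        for k in range(a, b):
                            acc += W[k] * np.exp(-(S[k] @ mua123))
                        total += w_i * w_j * scale[i, j] * acc
                        if i_lo == i_hi:
                            break
                assert got.values[c][0] == pytest.approx(total, rel=1e-12)

    def test_absorption_monotonically_darkens(self, lut):
        lam = default_wavelength_grid()
        sel = (lam >= 500) & (lam <= 600)
        i0 = forward_spectra(_stack(cheme=0.0), lut, lam).values
        i1 = forward_spectra(_stack(cheme=1.0, so2=0.5), lut, lam).values
        assert np.all(i1[:, sel] < i0[:, sel])

    def test_near_channel_brighter_than_far(self, lut):
        lam = default_wavelength_grid()
        for cheme in (0.0, 0.5):
            v = forward_spectra(_stack(cheme=cheme), lut, lam).values
            assert np.all(v[0] > v[1])

    def test_hull_violation_names_wavelength(self, lut):
        # steep Mie slope puts musp(475 nm) far above the 4 mm^-1 hull edge
        stack = build_layer_stack(
            SkinModelParams(tepi=0.0, alpha=2.0e8, beta=2.4, gamma=0.0,
                            cheme1=0.0, cheme2=0.0, so2=0.0, d_vessel=0.0,
                            fmel=0.0, gamma_mel=3.0)
        )
        with pytest.raises(ValueError, match="outside LUT hull"):
            forward_spectra(stack, lut, default_wavelength_grid())


class TestSamplingVolume:
    def test_fractions_normalized_and_epidermis_vanishes_without_layer(self, lut):
        for method in ("path", "depth"):
            rep = layer_sampling_fractions(_stack(tepi=0.0), lut, method=method)
            assert rep.averaged.sum() == pytest.approx(1.0, abs=1e-12)
            assert rep.per_channel.sum(axis=1) == pytest.approx(1.0, abs=1e-12)
            assert rep.averaged[0] == pytest.approx(0.0, abs=1e-12)

    def test_thicker_epidermis_takes_larger_share(self, lut):
        f150 = layer_sampling_fractions(_stack(tepi=150.0), lut).averaged[0]
        f300 = layer_sampling_fractions(_stack(tepi=300.0), lut).averaged[0]
        assert 0.0 < f150 < f300

    def test_invariant_to_uniform_weight_rescaling(self, lut):
        stack = _stack(tepi=150.0, cheme=0.2)
        ref = layer_sampling_fractions(stack, lut, method="path")
        scaled = copy.deepcopy(lut)
        for row in scaled.nodes:
            for chans in row:
                for rec in chans:
                    rec.weights = rec.weights * 0.25
        scaled._flat.clear()
        got = layer_sampling_fractions(stack, scaled, method="path")
        assert np.allclose(got.averaged, ref.averaged, rtol=1e-12)

    def test_unknown_method_rejected(self, lut):
        with pytest.raises(ValueError):
            layer_sampling_fractions(_stack(), lut, method="voxel")


class TestWeightedExpectedProperty:
    def test_uniform_values_pass_through(self):
        assert weighted_expected_property([3.0, 3.0, 3.0],
                                          [0.2, 0.3, 0.5]) == pytest.approx(3.0)

    def test_degenerate_fraction_selects_layer(self):
        assert weighted_expected_property([1.0, 2.0, 5.0],
                                          [1.0, 0.0, 0.0]) == 1.0

    def test_dot_product(self):
        assert weighted_expected_property(
            [1.0, 2.0, 2.0], [0.2, 0.4, 0.4]
        ) == pytest.approx(1.8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_expected_property([1.0, 2.0], [1.0, 0.0, 0.0])


class TestSpectrumContainer:
    def test_notch_band_flagged_excluded(self):
        lam = default_wavelength_grid()
        inc = included_mask(lam)
        assert not inc[(lam >= 770) & (lam <= 810)].any()
        assert inc[(lam < 770) | (lam > 810)].all()

    def test_validation(self):
        lam = np.array([500.0, 510.0])
        with pytest.raises(ValueError):
            Spectrum(lam, -np.ones((2, 2)))
        with pytest.raises(ValueError):
            Spectrum(lam[::-1], np.ones((2, 2)))
        with pytest.raises(ValueError):
            Spectrum(lam, np.ones((2, 3)))
        sp = Spectrum(lam, np.ones((2, 2)))
        with pytest.raises(KeyError):
            sp.channel("sds_0.8mm")
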
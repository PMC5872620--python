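"""Forward spectral model: Beer-Lambert on LUT records, sampling volume.

The detected intensity at wavelength lam and channel c is

    I_c(lam) = sum_records w * exp(-sum_l mu_a,l(lam) * s_l)

mixed bilinearly over the LUT nodes bracketing (tepi, mus'(lam)).  The
intensity is relative (per launched photon, per fiber face); the inverse fit
normalizes spectra by their in-band mean, so no absolute calibration is
modelled.  A notch band at 770-810 nm (laser suppression filter) is flagged
excluded from all fitting and metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import bl_intensity
from .tissue import LayerStack
from .transport import PathLengthLUT

__all__ = [
    "NOTCH_BAND_NM",
    "WAVELENGTH_RANGE_NM",
    "Spectrum",
    "default_wavelength_grid",
    "included_mask",
    "forward_spectra",
    "SamplingVolumeReport",
    "layer_sampling_fractions",
    "weighted_expected_property",
]

#: Notch-filter band excluded from fitting and metrics, nm.
NOTCH_BAND_NM = (770.0, 810.0)

#: Fit band, nm.
WAVELENGTH_RANGE_NM = (475.0, 850.0)

CHANNEL_LABELS = ("sds_0.4mm", "sds_1.2mm")


def default_wavelength_grid(step_nm: float = 2.0) -> np.ndarray:
    """Wavelength grid covering 475-850 nm at ``step_nm`` spacing."""
    lo, hi = WAVELENGTH_RANGE_NM
    return np.arange(lo, hi + 0.5 * step_nm, step_nm)


def included_mask(wavelengths) -> np.ndarray:
    """True where a wavelength takes part in fitting/metrics (notch excluded)."""
    lam = np.asarray(wavelengths, dtype=float)
    return ~((lam >= NOTCH_BAND_NM[0]) & (lam <= NOTCH_BAND_NM[1]))


@dataclass
class Spectrum:
    """Dual-channel spectrum on a common wavelength grid.

    ``values`` has shape (n_channels, n_wavelengths); channel order matches
    ``channels`` (short then long source-detector separation by default).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    channels: tuple = CHANNEL_LABELS
    unit: str = "relative_intensity"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.values.shape != (len(self.channels), self.wavelengths.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.channels)} channels x {self.wavelengths.size} wavelengths"
            )
        if np.any(self.values < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def included(self) -> np.ndarray:
        return included_mask(self.wavelengths)

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.values[self.channels.index(label)]
        except ValueError:
            raise KeyError(
                f"channel {label!r} not present; have {self.channels}"
            ) from None


def _check_hull(stack: LayerStack, lut: PathLengthLUT, lam: np.ndarray):
    musp = np.asarray(stack.musp(lam), dtype=float)
    glo, ghi = lut.musp_grid[0], lut.musp_grid[-1]
    bad = (musp < glo) | (musp > ghi)
    if np.any(bad):
        lam_bad = lam[bad][0]
        raise ValueError(
            f"mus'({lam_bad:g} nm) = {musp[bad][0]:.3g} mm^-1 outside LUT hull "
            f"[{glo:g}, {ghi:g}] mm^-1"
        )
    i_lo, i_hi, wi = lut.tepi_bracket(stack.tepi_um)  # raises when outside
    return musp, (i_lo, i_hi, wi)


def _bl_run(stack, lut, lam, frac_mode):
    lam = np.asarray(lam, dtype=float)
    musp, (i_lo, i_hi, wi) = _check_hull(stack, lut, lam)
    mua = stack.mua_matrix(lam)
    intensities = []
    fractions = []
    for c in range(len(lut.geometry.detector_offsets_mm)):
        S, Z, W, offsets, scale = lut.flat_arrays(c)
        I, F = bl_intensity(
            S, Z, W, offsets, scale, i_lo, i_hi, wi,
            lut.tepi_grid_um * 1e-3, lut.musp_grid, musp, mua, frac_mode,
        )
        intensities.append(I)
        fractions.append(F)
    return np.array(intensities), np.array(fractions)


def forward_spectra(stack: LayerStack, lut: PathLengthLUT, wavelengths=None) -> Spectrum:
    """Model DRS intensity spectra at both source-detector separations."""
    lam = default_wavelength_grid() if wavelengths is None else np.asarray(
        wavelengths, dtype=float
    )
    I, _ = _bl_run(stack, lut, lam, 0)
    return Spectrum(
        lam, I,
        channels=lut.geometry.channel_labels,
        meta={"tepi_um": stack.tepi_um, "mode": stack.mode},
    )


@dataclass(frozen=True)
class SamplingVolumeReport:
    """Per-layer share of the sampling volume, per channel and averaged.

    The sampling volume is summarized as the Beer-Lambert-weighted per-layer
    path-length share of the detected light, averaged over included
    wavelengths (and over channels for ``averaged``).  Each fraction vector
    sums to 1.
    """

    per_channel: np.ndarray       # (n_channels, 3)
    averaged: np.ndarray          # (3,)
    channels: tuple
    wavelength_range: tuple

    @property
    def dermis_fraction(self) -> float:
        """Averaged share of layers 2+3 (the blood-bearing layers)."""
        return float(self.averaged[1] + self.averaged[2])


def layer_sampling_fractions(
    stack: LayerStack, lut: PathLengthLUT, wavelengths=None,
    method: str = "depth",
) -> SamplingVolumeReport:
    """Fraction of the sampling volume in each layer.

    Two summaries of where the detected light samples are available, both
    Beer-Lambert weighted and normalized per wavelength and channel before
    averaging over included wavelengths (and channels for the summary):

    ``method="depth"`` (default)
        Partition of the detected weight by the deepest layer each photon
        visited: the share of the detected signal whose sampling region
        extends into (at most) each layer.  This spatial reading keeps the
        thin epidermis a small fraction even at the short separation.
    ``method="path"``
        Per-layer share of the Beer-Lambert-weighted path length,
        fraction_l = sum_r w e^{-mu.s} s_l / sum_r w e^{-mu.s} s_tot.
    """
    lam = default_wavelength_grid() if wavelengths is None else np.asarray(
        wavelengths, dtype=float
    )
    modes = {"path": 1, "depth": 2}
    if method not in modes:
        raise ValueError(f"unknown sampling-volume method {method!r}")
    _, F = _bl_run(stack, lut, lam, modes[method])
    inc = included_mask(lam)
    tot = F.sum(axis=2)                       # (nch, nlam)
    if np.any(tot[:, inc] <= 0):
        raise ValueError(
            "no detected weight at some wavelengths; cannot form sampling fractions"
        )
    frac = F / tot[:, :, None]                # (nch, nlam, 3)
    per_channel = frac[:, inc, :].mean(axis=1)
    averaged = per_channel.mean(axis=0)
    return SamplingVolumeReport(
        per_channel=per_channel,
        averaged=averaged,
        channels=lut.geometry.channel_labels,
        wavelength_range=(float(lam[0]), float(lam[-1])),
    )


def weighted_expected_property(values, fractions) -> float:
    """Sampling-volume-weighted expectation: dot(values, fractions).

    ``values`` holds a per-layer property (e.g. mus' of each layer at one
    wavelength); ``fractions`` the corresponding sampling-volume shares.
    """
    values = np.asarray(values, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if values.shape != fractions.shape:
        raise ValueError(
            f"length mismatch: values {values.shape} vs fractions {fractions.shape}"
        )
    return float(np.dot(values, fractions))
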
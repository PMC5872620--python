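"""Heme-area spectral quality statistic and inclusion gating.

Robust parameter estimation needs a clear hemoglobin signature in the
500-600 nm absorption bands.  The heme-area quantifies that signature as
the magnitude of the area enclosed between the (mean-normalized) spectrum
and the chord connecting its values at 506 and 614 nm, evaluated on the
long source-detector separation channel.  Spectra with heme-area at or
below 1.5 are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import Spectrum, included_mask

__all__ = ["HEME_AREA_THRESHOLD", "CHORD_ENDPOINTS_NM", "HemeAreaResult", "heme_area"]

HEME_AREA_THRESHOLD = 1.5
CHORD_ENDPOINTS_NM = (506.0, 614.0)


@dataclass(frozen=True)
class HemeAreaResult:
    heme_area: float
    endpoints_nm: tuple
    endpoint_values: tuple
    included: bool
    threshold: float
    channel: str

    def __bool__(self) -> bool:  # truthiness == inclusion
        return self.included


def heme_area(
    spectrum: Spectrum,
    channel: str = "sds_1.2mm",
    threshold: float = HEME_AREA_THRESHOLD,
    normalize: bool = True,
) -> HemeAreaResult:
    """Heme-area of one spectrum channel.

    The channel is divided by its mean over the included fit band (making
    the statistic scale-free), the chord linearly connects the values at
    506 and 614 nm, and the area |integral(chord - spectrum)| is taken by
    the trapezoidal rule on the native grid with interpolated endpoints.
    """
    lam = spectrum.wavelengths
    lo, hi = CHORD_ENDPOINTS_NM
    if lam[0] > lo or lam[-1] < hi:
        raise ValueError(
            f"spectrum grid [{lam[0]:g}, {lam[-1]:g}] nm does not cover the "
            f"chord band [{lo:g}, {hi:g}] nm"
        )
    vals = spectrum.channel(channel).astype(float)
    if normalize:
        inc = included_mask(lam)
        mean = vals[inc].mean()
        if mean <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        vals = vals / mean

    v_lo = float(np.interp(lo, lam, vals))
    v_hi = float(np.interp(hi, lam, vals))
    sel = (lam > lo) & (lam < hi)
    band_lam = np.concatenate(([lo], lam[sel], [hi]))
    band_val = np.concatenate(([v_lo], vals[sel], [v_hi]))
    chord = v_lo + (v_hi - v_lo) * (band_lam - lo) / (hi - lo)
    area = float(abs(np.trapezoid(chord - band_val, band_lam)))
    return HemeAreaResult(
        heme_area=area,
        endpoints_nm=(lo, hi),
        endpoint_values=(v_lo, v_hi),
        included=area > threshold,
        threshold=threshold,
        channel=channel,
    )
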
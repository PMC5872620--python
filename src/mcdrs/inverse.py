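"""Inverse problem: fit the skin-model parameters to measured dual-channel
DRS spectra.

The fit is shape-driven: measured and modeled spectra are each normalized
by their mean over the included band per channel, compared on a log scale,
and weighted so that the 500-600 nm hemoglobin absorption bands dominate
the residual.  A multistep strategy (coarse Latin-hypercube screening on a
thinned grid, trust-region-reflective refinement of the best starts, final
polish at full resolution) makes the search robust to local minima while
staying deterministic for a given seed.

Internally the scattering magnitude is parameterized by mus' at 600 nm and
the epidermal absorber by mu_a,epi at 525 nm; both are converted back to
the model's alpha / fmel after the fit.  This keeps the optimization box
well-scaled and nearly uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from dataclasses import replace as dc_replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .chromophores import MELANIN_SCALE, AbsorptionTable, hb_liquid, hbo2_liquid
from .forward import Spectrum, forward_spectra, included_mask
from .quality import HemeAreaResult, heme_area
from .tissue import (
    ParameterBounds,
    SkinModelParams,
    alpha_from_musp,
    build_layer_stack,
    reduced_scattering,
)
from .transport import PathLengthLUT

__all__ = ["FitConfig", "FitResult", "QualityError", "error_function", "fit", "fit_batch"]

_SCAT_REF_NM = 600.0
_EPI_REF_NM = 525.0

#: Free parameters per fit mode (order defines the optimization vector).
_MODE_FREE = {
    "liquid-phantom": ("musp600", "beta", "gamma", "cheme", "so2", "d_vessel"),
    "solid-phantom": ("tepi", "musp600", "beta", "gamma", "cheme", "so2",
                      "mua_epi525", "gamma_mel"),
    "in-vivo": ("tepi", "musp600", "beta", "gamma", "cheme1", "cheme2", "so2",
                "d_vessel", "mua_epi525", "gamma_mel"),
}


class QualityError(ValueError):
    """Raised for spectra too degenerate to fit (flat or non-positive)."""


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the inverse fit; defaults are desk-scale sensible."""

    bounds: ParameterBounds | None = None
    heme_band_nm: tuple = (500.0, 600.0)
    heme_weight: float = 3.0
    n_starts: int = 32
    refine_top: int = 3
    coarse_thin: int = 4
    refine_thin: int = 2
    max_nfev_refine: int = 600
    max_nfev_polish: int = 300
    tol: float = 1e-8
    seed: int = 0
    hb: AbsorptionTable | None = None
    hbo2: AbsorptionTable | None = None
    hull_penalty: float = 30.0
    #: Compare mean-normalized spectra (scale-invariant, the default) or
    #: absolute log-intensities (for instruments/simulations with a
    #: calibrated intensity scale, where the absolute level carries
    #: scattering information).
    normalize: bool = True

    def tables(self):
        return self.hb or hb_liquid(), self.hbo2 or hbo2_liquid()


@dataclass
class FitResult:
    """Recovered parameters plus residual and quality diagnostics."""

    params: SkinModelParams | None
    mode: str
    success: bool
    cost: float
    so2_percent: float
    frbc1: float
    frbc2: float
    d_um: float
    musp_fit: np.ndarray | None       # mus'(lam) on the measured grid
    residual: np.ndarray | None
    modeled: Spectrum | None
    heme: HemeAreaResult | None
    included: bool
    start_costs: np.ndarray
    nfev: int
    status: int
    message: str


def _mode_bounds(config: FitConfig, mode: str) -> ParameterBounds:
    """Default box constraints; solid phantoms may lack the top slab, so
    their epidermis thickness is allowed down to zero (in vivo keeps a
    physiological floor)."""
    if config.bounds is not None:
        return config.bounds
    if mode == "solid-phantom":
        return ParameterBounds(tepi=(0.0, 600.0))
    return ParameterBounds()


def _bound_tuple(bounds: ParameterBounds, name: str):
    if name in ("cheme", "cheme1", "cheme2"):
        return bounds.cheme
    return getattr(bounds, name)


def _params_from_free(free: dict, mode: str) -> SkinModelParams:
    beta = free.get("beta", 1.0)
    gamma = free.get("gamma", 0.0)
    alpha = alpha_from_musp(free["musp600"], _SCAT_REF_NM, beta, gamma)
    gmel = free.get("gamma_mel", 3.0)
    mua_epi = free.get("mua_epi525", 0.0)
    fmel = mua_epi / (MELANIN_SCALE * _EPI_REF_NM ** (-gmel))
    if mode == "liquid-phantom":
        return SkinModelParams(
            tepi=0.0, alpha=alpha, beta=beta, gamma=gamma,
            cheme1=free["cheme"], cheme2=free["cheme"], so2=free["so2"],
            d_vessel=free["d_vessel"], fmel=0.0, gamma_mel=gmel,
        )
    if mode == "solid-phantom":
        return SkinModelParams(
            tepi=free["tepi"], alpha=alpha, beta=beta, gamma=gamma,
            cheme1=free["cheme"], cheme2=free["cheme"], so2=free["so2"],
            d_vessel=0.0, fmel=fmel, gamma_mel=gmel,
        )
    return SkinModelParams(
        tepi=free["tepi"], alpha=alpha, beta=beta, gamma=gamma,
        cheme1=free["cheme1"], cheme2=free["cheme2"], so2=free["so2"],
        d_vessel=free["d_vessel"], fmel=fmel, gamma_mel=gmel,
    )


def _weight_profile(lam: np.ndarray, config: FitConfig) -> np.ndarray:
    w = np.ones_like(lam)
    lo, hi = config.heme_band_nm
    w[(lam >= lo) & (lam <= hi)] = config.heme_weight
    w[~included_mask(lam)] = 0.0
    return w


def _log_normalized(values: np.ndarray, weight: np.ndarray,
                    normalize: bool = True) -> np.ndarray:
    if normalize:
        sel = weight > 0
        mean = values[sel].mean()
        if mean <= 0:
            raise QualityError("spectrum has non-positive mean over the fit band")
        values = values / mean
    return np.log(np.maximum(values, 1e-12))


def error_function(measured: Spectrum, modeled: Spectrum,
                   weight_profile=None, config: FitConfig | None = None) -> np.ndarray:
    """Weighted residual vector between two spectra on a common grid.

    Per channel: both spectra are divided by their mean over the included
    band, the difference of the logs is taken, multiplied by the weight
    profile (default: 3x in the 500-600 nm heme band, 0 in the notch band),
    and the channels are concatenated.  Scale-invariant per channel by
    construction.
    """
    if measured.wavelengths.shape != modeled.wavelengths.shape or np.any(
        measured.wavelengths != modeled.wavelengths
    ):
        raise ValueError("measured and modeled spectra must share one wavelength grid")
    if measured.channels != modeled.channels:
        raise ValueError("measured and modeled spectra must share channels")
    lam = measured.wavelengths
    w = (np.asarray(weight_profile, dtype=float) if weight_profile is not None
         else _weight_profile(lam, config or FitConfig()))
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    norm = config.normalize if config is not None else True
    out = []
    for c in range(len(measured.channels)):
        r = _log_normalized(measured.values[c], w, norm) - _log_normalized(
            modeled.values[c], w, norm
        )
        out.append(w * r)
    return np.concatenate(out)


def _validate_measured(measured: Spectrum) -> None:
    frac_pos = np.mean(measured.values > 0)
    if frac_pos < 0.9:
        raise QualityError(
            f"only {100 * frac_pos:.0f}% of intensities are positive (need >= 90%)"
        )
    for c in range(measured.values.shape[0]):
        v = measured.values[c][measured.included]
        if v.max() <= 0 or (v.std() / max(v.mean(), 1e-300)) < 1e-6:
            raise QualityError("degenerate flat spectrum")


def fit(measured: Spectrum, lut: PathLengthLUT, config: FitConfig | None = None,
        mode: str = "in-vivo") -> FitResult:
    """Fit the model to one measured spectrum; deterministic given the seed."""
    config = config or FitConfig()
    if mode not in _MODE_FREE:
        raise ValueError(f"unknown fit mode {mode!r}")
    _validate_measured(measured)
    hb, hbo2 = config.tables()

    heme = None
    if "sds_1.2mm" in measured.channels and measured.wavelengths[0] <= 506.0 <= 614.0 <= measured.wavelengths[-1]:
        heme = heme_area(measured)

    names = _MODE_FREE[mode]
    bounds = _mode_bounds(config, mode)
    lo = np.array([_bound_tuple(bounds, n)[0] for n in names])
    hi = np.array([_bound_tuple(bounds, n)[1] for n in names])

    lam_full = measured.wavelengths
    w_full = _weight_profile(lam_full, config)
    glo, ghi = float(lut.musp_grid[0]), float(lut.musp_grid[-1])

    def make_residual(idx):
        lam = lam_full[idx]
        w = w_full[idx]
        meas_logn = np.vstack(
            [_log_normalized(measured.values[c][idx], w, config.normalize)
             for c in range(measured.values.shape[0])]
        )

        def residual(u):
            free = dict(zip(names, lo + u * (hi - lo)))
            params = _params_from_free(free, mode)
            musp = reduced_scattering(lam, params.alpha, params.beta, params.gamma)
            excess = np.maximum(musp - ghi, 0.0) + np.maximum(glo - musp, 0.0)
            stack = build_layer_stack(params, mode, hb, hbo2)
            if np.any(excess > 0):
                # soft hull handling: evaluate at the clipped scattering and
                # penalize the excess so the optimizer is pushed back inside
                orig_musp = stack.musp_func
                stack = dc_replace(
                    stack, musp_func=lambda l: np.clip(orig_musp(l), glo, ghi)
                )
            modeled = forward_spectra(stack, lut, lam)
            rows = []
            for c in range(modeled.values.shape[0]):
                mod_logn = _log_normalized(
                    np.maximum(modeled.values[c], 1e-300), w, config.normalize
                )
                rows.append(w * (mod_logn - meas_logn[c]))
            r = np.concatenate(rows)
            if np.any(excess > 0):
                r = np.concatenate([r, config.hull_penalty * excess])
            else:
                r = np.concatenate([r, np.zeros(lam.size)])
            return r

        return residual

    idx_all = np.arange(lam_full.size)
    res_coarse = make_residual(idx_all[:: config.coarse_thin])
    res_refine = make_residual(idx_all[:: config.refine_thin])
    res_full = make_residual(idx_all)

    sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
    starts = sampler.random(config.n_starts)
    start_costs = np.empty(config.n_starts)
    for k, u in enumerate(starts):
        try:
            r = res_coarse(u)
            start_costs[k] = 0.5 * float(r @ r)
        except (ValueError, FloatingPointError):
            start_costs[k] = np.inf

    order = np.argsort(start_costs, kind="stable")
    top = order[: max(1, config.refine_top)]

    candidates = []
    nfev = 0
    for k in top:
        if not np.isfinite(start_costs[k]):
            continue
        try:
            sol = least_squares(
                res_refine, starts[k], bounds=(0.0, 1.0), method="trf",
                diff_step=1e-4, xtol=config.tol, ftol=config.tol,
                gtol=config.tol, max_nfev=config.max_nfev_refine,
            )
            nfev += sol.nfev
            candidates.append(sol)
        except (ValueError, FloatingPointError):
            continue

    if not candidates:
        return FitResult(
            params=None, mode=mode, success=False, cost=np.inf,
            so2_percent=np.nan, frbc1=np.nan, frbc2=np.nan, d_um=np.nan,
            musp_fit=None, residual=None, modeled=None, heme=heme,
            included=bool(heme.included) if heme is not None else True,
            start_costs=start_costs, nfev=nfev, status=-1,
            message="no start converged",
        )

    # tie-break equal costs by the smaller bound-scaled parameter norm
    candidates.sort(key=lambda s: (s.cost, float(np.linalg.norm(s.x))))
    best = candidates[0]
    try:
        polish = least_squares(
            res_full, best.x, bounds=(0.0, 1.0), method="trf",
            diff_step=1e-4, xtol=config.tol, ftol=config.tol, gtol=config.tol,
            max_nfev=config.max_nfev_polish,
        )
        nfev += polish.nfev
    except (ValueError, FloatingPointError):
        polish = best

    free = dict(zip(names, lo + polish.x * (hi - lo)))
    params = _params_from_free(free, mode)
    stack = build_layer_stack(params, mode, hb, hbo2)
    modeled = forward_spectra(stack, lut, lam_full)
    residual = error_function(measured, modeled, w_full, config)
    musp_fit = reduced_scattering(lam_full, params.alpha, params.beta, params.gamma)
    from .tissue import frbc_from_cheme

    return FitResult(
        params=params, mode=mode, success=True,
        cost=0.5 * float(residual @ residual),
        so2_percent=100.0 * params.so2,
        frbc1=frbc_from_cheme(params.cheme1),
        frbc2=frbc_from_cheme(params.cheme2),
        d_um=params.d_vessel,
        musp_fit=musp_fit, residual=residual, modeled=modeled, heme=heme,
        included=bool(heme.included) if heme is not None else True,
        start_costs=start_costs, nfev=nfev, status=int(polish.status),
        message=str(polish.message),
    )


def fit_batch(spectra, lut: PathLengthLUT, config: FitConfig | None = None,
              mode: str = "in-vivo") -> list:
    """Fit a series of spectra independently, preserving order.

    Each item uses the same configuration (and seed), so identical spectra
    give identical results; per-item failures are isolated into failed
    FitResults rather than aborting the batch.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("empty spectrum series")
    out = []
    for sp in spectra:
        try:
            out.append(fit(sp, lut, config, mode))
        except (QualityError, ValueError) as exc:
            out.append(
                FitResult(
                    params=None, mode=mode, success=False, cost=np.inf,
                    so2_percent=np.nan, frbc1=np.nan, frbc2=np.nan,
                    d_um=np.nan, musp_fit=None, residual=None, modeled=None,
                    heme=None, included=False,
                    start_costs=np.array([]), nfev=0, status=-2,
                    message=f"fit failed: {exc}",
                )
            )
    return out
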
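"""Three-layer skin/phantom model: the 10 fit parameters and the per-layer
optical-property constructors.

The model stacks an epidermis of thickness ``tepi`` over a 200-um upper
dermis and a semi-infinite lower dermis.  All layers share one reduced
scattering spectrum

    mus'(lam) = alpha * [(1 - gamma) lam^-beta + gamma lam^-4]        (Mie + Rayleigh)

Epidermal absorption is melanin-like, fmel * 6.6e10 * lam^-gamma_mel.
Dermal absorption is hemoglobin at concentration cheme_n (g/dl), attenuated
by the vessel-packaging factor

    cvd = (1 - exp(-D mu_a,heme)) / (D mu_a,heme),   cvd -> 1 as D -> 0,

which accounts for blood being confined to discrete vessels of average
diameter D instead of homogeneously distributed.  The RBC tissue fraction
follows from cheme via the mean cell hemoglobin concentration of 31 g/dl.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chromophores import AbsorptionTable, hb_liquid, hbo2_liquid, mua_epidermis, mua_heme

__all__ = [
    "MEAN_CELL_HB_G_DL",
    "DERMIS1_THICKNESS_UM",
    "SkinModelParams",
    "ParameterBounds",
    "LayerStack",
    "reduced_scattering",
    "vessel_packaging",
    "mua_dermis",
    "frbc_from_cheme",
    "cheme_from_frbc",
    "build_layer_stack",
]

#: Mean cell hemoglobin concentration assumed for RBCs, g/dl.
MEAN_CELL_HB_G_DL = 31.0

#: Thickness of the upper dermis layer, um.
DERMIS1_THICKNESS_UM = 200.0


@dataclass(frozen=True)
class SkinModelParams:
    """The 10 variable model parameters.

    tepi : epidermis thickness, um
    alpha : scattering magnitude (mm^-1 * nm^beta scale)
    beta : Mie slope (dimensionless)
    gamma : Rayleigh fraction in [0, 1]
    cheme1, cheme2 : hemoglobin concentration in upper / lower dermis, g/dl
    so2 : hemoglobin oxygen saturation, fraction in [0, 1]
    d_vessel : average vessel diameter, um
    fmel : melanin fraction in the epidermis
    gamma_mel : melanin spectral slope
    """

    tepi: float
    alpha: float
    beta: float
    gamma: float
    cheme1: float
    cheme2: float
    so2: float
    d_vessel: float
    fmel: float
    gamma_mel: float

    def __post_init__(self) -> None:
        if self.tepi < 0:
            raise ValueError("tepi must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.cheme1 < 0 or self.cheme2 < 0:
            raise ValueError("cheme must be >= 0")
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError("so2 must lie in [0, 1]")
        if self.d_vessel < 0:
            raise ValueError("d_vessel must be >= 0")
        if self.fmel < 0:
            raise ValueError("fmel must be >= 0")

    def replace(self, **kw) -> "SkinModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints used by the inverse fit (all configurable).

    Scattering is bounded through musp at 600 nm rather than alpha directly,
    keeping the box meaningful across beta/gamma values.
    """

    tepi: tuple = (25.0, 600.0)
    musp600: tuple = (0.55, 3.9)      # mm^-1, inside the default LUT hull
    beta: tuple = (0.0, 4.0)
    gamma: tuple = (0.0, 1.0)
    cheme: tuple = (0.0, 10.0)        # g/dl
    so2: tuple = (0.0, 1.0)
    d_vessel: tuple = (0.0, 200.0)    # um
    mua_epi525: tuple = (0.0, 5.0)    # mm^-1, epidermal absorption at 525 nm
    gamma_mel: tuple = (2.0, 5.0)


def reduced_scattering(lam, alpha: float, beta: float, gamma: float):
    """mus'(lam) = alpha [(1-gamma) lam^-beta + gamma lam^-4], mm^-1, lam in nm."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    lam = np.asarray(lam, dtype=float)
    out = alpha * ((1.0 - gamma) * lam ** (-beta) + gamma * lam ** (-4.0))
    return out if out.ndim else float(out)


def alpha_from_musp(musp_ref: float, lam_ref: float, beta: float, gamma: float) -> float:
    """Scattering magnitude alpha giving mus'(lam_ref) = musp_ref."""
    shape = (1.0 - gamma) * lam_ref ** (-beta) + gamma * lam_ref ** (-4.0)
    return musp_ref / shape


def vessel_packaging(d_vessel_um: float, mua_heme_val) -> np.ndarray:
    """Vessel-packaging correction cvd = (1 - exp(-D mua)) / (D mua) in (0, 1].

    ``d_vessel_um`` is in um, ``mua_heme_val`` in mm^-1; the product uses D in
    mm.  The D*mua -> 0 limit evaluates exactly to 1 (expm1-based form).
    """
    if d_vessel_um < 0:
        raise ValueError("d_vessel must be >= 0")
    mua = np.asarray(mua_heme_val, dtype=float)
    if np.any(mua < 0):
        raise ValueError("mua_heme must be >= 0")
    x = (d_vessel_um * 1e-3) * mua
    out = np.ones_like(x)
    nz = x > 0
    out[nz] = -np.expm1(-x[nz]) / x[nz]
    return out if out.ndim else float(out)


def mua_dermis(lam, cheme_n: float, d_vessel_um: float, so2: float,
               hb: AbsorptionTable | None = None,
               hbo2: AbsorptionTable | None = None) -> np.ndarray:
    """Dermis absorption mu_a,n = (cheme_n / c_ref) cvd(lam) mu_a,heme(lam), mm^-1.

    ``cheme_n`` in g/dl is normalized by the tables' reference concentration;
    the packaging factor uses the full within-vessel blood absorption.
    """
    if cheme_n < 0:
        raise ValueError("cheme must be >= 0")
    hb = hb or hb_liquid()
    hbo2 = hbo2 or hbo2_liquid()
    mh = mua_heme(lam, so2, hb, hbo2)
    cvd = vessel_packaging(d_vessel_um, mh)
    return (cheme_n / hb.reference_concentration) * cvd * mh


def frbc_from_cheme(cheme_g_dl: float) -> float:
    """RBC tissue fraction from hemoglobin concentration: fRBC = cheme / 31 g/dl."""
    if cheme_g_dl < 0:
        raise ValueError("cheme must be >= 0")
    return cheme_g_dl / MEAN_CELL_HB_G_DL


def cheme_from_frbc(frbc: float) -> float:
    """Inverse of :func:`frbc_from_cheme`."""
    if frbc < 0:
        raise ValueError("frbc must be >= 0")
    return frbc * MEAN_CELL_HB_G_DL


@dataclass(frozen=True)
class LayerStack:
    """Resolved optical properties of the three model layers.

    ``thicknesses_mm`` holds (tepi, 0.2, inf).  ``mua_funcs`` are per-layer
    callables lam[nm] -> mm^-1; ``musp_func`` is shared by all layers.
    """

    thicknesses_mm: tuple
    mua_funcs: tuple
    musp_func: object
    refractive_index: float = 1.4
    params: SkinModelParams | None = None
    mode: str = "in-vivo"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.thicknesses_mm) != 3 or len(self.mua_funcs) != 3:
            raise ValueError("exactly 3 layers required")
        if self.thicknesses_mm[0] < 0 or self.thicknesses_mm[1] <= 0:
            raise ValueError("finite layer thicknesses must be positive")
        if not np.isinf(self.thicknesses_mm[2]):
            raise ValueError("last layer must be semi-infinite")

    @property
    def tepi_um(self) -> float:
        return self.thicknesses_mm[0] * 1e3

    def mua_matrix(self, lam) -> np.ndarray:
        """Per-layer absorption, shape (3, n_lam), mm^-1."""
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        return np.vstack([np.broadcast_to(f(lam), lam.shape) for f in self.mua_funcs])

    def musp(self, lam) -> np.ndarray:
        return self.musp_func(lam)


def build_layer_stack(params: SkinModelParams, mode: str = "in-vivo",
                      hb: AbsorptionTable | None = None,
                      hbo2: AbsorptionTable | None = None) -> LayerStack:
    """Resolve a parameter set into a three-layer stack of optical properties.

    Modes
    -----
    ``"in-vivo"``
        Full model, all parameters free.
    ``"solid-phantom"``
        Two-layer solid phantom: requires cheme1 == cheme2 and D == 0.
    ``"liquid-phantom"``
        Homogeneous medium: requires tepi == 0 and cheme1 == cheme2; all
        layers share the dermis properties (no epidermis present).
    """
    hb = hb or hb_liquid()
    hbo2 = hbo2 or hbo2_liquid()
    if mode not in ("in-vivo", "solid-phantom", "liquid-phantom"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "solid-phantom":
        if params.cheme1 != params.cheme2:
            raise ValueError("solid-phantom mode requires cheme1 == cheme2")
        if params.d_vessel != 0.0:
            raise ValueError("solid-phantom mode requires d_vessel == 0")
    if mode == "liquid-phantom":
        if params.tepi != 0.0:
            raise ValueError("liquid-phantom mode requires tepi == 0 (no epidermis)")
        if params.cheme1 != params.cheme2:
            raise ValueError("liquid-phantom mode requires a homogeneous medium")

    def musp_f(lam):
        return reduced_scattering(lam, params.alpha, params.beta, params.gamma)

    def mua_epi_f(lam):
        return np.broadcast_to(
            np.asarray(mua_epidermis(lam, params.fmel, params.gamma_mel), dtype=float),
            np.atleast_1d(np.asarray(lam, dtype=float)).shape,
        )

    def make_dermis(cheme):
        def f(lam):
            return mua_dermis(lam, cheme, params.d_vessel, params.so2, hb, hbo2)
        return f

    mua1 = make_dermis(params.cheme1)
    mua2 = make_dermis(params.cheme2)
    if mode == "liquid-phantom":
        funcs = (mua1, mua1, mua1)
    else:
        funcs = (mua_epi_f, mua1, mua2)
    tepi_mm = params.tepi * 1e-3
    if mode == "liquid-phantom":
        tepi_mm = 0.0
    return LayerStack(
        thicknesses_mm=(tepi_mm, DERMIS1_THICKNESS_UM * 1e-3, np.inf),
        mua_funcs=funcs,
        musp_func=musp_f,
        params=params,
        mode=mode,
    )
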
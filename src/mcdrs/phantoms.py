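"""Synthetic phantom experiments: the study conditions in software.

Two experiment families are emulated:

* liquid intralipid/blood phantoms whose oxygenation decays as yeast doses
  consume oxygen (pO2 160 mmHg downward, converted to SO2 through the
  Severinghaus dissociation curve), measured as a time series;
* a matrix of solid two-layered phantoms: epidermis-mimicking slabs (three
  coffee-surrogate absorber levels x three thicknesses, TiO2-like
  scattering) resting on thick dermis-mimicking slabs with two levels of
  spectrally damped freeze-dried hemoglobin, measured with four replicate
  probe placements each (2 bare-dermis + 18 layered = 20 combinations).

Ground truth for every generated spectrum is recorded alongside it; spectra
are produced by the package's own forward model on a supplied path-length
LUT with seeded replicate-level noise, so any (scenario, lut, seed) triple
is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .chromophores import (
    AbsorptionTable,
    build_solid_saturated_table,
    hb_liquid,
    severinghaus_so2,
)
from .forward import Spectrum, default_wavelength_grid, forward_spectra
from .tissue import (
    DERMIS1_THICKNESS_UM,
    LayerStack,
    SkinModelParams,
    alpha_from_musp,
    build_layer_stack,
    cheme_from_frbc,
)
from .transport import PathLengthLUT

__all__ = [
    "NoiseModel",
    "LiquidPhantomScenario",
    "SolidPhantomScenario",
    "LiquidExperimentResult",
    "SolidMeasurement",
    "SolidMatrixResult",
    "damped_hemoglobin",
    "simulate_liquid_experiment",
    "default_solid_scenarios",
    "solid_truth_stack",
    "simulate_solid_matrix",
]


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level acquisition noise: multiplicative Gaussian plus a
    small additive dark floor (relative to the channel mean)."""

    sigma_rel: float = 0.01
    dark_rel: float = 1e-4

    def __post_init__(self) -> None:
        if self.sigma_rel < 0 or self.dark_rel < 0:
            raise ValueError("noise levels must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = values * (1.0 + self.sigma_rel * rng.standard_normal(values.shape))
        dark = self.dark_rel * values.mean(axis=-1, keepdims=True)
        out = out + dark * rng.standard_normal(values.shape)
        return np.maximum(out, 0.0)


def damped_hemoglobin(table: AbsorptionTable | None = None, damping: float = 0.7,
                      window_nm: float = 60.0) -> AbsorptionTable:
    """Spectrally damped hemoglobin emulating freeze-dried Hb in silicone.

    Convex blend of the liquid table with its own running-mean baseline:
    damping 0 returns the table unchanged, damping 1 the fully smoothed
    baseline; intermediate values attenuate the 500-600 nm peak structure
    while preserving the overall magnitude.
    """
    if not 0.0 <= damping <= 1.0:
        raise ValueError("damping must lie in [0, 1]")
    table = table or hb_liquid()
    step = float(np.median(np.diff(table.wavelengths)))
    size = max(1, int(round(window_nm / step)))
    smooth = uniform_filter1d(table.mua, size=size, mode="nearest")
    mua = (1.0 - damping) * table.mua + damping * smooth
    return AbsorptionTable(
        table.wavelengths.copy(), mua, "Hb_solid", table.reference_concentration,
        {"damping": str(damping), "window_nm": str(window_nm)},
    )


# ---------------------------------------------------------------------------
# liquid phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LiquidPhantomScenario:
    """Homogeneous intralipid/blood/yeast phantom with decaying oxygenation.

    The pO2 trace follows dpO2/dt = -k * (cumulative yeast dose) * pO2 from
    160 mmHg; doses default to frequent small additions giving a smooth,
    monotone saturation decay over a 20-minute run.  Scattering is
    intralipid-like (steep Mie slope).
    """

    frbc: float = 0.008
    po2_init_mmhg: float = 160.0
    dose_times_min: tuple = tuple(float(t) for t in range(0, 20, 2))
    dose_strength: float = 0.3              # yeast packets per addition
    decay_k_per_min: float = 0.15           # per packet
    musp500: float = 2.8                    # mm^-1 at 500 nm
    beta: float = 2.4
    gamma: float = 0.0
    temperature_c: float = 37.0
    acquisition_interval_s: float = 60.0
    duration_min: float = 20.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.frbc <= 0.05:
            raise ValueError("frbc must lie in (0, 0.05]")
        if self.po2_init_mmhg < 0:
            raise ValueError("initial pO2 must be >= 0")
        if self.dose_strength < 0 or self.decay_k_per_min < 0:
            raise ValueError("doses and decay rate must be non-negative")

    @property
    def cheme_g_dl(self) -> float:
        return cheme_from_frbc(self.frbc)

    def po2_at(self, t_min) -> np.ndarray:
        """Piecewise-exponential pO2 decay driven by the cumulative dose."""
        t_min = np.atleast_1d(np.asarray(t_min, dtype=float))
        events = np.asarray(sorted(self.dose_times_min), dtype=float)
        out = np.empty_like(t_min)
        for i, t in enumerate(t_min):
            knots = np.concatenate([[0.0], events[events < t], [t]])
            knots = np.unique(knots)
            decay = 0.0
            for a, b in zip(knots[:-1], knots[1:]):
                cum = self.dose_strength * np.sum(events <= a)
                decay += self.decay_k_per_min * cum * (b - a)
            out[i] = self.po2_init_mmhg * np.exp(-decay)
        return out

    def acquisition_times_min(self) -> np.ndarray:
        n = int(round(self.duration_min * 60.0 / self.acquisition_interval_s))
        return (np.arange(n) + 1) * self.acquisition_interval_s / 60.0

    def truth_params(self, so2_fraction: float) -> SkinModelParams:
        alpha = alpha_from_musp(self.musp500, 500.0, self.beta, self.gamma)
        c = self.cheme_g_dl
        return SkinModelParams(
            tepi=0.0, alpha=alpha, beta=self.beta, gamma=self.gamma,
            cheme1=c, cheme2=c, so2=so2_fraction, d_vessel=0.0,
            fmel=0.0, gamma_mel=3.0,
        )


@dataclass
class LiquidExperimentResult:
    scenario: LiquidPhantomScenario
    times_min: np.ndarray
    po2_mmhg: np.ndarray
    so2_truth_percent: np.ndarray
    truth_params: list
    spectra: list


def simulate_liquid_experiment(
    scenario: LiquidPhantomScenario,
    lut: PathLengthLUT,
    wavelengths=None,
) -> LiquidExperimentResult:
    """Generate the liquid-phantom time series (truth + noisy spectra)."""
    lam = default_wavelength_grid() if wavelengths is None else np.asarray(
        wavelengths, dtype=float
    )
    times = scenario.acquisition_times_min()
    po2 = scenario.po2_at(times)
    so2 = np.asarray(severinghaus_so2(po2), dtype=float)
    truths, spectra = [], []
    for i, (t, s) in enumerate(zip(times, so2)):
        params = scenario.truth_params(s / 100.0)
        stack = build_layer_stack(params, "liquid-phantom")
        clean = forward_spectra(stack, lut, lam)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(scenario.seed), 101, i])
        )
        noisy = scenario.noise.apply(clean.values, rng)
        truths.append(params)
        spectra.append(
            Spectrum(lam, noisy, channels=clean.channels,
                     meta={"t_min": float(t), "po2_mmhg": float(po2[i])})
        )
    return LiquidExperimentResult(
        scenario=scenario, times_min=times, po2_mmhg=po2,
        so2_truth_percent=so2, truth_params=truths, spectra=spectra,
    )


# ---------------------------------------------------------------------------
# solid two-layered phantoms
# ---------------------------------------------------------------------------

#: Epidermis-slab thicknesses (um) per coffee level, as fabricated.
SOLID_THICKNESSES_UM = {
    "no coffee": (90.0, 155.0, 270.0),
    "low coffee": (75.0, 160.0, 260.0),
    "high coffee": (70.0, 160.0, 210.0),
}

#: Coffee-surrogate absorption at 500 nm per level, mm^-1.
COFFEE_MUA500 = {"none": 0.0, "no coffee": 0.0, "low coffee": 0.6, "high coffee": 1.2}

#: Dermis-slab hemoglobin concentration per level, g/dl.
DERMIS_CHEME = {"low": 0.005, "high": 0.010}


@dataclass(frozen=True)
class SolidPhantomScenario:
    """One epidermis-on-dermis combination of the solid phantom matrix."""

    dermis_level: str = "high"              # "low" | "high" hemoglobin
    coffee_level: str = "none"              # "none" | "no coffee" | "low coffee" | "high coffee"
    tepi_um: float = 0.0                    # 0 => no epidermal slab
    cheme_g_dl: float | None = None
    coffee_mua500: float | None = None
    coffee_decay_nm: float = 140.0
    damping: float = 0.7
    musp500: float = 2.5                    # TiO2-like, mm^-1 at 500 nm
    beta: float = 0.9
    gamma: float = 0.0
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.dermis_level not in DERMIS_CHEME:
            raise ValueError(f"unknown dermis level {self.dermis_level!r}")
        if self.coffee_level not in COFFEE_MUA500:
            raise ValueError(f"unknown coffee level {self.coffee_level!r}")
        if self.tepi_um < 0:
            raise ValueError("tepi must be >= 0")
        if self.coffee_level == "none" and self.tepi_um != 0.0:
            raise ValueError("'none' epidermis means no slab: tepi must be 0")

    @property
    def label(self) -> str:
        if self.tepi_um == 0.0:
            return f"{self.dermis_level}-Hb dermis / bare"
        return (f"{self.dermis_level}-Hb dermis / {self.coffee_level} "
                f"{self.tepi_um:g} um")

    @property
    def cheme(self) -> float:
        return (self.cheme_g_dl if self.cheme_g_dl is not None
                else DERMIS_CHEME[self.dermis_level])

    @property
    def mua_epi500(self) -> float:
        return (self.coffee_mua500 if self.coffee_mua500 is not None
                else COFFEE_MUA500[self.coffee_level])

    def truth_params(self) -> SkinModelParams:
        """Model-space ground truth (SO2 = 0 by the saturated-ratio
        convention; coffee absorption is not a model parameter and lives in
        the truth stack only)."""
        alpha = alpha_from_musp(self.musp500, 500.0, self.beta, self.gamma)
        return SkinModelParams(
            tepi=self.tepi_um, alpha=alpha, beta=self.beta, gamma=self.gamma,
            cheme1=self.cheme, cheme2=self.cheme, so2=0.0, d_vessel=0.0,
            fmel=0.0, gamma_mel=3.0,
        )


def default_solid_scenarios(noise: NoiseModel | None = None,
                            damping: float = 0.7) -> list:
    """The 20 fabricated combinations: 2 bare dermis + 2 x 3 x 3 layered."""
    noise = noise or NoiseModel()
    out = []
    for dermis in ("low", "high"):
        out.append(SolidPhantomScenario(
            dermis_level=dermis, coffee_level="none", tepi_um=0.0,
            damping=damping, noise=noise,
        ))
        for coffee, thicknesses in SOLID_THICKNESSES_UM.items():
            for t in thicknesses:
                out.append(SolidPhantomScenario(
                    dermis_level=dermis, coffee_level=coffee, tepi_um=t,
                    damping=damping, noise=noise,
                ))
    return out


def solid_truth_stack(scenario: SolidPhantomScenario,
                      hb_solid: AbsorptionTable | None = None) -> LayerStack:
    """Ground-truth optical properties of one solid phantom combination.

    The dermis absorbs as the damped hemoglobin table scaled to the slab
    concentration (zero saturation by convention); the epidermis absorbs as
    the coffee surrogate, an exponentially decaying spectrum.  All layers
    share the TiO2-like reduced scattering (the fabrication targeted equal
    scattering in both slabs).
    """
    hb_solid = hb_solid or damped_hemoglobin(damping=scenario.damping)
    params = scenario.truth_params()

    def musp_f(lam):
        lam = np.asarray(lam, dtype=float)
        from .tissue import reduced_scattering
        return reduced_scattering(lam, params.alpha, params.beta, params.gamma)

    a500 = scenario.mua_epi500
    tau = scenario.coffee_decay_nm

    def mua_epi(lam):
        lam = np.asarray(lam, dtype=float)
        return a500 * np.exp(-(lam - 500.0) / tau)

    cref = hb_solid.reference_concentration
    c = scenario.cheme

    def mua_derm(lam):
        return (c / cref) * hb_solid(lam)

    return LayerStack(
        thicknesses_mm=(scenario.tepi_um * 1e-3, DERMIS1_THICKNESS_UM * 1e-3, np.inf),
        mua_funcs=(mua_epi, mua_derm, mua_derm),
        musp_func=musp_f,
        params=params,
        mode="solid-truth",
        meta={"label": scenario.label},
    )


@dataclass
class SolidMeasurement:
    scenario: SolidPhantomScenario
    replicate: int
    truth_params: SkinModelParams
    truth_stack: LayerStack
    spectrum: Spectrum


@dataclass
class SolidMatrixResult:
    measurements: list
    hb_solid: AbsorptionTable
    hbo2_solid: AbsorptionTable
    seed: int

    def spectra(self) -> list:
        return [m.spectrum for m in self.measurements]


def simulate_solid_matrix(
    scenarios,
    lut: PathLengthLUT,
    n_replicates: int = 4,
    seed: int = 0,
    wavelengths=None,
) -> SolidMatrixResult:
    """Generate the solid phantom matrix: replicate spectra plus truth.

    All scenarios must share one damping level (one freeze-dried hemoglobin
    batch); the damped table and its artificial saturated counterpart are
    returned with the dataset so a fit can use the matching chromophores.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("no scenarios supplied")
    dampings = {s.damping for s in scenarios}
    if len(dampings) != 1:
        raise ValueError("all scenarios must share one hemoglobin damping level")
    hb_solid = damped_hemoglobin(damping=dampings.pop())
    hbo2_solid = build_solid_saturated_table(hb_solid)
    lam = default_wavelength_grid() if wavelengths is None else np.asarray(
        wavelengths, dtype=float
    )
    measurements = []
    for i_sc, sc in enumerate(scenarios):
        stack = solid_truth_stack(sc, hb_solid)
        clean = forward_spectra(stack, lut, lam)
        for rep in range(n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 202, i_sc, rep])
            )
            noisy = sc.noise.apply(clean.values, rng)
            measurements.append(
                SolidMeasurement(
                    scenario=sc, replicate=rep,
                    truth_params=sc.truth_params(), truth_stack=stack,
                    spectrum=Spectrum(
                        lam, noisy, channels=clean.channels,
                        meta={"label": sc.label, "replicate": rep},
                    ),
                )
            )
    return SolidMatrixResult(
        measurements=measurements, hb_solid=hb_solid,
        hbo2_solid=hbo2_solid, seed=seed,
    )
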
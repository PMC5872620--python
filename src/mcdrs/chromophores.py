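"""Chromophore absorption spectra and oxygen-dissociation conversion.

Absorption tables carry the absorption coefficient mu_a (mm^-1) of a species
at a stated reference concentration (g/dl for hemoglobins).  The two shipped
hemoglobin tables are *synthetic re-tabulations*: monotone interpolations
through widely published visible/NIR extinction anchor values, with the
common isosbestic points pinned, at a whole-blood reference concentration of
15 g/dl.  They are not a copy of any single published compilation and can be
swapped for a measured table via the two-column text format documented in
:func:`read_absorption_table`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AbsorptionTable",
    "read_absorption_table",
    "write_absorption_table",
    "hb_liquid",
    "hbo2_liquid",
    "severinghaus_so2",
    "mua_heme",
    "mua_epidermis",
    "build_solid_saturated_table",
]

#: Scale constant of the melanin-like epidermal absorber,
#: mu_a(lambda) = fmel * 6.6e10 * lambda**(-gamma_mel), lambda in nm, mu_a in mm^-1.
MELANIN_SCALE = 6.6e10


@dataclass(frozen=True)
class AbsorptionTable:
    """Tabulated absorption coefficient of one chromophore species.

    Parameters
    ----------
    wavelengths : ndarray
        Strictly increasing wavelength grid in nm.
    mua : ndarray
        Absorption coefficient in mm^-1 at ``reference_concentration``.
    species : str
        Label, e.g. ``"Hb"``, ``"HbO2"``, ``"Hb_solid"``.
    reference_concentration : float
        Concentration (g/dl) at which ``mua`` is tabulated.
    """

    wavelengths: np.ndarray
    mua: np.ndarray
    species: str
    reference_concentration: float = 15.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        m = np.asarray(self.mua, dtype=float)
        if w.ndim != 1 or w.size < 2 or m.shape != w.shape:
            raise ValueError("wavelengths and mua must be 1-d arrays of equal length >= 2")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(m < 0):
            raise ValueError(f"negative mua in table {self.species!r}")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "mua", m)

    def __call__(self, lam) -> np.ndarray:
        """Linear interpolation of mu_a at wavelength(s) ``lam`` (nm).

        No extrapolation: wavelengths outside the tabulated range raise.
        """
        lam = np.asarray(lam, dtype=float)
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            bad = lam[(lam < lo) | (lam > hi)]
            raise ValueError(
                f"wavelength {np.atleast_1d(bad)[0]:g} nm outside table "
                f"{self.species!r} range [{lo:g}, {hi:g}] nm"
            )
        return np.interp(lam, self.wavelengths, self.mua)

    def scaled(self, factor: float, species: str | None = None) -> "AbsorptionTable":
        return AbsorptionTable(
            self.wavelengths.copy(),
            self.mua * factor,
            species or self.species,
            self.reference_concentration,
            dict(self.meta),
        )


def read_absorption_table(path) -> AbsorptionTable:
    """Read a two-column delimited table (wavelength_nm, mua_per_mm).

    Header lines start with ``#``; recognised keys are ``species`` and
    ``reference_concentration_g_dl``.
    """
    species = "unknown"
    cref = 15.0
    meta: dict = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                val = val.strip()
                if key == "species":
                    species = val
                elif key == "reference_concentration_g_dl":
                    cref = float(val)
                else:
                    meta.setdefault(key, val)
            continue
        parts = line.replace(",", "\t").split()
        rows.append((float(parts[0]), float(parts[1])))
    arr = np.array(rows, dtype=float)
    return AbsorptionTable(arr[:, 0], arr[:, 1], species, cref, meta)


def write_absorption_table(table: AbsorptionTable, path) -> None:
    with open(path, "w") as f:
        f.write(f"# species: {table.species}\n")
        f.write(f"# reference_concentration_g_dl: {table.reference_concentration}\n")
        f.write("# units: wavelength_nm\tmua_per_mm\n")
        for key, val in table.meta.items():
            f.write(f"# {key}: {val}\n")
        for l, m in zip(table.wavelengths, table.mua):
            f.write(f"{l:.6g}\t{m:.8g}\n")


def _load_packaged(fname: str) -> AbsorptionTable:
    ref = importlib.resources.files("mcdrs") / "data" / fname
    with importlib.resources.as_file(ref) as p:
        return read_absorption_table(p)


_CACHE: dict[str, AbsorptionTable] = {}


def hb_liquid() -> AbsorptionTable:
    """Reduced (deoxygenated) hemoglobin table for liquid blood, 15 g/dl."""
    if "hb" not in _CACHE:
        _CACHE["hb"] = _load_packaged("hb_deoxy_synthetic.tsv")
    return _CACHE["hb"]


def hbo2_liquid() -> AbsorptionTable:
    """Oxygenated hemoglobin table for liquid blood, 15 g/dl."""
    if "hbo2" not in _CACHE:
        _CACHE["hbo2"] = _load_packaged("hbo2_oxy_synthetic.tsv")
    return _CACHE["hbo2"]


def severinghaus_so2(po2) -> np.ndarray:
    """Hemoglobin oxygen saturation (%) from oxygen tension pO2 (mmHg).

    The empirical dissociation curve

        SO2 = 100 / (23400 / (pO2^3 + 150 pO2) + 1)

    at standard temperature/pH.  Strictly increasing, SO2(0) = 0 and
    SO2 -> 100 as pO2 -> inf.
    """
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("pO2 must be non-negative")
    denom = po2**3 + 150.0 * po2
    with np.errstate(divide="ignore"):
        so2 = 100.0 / (23400.0 / denom + 1.0)
    so2 = np.where(denom == 0.0, 0.0, so2)
    return so2 if so2.ndim else float(so2)


def mua_heme(lam, so2: float, hb: AbsorptionTable | None = None,
             hbo2: AbsorptionTable | None = None) -> np.ndarray:
    """Blood absorption (mm^-1) at saturation ``so2`` (fraction in [0, 1]).

    Convex combination (1 - SO2) * mu_a,Hb + SO2 * mu_a,HbO2 evaluated by
    linear interpolation of the two species tables at ``lam`` (nm).
    """
    if not 0.0 <= so2 <= 1.0:
        raise ValueError("so2 must lie in [0, 1]")
    hb = hb or hb_liquid()
    hbo2 = hbo2 or hbo2_liquid()
    return (1.0 - so2) * hb(lam) + so2 * hbo2(lam)


def mua_epidermis(lam, fmel: float, gamma_mel: float) -> np.ndarray:
    """Melanin-like epidermal absorption fmel * 6.6e10 * lam^(-gamma_mel) in mm^-1."""
    if fmel < 0:
        raise ValueError("fmel must be non-negative")
    lam = np.asarray(lam, dtype=float)
    out = fmel * MELANIN_SCALE * lam ** (-gamma_mel)
    return out if out.ndim else float(out)


def build_solid_saturated_table(
    hb_solid: AbsorptionTable,
    hb_liq: AbsorptionTable | None = None,
    hbo2_liq: AbsorptionTable | None = None,
) -> AbsorptionTable:
    """Artificial oxygenated counterpart of a solid-phantom hemoglobin table.

    mu_a,HbO2,solid = mu_a,Hb,solid * mu_a,HbO2,liquid / mu_a,Hb,liquid,
    pointwise on the solid table's grid: the oxy/deoxy spectral ratio of the
    liquid pair is transplanted onto the solid reduced spectrum, so a medium
    made of ``hb_solid`` alone corresponds to saturation zero by convention.
    """
    hb_liq = hb_liq or hb_liquid()
    hbo2_liq = hbo2_liq or hbo2_liquid()
    grid = hb_solid.wavelengths
    lo = max(grid[0], hb_liq.wavelengths[0], hbo2_liq.wavelengths[0])
    hi = min(grid[-1], hb_liq.wavelengths[-1], hbo2_liq.wavelengths[-1])
    if lo >= hi:
        raise ValueError("tables share no overlapping wavelength range")
    sel = (grid >= lo) & (grid <= hi)
    grid = grid[sel]
    denom = hb_liq(grid)
    if np.any(denom <= 0):
        lam_bad = grid[denom <= 0][0]
        raise ArithmeticError(
            f"mu_a,Hb,liquid is non-positive at {lam_bad:g} nm; ratio undefined"
        )
    mua = hb_solid.mua[sel] * hbo2_liq(grid) / denom
    return AbsorptionTable(
        grid, mua, "HbO2_solid", hb_solid.reference_concentration,
        {"derived_from": hb_solid.species},
    )
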
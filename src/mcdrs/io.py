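"""Text I/O: spectra, model parameter files, batch tables, run manifests.

All interchange formats are delimited text with ``#`` header lines, except
the path-length LUT which lives in its own HDF5 container (see
:mod:`mcdrs.transport`).
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import Spectrum
from .tissue import SkinModelParams

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_params_file",
    "read_params_file",
    "write_fit_table",
    "write_manifest",
]

_PARAM_UNITS = {
    "tepi": "um", "alpha": "mm^-1*nm^beta", "beta": "-", "gamma": "-",
    "cheme1": "g/dl", "cheme2": "g/dl", "so2": "fraction", "d_vessel": "um",
    "fmel": "fraction", "gamma_mel": "-",
}


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Delimited text: wavelength_nm then one intensity column per channel."""
    with open(path, "w") as f:
        f.write(f"# unit: {spectrum.unit}\n")
        f.write(f"# channels: {', '.join(spectrum.channels)}\n")
        for k, v in spectrum.meta.items():
            f.write(f"# {k}: {v}\n")
        cols = "\t".join(c.replace(".", "") for c in
                         ("wavelength_nm",) + spectrum.channels)
        f.write(cols + "\n")
        for i, lam in enumerate(spectrum.wavelengths):
            vals = "\t".join(f"{spectrum.values[c, i]:.8g}"
                             for c in range(spectrum.values.shape[0]))
            f.write(f"{lam:.6g}\t{vals}\n")


def read_spectrum(path) -> Spectrum:
    unit = "relative_intensity"
    channels = None
    meta = {}
    header_seen = False
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            key, _, val = body.partition(":")
            key, val = key.strip(), val.strip()
            if key == "unit":
                unit = val
            elif key == "channels":
                channels = tuple(c.strip() for c in val.split(","))
            else:
                meta[key] = val
            continue
        if not header_seen and not line[0].isdigit():
            header_seen = True
            continue
        rows.append([float(x) for x in line.replace(",", "\t").split()])
    arr = np.array(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"{path}: expected wavelength plus >=1 intensity column")
    nch = arr.shape[1] - 1
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(nch))
    if len(channels) != nch:
        raise ValueError(
            f"{path}: header lists {len(channels)} channels but file has {nch}"
        )
    return Spectrum(arr[:, 0], arr[:, 1:].T, channels=channels, unit=unit, meta=meta)


def write_params_file(params: SkinModelParams, path, extra: dict | None = None) -> None:
    """Flat key/value text with explicit units."""
    with open(path, "w") as f:
        f.write("# mcdrs skin-model parameters\n")
        for fld in fields(SkinModelParams):
            val = getattr(params, fld.name)
            f.write(f"{fld.name} = {val!r}  # {_PARAM_UNITS[fld.name]}\n")
        for k, v in (extra or {}).items():
            f.write(f"# {k}: {v}\n")


def read_params_file(path) -> SkinModelParams:
    values = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed line {line!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _PARAM_UNITS:
            raise ValueError(f"{path}: unknown parameter {key!r}")
        values[key] = float(val.strip())
    missing = set(_PARAM_UNITS) - set(values)
    if missing:
        raise ValueError(f"{path}: missing parameters {sorted(missing)}")
    return SkinModelParams(**values)


def write_fit_table(results, path) -> None:
    """One row per fitted spectrum: parameters, derived outputs, quality."""
    rows = []
    for i, r in enumerate(results):
        row = {"index": i, "success": r.success, "mode": r.mode,
               "cost": r.cost, "nfev": r.nfev, "message": r.message}
        if r.params is not None:
            row.update(asdict(r.params))
            row.update(
                frbc1_pct=100.0 * r.frbc1, frbc2_pct=100.0 * r.frbc2,
                so2_pct=r.so2_percent,
            )
        if r.heme is not None:
            row.update(heme_area=r.heme.heme_area, included=r.included)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(path, command: str, config: dict) -> None:
    """Machine-readable record sufficient to regenerate the artifact."""
    import mcdrs

    payload = {
        "command": command,
        "config": config,
        "versions": {
            "mcdrs": mcdrs.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
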
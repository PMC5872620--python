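"""White Monte Carlo transport: path-length lookup tables for the probe.

Photon paths are presimulated without absorption ("white" Monte Carlo) on a
grid of epidermis thicknesses and reduced scattering values.  Each node
stores detected-photon records of per-layer path lengths; absorption is
applied afterwards with Beer-Lambert, which is exact per record.

Anisotropy is handled through the similarity relation: simulations run with
a Henyey-Greenstein phase function at g = 0.8 and mus = mus' / (1 - g), so
one mus' axis parameterizes the table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from ._kernels import mc_node

__all__ = [
    "ProbeGeometry",
    "NodeRecords",
    "PathLengthLUT",
    "simulate_node",
    "build_lut",
    "derive_node_seed",
    "DEFAULT_TEPI_GRID_UM",
    "DEFAULT_MUSP_GRID",
]

#: Default epidermis-thickness axis, um (spans bare phantoms to thick skin).
DEFAULT_TEPI_GRID_UM = (0.0, 75.0, 150.0, 300.0, 600.0)

#: Default reduced-scattering axis at the evaluation wavelength, mm^-1.
DEFAULT_MUSP_GRID = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class ProbeGeometry:
    """Fiber-optic probe: one source fiber, two detector fibers.

    Offsets are center-to-center source-detector separations in mm.  The
    numerical aperture applies to launch and acceptance cones; refraction at
    the tissue surface uses ``n_tissue`` against ``n_ambient``.
    """

    source_diameter_um: float = 200.0
    detector_offsets_mm: tuple = (0.4, 1.2)
    detector_diameter_um: float = 200.0
    numerical_aperture: float = 0.37
    n_tissue: float = 1.4
    n_ambient: float = 1.0
    g: float = 0.8

    def __post_init__(self) -> None:
        off = np.asarray(self.detector_offsets_mm, dtype=float)
        if np.any(off <= 0) or len(set(off.tolist())) != off.size:
            raise ValueError("detector offsets must be positive and distinct")
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError("numerical aperture must lie in (0, 1)")

    @property
    def channel_labels(self) -> tuple:
        return tuple(f"sds_{off:g}mm" for off in self.detector_offsets_mm)

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "source_diameter_um": self.source_diameter_um,
                "detector_offsets_mm": list(self.detector_offsets_mm),
                "detector_diameter_um": self.detector_diameter_um,
                "numerical_aperture": self.numerical_aperture,
                "n_tissue": self.n_tissue,
                "n_ambient": self.n_ambient,
                "g": self.g,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class NodeRecords:
    """Detected-photon records of one (tepi, mus') node and channel."""

    paths_mm: np.ndarray      # (n_stored, 3) per-layer path lengths
    zmax_mm: np.ndarray       # (n_stored,) maximum depth reached
    weights: np.ndarray       # (n_stored,) in (0, 1]
    n_seen: int               # detections before reservoir thinning
    n_photons: int
    seed: int

    @property
    def thinning_factor(self) -> float:
        n = len(self.weights)
        return self.n_seen / n if n else 1.0


def derive_node_seed(seed: int, i_tepi: int, i_musp: int) -> int:
    """Deterministic per-node RNG seed below 2**31."""
    return int(
        np.random.SeedSequence([int(seed), i_tepi, i_musp]).generate_state(1)[0]
        % (2**31 - 1)
    )


def simulate_node(
    geometry: ProbeGeometry,
    tepi_um: float,
    musp: float,
    n_photons: int,
    seed: int,
    mua_layers=(0.0, 0.0, 0.0),
    cap: int = 6000,
    smax_mm: float = 200.0,
    rmax_mm: float = 20.0,
):
    """Simulate one LUT node; returns (records per channel, escape weight).

    ``mua_layers`` defaults to zero (white simulation); non-zero values give
    a directly absorbing run, used as an independent oracle for the
    Beer-Lambert rescaling.  A non-scattering medium yields empty record
    sets: without scattering no light reaches the lateral detectors.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if tepi_um < 0:
        raise ValueError("tepi must be >= 0")
    offsets = np.asarray(geometry.detector_offsets_mm, dtype=float)
    if musp <= 0.0:
        empty = [
            NodeRecords(np.zeros((0, 3)), np.zeros(0), np.zeros(0), 0,
                        n_photons, seed)
            for _ in offsets
        ]
        return empty, 0.0
    mus = musp / (1.0 - geometry.g)
    z1 = tepi_um * 1e-3
    z2 = z1 + 0.2
    mua = np.asarray(mua_layers, dtype=float)
    S, Z, W, n_stored, n_seen, escape_w = mc_node(
        int(seed),
        int(n_photons),
        float(mus),
        float(geometry.g),
        float(geometry.n_tissue),
        float(geometry.n_ambient),
        float(z1),
        float(z2),
        float(geometry.source_diameter_um) * 5e-4,
        offsets,
        float(geometry.detector_diameter_um) * 5e-4,
        float(geometry.numerical_aperture),
        float(mua[0]),
        float(mua[1]),
        float(mua[2]),
        float(smax_mm),
        float(rmax_mm),
        int(cap),
    )
    records = []
    for c in range(offsets.size):
        n = int(n_stored[c])
        records.append(
            NodeRecords(S[c, :n].copy(), Z[c, :n].copy(), W[c, :n].copy(),
                        int(n_seen[c]), n_photons, seed)
        )
    return records, float(escape_w)


@dataclass
class PathLengthLUT:
    """Per-node detected-photon path-length records on a (tepi, mus') grid."""

    geometry: ProbeGeometry
    tepi_grid_um: np.ndarray
    musp_grid: np.ndarray
    nodes: list                      # nodes[i][j] -> list[NodeRecords] per channel
    n_photons: int
    seed: int
    smax_mm: float = 200.0

    _flat: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.tepi_grid_um = np.asarray(self.tepi_grid_um, dtype=float)
        self.musp_grid = np.asarray(self.musp_grid, dtype=float)
        for g in (self.tepi_grid_um, self.musp_grid):
            if g.size == 0 or np.any(np.diff(g) <= 0):
                raise ValueError("grid axes must be non-empty and strictly increasing")

    # -- interpolation -------------------------------------------------
    def tepi_bracket(self, tepi_um: float):
        """Lower/upper node indices and lower-node weight for a thickness."""
        g = self.tepi_grid_um
        if tepi_um < g[0] or tepi_um > g[-1]:
            raise ValueError(
                f"tepi {tepi_um:g} um outside LUT hull [{g[0]:g}, {g[-1]:g}]"
            )
        hi = int(np.searchsorted(g, tepi_um, side="left"))
        if g[hi] == tepi_um:
            return hi, hi, 1.0
        lo = hi - 1
        return lo, hi, float((g[hi] - tepi_um) / (g[hi] - g[lo]))

    def musp_bracket(self, musp: float):
        g = self.musp_grid
        if musp < g[0] or musp > g[-1]:
            raise ValueError(
                f"musp {musp:g} mm^-1 outside LUT hull [{g[0]:g}, {g[-1]:g}]"
            )
        hi = int(np.searchsorted(g, musp, side="left"))
        if g[hi] == musp:
            return hi, hi, 1.0
        lo = hi - 1
        return lo, hi, float((g[hi] - musp) / (g[hi] - g[lo]))

    def interpolate_node(self, tepi_um: float, musp: float):
        """Bilinear mixture weights over the (up to) 4 surrounding nodes."""
        i_lo, i_hi, wi = self.tepi_bracket(tepi_um)
        j_lo, j_hi, wj = self.musp_bracket(musp)
        out = []
        for i, w_i in ((i_lo, wi), (i_hi, 1.0 - wi)):
            if w_i == 0.0:
                continue
            for j, w_j in ((j_lo, wj), (j_hi, 1.0 - wj)):
                if w_j == 0.0:
                    continue
                out.append((i, j, w_i * w_j))
            if i_lo == i_hi:
                break
        return out

    # -- flattened arrays for the Beer-Lambert kernel ------------------
    def flat_arrays(self, channel: int):
        """Concatenated records + per-node scale for one detector channel.

        The scale folds reservoir thinning, 1/n_photons and the annulus ->
        fiber-face geometric factor r_det / (4 R), making mixed node sums a
        per-fiber relative intensity.
        """
        if channel not in self._flat:
            nt, nm = self.tepi_grid_um.size, self.musp_grid.size
            offsets = np.zeros((nt, nm, 2), dtype=np.int64)
            scale = np.zeros((nt, nm))
            chunks_s, chunks_z, chunks_w = [], [], []
            pos = 0
            r_det = self.geometry.detector_diameter_um * 5e-4
            off_mm = self.geometry.detector_offsets_mm[channel]
            geom_factor = r_det / (4.0 * off_mm)
            for i in range(nt):
                for j in range(nm):
                    rec: NodeRecords = self.nodes[i][j][channel]
                    n = len(rec.weights)
                    offsets[i, j] = (pos, pos + n)
                    scale[i, j] = (
                        rec.thinning_factor * geom_factor / rec.n_photons
                    )
                    chunks_s.append(rec.paths_mm)
                    chunks_z.append(rec.zmax_mm)
                    chunks_w.append(rec.weights)
                    pos += n
            S = np.vstack(chunks_s) if pos else np.zeros((0, 3))
            Z = np.concatenate(chunks_z) if pos else np.zeros(0)
            Wt = np.concatenate(chunks_w) if pos else np.zeros(0)
            self._flat[channel] = (S, Z, Wt, offsets, scale)
        return self._flat[channel]

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Persist to a single HDF5 container with embedded metadata."""
        with h5py.File(path, "w") as f:
            f.attrs["format"] = "mcdrs-path-length-lut-v1"
            f.attrs["geometry_json"] = json.dumps(
                {
                    "source_diameter_um": self.geometry.source_diameter_um,
                    "detector_offsets_mm": list(self.geometry.detector_offsets_mm),
                    "detector_diameter_um": self.geometry.detector_diameter_um,
                    "numerical_aperture": self.geometry.numerical_aperture,
                    "n_tissue": self.geometry.n_tissue,
                    "n_ambient": self.geometry.n_ambient,
                    "g": self.geometry.g,
                }
            )
            f.attrs["fingerprint"] = self.geometry.fingerprint()
            f.attrs["n_photons"] = self.n_photons
            f.attrs["seed"] = self.seed
            f.attrs["smax_mm"] = self.smax_mm
            f.create_dataset("tepi_grid_um", data=self.tepi_grid_um)
            f.create_dataset("musp_grid", data=self.musp_grid)
            for i in range(self.tepi_grid_um.size):
                for j in range(self.musp_grid.size):
                    for c, rec in enumerate(self.nodes[i][j]):
                        grp = f.create_group(f"nodes/{i}/{j}/{c}")
                        grp.create_dataset("paths_mm", data=rec.paths_mm)
                        grp.create_dataset("zmax_mm", data=rec.zmax_mm)
                        grp.create_dataset("weights", data=rec.weights)
                        grp.attrs["n_seen"] = rec.n_seen
                        grp.attrs["n_photons"] = rec.n_photons
                        grp.attrs["seed"] = rec.seed

    @classmethod
    def load(cls, path) -> "PathLengthLUT":
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "mcdrs-path-length-lut-v1":
                raise IOError(f"{path}: not a mcdrs path-length LUT container")
            geom = ProbeGeometry(**{
                k: tuple(v) if isinstance(v, (list, np.ndarray)) else v
                for k, v in json.loads(f.attrs["geometry_json"]).items()
            })
            tepi = f["tepi_grid_um"][()]
            musp = f["musp_grid"][()]
            nch = len(geom.detector_offsets_mm)
            nodes = []
            for i in range(tepi.size):
                row = []
                for j in range(musp.size):
                    chans = []
                    for c in range(nch):
                        grp = f[f"nodes/{i}/{j}/{c}"]
                        chans.append(
                            NodeRecords(
                                grp["paths_mm"][()],
                                grp["zmax_mm"][()],
                                grp["weights"][()],
                                int(grp.attrs["n_seen"]),
                                int(grp.attrs["n_photons"]),
                                int(grp.attrs["seed"]),
                            )
                        )
                    row.append(chans)
                nodes.append(row)
            return cls(
                geometry=geom,
                tepi_grid_um=tepi,
                musp_grid=musp,
                nodes=nodes,
                n_photons=int(f.attrs["n_photons"]),
                seed=int(f.attrs["seed"]),
                smax_mm=float(f.attrs["smax_mm"]),
            )


def build_lut(
    geometry: ProbeGeometry = ProbeGeometry(),
    tepi_grid_um=DEFAULT_TEPI_GRID_UM,
    musp_grid=DEFAULT_MUSP_GRID,
    n_photons: int = 1_000_000,
    seed: int = 0,
    cap: int = 6000,
    smax_mm: float = 200.0,
    progress=None,
) -> PathLengthLUT:
    """Simulate every (tepi, mus') node and assemble the lookup table.

    Deterministic: node seeds derive from ``seed`` and the grid indices, so
    a 1x1 grid reproduces a direct :func:`simulate_node` call with
    ``derive_node_seed(seed, 0, 0)``.
    """
    tepi_grid_um = np.asarray(tepi_grid_um, dtype=float)
    musp_grid = np.asarray(musp_grid, dtype=float)
    nodes = []
    for i, tepi in enumerate(tepi_grid_um):
        row = []
        for j, musp in enumerate(musp_grid):
            node_seed = derive_node_seed(seed, i, j)
            recs, _ = simulate_node(
                geometry, float(tepi), float(musp), n_photons, node_seed,
                cap=cap, smax_mm=smax_mm,
            )
            row.append(recs)
            if progress is not None:
                progress(i, j)
        nodes.append(row)
    return PathLengthLUT(
        geometry=geometry,
        tepi_grid_um=tepi_grid_um,
        musp_grid=musp_grid,
        nodes=nodes,
        n_photons=n_photons,
        seed=seed,
        smax_mm=smax_mm,
    )
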
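"""Configurations, trajectories, topologies and tabular series.

Unit conventions used throughout the package: lengths in Å, times in ps,
temperatures in K (assay tables use °C at the I/O boundary and say so),
pressures in bar, surface tensions in mN m⁻¹.  Conversions happen only when
reading or writing files (e.g. GRO stores nm).

Slab geometry: boxes are orthorhombic; ``z`` is the interface normal and is
non-periodic by default (``periodic = (True, True, False)``).
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass
class Configuration:
    """A single snapshot: atom names, molecule ids, coordinates and box.

    Parameters
    ----------
    atom_names : array of str, shape (n,)
    molecule_ids : int array, shape (n,)
        Non-negative, 0-based molecule index per atom.
    coords : float array, shape (n, 3)
        Cartesian coordinates in Å.
    box : float array, shape (3,)
        Orthorhombic edge lengths (Lx, Ly, Lz) in Å.
    periodic : bool array, shape (3,)
        Per-axis periodicity flags; slab default ``(True, True, False)``.
    """

    atom_names: np.ndarray
    molecule_ids: np.ndarray
    coords: np.ndarray
    box: np.ndarray
    periodic: np.ndarray = field(default_factory=lambda: np.array([True, True, False]))

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.periodic = np.asarray(self.periodic, dtype=bool).reshape(3)
        n = len(self.coords)
        if len(self.atom_names) != n or len(self.molecule_ids) != n:
            raise ValueError(
                f"inconsistent lengths: {len(self.atom_names)} names, "
                f"{len(self.molecule_ids)} molecule ids, {n} coordinate rows"
            )
        if not np.all(self.box > 0):
            raise ValueError(f"box edges must be positive, got {self.box}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        if n and self.molecule_ids.min() < 0:
            raise ValueError("molecule ids must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def copy(self) -> "Configuration":
        return replace(
            self,
            atom_names=self.atom_names.copy(),
            molecule_ids=self.molecule_ids.copy(),
            coords=self.coords.copy(),
            box=self.box.copy(),
            periodic=self.periodic.copy(),
        )


@dataclass
class Trajectory:
    """Ordered frames with strictly increasing times (ps)."""

    frames: list
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("frame/time length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        n0 = self.frames[0].n_atoms if self.frames else 0
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != n0:
                raise ValueError(f"frame {k} has {fr.n_atoms} atoms, expected {n0}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class MoleculeTopology:
    """Role map per molecule.

    waters : list of (o, h1, h2) atom-index triples
    chols : list of (axis_tail, axis_head, hydroxyl_o, hydroxyl_h) tuples
        ``axis_tail`` is the C25-like site, ``axis_head`` the C3-like site.
    other : list of molecule ids not matching either role
    """

    waters: list
    chols: list
    other: list

    @property
    def water_oxygens(self) -> np.ndarray:
        return np.array([w[0] for w in self.waters], dtype=np.int64)

    @property
    def chol_oxygens(self) -> np.ndarray:
        return np.array([c[2] for c in self.chols], dtype=np.int64)


@dataclass
class TabularSeries:
    """Rectangular float table with declared units per column."""

    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"column {name!r} not present (have {list(self.data.columns)})")
        return self.data[name].to_numpy(dtype=float)


# --------------------------------------------------------------------------- #
# periodic displacement
# --------------------------------------------------------------------------- #


def minimum_image(dvec, box, periodic):
    """Minimum-image displacement honouring per-axis periodicity flags.

    With all flags false this is the raw difference.  Works on a single
    3-vector or an (n, 3) array.
    """
    d = np.array(dvec, dtype=float, copy=True)
    box = np.asarray(box, dtype=float)
    periodic = np.asarray(periodic, dtype=bool)
    for ax in range(3):
        if periodic[ax]:
            d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d


def wrap_coords(coords, box, periodic):
    """Wrap coordinates into [0, L) along periodic axes only."""
    c = np.array(coords, dtype=float, copy=True)
    for ax in range(3):
        if periodic[ax]:
            c[..., ax] %= box[ax]
    return c


# --------------------------------------------------------------------------- #
# extended XYZ
# --------------------------------------------------------------------------- #

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_PBC_RE = re.compile(r'pbc="([^"]+)"')


def _parse_xyz_ext(lines, path):
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:1: expected atom count, got {lines[0]!r}") from exc
    header = lines[1]
    m = _LATTICE_RE.search(header)
    if m is None:
        raise ParseError(f"{path}:2: missing Lattice=\"...\" header (plain XYZ is rejected)")
    lat = np.fromstring(m.group(1), sep=" ")
    if lat.size != 9:
        raise ParseError(f"{path}:2: Lattice must hold 9 numbers, got {lat.size}")
    lat = lat.reshape(3, 3)
    off = lat - np.diag(np.diag(lat))
    if np.any(np.abs(off) > 1e-10):
        raise ValueError(f"{path}: triclinic lattice not supported (orthorhombic only)")
    box = np.diag(lat).copy()
    pm = _PBC_RE.search(header)
    periodic = np.array([True, True, False])
    if pm:
        flags = pm.group(1).split()
        if len(flags) != 3:
            raise ParseError(f"{path}:2: pbc must hold 3 flags")
        periodic = np.array([f.upper() in ("T", "TRUE", "1") for f in flags])
    names, mols, coords = [], [], []
    for k in range(n):
        lineno = 3 + k
        try:
            parts = lines[2 + k].split()
        except IndexError as exc:
            raise ParseError(f"{path}:{lineno}: truncated file ({n} atoms declared)") from exc
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: expected 'name x y z [mol]', got {lines[2 + k]!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
            mol = int(parts[4]) if len(parts) > 4 else k
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
        names.append(parts[0])
        mols.append(mol)
        coords.append(xyz)
    return Configuration(names, mols, np.array(coords).reshape(-1, 3), box, periodic), 2 + n


def _format_xyz_ext(config: Configuration) -> str:
    b = config.box
    lat = f'Lattice="{b[0]:.10g} 0 0 0 {b[1]:.10g} 0 0 0 {b[2]:.10g}"'
    pbc = 'pbc="' + " ".join("T" if p else "F" for p in config.periodic) + '"'
    props = 'Properties=species:S:1:pos:R:3:mol:I:1'
    out = [str(config.n_atoms), f"{lat} {props} {pbc}"]
    for name, mol, (x, y, z) in zip(config.atom_names, config.molecule_ids, config.coords):
        out.append(f"{name} {x:.8f} {y:.8f} {z:.8f} {mol}")
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------- #
# GRO
# --------------------------------------------------------------------------- #


def _read_gro(path):
    import MDAnalysis as mda

    with open(path) as fh:
        title = fh.readline()
    u = mda.Universe(str(path))
    if u.dimensions is None:
        raise ParseError(f"{path}: missing box record")
    dims = u.dimensions
    if not np.allclose(dims[3:], 90.0):
        raise ValueError(f"{path}: triclinic box not supported (orthorhombic only)")
    box = np.asarray(dims[:3], dtype=float)
    if not np.all(box > 0):
        raise ParseError(f"{path}: missing or degenerate box record")
    periodic = np.array([True, True, False])
    pm = _PBC_RE.search(title)
    if pm:
        periodic = np.array([f.upper() in ("T", "TRUE", "1") for f in pm.group(1).split()])
    names = u.atoms.names.astype(object)
    mols = u.atoms.resids.astype(np.int64) - 1  # GRO is 1-based
    coords = u.atoms.positions.astype(float)  # MDAnalysis converts nm -> Å
    return Configuration(names, mols, coords, box, periodic)


def _format_gro(config: Configuration) -> str:
    pbc = 'pbc="' + " ".join("T" if p else "F" for p in config.periodic) + '"'
    lines = [f"icemono configuration {pbc}", f"{config.n_atoms}"]
    for i, (name, mol) in enumerate(zip(config.atom_names, config.molecule_ids)):
        resid = (int(mol) + 1) % 100000  # GRO field width
        atomid = (i + 1) % 100000
        x, y, z = config.coords[i] / 10.0  # Å -> nm
        resname = "SOL" if str(name).startswith(("O", "H", "M")) else "CHL"
        lines.append(f"{resid:5d}{resname:<5s}{str(name)[:5]:>5s}{atomid:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    bx, by, bz = config.box / 10.0
    lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------- #
# public I/O
# --------------------------------------------------------------------------- #

_FORMATS = ("xyz_ext", "gro")


def read_configuration(path, format: str = "xyz_ext") -> Configuration:
    """Read one configuration; coordinates are returned in Å."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    if format == "gro":
        return _read_gro(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    config, _ = _parse_xyz_ext(lines, str(path))
    return config


def write_configuration(config: Configuration, path, format: str = "xyz_ext") -> None:
    """Write a configuration; refuses empty configurations."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    if config.n_atoms == 0:
        raise ValueError("refusing to write an empty configuration")
    text = _format_xyz_ext(config) if format == "xyz_ext" else _format_gro(config)
    with open(path, "w") as fh:
        fh.write(text)


def read_trajectory(path, times=None) -> Trajectory:
    """Read a concatenated extended-XYZ trajectory."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames = []
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        config, used = _parse_xyz_ext(lines[pos:], str(path))
        frames.append(config)
        pos += used
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return Trajectory(frames, times)


def write_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(_format_xyz_ext(frame))


# --------------------------------------------------------------------------- #
# topology inference
# --------------------------------------------------------------------------- #


def infer_topology(config: Configuration, naming_scheme: str = "default",
                   strict: bool = False) -> MoleculeTopology:
    """Classify molecules as water, surrogate cholesterol, or other.

    The default scheme recognises waters by one O-name plus two H-names in a
    3-atom molecule, and surrogate cholesterol by the presence of both C25
    (tail) and C3 (head) axis sites plus a hydroxyl O/H pair.
    """
    if naming_scheme != "default":
        raise ValueError(f"unknown naming scheme {naming_scheme!r}")
    order = np.argsort(config.molecule_ids, kind="stable")
    sorted_mols = config.molecule_ids[order]
    waters, chols, other = [], [], []
    for mol in np.unique(config.molecule_ids):
        lo = np.searchsorted(sorted_mols, mol, side="left")
        hi = np.searchsorted(sorted_mols, mol, side="right")
        idx = order[lo:hi]
        names = [str(config.atom_names[i]) for i in idx]
        o_idx = [i for i, nm in zip(idx, names) if nm.upper().startswith("O")]
        h_idx = [i for i, nm in zip(idx, names) if nm.upper().startswith("H")]
        c_map = {nm.upper(): i for i, nm in zip(idx, names)}
        if len(idx) == 3 and len(o_idx) == 1 and len(h_idx) == 2:
            waters.append((int(o_idx[0]), int(h_idx[0]), int(h_idx[1])))
        elif "C25" in c_map and "C3" in c_map:
            if not o_idx or not h_idx:
                raise ValueError(f"molecule {mol}: surrogate cholesterol lacks hydroxyl O/H")
            chols.append((int(c_map["C25"]), int(c_map["C3"]), int(o_idx[0]), int(h_idx[0])))
        else:
            water_like = (o_idx or h_idx) and len(idx) >= 2 \
                and not any(nm.upper().startswith("C") for nm in names) \
                and len(idx) <= 4
            if water_like:
                raise ValueError(
                    f"molecule {mol}: water-like names {names} but not 1 O + 2 H"
                )
            if strict:
                raise ValueError(f"molecule {mol}: unrecognised atom names {names}")
            other.append(int(mol))
    return MoleculeTopology(waters, chols, other)


# --------------------------------------------------------------------------- #
# tabular series
# --------------------------------------------------------------------------- #


def read_series(path, columns=None, units=None) -> TabularSeries:
    """Read a delimited text table (comma or whitespace, header row)."""
    head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                head = line
                break
    sep = "," if "," in head else r"\s+"
    df = pd.read_csv(path, sep=sep, comment="#")
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise KeyError(f"missing column(s) {missing} in {path}")
        df = df[list(columns)]
    return TabularSeries(df.astype(float), dict(units or {}))


def write_series(series: TabularSeries, path) -> None:
    buf = _io.StringIO()
    if series.units:
        buf.write("# units: " + " ".join(f"{k}={v}" for k, v in series.units.items()) + "\n")
    series.data.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
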
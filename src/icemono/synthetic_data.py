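"""Synthetic inputs with planted ground truth.

Every generator is a pure function of its seed (identical seeds give
bit-identical outputs) and emits its ground truth alongside the data so
downstream analyses can be validated by recovery.

Defaults encode the study conditions this package targets: ideal ice
lattices built on a 2.75 Å O–O nearest-neighbour distance, water slabs of
up to 4752 molecules, monolayers of 64 two-site cholesterol surrogates per
leaflet (in-plane box edge √(n·S_A/mol), e.g. ≈67 Å at 70 Å²/mol), and
cold-stage assays of 96 droplets cooled from 0 to −30 °C at 1 °C min⁻¹
with a 0.5 K measurement grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay_stats import FreezingAssayData, make_grid
from .interface import PressureTrace
from .trajectory_io import Configuration, MoleculeTopology, Trajectory, minimum_image, wrap_coords

OO_DISTANCE = 2.75       # Å, ideal ice O–O nearest-neighbour distance
OH_BOND = 0.9572         # Å, rigid water geometry
HOH_ANGLE = 104.52       # deg


@dataclass
class ThermalState:
    """Simulation temperature relative to the model melting point (K)."""

    temperature: float
    melting_temperature: float = 270.0   # TIP4P/Ice-like default

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def supercooling(self) -> float:
        return self.melting_temperature - self.temperature


@dataclass
class AssayGroundTruth:
    """Known site-density function driving a simulated freezing assay.

    ``site_density_fn(T °C)`` is the cumulative number of active sites per
    substrate molecule at or above T (non-increasing in T);
    ``background_rate_fn(T °C)`` likewise, per droplet.
    """

    site_density_fn: object
    molecules_per_droplet: float
    background_rate_fn: object = None
    t_start: float = 0.0
    t_end: float = -30.0
    cooling_rate: float = 1.0
    n_droplets: int = 96
    bin_width: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("need at least one droplet")
        if self.molecules_per_droplet <= 0:
            raise ValueError("molecules_per_droplet must be positive")

    def lam(self, grid) -> np.ndarray:
        """Mean number of active sites per droplet at or above each grid T."""
        grid = np.asarray(grid, dtype=float)
        lam = self.molecules_per_droplet * np.array(
            [self.site_density_fn(t) for t in grid], dtype=float)
        if self.background_rate_fn is not None:
            lam = lam + np.array([self.background_rate_fn(t) for t in grid], dtype=float)
        if np.any(lam < 0):
            raise ValueError("site density must be non-negative")
        if np.any(np.diff(lam) < -1e-12):
            raise ValueError("cumulative site density must be non-increasing in T")
        return lam

    def true_nmol(self, grid) -> np.ndarray:
        return np.array([self.site_density_fn(t) for t in np.asarray(grid)], dtype=float)


# --------------------------------------------------------------------------- #
# rigid water placement
# --------------------------------------------------------------------------- #


def _water_h_offsets(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random rigid-water H offsets relative to O: shape (n, 2, 3)."""
    half = np.radians(HOH_ANGLE / 2)
    local = np.array([
        [np.sin(half), 0.0, np.cos(half)],
        [-np.sin(half), 0.0, np.cos(half)],
    ]) * OH_BOND
    # random rotations via QR of Gaussian matrices (Haar measure)
    mats = rng.standard_normal((n, 3, 3))
    q, r = np.linalg.qr(mats)
    q *= np.sign(np.einsum("nii->ni", r))[:, None, :]
    return np.einsum("nij,kj->nki", q, local)


def _assemble_waters(o_pos, h_off, box, periodic, mol_offset: int = 0) -> Configuration:
    n = len(o_pos)
    coords = np.empty((3 * n, 3))
    coords[0::3] = o_pos
    coords[1::3] = o_pos + h_off[:, 0]
    coords[2::3] = o_pos + h_off[:, 1]
    names = np.array(["OW", "HW1", "HW2"] * n, dtype=object)
    mols = mol_offset + np.repeat(np.arange(n), 3)
    return Configuration(names, mols, coords, box, periodic)


# --------------------------------------------------------------------------- #
# ideal ice lattices
# --------------------------------------------------------------------------- #


def _ic_cell(a: float):
    """Diamond-cubic oxygen basis in a cubic cell of edge a."""
    fcc = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    basis = np.concatenate([fcc, fcc + 0.25])
    return basis * a, np.array([a, a, a])


def _ih_cell(a: float):
    """Lonsdaleite oxygen basis in an orthohexagonal cell (a, a√3, c)."""
    c = a * np.sqrt(8.0 / 3.0)
    box = np.array([a, a * np.sqrt(3.0), c])
    lattice_xy = np.array([[0.0, 0.0], [0.5 * a, 0.5 * a * np.sqrt(3.0)]])
    d_a = np.array([0.0, 0.0])
    d_b = np.array([0.0, a / np.sqrt(3.0)])
    rows = []
    for lx, ly in lattice_xy:
        rows.append([lx + d_a[0], ly + d_a[1], 0.0])
        rows.append([lx + d_b[0], ly + d_b[1], c / 8.0])
        rows.append([lx + d_b[0], ly + d_b[1], c / 2.0])
        rows.append([lx + d_a[0], ly + d_a[1], 5.0 * c / 8.0])
    return np.array(rows), box


def ideal_lattice_parameter(polytype: str, d_oo: float = OO_DISTANCE) -> float:
    if polytype == "Ic":
        return 4.0 * d_oo / np.sqrt(3.0)
    if polytype == "Ih":
        return d_oo * np.sqrt(8.0 / 3.0)
    raise ValueError(f"unknown polytype {polytype!r}")


def build_ice_lattice(polytype: str, n_cells=(1, 1, 1), a: float | None = None,
                      noise_sigma: float = 0.0, seed: int = 0,
                      protons: bool = False) -> Configuration:
    """Ideal ice Ih/Ic oxygen lattice under full 3D periodicity.

    Optional Gaussian displacement noise and ice-rule proton decoration
    (each O carries two H; every O–O contact carries exactly one H).
    """
    n_cells = tuple(int(v) for v in n_cells)
    if any(v < 1 for v in n_cells):
        raise ValueError("n_cells must be ≥ 1 along every axis")
    if a is None:
        a = ideal_lattice_parameter(polytype)
    if a <= 0:
        raise ValueError("lattice parameter must be positive")
    basis, cell = (_ic_cell(a) if polytype == "Ic" else _ih_cell(a))
    shifts = np.array([[i, j, k] for i in range(n_cells[0])
                       for j in range(n_cells[1]) for k in range(n_cells[2])], dtype=float)
    o_pos = (shifts[:, None, :] * cell + basis[None, :, :]).reshape(-1, 3)
    box = cell * np.array(n_cells)
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        o_pos = o_pos + rng.normal(0.0, noise_sigma, o_pos.shape)
    o_pos = wrap_coords(o_pos, box, (True, True, True))
    n = len(o_pos)
    if not protons:
        names = np.array(["OW"] * n, dtype=object)
        return Configuration(names, np.arange(n), o_pos, box, (True, True, True))
    h_pairs = _decorate_protons(o_pos, box, rng)
    coords = np.empty((3 * n, 3))
    coords[0::3] = o_pos
    coords[1::3] = h_pairs[:, 0]
    coords[2::3] = h_pairs[:, 1]
    names = np.array(["OW", "HW1", "HW2"] * n, dtype=object)
    mols = np.repeat(np.arange(n), 3)
    return Configuration(names, mols, coords, box, (True, True, True))


def _decorate_protons(o_pos, box, rng, max_sweeps: int = 2000) -> np.ndarray:
    """Randomised ice-rule assignment: orient every O–O contact, then repair
    until every oxygen donates exactly two hydrogens."""
    from .order_params import neighbor_list_points

    n = len(o_pos)
    graph = neighbor_list_points(o_pos, box, (True, True, True), cutoff=1.2 * OO_DISTANCE,
                                 method="brute")
    counts = graph.neighbor_counts
    if np.any(counts != 4):
        raise ValueError(
            "O–O contact graph is not 4-regular (noise too large for proton decoration)"
        )
    pairs = graph.pairs
    m = len(pairs)
    orient = rng.integers(0, 2, m)          # 0: i donates, 1: j donates
    out_deg = np.zeros(n, dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        out_deg[i if orient[k] == 0 else j] += 1
    edge_order = np.arange(m)
    for _ in range(max_sweeps):
        if np.all(out_deg == 2):
            break
        rng.shuffle(edge_order)
        improved = False
        for k in edge_order:
            i, j = pairs[k]
            donor, acceptor = (i, j) if orient[k] == 0 else (j, i)
            # flip moves a donation from `donor` to `acceptor`
            before = (out_deg[donor] - 2) ** 2 + (out_deg[acceptor] - 2) ** 2
            after = (out_deg[donor] - 3) ** 2 + (out_deg[acceptor] - 1) ** 2
            if after < before:
                orient[k] = 1 - orient[k]
                out_deg[donor] -= 1
                out_deg[acceptor] += 1
                improved = True
        if not improved and not np.all(out_deg == 2):
            # random kick to escape a plateau
            k = rng.integers(0, m)
            i, j = pairs[k]
            donor, acceptor = (i, j) if orient[k] == 0 else (j, i)
            orient[k] = 1 - orient[k]
            out_deg[donor] -= 1
            out_deg[acceptor] += 1
    if not np.all(out_deg == 2):
        raise RuntimeError("ice-rule repair did not converge")
    h_pos = np.zeros((n, 2, 3))
    slot = np.zeros(n, dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        donor = i if orient[k] == 0 else j
        other = j if orient[k] == 0 else i
        d = minimum_image(o_pos[other] - o_pos[donor], box, (True, True, True))
        h_pos[donor, slot[donor]] = o_pos[donor] + OH_BOND * d / np.linalg.norm(d)
        slot[donor] += 1
    return h_pos


# --------------------------------------------------------------------------- #
# liquid slab
# --------------------------------------------------------------------------- #


def build_liquid_slab(n_molecules: int, box, min_dist: float = 2.5, seed: int = 0,
                      z_range: tuple | None = None, max_attempts_per_molecule: int = 2000
                      ) -> Configuration:
    """Random sequential insertion of rigid waters (O–O ≥ min_dist under xy
    periodicity), randomly oriented.  ``z_range`` restricts the slab extent
    along the non-periodic axis (default: the whole box)."""
    box = np.asarray(box, dtype=float)
    periodic = np.array([True, True, False])
    rng = np.random.default_rng(seed)
    if n_molecules == 0:
        return Configuration(np.array([], dtype=object), np.array([], dtype=int),
                             np.zeros((0, 3)), box, periodic)
    z_lo, z_hi = (0.0, box[2]) if z_range is None else z_range
    cell = max(min_dist, 1e-6)
    buckets: dict = {}
    accepted = np.zeros((n_molecules, 3))
    n_acc = 0
    budget = n_molecules * max_attempts_per_molecule
    while n_acc < n_molecules and budget > 0:
        budget -= 1
        pos = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                        rng.uniform(z_lo, z_hi)])
        key = tuple((pos // cell).astype(int))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    kx = (key[0] + dx) % max(int(box[0] // cell), 1)
                    ky = (key[1] + dy) % max(int(box[1] // cell), 1)
                    for idx in buckets.get((kx, ky, key[2] + dz), ()):
                        d = minimum_image(accepted[idx] - pos, box, periodic)
                        if np.dot(d, d) < min_dist ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted[n_acc] = pos
            nx = max(int(box[0] // cell), 1)
            ny = max(int(box[1] // cell), 1)
            buckets.setdefault((key[0] % nx, key[1] % ny, key[2]), []).append(n_acc)
            n_acc += 1
    if n_acc < n_molecules:
        raise RuntimeError(
            f"could not place {n_molecules} molecules at min_dist={min_dist} "
            f"(placed {n_acc}); density infeasible for sequential insertion"
        )
    h_off = _water_h_offsets(rng, n_molecules)
    return _assemble_waters(accepted, h_off, box, periodic)


# --------------------------------------------------------------------------- #
# monolayer slab
# --------------------------------------------------------------------------- #

CHL_ROD_LENGTH = 17.0    # Å, C25→C3 span of the surrogate
CHL_HEAD_GAP = 3.0       # Å, head-to-water-surface offset
CHL_MIN_XY = 5.0         # Å, in-plane exclusion between surrogates


def build_monolayer_slab(n_chl: int = 64, s_a_per_mol: float = 70.0,
                         tilt_mean: float = 0.0, tilt_kappa: float = 100.0,
                         water_params: dict | None = None, seed: int = 0):
    """Two-leaflet surrogate cholesterol monolayer on a water slab.

    Each surrogate is a rigid rod (C25 tail → C3 head, hydroxyl O–H beyond
    the head) with its head toward the water.  Axis polar angles are drawn
    about ``tilt_mean`` (degrees, against the leaflet's water-pointing
    normal) with concentration ``tilt_kappa`` (von Mises–Fisher-like:
    angular spread ≈ 1/√κ).  In-plane box edge is √(n_chl · S_A/mol).

    Returns (Configuration, MoleculeTopology, ground_truth dict).
    """
    if n_chl < 1:
        raise ValueError("need at least one surrogate molecule per leaflet")
    if s_a_per_mol <= 0:
        raise ValueError("area per molecule must be positive")
    if not 0 <= tilt_mean <= 90:
        raise ValueError("tilt_mean must lie in [0, 90] degrees")
    rng = np.random.default_rng(seed)
    edge = float(np.sqrt(n_chl * s_a_per_mol))
    wp = dict(water_params or {})
    n_water = int(wp.get("n_molecules", max(64, int(0.8 * 0.0334 * edge * edge * 20))))
    thickness = float(wp.get("thickness", max(12.0, n_water / (0.0334 * edge * edge))))
    min_dist = float(wp.get("min_dist", 2.5))
    l_z = float(wp.get("l_z", thickness + 2 * (CHL_ROD_LENGTH + CHL_HEAD_GAP + 10.0) + 40.0))
    box = np.array([edge, edge, l_z])
    mid = l_z / 2.0
    z_lo, z_hi = mid - thickness / 2.0, mid + thickness / 2.0
    water = build_liquid_slab(n_water, box, min_dist=min_dist,
                              seed=int(rng.integers(2 ** 31)), z_range=(z_lo, z_hi))

    sigma = np.degrees(1.0 / np.sqrt(tilt_kappa)) if np.isfinite(tilt_kappa) else 0.0
    names, mols, coords = list(water.atom_names), list(water.molecule_ids), [water.coords]
    mol0 = n_water
    tilts_truth = []
    for leaflet, (surface_z, toward_water) in enumerate(
            [(z_hi, -1.0), (z_lo, +1.0)]):
        xy = _rsa_plane(n_chl, edge, CHL_MIN_XY, rng)
        theta = _draw_tilts(rng, n_chl, tilt_mean, sigma)
        phi = rng.uniform(0, 2 * np.pi, n_chl)
        tilts_truth.append(theta)
        # axis unit vector at polar angle theta from the water-pointing normal
        st, ct = np.sin(np.radians(theta)), np.cos(np.radians(theta))
        u = np.stack([st * np.cos(phi), st * np.sin(phi),
                      toward_water * ct], axis=1)  # C25 -> C3 direction
        # head sits CHL_HEAD_GAP outside the water surface, axis running away
        head_z = surface_z - toward_water * CHL_HEAD_GAP
        head = np.concatenate([xy, np.full((n_chl, 1), head_z)], axis=1)
        tail = head - CHL_ROD_LENGTH * u
        oxy = head + 1.4 * u
        hyd = oxy + 0.96 * u
        for k in range(n_chl):
            for nm, pos in (("C25", tail[k]), ("C3", head[k]), ("O1", oxy[k]),
                            ("H1", hyd[k])):
                names.append(nm)
                mols.append(mol0)
                coords.append(pos.reshape(1, 3))
            mol0 += 1
    config = Configuration(np.array(names, dtype=object), np.array(mols),
                           np.concatenate(coords), box, (True, True, False))
    from .trajectory_io import infer_topology

    topology = infer_topology(config)
    truth = {
        "tilt_mean": tilt_mean,
        "tilt_kappa": tilt_kappa,
        "tilts_deg": np.concatenate(tilts_truth),
        "s_a_per_mol": s_a_per_mol,
        "edge": edge,
        "midplane": mid,
        "water_surface_z": (z_lo, z_hi),
        "seed": seed,
    }
    return config, topology, truth


def _rsa_plane(n: int, edge: float, min_xy: float, rng) -> np.ndarray:
    pts = []
    for _ in range(200000):
        if len(pts) == n:
            break
        cand = rng.uniform(0, edge, 2)
        ok = True
        for p in pts:
            d = cand - p
            d -= edge * np.round(d / edge)
            if np.dot(d, d) < min_xy ** 2:
                ok = False
                break
        if ok:
            pts.append(cand)
    if len(pts) < n:
        raise RuntimeError(f"cannot place {n} molecules in-plane at {min_xy} Å exclusion")
    return np.array(pts)


def _draw_tilts(rng, n: int, mean: float, sigma: float) -> np.ndarray:
    theta = rng.normal(mean, sigma, n) if sigma > 0 else np.full(n, float(mean))
    # reflect into [0, 180]
    theta = np.abs(theta)
    theta = np.where(theta > 180, 360 - theta, theta)
    return theta


# --------------------------------------------------------------------------- #
# planted-nucleus trajectories
# --------------------------------------------------------------------------- #


def plant_nuclei_trajectory(base_slab: Configuration, nucleus_size: int,
                            z_density, n_frames: int, seed: int = 0,
                            z_range: tuple | None = None,
                            clear_dist: float = 2.6):
    """Frames of the base slab with an ideal-ice cluster planted at a z drawn
    from ``z_density`` (callable of z, or (edges, weights)); overlapping base
    waters are removed.  Returns (Trajectory, ground_truth list of dicts).
    """
    from .trajectory_io import infer_topology

    rng = np.random.default_rng(seed)
    topo = infer_topology(base_slab)
    if not topo.waters:
        raise ValueError("base slab contains no waters")
    box = base_slab.box
    # ideal-ice blueprint large enough to carve the nucleus from
    n_c = max(2, int(np.ceil((2.0 * (nucleus_size ** (1 / 3)) * OO_DISTANCE) /
                             ideal_lattice_parameter("Ic"))))
    blueprint = build_ice_lattice("Ic", (n_c, n_c, n_c), seed=0)
    center = blueprint.box / 2
    order = np.argsort(np.linalg.norm(
        minimum_image(blueprint.coords - center, blueprint.box, (True, True, True)),
        axis=1))
    if nucleus_size > len(order):
        raise ValueError("nucleus larger than the blueprint lattice")
    cluster0 = minimum_image(blueprint.coords[order[:nucleus_size]] - center,
                             blueprint.box, (True, True, True))
    extent = cluster0[:, 2].max() - cluster0[:, 2].min()
    w_o = base_slab.coords[topo.water_oxygens]
    slab_lo, slab_hi = w_o[:, 2].min(), w_o[:, 2].max()
    if extent > (slab_hi - slab_lo):
        raise ValueError("nucleus larger than the water slab")
    if z_range is None:
        z_range = (slab_lo + extent / 2, slab_hi - extent / 2)
    zg = np.linspace(z_range[0], z_range[1], 2049)
    zc = 0.5 * (zg[:-1] + zg[1:])
    if callable(z_density):
        w = np.array([z_density(z) for z in zc], dtype=float)
    else:
        edges, weights = z_density
        w = np.interp(zc, 0.5 * (np.asarray(edges)[:-1] + np.asarray(edges)[1:]),
                      np.asarray(weights, dtype=float))
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("z density must be non-negative with positive mass")
    p = w / w.sum()

    frames, truths = [], []
    for fr in range(n_frames):
        z0 = float(rng.choice(zc, p=p))
        x0 = rng.uniform(0, box[0])
        y0 = rng.uniform(0, box[1])
        rot = _random_rotation(rng)
        cluster = cluster0 @ rot.T + np.array([x0, y0, z0])
        keep = np.ones(len(topo.waters), dtype=bool)
        for k, pos in enumerate(w_o):
            d = minimum_image(cluster - pos, box, base_slab.periodic)
            if np.min(np.einsum("ij,ij->i", d, d)) < clear_dist ** 2:
                keep[k] = False
        kept = [topo.waters[k] for k in np.nonzero(keep)[0]]
        names, mols, coords = [], [], []
        mol = 0
        for (o, h1, h2) in kept:
            for nm, idx in (("OW", o), ("HW1", h1), ("HW2", h2)):
                names.append(nm)
                mols.append(mol)
                coords.append(base_slab.coords[idx])
            mol += 1
        # keep the water count constant across frames: re-insert as many
        # waters as were displaced, away from the nucleus
        n_removed = int((~keep).sum())
        if n_removed:
            existing = np.concatenate([w_o[keep], cluster])
            refill = _refill_waters(n_removed, existing, box, base_slab.periodic,
                                    (slab_lo, slab_hi), clear_dist, rng)
            h_ref = _water_h_offsets(rng, n_removed)
            for k in range(n_removed):
                for nm, pos in (("OW", refill[k]), ("HW1", refill[k] + h_ref[k, 0]),
                                ("HW2", refill[k] + h_ref[k, 1])):
                    names.append(nm)
                    mols.append(mol)
                    coords.append(pos)
                mol += 1
        h_off = _water_h_offsets(rng, nucleus_size)
        planted_first = mol
        for k in range(nucleus_size):
            for nm, pos in (("OW", cluster[k]), ("HW1", cluster[k] + h_off[k, 0]),
                            ("HW2", cluster[k] + h_off[k, 1])):
                names.append(nm)
                mols.append(mol)
                coords.append(pos)
            mol += 1
        coords = wrap_coords(np.array(coords), box, base_slab.periodic)
        frames.append(Configuration(np.array(names, dtype=object), np.array(mols),
                                    coords, box.copy(), base_slab.periodic.copy()))
        truths.append({
            "planted_molecules": list(range(planted_first, mol)),
            "com_z": z0,
            "frame": fr,
        })
    traj = Trajectory(frames, np.arange(n_frames, dtype=float))
    return traj, truths


def _refill_waters(n: int, existing, box, periodic, z_range, min_dist, rng,
                   max_attempts: int = 200000) -> np.ndarray:
    placed = []
    pool = np.asarray(existing)
    for _ in range(max_attempts):
        if len(placed) == n:
            break
        pos = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                        rng.uniform(*z_range)])
        d = minimum_image(pool - pos, box, periodic)
        if np.min(np.einsum("ij,ij->i", d, d)) < min_dist ** 2:
            continue
        if placed:
            d2 = minimum_image(np.array(placed) - pos, box, periodic)
            if np.min(np.einsum("ij,ij->i", d2, d2)) < min_dist ** 2:
                continue
        placed.append(pos)
    if len(placed) < n:
        raise RuntimeError("could not re-insert displaced waters")
    return np.array(placed)


def _random_rotation(rng) -> np.ndarray:
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# --------------------------------------------------------------------------- #
# pressure traces
# --------------------------------------------------------------------------- #


def generate_pressure_trace(mean_pxx: float, mean_pyy: float, mean_pzz: float,
                            sigma: float, n_samples: int, l_z: float,
                            seed: int = 0, dt: float = 1.0):
    """I.i.d. Gaussian pressure components; returns (PressureTrace, known γ
    in mN m⁻¹)."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    times = dt * np.arange(n_samples, dtype=float)
    pxx = rng.normal(mean_pxx, sigma, n_samples)
    pyy = rng.normal(mean_pyy, sigma, n_samples)
    pzz = rng.normal(mean_pzz, sigma, n_samples)
    gamma_true = (l_z / 2.0) * (mean_pzz - 0.5 * (mean_pxx + mean_pyy)) * 0.01
    return PressureTrace(times, pxx, pyy, pzz, l_z), float(gamma_true)


# --------------------------------------------------------------------------- #
# freezing assays
# --------------------------------------------------------------------------- #


def simulate_freezing_assay(truth: AssayGroundTruth) -> FreezingAssayData:
    """Singular-model assay on the measurement grid.

    Per droplet, the number of sites active at or above each grid T is
    Poisson with mean λ(T) = X·n_s(T) + background(T); the freezing
    temperature is the highest grid T with at least one active site, and
    droplets with none by the end of the ramp are censored.
    """
    grid = make_grid(truth.t_start, truth.t_end, truth.bin_width)
    lam = truth.lam(grid)
    rng = np.random.default_rng(truth.seed)
    increments = np.diff(np.concatenate([[0.0], lam]))
    draws = rng.poisson(lam=np.broadcast_to(increments, (truth.n_droplets, len(grid))))
    cum = np.cumsum(draws, axis=1)
    active = cum >= 1
    t_freeze = np.full(truth.n_droplets, np.nan)
    censored = np.ones(truth.n_droplets, dtype=bool)
    for d in range(truth.n_droplets):
        idx = np.argmax(active[d])
        if active[d, idx]:
            t_freeze[d] = grid[idx]
            censored[d] = False
    records = pd.DataFrame({
        "droplet_id": np.arange(truth.n_droplets),
        "t_freeze": t_freeze,
        "censored": censored,
    })
    return FreezingAssayData(records, truth.molecules_per_droplet,
                             t_start=truth.t_start, t_end=truth.t_end,
                             cooling_rate=truth.cooling_rate)
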
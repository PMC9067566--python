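"""Neighbour graphs and Steinhardt bond-orientational order parameters.

Water molecules are represented by their oxygen positions; hydrogens play no
role here.  The per-molecule invariant is

    q_lm(i) = (1/N_b(i)) Σ_j Y_lm(r̂_ij),
    q_l(i)  = sqrt( 4π/(2l+1) Σ_m |q_lm(i)|² ),

optionally locally averaged (coefficient vectors averaged over the molecule
and its neighbours before taking the modulus), which sharpens the contrast
between ice-like and liquid-like environments.  Ice-like molecules are those
whose (averaged) q_l exceeds a threshold calibrated on reference fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .trajectory_io import Configuration, minimum_image


@dataclass
class NeighborGraph:
    """Symmetric neighbour graph with minimum-image displacement vectors.

    ``pairs`` holds each undirected edge once as (i, j) with i < j;
    ``vectors[k]`` is the displacement from i to j for ``pairs[k]`` (Å).
    """

    n_atoms: int
    pairs: np.ndarray          # (m, 2) int
    vectors: np.ndarray        # (m, 3) float, i -> j
    cutoff: float
    periodic: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)
        self._adj = None

    @property
    def adjacency(self) -> list:
        """Neighbour index lists, one per atom."""
        if self._adj is None:
            adj = [[] for _ in range(self.n_atoms)]
            for i, j in self.pairs:
                adj[i].append(int(j))
                adj[j].append(int(i))
            self._adj = [sorted(a) for a in adj]
        return self._adj

    @property
    def neighbor_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_atoms, dtype=np.int64)
        for i, j in self.pairs:
            counts[i] += 1
            counts[j] += 1
        return counts

    def adjacency_sets(self) -> list:
        return [set(a) for a in self.adjacency]


@dataclass
class OrderParameterSet:
    """Per-molecule q_l values and complex coefficient vectors q_lm."""

    l: int
    q: np.ndarray              # (n,), NaN where undefined
    qlm: np.ndarray            # (n, 2l+1) complex, NaN rows where undefined
    neighbor_counts: np.ndarray
    variant: str = "q"         # "q" | "locally_averaged_q"

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.q)


@dataclass
class IceLabels:
    """Boolean ice-like label per molecule, with provenance."""

    ice_like: np.ndarray
    threshold: float
    variant: str

    def __post_init__(self) -> None:
        self.ice_like = np.asarray(self.ice_like, dtype=bool)


# --------------------------------------------------------------------------- #
# neighbour lists
# --------------------------------------------------------------------------- #


def _positions(config_or_coords):
    if isinstance(config_or_coords, Configuration):
        return config_or_coords.coords, config_or_coords.box, config_or_coords.periodic
    raise TypeError("expected a Configuration; use neighbor_list_points for raw arrays")


def neighbor_list_points(coords, box, periodic, cutoff: float,
                         method: str = "cell") -> NeighborGraph:
    """Neighbour graph over raw points (inclusive cutoff: d ≤ cutoff)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    box = np.asarray(box, dtype=float)
    periodic = np.asarray(periodic, dtype=bool)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if method == "brute":
        pairs, vectors = _brute_pairs(coords, box, periodic, cutoff)
    elif method == "cell":
        per_edges = box[periodic]
        if per_edges.size and cutoff > per_edges.min() / 2:
            raise ValueError(
                f"cutoff {cutoff} exceeds half the smallest periodic edge "
                f"({per_edges.min():.3f}); use method='brute'"
            )
        pairs, vectors = _cell_pairs(coords, box, periodic, cutoff)
    else:
        raise ValueError(f"unknown method {method!r}")
    return NeighborGraph(len(coords), pairs, vectors, cutoff, periodic.copy())


def neighbor_list(config: Configuration, cutoff: float, method: str = "cell",
                  subset=None) -> NeighborGraph:
    """Neighbour graph over a configuration (optionally a subset of atoms).

    With ``subset`` the graph indices refer to positions within the subset.
    """
    coords, box, periodic = _positions(config)
    if subset is not None:
        coords = coords[np.asarray(subset, dtype=np.int64)]
    return neighbor_list_points(coords, box, periodic, cutoff, method)


def _brute_pairs(coords, box, periodic, cutoff):
    n = len(coords)
    pairs, vectors = [], []
    if n < 2:
        return np.zeros((0, 2), dtype=np.int64), np.zeros((0, 3))
    # chunk rows to bound memory at ~n * chunk
    chunk = max(1, int(4e6 // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        d = coords[None, start:stop, :] - coords[:, None, :]  # i, row j
        d = minimum_image(d, box, periodic)
        dist = np.linalg.norm(d, axis=-1)
        ii, jj = np.nonzero(dist <= cutoff)
        keep = ii < (jj + start)
        ii, jj = ii[keep], jj[keep]
        pairs.append(np.stack([ii, jj + start], axis=1))
        vectors.append(d[ii, jj])
    return np.concatenate(pairs), np.concatenate(vectors)


def _cell_pairs(coords, box, periodic, cutoff):
    n = len(coords)
    if n < 2:
        return np.zeros((0, 2), dtype=np.int64), np.zeros((0, 3))
    wrapped = coords.copy()
    lo = np.zeros(3)
    span = box.astype(float).copy()
    for ax in range(3):
        if periodic[ax]:
            wrapped[:, ax] %= box[ax]
        else:
            lo[ax] = wrapped[:, ax].min()
            span[ax] = max(wrapped[:, ax].max() - lo[ax], 1e-9)
    ncell = np.maximum(1, np.floor(span / cutoff).astype(int))
    for ax in range(3):
        if periodic[ax] and ncell[ax] < 3:
            ncell[ax] = 1  # degenerate: single cell along this axis still correct
    cell_of = np.minimum(
        ((wrapped - lo) / (span / ncell)).astype(int), ncell - 1
    )
    buckets: dict = {}
    for idx, c in enumerate(map(tuple, cell_of)):
        buckets.setdefault(c, []).append(idx)
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    pairs, vectors = [], []
    for c, members in buckets.items():
        neigh_cells = set()
        for off in offsets:
            nc = []
            ok = True
            for ax in range(3):
                v = c[ax] + off[ax]
                if periodic[ax]:
                    v %= ncell[ax]
                elif not (0 <= v < ncell[ax]):
                    ok = False
                    break
                nc.append(v)
            if ok:
                neigh_cells.add(tuple(nc))
        cand = sorted({m for ncl in neigh_cells for m in buckets.get(ncl, [])})
        cand = np.array(cand, dtype=np.int64)
        mem = np.array(members, dtype=np.int64)
        d = coords[cand][None, :, :] - coords[mem][:, None, :]
        d = minimum_image(d, box, periodic)
        dist = np.linalg.norm(d, axis=-1)
        ii, jj = np.nonzero(dist <= cutoff)
        gi, gj = mem[ii], cand[jj]
        keep = gi < gj
        pairs.append(np.stack([gi[keep], gj[keep]], axis=1))
        vectors.append(d[ii[keep], jj[keep]])
    pairs = np.concatenate(pairs) if pairs else np.zeros((0, 2), dtype=np.int64)
    vectors = np.concatenate(vectors) if vectors else np.zeros((0, 3))
    # duplicates can arise when a pair is found from both endpoints' cells
    if len(pairs):
        key = pairs[:, 0] * n + pairs[:, 1]
        _, uniq = np.unique(key, return_index=True)
        pairs, vectors = pairs[uniq], vectors[uniq]
    return pairs, vectors


# --------------------------------------------------------------------------- #
# Steinhardt parameters
# --------------------------------------------------------------------------- #


def _qlm_from_graph(graph: NeighborGraph, l: int):
    n = graph.n_atoms
    qlm = np.zeros((n, 2 * l + 1), dtype=complex)
    counts = np.zeros(n, dtype=np.int64)
    if len(graph.pairs):
        vecs = np.concatenate([graph.vectors, -graph.vectors])
        srcs = np.concatenate([graph.pairs[:, 0], graph.pairs[:, 1]])
        r = np.linalg.norm(vecs, axis=1)
        if np.any(r == 0):
            raise ValueError("zero-length bond vector in neighbour graph")
        theta = np.arccos(np.clip(vecs[:, 2] / r, -1.0, 1.0))  # polar
        phi = np.arctan2(vecs[:, 1], vecs[:, 0])               # azimuth
        for mi, m in enumerate(range(-l, l + 1)):
            ylm = sph_harm_y(l, m, theta, phi)
            np.add.at(qlm, (srcs, np.full_like(srcs, mi)), ylm)
        np.add.at(counts, srcs, 1)
    with np.errstate(invalid="ignore"):
        qlm = np.where(counts[:, None] > 0, qlm / np.maximum(counts, 1)[:, None], np.nan)
    return qlm, counts


def _modulus(qlm, l):
    q = np.sqrt(4 * np.pi / (2 * l + 1) * np.sum(np.abs(qlm) ** 2, axis=1))
    return q


def steinhardt_q(config_or_graph, graph: NeighborGraph | None = None,
                 l: int = 6) -> OrderParameterSet:
    """Per-molecule Steinhardt q_l; undefined (NaN) where no neighbours.

    Accepts ``steinhardt_q(graph, l=...)`` or ``steinhardt_q(config, graph, l)``
    (the configuration is only a carrier — bond vectors live on the graph).
    """
    if isinstance(config_or_graph, NeighborGraph):
        graph = config_or_graph
    elif graph is None:
        raise TypeError("a NeighborGraph is required")
    if l < 0:
        raise ValueError("l must be non-negative")
    qlm, counts = _qlm_from_graph(graph, l)
    q = _modulus(qlm, l)
    q[counts == 0] = np.nan
    return OrderParameterSet(l, q, qlm, counts, variant="q")


def local_average_q(order_set: OrderParameterSet, graph: NeighborGraph) -> OrderParameterSet:
    """Locally averaged variant: average q_lm over {i} ∪ N(i), then modulus.

    Averaging twice is *not* the same as averaging once (documented
    non-idempotence): each application widens the effective neighbourhood.
    """
    if len(order_set.q) != graph.n_atoms:
        raise ValueError("order set and graph refer to different atom counts")
    qlm = order_set.qlm
    avg = np.where(np.isnan(qlm), 0, qlm).copy()
    contrib = order_set.defined.astype(np.int64).copy()
    for i, j in graph.pairs:
        if order_set.defined[j]:
            avg[i] += qlm[j]
            contrib[i] += 1
        if order_set.defined[i]:
            avg[j] += qlm[i]
            contrib[j] += 1
    with np.errstate(invalid="ignore"):
        avg = np.where(contrib[:, None] > 0, avg / np.maximum(contrib, 1)[:, None], np.nan)
    q = _modulus(avg, order_set.l)
    q[contrib == 0] = np.nan
    return OrderParameterSet(order_set.l, q, avg, order_set.neighbor_counts,
                             variant="locally_averaged_q")


# --------------------------------------------------------------------------- #
# classification
# --------------------------------------------------------------------------- #


def classify_ice(order_set: OrderParameterSet, threshold: float,
                 min_neighbors: int = 4) -> IceLabels:
    """Threshold the (averaged) q_l; undefined values are liquid by fiat.

    ``min_neighbors`` additionally requires ice-like molecules to be at least
    4-coordinated (the interior coordination of ice): q_l computed over very
    few bonds is biased high (E[q_l²] ∝ 1/N_b for random bond directions), so
    under-coordinated surface molecules would otherwise masquerade as ice.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    q = order_set.q
    labels = np.where(np.isnan(q), False, q >= threshold)
    labels &= order_set.neighbor_counts >= min_neighbors
    return IceLabels(labels, threshold, order_set.variant)


class CalibrationError(ValueError):
    """Ice and liquid reference distributions overlap at the calibration percentiles."""


def calibrate_threshold(ice_values, liquid_values,
                        ice_percentile: float = 1.0,
                        liquid_percentile: float = 99.0) -> float:
    """Midpoint between the 1st percentile of the ice q distribution and the
    99th percentile of the liquid q distribution; errors on overlap."""
    ice_values = np.asarray(ice_values, dtype=float)
    liquid_values = np.asarray(liquid_values, dtype=float)
    ice_values = ice_values[~np.isnan(ice_values)]
    liquid_values = liquid_values[~np.isnan(liquid_values)]
    if not len(ice_values) or not len(liquid_values):
        raise ValueError("empty calibration distribution")
    lo = np.percentile(ice_values, ice_percentile)
    hi = np.percentile(liquid_values, liquid_percentile)
    if hi >= lo:
        raise CalibrationError(
            f"distributions overlap: liquid p{liquid_percentile}={hi:.4f} ≥ "
            f"ice p{ice_percentile}={lo:.4f}"
        )
    return float((lo + hi) / 2)
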
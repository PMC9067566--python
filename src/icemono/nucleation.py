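"""Ice nuclei: clustering, centre-of-mass z profiles, and cage detection.

A nucleus is a connected component of the ice-like molecules under the
O–O neighbour graph.  The z-profile of the largest nucleus per frame is
histogrammed, normalised so the bulk (baseline) density is one, and aligned
so the interfacial peak sits at zero — the interfacial enhancement is then
read off directly as the mean normalised density in the interface window.

Cages are classified topologically from primitive 6-rings:

* hexagonal cage (HC): two disjoint 6-rings joined by exactly three
  inter-ring bonds that pair alternating vertices of both rings — the motif
  of hexagonal ice, absent from cubic ice;
* double-diamond cage (DDC): a 6-ring whose two alternating vertex triples
  each carry a three-bridge cap converging on an apex molecule (two fused
  adamantane cages sharing the equatorial ring, 14 molecules) — the motif of
  cubic ice, absent from hexagonal ice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .order_params import IceLabels, NeighborGraph
from .trajectory_io import Configuration, minimum_image


@dataclass
class NucleusSet:
    """Disjoint clusters of ice-like molecules; ``largest_index`` is None when
    no molecule is ice-like."""

    clusters: list                    # list of sorted index lists
    largest_index: int | None
    time: float = 0.0

    @property
    def largest(self) -> list | None:
        if self.largest_index is None:
            return None
        return self.clusters[self.largest_index]

    @property
    def largest_size(self) -> int:
        return 0 if self.largest_index is None else len(self.clusters[self.largest_index])


@dataclass
class ComZProfile:
    edges: np.ndarray                 # bin edges (folded coordinate if fold)
    counts: np.ndarray
    density: np.ndarray               # normalised: baseline mean == 1
    baseline_window: tuple
    interface_window: tuple
    peak_index: int
    offset: float                     # alignment shift (Å); peak centre maps to 0
    fold: bool
    midplane: float | None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def aligned_centers(self) -> np.ndarray:
        return self.centers - self.offset


@dataclass
class CageSet:
    rings: list                       # canonical 6-cycles (tuples)
    ddc_list: list                    # frozensets of member molecule ids
    hc_list: list

    @property
    def n_ddc(self) -> int:
        return len(self.ddc_list)

    @property
    def n_hc(self) -> int:
        return len(self.hc_list)


# --------------------------------------------------------------------------- #
# clustering
# --------------------------------------------------------------------------- #


def cluster_nuclei(labels: IceLabels, graph: NeighborGraph, time: float = 0.0) -> NucleusSet:
    """Connected components of the ice-like induced subgraph (union-find).

    The largest cluster is selected; ties are broken toward the cluster whose
    minimum molecule id is smallest, which is deterministic and independent
    of input ordering.
    """
    ice = labels.ice_like
    if len(ice) != graph.n_atoms:
        raise ValueError("labels and graph refer to different molecule counts")
    parent = np.arange(graph.n_atoms)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in graph.pairs:
        if ice[i] and ice[j]:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    groups: dict = {}
    for i in np.nonzero(ice)[0]:
        groups.setdefault(find(i), []).append(int(i))
    clusters = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
    if not clusters:
        return NucleusSet([], None, time)
    sizes = [len(c) for c in clusters]
    best = int(np.argmax(sizes))  # argmax takes first on ties; clusters sorted by min id
    return NucleusSet(clusters, best, time)


def nucleus_com_z(nucleus, config: Configuration) -> float:
    """COM z of a nucleus: member oxygens unwrapped (minimum image in the
    periodic axes, relative to the lowest-index member), then averaged.
    z is the non-periodic axis and enters raw."""
    members = sorted(int(m) for m in nucleus)
    if not members:
        raise ValueError("empty nucleus has no centre of mass")
    if config.periodic[2]:
        raise ValueError("z must be the non-periodic axis for COM_z")
    seed = config.coords[members[0]]
    rel = minimum_image(config.coords[members] - seed, config.box, config.periodic)
    return float(np.mean(seed[2] + rel[:, 2]))


# --------------------------------------------------------------------------- #
# COM-z profile
# --------------------------------------------------------------------------- #


def com_z_profile(com_zs, bin_width: float = 0.5, fold: bool = True,
                  midplane: float | None = None,
                  baseline_window: tuple = (0.0, 5.0),
                  interface_window: tuple = (10.0, 25.0)) -> ComZProfile:
    """Histogram a stream of largest-nucleus COM z values.

    With ``fold`` the coordinate is |z − midplane| so the two equivalent
    interfaces of the slab superpose; the windows are then distances from the
    midplane.  The density is normalised so its mean over the baseline window
    is exactly one, and the alignment offset puts the maximum bin inside the
    interface window at zero.
    """
    z = np.asarray(com_zs, dtype=float)
    z = z[~np.isnan(z)]
    if z.size == 0:
        raise ValueError("no valid COM values")
    lo_b, hi_b = baseline_window
    lo_i, hi_i = interface_window
    if max(lo_b, lo_i) < min(hi_b, hi_i):
        raise ValueError("baseline and interface windows must be disjoint")
    if fold:
        if midplane is None:
            midplane = float(np.mean(z))
        coord = np.abs(z - midplane)
        start = 0.0
    else:
        coord = z
        start = np.floor(coord.min() / bin_width) * bin_width
    nbins = int(np.ceil((coord.max() - start) / bin_width)) + 1
    edges = start + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(coord, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    base = (centers >= lo_b) & (centers < hi_b)
    if not base.any() or counts[base].sum() == 0:
        raise ValueError("baseline window is unoccupied; cannot normalise")
    density = counts / counts[base].mean()
    inter = (centers >= lo_i) & (centers < hi_i)
    if not inter.any():
        raise ValueError("interface window lies outside the histogram support")
    peak = int(np.nonzero(inter)[0][np.argmax(density[inter])])
    return ComZProfile(edges, counts, density, tuple(baseline_window),
                       tuple(interface_window), peak, float(centers[peak]),
                       fold, midplane)


def interfacial_enhancement(profile: ComZProfile, interface_window: tuple | None = None) -> float:
    """Mean normalised density over the interface window (baseline is 1)."""
    window = profile.interface_window if interface_window is None else interface_window
    centers = profile.centers
    sel = (centers >= window[0]) & (centers < window[1])
    if not sel.any():
        raise ValueError("interface window outside histogram support")
    return float(profile.density[sel].mean())


def trajectory_largest_nucleus_comz(traj, cutoff: float = 3.5, l: int = 6,
                                    threshold: float = 0.5,
                                    variant: str = "locally_averaged_q") -> np.ndarray:
    """Largest-nucleus COM z per frame via the full detection chain:
    O–O neighbour graph → Steinhardt q_l → (optional) local averaging →
    threshold classification → clustering.  Frames with no ice-like
    molecule yield NaN."""
    from .order_params import classify_ice, local_average_q, neighbor_list, steinhardt_q
    from .trajectory_io import infer_topology

    out = np.full(len(traj.frames), np.nan)
    for k, frame in enumerate(traj.frames):
        topo = infer_topology(frame)
        oxy = topo.water_oxygens
        graph = neighbor_list(frame, cutoff, method="cell", subset=oxy)
        qset = steinhardt_q(graph, l=l)
        if variant == "locally_averaged_q":
            qset = local_average_q(qset, graph)
        labels = classify_ice(qset, threshold)
        nuclei = cluster_nuclei(labels, graph, time=float(traj.times[k]))
        if nuclei.largest is None:
            continue
        sub = frame.coords[oxy]
        members = nuclei.largest
        seed = sub[members[0]]
        rel = minimum_image(sub[members] - seed, frame.box, frame.periodic)
        out[k] = float(np.mean(seed[2] + rel[:, 2]))
    return out


# --------------------------------------------------------------------------- #
# rings
# --------------------------------------------------------------------------- #


def enumerate_rings(graph: NeighborGraph, size: int = 6) -> list:
    """All primitive ``size``-cycles, each once in canonical order.

    Primitive: for every pair of ring members the full-graph geodesic
    distance equals the in-ring distance (no shortcuts).  Canonical order:
    lowest member first, lower of its two ring neighbours second.
    """
    adj = graph.adjacency_sets()
    n = graph.n_atoms
    cycles = set()

    def dfs(path, seen):
        last = path[-1]
        if len(path) == size:
            if path[0] in adj[last] and path[1] < last:
                cycles.add(tuple(path))
            return
        for nxt in adj[last]:
            if nxt > path[0] and nxt not in seen:
                seen.add(nxt)
                path.append(nxt)
                dfs(path, seen)
                path.pop()
                seen.remove(nxt)

    for v0 in range(n):
        dfs([v0], {v0})

    half = size // 2
    dist_cache: dict = {}

    def bfs_dist(src):
        if src in dist_cache:
            return dist_cache[src]
        dist = {src: 0}
        frontier = [src]
        for d in range(1, half + 1):
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = d
                        nxt.append(w)
            frontier = nxt
        dist_cache[src] = dist
        return dist

    rings = []
    for cyc in sorted(cycles):
        ok = True
        for a in range(size):
            da = bfs_dist(cyc[a])
            for b in range(a + 1, size):
                ring_d = min(b - a, size - (b - a))
                if da.get(cyc[b], half + 1) < ring_d:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            rings.append(cyc)
    return rings


# --------------------------------------------------------------------------- #
# cages
# --------------------------------------------------------------------------- #


def _alternating_triples(ring):
    return (ring[0], ring[2], ring[4]), (ring[1], ring[3], ring[5])


def _find_caps(triple, ring_set, adj):
    """Three distinct bridges (one per triple vertex, outside the ring) that
    share a common apex outside ring and bridges."""
    caps = []
    c1, c2, c3 = triple
    out1 = [b for b in adj[c1] if b not in ring_set]
    out2 = [b for b in adj[c2] if b not in ring_set]
    out3 = [b for b in adj[c3] if b not in ring_set]
    for b1 in out1:
        for b2 in out2:
            if b2 == b1:
                continue
            for b3 in out3:
                if b3 in (b1, b2):
                    continue
                common = (adj[b1] & adj[b2] & adj[b3]) - ring_set - {b1, b2, b3}
                for apex in common:
                    caps.append(frozenset((b1, b2, b3, apex)))
    return caps


def detect_cages(rings, graph: NeighborGraph) -> CageSet:
    """Detect DDCs and HCs among primitive 6-rings (see module docstring).

    Cages are keyed (and de-duplicated) by their full member set; DDC and HC
    lists may share molecules but never a member set.
    """
    adj = graph.adjacency_sets()
    ring_sets = [set(r) for r in rings]

    ddc = set()
    for ring, ring_set in zip(rings, ring_sets):
        t_up, t_down = _alternating_triples(ring)
        caps_up = _find_caps(t_up, ring_set, adj)
        caps_down = _find_caps(t_down, ring_set, adj)
        for cu in caps_up:
            for cd in caps_down:
                if cu & cd:
                    continue
                ddc.add(frozenset(ring) | cu | cd)

    by_node: dict = {}
    for k, rs in enumerate(ring_sets):
        for v in rs:
            by_node.setdefault(v, []).append(k)
    hc = set()
    for k1, (r1, s1) in enumerate(zip(rings, ring_sets)):
        cand = set()
        for v in s1:
            for b in adj[v]:
                if b not in s1:
                    cand.update(by_node.get(b, ()))
        for k2 in cand:
            if k2 <= k1:
                continue
            r2, s2 = rings[k2], ring_sets[k2]
            if s1 & s2:
                continue
            inter = [(a, b) for a in r1 for b in adj[a] if b in s2]
            if len(inter) != 3:
                continue
            a_side = [a for a, _ in inter]
            b_side = [b for _, b in inter]
            if len(set(a_side)) != 3 or len(set(b_side)) != 3:
                continue
            if set(a_side) not in map(set, _alternating_triples(r1)):
                continue
            if set(b_side) not in map(set, _alternating_triples(r2)):
                continue
            hc.add(frozenset(s1 | s2))
    return CageSet(list(rings), sorted(ddc, key=sorted), sorted(hc, key=sorted))
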
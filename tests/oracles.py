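"""Independent reference implementations used to cross-check the package.

Everything here deliberately takes a different route from the library code:
plain-Python loops, networkx graph algorithms, associated-Legendre spherical
harmonics, and explicit replication instead of minimum-image arithmetic.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy.special import lpmv


# --------------------------------------------------------------------------- #
# spherical harmonics / Steinhardt
# --------------------------------------------------------------------------- #


def ylm(l: int, m: int, theta: float, phi: float) -> complex:
    """Y_lm from the associated Legendre function (Condon–Shortley phase)."""
    am = abs(m)
    norm = math.sqrt((2 * l + 1) / (4 * math.pi) *
                     math.factorial(l - am) / math.factorial(l + am))
    val = norm * lpmv(am, l, math.cos(theta)) * np.exp(1j * am * phi)
    if m < 0:
        val = (-1) ** am * np.conjugate(val)
    return complex(val)


def steinhardt_q_brute(positions, box, periodic, cutoff: float, l: int) -> np.ndarray:
    """q_l per particle by direct double loop over minimum-image pairs."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    out = np.full(n, np.nan)
    for i in range(n):
        qlm = np.zeros(2 * l + 1, dtype=complex)
        nb = 0
        for j in range(n):
            if i == j:
                continue
            d = positions[j] - positions[i]
            for ax in range(3):
                if periodic[ax]:
                    d[ax] -= box[ax] * round(d[ax] / box[ax])
            r = math.sqrt(float(np.dot(d, d)))
            if r <= cutoff:
                theta = math.acos(max(-1.0, min(1.0, d[2] / r)))
                phi = math.atan2(d[1], d[0])
                for k, m in enumerate(range(-l, l + 1)):
                    qlm[k] += ylm(l, m, theta, phi)
                nb += 1
        if nb:
            qlm /= nb
            out[i] = math.sqrt(4 * math.pi / (2 * l + 1) * float(np.sum(np.abs(qlm) ** 2)))
    return out


# --------------------------------------------------------------------------- #
# graphs
# --------------------------------------------------------------------------- #


def to_networkx(graph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_atoms))
    g.add_edges_from(map(tuple, graph.pairs))
    return g


def connected_components_oracle(ice_mask, graph) -> list:
    """Clusters of ice-like nodes via networkx connected components."""
    g = to_networkx(graph).subgraph(np.nonzero(ice_mask)[0])
    return sorted((sorted(int(v) for v in comp) for comp in nx.connected_components(g)),
                  key=lambda c: c[0])


def rings_oracle(graph, size: int = 6) -> set:
    """Primitive size-cycles via networkx simple_cycles + geodesic check."""
    g = to_networkx(graph)
    out = set()
    for cyc in nx.simple_cycles(g, length_bound=size):
        if len(cyc) != size:
            continue
        ok = True
        for a, b in itertools.combinations(range(size), 2):
            ring_d = min(b - a, size - (b - a))
            if nx.shortest_path_length(g, cyc[a], cyc[b]) < ring_d:
                ok = False
                break
        if ok:
            out.add(frozenset(cyc))
    return out


def cages_oracle(graph) -> tuple:
    """Exhaustive DDC/HC pattern match built on networkx primitives.

    Returns (set of DDC member frozensets, set of HC member frozensets) under
    the same topological definitions the package documents: DDC = equatorial
    6-ring with a three-bridge + apex cap on each alternating triple; HC =
    two disjoint 6-rings joined by exactly three bonds pairing alternating
    vertices of both.
    """
    g = to_networkx(graph)
    ring_sets = rings_oracle(graph, 6)
    # recover a cyclic ordering for each ring from the induced subgraph
    ordered = []
    for rs in ring_sets:
        sub = g.subgraph(rs)
        cyc = nx.cycle_basis(sub)[0]
        ordered.append(tuple(cyc))

    ddc = set()
    for ring in ordered:
        caps_by_parity = []
        for parity in (0, 1):
            triple = (ring[parity], ring[(parity + 2) % 6], ring[(parity + 4) % 6])
            caps = []
            outs = [[b for b in g.neighbors(c) if b not in ring] for c in triple]
            for b1, b2, b3 in itertools.product(*outs):
                if len({b1, b2, b3}) != 3:
                    continue
                shared = set(g.neighbors(b1)) & set(g.neighbors(b2)) & set(g.neighbors(b3))
                for apex in shared - set(ring) - {b1, b2, b3}:
                    caps.append(frozenset((b1, b2, b3, apex)))
            caps_by_parity.append(caps)
        for cu in caps_by_parity[0]:
            for cd in caps_by_parity[1]:
                if not cu & cd:
                    ddc.add(frozenset(ring) | cu | cd)

    hc = set()
    for r1, r2 in itertools.combinations(ordered, 2):
        s1, s2 = set(r1), set(r2)
        if s1 & s2:
            continue
        bonds = [(a, b) for a in r1 for b in g.neighbors(a) if b in s2]
        if len(bonds) != 3:
            continue
        a_side = {a for a, _ in bonds}
        b_side = {b for _, b in bonds}
        if len(a_side) != 3 or len(b_side) != 3:
            continue
        alts1 = [{r1[p], r1[(p + 2) % 6], r1[(p + 4) % 6]} for p in (0, 1)]
        alts2 = [{r2[p], r2[(p + 2) % 6], r2[(p + 4) % 6]} for p in (0, 1)]
        if a_side in alts1 and b_side in alts2:
            hc.add(frozenset(s1 | s2))
    return ddc, hc


# --------------------------------------------------------------------------- #
# unwrapped centre of mass
# --------------------------------------------------------------------------- #


def com_z_replicated(members, coords, box, periodic) -> float:
    """COM z by explicit replication: pick the periodic image of every member
    closest to the running cluster mean (greedy, order-independent for small
    compact clusters)."""
    members = sorted(members)
    images = []
    shifts = []
    for ax in range(3):
        shifts.append([-1, 0, 1] if periodic[ax] else [0])
    ref = coords[members[0]]
    pts = [np.asarray(ref, dtype=float)]
    for m in members[1:]:
        best, best_d = None, np.inf
        for sx in shifts[0]:
            for sy in shifts[1]:
                for sz in shifts[2]:
                    cand = coords[m] + box * np.array([sx, sy, sz])
                    d = float(np.linalg.norm(cand - ref))
                    if d < best_d:
                        best, best_d = cand, d
        pts.append(best)
    return float(np.mean([p[2] for p in pts]))
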
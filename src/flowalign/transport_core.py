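"""Truncated-Wasserstein transport between two spectra as min-cost flow.

Two spectra, viewed as discrete probability measures over peak positions,
are compared by optimal transport under a *truncated* ground cost: moving
mass between peaks closer than ``d_max`` costs their distance, while any
mass left unmatched pays a flat penalty ``delta_max`` per unit.  The
truncation caps the influence of outlier peaks and keeps matches within the
physically plausible shift range.

The problem is encoded as an integer min-cost-flow network: a source feeds
one node per peak of spectrum A (arc capacity = quantized intensity, cost
0), matching arcs join A-peaks to B-peaks closer than the pruning radius
(cost = quantized distance), B-peak nodes drain into a sink, and a single
source->sink "mismatch" arc carries all unmatched mass at cost
``delta_max``.  Matching arcs farther than ``delta_max`` can never carry
flow in an optimum and are pruned up front, which keeps the network sparse
and the solve near-linear in peak count.

Intensities are quantized by largest-remainder rounding so both sides sum
to exactly ``intensity_scale`` units; costs are rounded at ``cost_scale``
units per unit distance.  Network Simplex then works in exact integer
arithmetic and the reported transport cost is the de-quantized optimum.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, TextIO

import numpy as np
from scipy.spatial import cKDTree

from . import netsimplex
from .spectra_io import Spectrum, normalize_spectrum

__all__ = [
    "TransportParams",
    "FlowNetwork",
    "TransportPlan",
    "build_candidate_edges",
    "build_flow_network",
    "solve_transport",
    "truncated_wasserstein",
    "quantize_masses",
]

_METRIC_P = {"euclidean": 2, "l1": 1}


@dataclass(frozen=True)
class TransportParams:
    """Parameters of the truncated transport problem.

    d_max:
        Maximum matchable distance (in the, possibly rescaled, coordinate
        units of the spectra).  Peak pairs farther apart are never matched.
    delta_max:
        Flat cost per unit of unmatched mass; also the cost cap beyond which
        matching is never worthwhile.
    metric:
        Ground metric, ``euclidean`` or ``l1``.
    intensity_scale:
        Integer flow units per unit of normalized intensity (quantization
        resolution; at least 10^4 so rounding is negligible).
    cost_scale:
        Integer cost units per unit of distance.
    """

    d_max: float
    delta_max: float
    metric: str = "euclidean"
    intensity_scale: int = 10 ** 6
    cost_scale: int = 10 ** 6

    def __post_init__(self) -> None:
        if self.d_max < 0 or self.delta_max < 0:
            raise ValueError("d_max and delta_max must be nonnegative")
        if self.metric not in _METRIC_P:
            raise ValueError(f"metric must be one of {sorted(_METRIC_P)}")
        if self.intensity_scale < 10 ** 4:
            raise ValueError("intensity_scale must be at least 10^4")
        if self.cost_scale < 1:
            raise ValueError("cost_scale must be a positive integer")

    @property
    def prune_radius(self) -> float:
        """Matching arcs beyond min(d_max, delta_max) are dead weight."""
        return min(self.d_max, self.delta_max)


@dataclass
class FlowNetwork:
    """Integer min-cost-flow instance for one pairwise alignment.

    Node layout: ``0..nA-1`` = A-peaks, ``nA..nA+nB-1`` = B-peaks, then
    source and sink.  ``match_arcs`` maps arc index -> (A index, B index,
    geometric distance) for the matching arcs; ``mismatch_arc`` is the
    single source->sink arc.
    """

    n_nodes: int
    tails: list[int]
    heads: list[int]
    caps: list[int]
    costs: list[int]
    supply: list[int]
    source: int
    sink: int
    n_a: int
    n_b: int
    mismatch_arc: int
    match_arcs: dict[int, tuple[int, int, float]] = field(default_factory=dict)
    supply_arcs: list[int] = field(default_factory=list)   # source -> A_i
    demand_arcs: list[int] = field(default_factory=list)   # B_j -> sink

    @property
    def n_arcs(self) -> int:
        return len(self.tails)


@dataclass(frozen=True)
class TransportPlan:
    """Optimal transport plan plus the truncated Wasserstein value.

    ``matched`` lists positive transports (A id, B id, mass, distance) in
    normalized-intensity units; ``unmatched_mass_a``/``_b`` give the mass of
    each peak routed through the mismatch arc; ``total_cost`` is the
    truncated Wasserstein distance W_tr.
    """

    matched: tuple[tuple[str, str, float, float], ...]
    unmatched_mass_a: dict[str, float]
    unmatched_mass_b: dict[str, float]
    total_cost: float
    params: TransportParams

    @property
    def mismatch_mass(self) -> float:
        return sum(self.unmatched_mass_a.values())

    def matched_mass_of_a(self, peak_id: str) -> float:
        return sum(m for ia, _, m, _ in self.matched if ia == peak_id)

    def flows_from_a(self, peak_id: str) -> list[tuple[str, float, float]]:
        return [(ib, m, d) for ia, ib, m, d in self.matched if ia == peak_id]

    def write_tsv(self, out: TextIO) -> None:
        p = self.params
        out.write(f"# W_tr\t{self.total_cost:.12g}\n")
        out.write(f"# d_max\t{p.d_max:g}\n# delta_max\t{p.delta_max:g}\n")
        out.write(f"# metric\t{p.metric}\n")
        out.write(f"# intensity_scale\t{p.intensity_scale}\n")
        out.write(f"# cost_scale\t{p.cost_scale}\n")
        out.write("id_a\tid_b\tmass\tdistance\n")
        for ia, ib, m, d in self.matched:
            out.write(f"{ia}\t{ib}\t{m:.12g}\t{d:.12g}\n")
        out.write("# unmatched\nside\tid\tmass\n")
        for pid, m in self.unmatched_mass_a.items():
            if m > 0:
                out.write(f"A\t{pid}\t{m:.12g}\n")
        for pid, m in self.unmatched_mass_b.items():
            if m > 0:
                out.write(f"B\t{pid}\t{m:.12g}\n")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_candidate_edges(a: Spectrum, b: Spectrum,
                          params: TransportParams) -> list[tuple[int, int, float]]:
    """All (A index, B index, distance) pairs within the pruning radius.

    Found with a k-d tree, so runtime scales with the number of nearby
    pairs, not with |A| x |B|; the result equals the exhaustive set.
    """
    if a.dim != b.dim:
        raise ValueError(f"dimension mismatch: {a.dim} vs {b.dim}")
    if a.n_peaks == 0 or b.n_peaks == 0:
        return []
    p = _METRIC_P[params.metric]
    radius = params.prune_radius
    tree_a = cKDTree(a.positions)
    tree_b = cKDTree(b.positions)
    sdm = tree_a.sparse_distance_matrix(tree_b, max_distance=radius, p=p,
                                        output_type="coo_matrix")
    edges = sorted(zip(sdm.row.tolist(), sdm.col.tolist(), sdm.data.tolist()))
    return [(int(i), int(j), float(d)) for i, j, d in edges]


def quantize_masses(weights: np.ndarray, scale: int) -> np.ndarray:
    """Largest-remainder rounding of nonnegative weights summing to ~1.

    Returns integers summing to exactly ``scale``, each within one unit of
    ``weights * scale`` — keeping the two sides of the network balanced
    without any slack arc.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("cannot quantize an empty weight vector")
    target = w * scale
    base = [int(np.floor(t)) for t in target]
    remainder = [t - f for t, f in zip(target, base)]
    shortfall = scale - sum(base)
    if shortfall > 0:
        order = sorted(range(len(base)), key=lambda k: (-remainder[k], k))
        for k in order[:shortfall]:
            base[k] += 1
    elif shortfall < 0:  # float drift above 1.0: trim smallest remainders
        order = sorted(range(len(base)), key=lambda k: (remainder[k], k))
        taken = 0
        for k in order:
            if taken == -shortfall:
                break
            if base[k] > 0:
                base[k] -= 1
                taken += 1
    return np.array(base, dtype=object)


def build_flow_network(a: Spectrum, b: Spectrum,
                       edges: list[tuple[int, int, float]],
                       params: TransportParams) -> FlowNetwork:
    """Assemble the bipartite-plus-mismatch min-cost-flow instance.

    Requires both spectra normalized to total intensity 1 (checked); after
    largest-remainder quantization the source supply equals the sink demand
    exactly, so the instance is always balanced.
    """
    for name, s in (("first", a), ("second", b)):
        if abs(s.total_intensity - 1.0) > 1e-9:
            raise ValueError(f"{name} spectrum is not normalized (sum != 1)")
    scale = params.intensity_scale
    qa = quantize_masses(a.intensities, scale)
    qb = quantize_masses(b.intensities, scale)
    n_a, n_b = a.n_peaks, b.n_peaks
    source, sink = n_a + n_b, n_a + n_b + 1

    tails: list[int] = []
    heads: list[int] = []
    caps: list[int] = []
    costs: list[int] = []
    supply_arcs, demand_arcs = [], []
    match_arcs: dict[int, tuple[int, int, float]] = {}

    for i in range(n_a):
        supply_arcs.append(len(tails))
        tails.append(source)
        heads.append(i)
        caps.append(int(qa[i]))
        costs.append(0)
    for j in range(n_b):
        demand_arcs.append(len(tails))
        tails.append(n_a + j)
        heads.append(sink)
        caps.append(int(qb[j]))
        costs.append(0)
    for i, j, dist in edges:
        match_arcs[len(tails)] = (i, j, dist)
        tails.append(i)
        heads.append(n_a + j)
        caps.append(scale)  # "infinite": no flow can exceed total supply
        costs.append(int(round(dist * params.cost_scale)))
    mismatch_arc = len(tails)
    tails.append(source)
    heads.append(sink)
    caps.append(scale)
    costs.append(int(round(params.delta_max * params.cost_scale)))

    supply = [0] * (n_a + n_b + 2)
    supply[source] = scale
    supply[sink] = -scale
    return FlowNetwork(
        n_nodes=n_a + n_b + 2, tails=tails, heads=heads, caps=caps,
        costs=costs, supply=supply, source=source, sink=sink,
        n_a=n_a, n_b=n_b, mismatch_arc=mismatch_arc,
        match_arcs=match_arcs, supply_arcs=supply_arcs,
        demand_arcs=demand_arcs,
    )


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

def solve_transport(a: Spectrum, b: Spectrum,
                    params: TransportParams,
                    solver=netsimplex.solve) -> TransportPlan:
    """Compute the optimal truncated transport plan between two spectra.

    Spectra are normalized internally; masses in the returned plan are in
    normalized-intensity units (each side sums to 1 up to quantization).
    The full supply is always routed: what cannot be matched within
    ``d_max`` flows through the mismatch arc at cost ``delta_max``.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("cannot align an empty spectrum")
    an, bn = normalize_spectrum(a), normalize_spectrum(b)
    edges = build_candidate_edges(an, bn, params)
    net = build_flow_network(an, bn, edges, params)
    result = solver(net)
    return extract_plan(an, bn, net, result, params)


def extract_plan(a: Spectrum, b: Spectrum, net: FlowNetwork,
                 result: netsimplex.FlowResult,
                 params: TransportParams) -> TransportPlan:
    scale = params.intensity_scale
    matched = []
    out_a = np.zeros(net.n_a)
    in_b = np.zeros(net.n_b)
    for arc, (i, j, dist) in net.match_arcs.items():
        f = result.flow[arc]
        if f > 0:
            mass = f / scale
            matched.append((a.ids[i], b.ids[j], mass, dist))
            out_a[i] += mass
            in_b[j] += mass
    qa = np.array([net.caps[arc] for arc in net.supply_arcs]) / scale
    qb = np.array([net.caps[arc] for arc in net.demand_arcs]) / scale
    unmatched_a = {a.ids[i]: float(qa[i] - out_a[i]) for i in range(net.n_a)}
    unmatched_b = {b.ids[j]: float(qb[j] - in_b[j]) for j in range(net.n_b)}
    total = result.cost / (scale * params.cost_scale)
    return TransportPlan(
        matched=tuple(matched),
        unmatched_mass_a=unmatched_a,
        unmatched_mass_b=unmatched_b,
        total_cost=float(total),
        params=params,
    )


def truncated_wasserstein(a: Spectrum, b: Spectrum,
                          params: TransportParams) -> float:
    """The truncated Wasserstein distance W_tr between two spectra."""
    return solve_transport(a, b, params).total_cost
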
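"""Exact integer min-cost flow via the Network Simplex method.

The alignment problem is reduced to a min-cost-flow instance with integer
supplies, capacities and costs; this module solves it exactly.  Network
Simplex maintains a spanning-tree basis: every pivot brings one non-tree arc
with negative reduced cost into the tree, pushes flow around the unique
cycle it closes, and drops a blocking arc.  All arithmetic is on Python
integers, so there is no rounding anywhere and the optimum is certified by
the node potentials (complementary slackness).

Design choices
--------------
* Entering arc: block search — arcs are scanned cyclically in blocks of
  ~sqrt(m); the most negative reduced-cost violation within a block enters.
* Initial basis: an artificial root node joined to every node by a high-cost
  (big-M) arc, giving an always-feasible starting tree without a phase-one.
* Anti-cycling: strongly feasible trees, maintained by choosing the *last*
  blocking arc encountered when traversing the pivot cycle in its push
  direction starting from the apex.

``reference_solve`` is an independent successive-shortest-paths solver
(Dijkstra with Johnson potentials on the residual network).  It shares no
code with the simplex and exists so the two can be checked against each
other; it is slower and meant for small instances.
"""
from __future__ import annotations

from dataclasses import dataclass
from heapq import heappop, heappush
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FlowResult",
    "InfeasibleFlowError",
    "solve",
    "reference_solve",
    "verify_optimality",
    "to_dimacs",
]


class InfeasibleFlowError(ValueError):
    """Raised when the demanded flow cannot be routed."""


@dataclass(frozen=True)
class FlowResult:
    """An integral flow with its cost and certifying dual potentials.

    ``flow[a]`` is the flow on arc ``a`` in the order the arcs were given;
    ``cost`` is ``sum(flow * arc_cost)``; ``potentials`` are node duals such
    that every arc satisfies complementary slackness (reduced cost
    ``c + pi[tail] - pi[head]`` is >= 0 on empty arcs, <= 0 on saturated
    arcs, and flow is free only where it is 0).
    """

    flow: tuple[int, ...]
    cost: int
    potentials: tuple[int, ...]


def _validate(n_nodes, tails, heads, caps, costs, supply):
    m = len(tails)
    if not (len(heads) == len(caps) == len(costs) == m):
        raise ValueError("arc arrays must have equal length")
    if len(supply) != n_nodes:
        raise ValueError("supply must have one entry per node")
    if sum(supply) != 0:
        raise ValueError("supplies must sum to zero")
    for a in range(m):
        if not (0 <= tails[a] < n_nodes and 0 <= heads[a] < n_nodes):
            raise ValueError(f"arc {a} references an unknown node")
        if caps[a] < 0 or costs[a] < 0:
            raise ValueError(f"arc {a} has negative capacity or cost")


# ---------------------------------------------------------------------------
# Network Simplex
# ---------------------------------------------------------------------------

class _Simplex:
    def __init__(self, n_nodes: int, tails, heads, caps, costs, supply):
        self.n = n_nodes
        self.root = n_nodes
        self.m = len(tails)
        total_pos = sum(s for s in supply if s > 0)
        art_cap = max(1, total_pos)
        # big-M exceeds the cost of any feasible flow on original arcs
        big_m = 1 + sum(c * min(cap, art_cap) for c, cap in zip(costs, caps))

        self.tail = list(tails) + []
        self.head = list(heads) + []
        self.cap = list(caps) + []
        self.cost = list(costs) + []
        self.flow = [0] * self.m
        # artificial arcs: one per node, to/from the root
        for v in range(n_nodes):
            if supply[v] >= 0:
                self.tail.append(v)
                self.head.append(self.root)
                self.flow.append(supply[v])
            else:
                self.tail.append(self.root)
                self.head.append(v)
                self.flow.append(-supply[v])
            self.cap.append(art_cap)
            self.cost.append(big_m)

        nn = n_nodes + 1
        self.parent = [self.root] * nn
        self.parent_arc = [0] * nn
        self.depth = [1] * nn
        self.pi = [0] * nn
        self.in_tree = [False] * len(self.tail)
        self.tree_arcs: list[set[int]] = [set() for _ in range(nn)]
        self.parent[self.root] = -1
        self.parent_arc[self.root] = -1
        self.depth[self.root] = 0
        for v in range(n_nodes):
            a = self.m + v
            self.parent_arc[v] = a
            self.in_tree[a] = True
            self.tree_arcs[v].add(a)
            self.tree_arcs[self.root].add(a)
            self.pi[v] = -big_m if self.tail[a] == v else big_m

    # -- reduced cost ----------------------------------------------------
    def _rc(self, a: int) -> int:
        return self.cost[a] + self.pi[self.tail[a]] - self.pi[self.head[a]]

    # -- entering arc: cyclic block search -------------------------------
    def _find_entering(self, state: list[int]) -> Optional[tuple[int, bool]]:
        m_tot = len(self.tail)
        block = max(10, int(m_tot ** 0.5) + 1)
        start = state[0]
        scanned = 0
        best, best_viol, best_fwd = -1, 0, True
        a = start
        while scanned < m_tot:
            in_block = 0
            while in_block < block and scanned < m_tot:
                if not self.in_tree[a]:
                    rc = self._rc(a)
                    if self.flow[a] < self.cap[a] and rc < 0 and -rc > best_viol:
                        best, best_viol, best_fwd = a, -rc, True
                    elif self.flow[a] > 0 and rc > 0 and rc > best_viol:
                        best, best_viol, best_fwd = a, rc, False
                in_block += 1
                scanned += 1
                a += 1
                if a == m_tot:
                    a = 0
            if best >= 0:
                state[0] = a
                return best, best_fwd
        return None

    # -- pivot -----------------------------------------------------------
    def _pivot(self, e: int, forward: bool) -> None:
        # push direction along e: u -> v
        u = self.tail[e] if forward else self.head[e]
        v = self.head[e] if forward else self.tail[e]

        # climb to the apex, recording (arc, child-node, traversal direction)
        up_v, up_u = [], []  # tree arcs from v (resp. u) up to the apex
        x, y = v, u
        while x != y:
            if self.depth[x] >= self.depth[y]:
                up_v.append((self.parent_arc[x], x))
                x = self.parent[x]
            else:
                up_u.append((self.parent_arc[y], y))
                y = self.parent[y]
        # cycle in push direction starting at the apex:
        #   apex -> ... -> u, then e, then v -> ... -> apex
        ordered: list[tuple[int, int, bool]] = []  # (arc, residual, child-is-source?)
        for a, child in reversed(up_u):
            # traversing parent -> child: with the arc oriented child->parent
            # this is a backward traversal (residual = flow)
            if self.tail[a] == child:
                ordered.append((a, self.flow[a], False))
            else:
                ordered.append((a, self.cap[a] - self.flow[a], True))
        res_e = (self.cap[e] - self.flow[e]) if forward else self.flow[e]
        ordered.append((e, res_e, forward))
        for a, child in up_v:
            # traversing child -> parent
            if self.tail[a] == child:
                ordered.append((a, self.cap[a] - self.flow[a], True))
            else:
                ordered.append((a, self.flow[a], False))

        theta = min(r for _, r, _ in ordered)
        # Cunningham's rule: last blocking arc along the cycle keeps the
        # tree strongly feasible (finite termination under degeneracy)
        leave_idx = max(i for i, (_, r, _) in enumerate(ordered) if r == theta)
        leaving, _, _ = ordered[leave_idx]

        if theta > 0:
            for a, _, fwd in ordered:
                self.flow[a] += theta if fwd else -theta

        if leaving == e:
            return

        # subtree cut off by removing the leaving arc: rooted at its child
        w = None
        for a, child in up_u:
            if a == leaving:
                w = child
                break
        if w is None:
            for a, child in up_v:
                if a == leaving:
                    w = child
                    break
        assert w is not None

        # endpoint of e inside the cut-off subtree (old tree)
        z = u if self._in_subtree(u, w) else v
        anchor = v if z == u else u  # stays in the root component

        # swap arcs in the tree structure
        self.in_tree[leaving] = False
        self.tree_arcs[self.tail[leaving]].discard(leaving)
        self.tree_arcs[self.head[leaving]].discard(leaving)
        self.in_tree[e] = True
        self.tree_arcs[self.tail[e]].add(e)
        self.tree_arcs[self.head[e]].add(e)

        # re-root the subtree at z: reverse parent pointers along z..w
        prev, prev_arc = anchor, e
        x = z
        while True:
            px, pa = self.parent[x], self.parent_arc[x]
            self.parent[x] = prev
            self.parent_arc[x] = prev_arc
            if x == w:
                break
            prev, prev_arc = x, pa
            x = px

        # refresh depth and potentials throughout the re-hung subtree
        self.depth[z] = self.depth[anchor] + 1
        a = self.parent_arc[z]
        self.pi[z] = (self.pi[anchor] + self.cost[a]
                      if self.tail[a] == anchor else self.pi[anchor] - self.cost[a])
        stack = [z]
        seen = {z, anchor}
        while stack:
            x = stack.pop()
            for a in self.tree_arcs[x]:
                ynode = self.head[a] if self.tail[a] == x else self.tail[a]
                if ynode in seen:
                    continue
                seen.add(ynode)
                self.depth[ynode] = self.depth[x] + 1
                self.pi[ynode] = (self.pi[x] + self.cost[a]
                                  if self.tail[a] == x else self.pi[x] - self.cost[a])
                stack.append(ynode)

    def _in_subtree(self, node: int, sub_root: int) -> bool:
        x = node
        while self.depth[x] > self.depth[sub_root]:
            x = self.parent[x]
        return x == sub_root

    def run(self) -> tuple[list[int], int, list[int]]:
        state = [0]
        while True:
            found = self._find_entering(state)
            if found is None:
                break
            self._pivot(*found)
        if any(self.flow[self.m + v] > 0 for v in range(self.n)):
            raise InfeasibleFlowError(
                "demand exceeds routable capacity: no feasible flow exists"
            )
        flow = self.flow[: self.m]
        cost = sum(f * c for f, c in zip(flow, self.cost[: self.m]))
        return flow, cost, self.pi[: self.n]


def solve(net) -> FlowResult:
    """Solve a min-cost-flow instance exactly with Network Simplex.

    ``net`` is any object exposing ``n_nodes``, ``tails``, ``heads``,
    ``caps``, ``costs`` (nonnegative integers) and ``supply`` (integers
    summing to zero, positive = source-like).  Deterministic: identical
    inputs give identical results.

    Raises
    ------
    InfeasibleFlowError
        If the supplies cannot be routed within the capacities.
    """
    tails, heads = list(net.tails), list(net.heads)
    caps, costs = list(net.caps), list(net.costs)
    supply = list(net.supply)
    _validate(net.n_nodes, tails, heads, caps, costs, supply)
    flow, cost, pi = _Simplex(net.n_nodes, tails, heads, caps, costs, supply).run()
    return FlowResult(flow=tuple(flow), cost=cost, potentials=tuple(pi))


# ---------------------------------------------------------------------------
# independent reference: successive shortest paths
# ---------------------------------------------------------------------------

def reference_solve(net) -> FlowResult:
    """Min-cost flow by successive shortest augmenting paths.

    Independent oracle for :func:`solve`: Dijkstra on the residual network
    with Johnson potentials, pushing along a shortest source-to-deficit path
    until all supply is routed.  Quadratic-ish; use on small instances.
    """
    tails, heads = list(net.tails), list(net.heads)
    caps, costs = list(net.caps), list(net.costs)
    supply = list(net.supply)
    n = net.n_nodes
    _validate(n, tails, heads, caps, costs, supply)
    m = len(tails)

    # residual arcs: 2k = forward copy of arc k, 2k+1 = backward copy
    res_cap = [0] * (2 * m)
    adj: list[list[int]] = [[] for _ in range(n)]
    for k in range(m):
        res_cap[2 * k] = caps[k]
        adj[tails[k]].append(2 * k)
        adj[heads[k]].append(2 * k + 1)

    def other(ra: int) -> int:
        k = ra // 2
        return heads[k] if ra % 2 == 0 else tails[k]

    def origin(ra: int) -> int:
        k = ra // 2
        return tails[k] if ra % 2 == 0 else heads[k]

    def rcost(ra: int) -> int:
        k = ra // 2
        return costs[k] if ra % 2 == 0 else -costs[k]

    excess = list(supply)
    pi = [0] * n
    INF = float("inf")

    while True:
        try:
            s = next(v for v in range(n) if excess[v] > 0)
        except StopIteration:
            break
        # Dijkstra with reduced costs from s
        dist = [INF] * n
        pred_arc: list[int] = [-1] * n
        dist[s] = 0
        heap = [(0, s)]
        done = [False] * n
        while heap:
            d, x = heappop(heap)
            if done[x]:
                continue
            done[x] = True
            for ra in adj[x]:
                if res_cap[ra] <= 0:
                    continue
                rc = rcost(ra) + pi[x] - pi[other(ra)]
                nd = d + rc
                ynode = other(ra)
                if nd < dist[ynode]:
                    dist[ynode] = nd
                    pred_arc[ynode] = ra
                    heappush(heap, (nd, ynode))
        targets = [v for v in range(n) if excess[v] < 0 and dist[v] < INF]
        if not targets:
            raise InfeasibleFlowError(
                "demand exceeds routable capacity: no feasible flow exists"
            )
        t = min(targets, key=lambda v: (dist[v], v))
        d_t = dist[t]
        for v in range(n):
            pi[v] += min(dist[v], d_t)
        # bottleneck along the path
        push = min(excess[s], -excess[t])
        x = t
        while x != s:
            ra = pred_arc[x]
            push = min(push, res_cap[ra])
            x = origin(ra)
        x = t
        while x != s:
            ra = pred_arc[x]
            res_cap[ra] -= push
            res_cap[ra ^ 1] += push
            x = origin(ra)
        excess[s] -= push
        excess[t] += push

    flow = tuple(res_cap[2 * k + 1] for k in range(m))
    cost = sum(f * c for f, c in zip(flow, costs))
    return FlowResult(flow=flow, cost=cost, potentials=tuple(pi))


# ---------------------------------------------------------------------------
# verification / export
# ---------------------------------------------------------------------------

def verify_optimality(net, r: FlowResult, report: Optional[list] = None) -> bool:
    """Check feasibility and complementary slackness of a flow result.

    Returns ``True`` iff ``r`` conserves flow, respects capacities, and its
    potentials certify optimality: reduced cost >= 0 on every empty arc,
    <= 0 on every saturated arc, 0 wherever flow is strictly between the
    bounds.  Violations are appended to ``report`` when given.
    """
    out: list = report if report is not None else []
    tails, heads = list(net.tails), list(net.heads)
    caps, costs = list(net.caps), list(net.costs)
    supply = list(net.supply)
    ok = True
    balance = [0] * net.n_nodes
    for a, f in enumerate(r.flow):
        if not 0 <= f <= caps[a]:
            out.append(("capacity", a, f))
            ok = False
        balance[tails[a]] += f
        balance[heads[a]] -= f
    for v in range(net.n_nodes):
        if balance[v] != supply[v]:
            out.append(("conservation", v, balance[v] - supply[v]))
            ok = False
    pi = r.potentials
    for a in range(len(tails)):
        rc = costs[a] + pi[tails[a]] - pi[heads[a]]
        f = r.flow[a]
        if f == 0 and rc < 0:
            out.append(("slackness-lower", a, rc))
            ok = False
        elif f == caps[a] and caps[a] > 0 and rc > 0:
            out.append(("slackness-upper", a, rc))
            ok = False
        elif 0 < f < caps[a] and rc != 0:
            out.append(("slackness-interior", a, rc))
            ok = False
    return ok


def to_dimacs(net) -> str:
    """Render an instance in DIMACS min-cost-flow text format (debugging)."""
    lines = [f"p min {net.n_nodes} {len(list(net.tails))}"]
    for v, s in enumerate(net.supply):
        if s != 0:
            lines.append(f"n {v + 1} {s}")
    for t, h, cap, c in zip(net.tails, net.heads, net.caps, net.costs):
        lines.append(f"a {t + 1} {h + 1} 0 {cap} {c}")
    return "\n".join(lines) + "\n"
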
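"""LC-MS front-end: axis rescaling, pairwise alignment, consensus pairs.

Retention-time shifts between LC-MS runs are orders of magnitude larger
than m/z deviations, so before transport the m/z axis is rescaled by
``max_rt_shift / max_mz_shift``: after rescaling, a shift of
``max_mz_shift`` Th and a shift of ``max_rt_shift`` s have the same length,
and a single distance threshold ``d_max = delta_max = max_rt_shift``
bounds both dimensions simultaneously.  The optimal transport plan is then
reduced to *consensus feature pairs*: each feature keeps only its principal
match, the counterpart receiving the largest share of its mass.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import AxisScaling, Spectrum, scale_axes
from .transport_core import TransportParams, TransportPlan, solve_transport

__all__ = [
    "LcmsParams",
    "MatchTable",
    "rescale_for_alignment",
    "align_lcms",
    "principal_matches",
]


@dataclass(frozen=True)
class LcmsParams:
    """Interpretable shift bounds for an LC-MS alignment.

    max_mz_shift:
        Largest expected m/z deviation between runs (Th).
    max_rt_shift:
        Largest expected retention-time deviation between runs (seconds).
    match_fraction:
        Minimum fraction of a feature's intensity that must be matched for
        it to assert a consensus pair (default 0.5: majority flow).
    """

    max_mz_shift: float
    max_rt_shift: float
    match_fraction: float = 0.5
    intensity_scale: int = 10 ** 6
    cost_scale: int = 10 ** 6

    def __post_init__(self) -> None:
        if self.max_mz_shift <= 0 or self.max_rt_shift <= 0:
            raise ValueError("shift bounds must be strictly positive")
        if not 0.0 < self.match_fraction <= 1.0:
            raise ValueError("match_fraction must lie in (0, 1]")

    @property
    def mz_scale_factor(self) -> float:
        return self.max_rt_shift / self.max_mz_shift

    def transport_params(self) -> TransportParams:
        return TransportParams(
            d_max=self.max_rt_shift,
            delta_max=self.max_rt_shift,
            metric="euclidean",
            intensity_scale=self.intensity_scale,
            cost_scale=self.cost_scale,
        )


@dataclass(frozen=True)
class MatchTable:
    """Principal-match reduction of a transport plan.

    ``pairs`` holds (id in A, id in B, matched mass, distance in the scaled
    metric); each A id appears at most once.  ``unmatched_a`` are A peaks
    without a consensus pair; ``unmatched_b`` are B peaks no emitted pair
    points to.  ``deltas`` optionally carries per-axis coordinate
    differences (B minus A, unscaled units) keyed by A id.
    """

    pairs: tuple[tuple[str, str, float, float], ...]
    unmatched_a: tuple[str, ...]
    unmatched_b: tuple[str, ...]
    deltas: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def matched_a_ids(self) -> set[str]:
        return {p[0] for p in self.pairs}

    @property
    def matched_b_ids(self) -> set[str]:
        return {p[1] for p in self.pairs}

    def as_mapping(self) -> dict[str, str]:
        return {ia: ib for ia, ib, _, _ in self.pairs}


def rescale_for_alignment(s: Spectrum, p: LcmsParams) -> Spectrum:
    """Multiply the m/z axis by ``max_rt_shift / max_mz_shift``.

    Expects a 2-D (m/z, RT) feature map; RT is left untouched.
    """
    if s.dim != 2:
        raise ValueError("LC-MS feature maps must be 2-dimensional (m/z, RT)")
    return scale_axes(s, AxisScaling((p.mz_scale_factor, 1.0)))


def align_lcms(a: Spectrum, b: Spectrum,
               p: LcmsParams) -> tuple[TransportPlan, MatchTable]:
    """Align two centroided feature maps and reduce to consensus pairs.

    Both maps are rescaled and normalized, transport is solved with
    ``d_max = delta_max = max_rt_shift`` in the rescaled metric, and the
    plan is reduced to principal matches.  Reported distances are in scaled
    units; per-axis (delta-m/z, delta-RT) components are attached in
    original units.
    """
    a_s = rescale_for_alignment(a, p)
    b_s = rescale_for_alignment(b, p)
    plan = solve_transport(a_s, b_s, p.transport_params())
    table = principal_matches(plan, p.match_fraction)
    deltas = {
        ia: b.position_of(ib) - a.position_of(ia) for ia, ib, _, _ in table.pairs
    }
    return plan, MatchTable(
        pairs=table.pairs,
        unmatched_a=table.unmatched_a,
        unmatched_b=table.unmatched_b,
        deltas=deltas,
    )


def principal_matches(plan: TransportPlan, match_fraction: float,
                      strict_one_to_one: bool = False) -> MatchTable:
    """Reduce a transport plan to one principal match per source peak.

    A peak of the first spectrum earns a pair only when at least
    ``match_fraction`` of its (normalized) intensity was matched at all;
    the pair partner is the peak receiving its largest flow.  Exact flow
    ties break toward the geometrically nearer peak, then the lower id.
    With ``strict_one_to_one`` a contested B peak keeps only the A partner
    sending the largest flow (same tie-breaks).
    """
    if not 0.0 < match_fraction <= 1.0:
        raise ValueError("match_fraction must lie in (0, 1]")
    flows_by_a: dict[str, list[tuple[str, float, float]]] = {}
    for ia, ib, mass, dist in plan.matched:
        flows_by_a.setdefault(ia, []).append((ib, mass, dist))

    a_ids = list(plan.unmatched_mass_a)
    b_ids = list(plan.unmatched_mass_b)
    pairs: list[tuple[str, str, float, float]] = []
    unmatched_a: list[str] = []
    for ia in a_ids:
        outs = flows_by_a.get(ia, [])
        matched_mass = sum(m for _, m, _ in outs)
        total = matched_mass + plan.unmatched_mass_a[ia]
        if not outs or matched_mass + 1e-15 < match_fraction * total:
            unmatched_a.append(ia)
            continue
        ib, mass, dist = min(outs, key=lambda t: (-t[1], t[2], t[0]))
        pairs.append((ia, ib, mass, dist))

    if strict_one_to_one:
        best_for_b: dict[str, tuple[str, str, float, float]] = {}
        for pair in pairs:
            ia, ib, mass, dist = pair
            cur = best_for_b.get(ib)
            if cur is None or (-mass, dist, ia) < (-cur[2], cur[3], cur[0]):
                best_for_b[ib] = pair
        demoted = [p[0] for p in pairs if best_for_b[p[1]] is not p]
        pairs = [p for p in pairs if best_for_b[p[1]] is p]
        unmatched_a.extend(demoted)
        unmatched_a.sort(key=a_ids.index)

    matched_b = {p[1] for p in pairs}
    unmatched_b = [ib for ib in b_ids if ib not in matched_b]
    return MatchTable(
        pairs=tuple(pairs),
        unmatched_a=tuple(unmatched_a),
        unmatched_b=tuple(unmatched_b),
    )
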
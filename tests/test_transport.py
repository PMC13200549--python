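"""Transport-layer tests: network construction, W_tr values, invariants."""
import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import wasserstein_distance

from flowalign import (
    Spectrum,
    TransportParams,
    build_candidate_edges,
    build_flow_network,
    netsimplex,
    normalize_spectrum,
    solve_transport,
    truncated_wasserstein,
)
from flowalign.transport_core import quantize_masses

from conftest import random_spectrum


def exhaustive_edges(a, b, params):
    p = {"euclidean": 2, "l1": 1}[params.metric]
    out = []
    for i in range(a.n_peaks):
        for j in range(b.n_peaks):
            d = np.linalg.norm(a.positions[i] - b.positions[j], ord=p)
            if d <= params.prune_radius:
                out.append((i, j, float(d)))
    return sorted(out)


class TestCandidateEdges:
    def test_worked_example(self, spectrum_pair_1d):
        a, b = spectrum_pair_1d
        edges = build_candidate_edges(a, b, TransportParams(5, 5))
        assert len(edges) == 1
        i, j, d = edges[0]
        assert (i, j) == (0, 0) and d == pytest.approx(1.0)

    def test_identical_single_peak(self):
        s = Spectrum(positions=[[1.0, 2.0]], intensities=[1.0],
                     ids=("a",), axes=("x", "y"))
        edges = build_candidate_edges(s, s, TransportParams(0.5, 0.5))
        assert edges == [(0, 0, 0.0)]

    def test_nothing_within_radius(self, spectrum_pair_1d):
        a, b = spectrum_pair_1d
        assert build_candidate_edges(a, b, TransportParams(0.5, 0.5)) == []

    def test_dimension_mismatch(self, spectrum_pair_1d):
        a, _ = spectrum_pair_1d
        b2 = Spectrum(positions=[[0.0, 0.0]], intensities=[1],
                      ids=("b",), axes=("x", "y"))
        with pytest.raises(ValueError):
            build_candidate_edges(a, b2, TransportParams(1, 1))

    @pytest.mark.parametrize("metric", ["euclidean", "l1"])
    def test_equals_exhaustive_enumeration(self, rng, metric):
        for _ in range(10):
            a = random_spectrum(rng, int(rng.integers(1, 20)), dim=2)
            b = random_spectrum(rng, int(rng.integers(1, 20)), dim=2, prefix="q")
            params = TransportParams(d_max=float(rng.random() * 2),
                                     delta_max=float(rng.random() * 2),
                                     metric=metric)
            got = build_candidate_edges(a, b, params)
            want = exhaustive_edges(a, b, params)
            assert [(i, j) for i, j, _ in got] == [(i, j) for i, j, _ in want]
            np.testing.assert_allclose([d for _, _, d in got],
                                       [d for _, _, d in want], rtol=1e-12)


class TestQuantization:
    def test_sums_exactly_to_scale(self, rng):
        for n in (1, 2, 7, 100):
            w = rng.random(n)
            w /= w.sum()
            q = quantize_masses(w, 10 ** 6)
            assert sum(q) == 10 ** 6
            np.testing.assert_array_less(
                np.abs(np.asarray(q, dtype=float) - w * 10 ** 6), 1.0 + 1e-9)

    def test_both_sides_equal_after_quantization(self, rng):
        a = normalize_spectrum(random_spectrum(rng, 9))
        b = normalize_spectrum(random_spectrum(rng, 4, prefix="q"))
        params = TransportParams(1, 1)
        net = build_flow_network(a, b, build_candidate_edges(a, b, params),
                                 params)
        assert sum(net.caps[k] for k in net.supply_arcs) \
            == sum(net.caps[k] for k in net.demand_arcs) \
            == params.intensity_scale


class TestNetworkShape:
    def test_counts_per_construction(self):
        a = normalize_spectrum(Spectrum(positions=[[0.0], [10.0]],
                                        intensities=[1, 1], ids=("a0", "a1"),
                                        axes=("x",)))
        b = normalize_spectrum(Spectrum(positions=[[0.1], [30.0]],
                                        intensities=[1, 1], ids=("b0", "b1"),
                                        axes=("x",)))
        params = TransportParams(5, 5)
        edges = build_candidate_edges(a, b, params)
        assert len(edges) == 1
        net = build_flow_network(a, b, edges, params)
        assert net.n_nodes == 2 + 2 + 2         # peaks + source + sink
        assert net.n_arcs == 2 + 2 + 1 + 1      # supply + demand + match + mismatch
        assert net.tails[net.mismatch_arc] == net.source
        assert net.heads[net.mismatch_arc] == net.sink
        assert sum(net.supply) == 0

    def test_unnormalized_rejected(self, spectrum_pair_1d):
        a, b = spectrum_pair_1d
        with pytest.raises(ValueError, match="normalized"):
            build_flow_network(a, normalize_spectrum(b), [],
                               TransportParams(5, 5))

    def test_empty_candidates_route_via_mismatch(self, spectrum_pair_1d):
        a, b = spectrum_pair_1d
        plan = solve_transport(a, b, TransportParams(0.5, 2.0))
        assert plan.matched == ()
        assert plan.total_cost == pytest.approx(2.0)
        assert plan.mismatch_mass == pytest.approx(1.0)


class TestSolveTransport:
    def test_worked_example_seven_thirds(self, spectrum_pair_1d):
        a, b = spectrum_pair_1d
        plan = solve_transport(a, b, TransportParams(5, 5))
        tol = 10 * (1e-6 + 1e-6)
        assert plan.total_cost == pytest.approx(7 / 3, abs=tol)
        assert len(plan.matched) == 1
        ia, ib, mass, dist = plan.matched[0]
        assert (ia, ib) == ("a0", "b0")
        assert mass == pytest.approx(2 / 3, abs=1e-5)
        assert dist == pytest.approx(1.0)
        assert plan.mismatch_mass == pytest.approx(1 / 3, abs=1e-5)

    def test_self_distance_zero(self, rng):
        s = random_spectrum(rng, 12)
        assert truncated_wasserstein(s, s, TransportParams(1, 1)) == 0.0

    def test_bounded_by_delta_max(self, rng):
        a = random_spectrum(rng, 8)
        b = random_spectrum(rng, 5, prefix="q")
        for delta in (0.05, 0.3, 1.0):
            w = truncated_wasserstein(a, b, TransportParams(0.4, delta))
            assert w <= delta + 1e-9

    def test_empty_spectrum_rejected(self, rng):
        a = random_spectrum(rng, 3)
        empty = Spectrum.empty(("axis0", "axis1"))
        with pytest.raises(ValueError, match="empty"):
            solve_transport(a, empty, TransportParams(1, 1))

    def test_symmetry_exact_in_quantized_arithmetic(self, rng):
        for _ in range(5):
            a = random_spectrum(rng, int(rng.integers(2, 12)))
            b = random_spectrum(rng, int(rng.integers(2, 12)), prefix="q")
            params = TransportParams(0.8, 1.0)
            assert truncated_wasserstein(a, b, params) \
                == truncated_wasserstein(b, a, params)

    def test_matched_distances_within_d_max(self, rng):
        a = random_spectrum(rng, 15)
        b = random_spectrum(rng, 15, prefix="q")
        plan = solve_transport(a, b, TransportParams(0.3, 0.9))
        assert all(d <= 0.3 for _, _, _, d in plan.matched)

    def test_mass_conservation(self, rng):
        a = random_spectrum(rng, 10)
        b = random_spectrum(rng, 13, prefix="q")
        params = TransportParams(0.5, 0.7)
        plan = solve_transport(a, b, params)
        an = normalize_spectrum(a)
        tol = 2 / params.intensity_scale
        for i, pid in enumerate(an.ids):
            total = plan.matched_mass_of_a(pid) + plan.unmatched_mass_a[pid]
            assert total == pytest.approx(an.intensities[i], abs=tol)
        bn = normalize_spectrum(b)
        in_b = {pid: 0.0 for pid in bn.ids}
        for _, ib, m, _ in plan.matched:
            in_b[ib] += m
        for j, pid in enumerate(bn.ids):
            total = in_b[pid] + plan.unmatched_mass_b[pid]
            assert total == pytest.approx(bn.intensities[j], abs=tol)

    def test_cost_identity(self, rng):
        a = random_spectrum(rng, 9)
        b = random_spectrum(rng, 7, prefix="q")
        params = TransportParams(0.5, 0.7)
        plan = solve_transport(a, b, params)
        recomputed = sum(m * d for _, _, m, d in plan.matched) \
            + params.delta_max * plan.mismatch_mass
        # quantization of costs and masses both contribute
        assert plan.total_cost == pytest.approx(recomputed, abs=1e-4)

    def test_monotone_in_delta_max(self, rng):
        a = random_spectrum(rng, 12)
        b = random_spectrum(rng, 12, prefix="q")
        values = [truncated_wasserstein(a, b, TransportParams(0.4, dm))
                  for dm in np.linspace(0.05, 1.5, 10)]
        assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(values, values[1:]))

    def test_1d_closed_form(self, rng):
        params = TransportParams(100.0, 100.0)
        tol = 10 * (1 / params.intensity_scale + 1 / params.cost_scale)
        for _ in range(10):
            a = random_spectrum(rng, int(rng.integers(2, 15)), dim=1, span=5)
            b = random_spectrum(rng, int(rng.integers(2, 15)), dim=1, span=5,
                                prefix="q")
            w = truncated_wasserstein(a, b, params)
            ref = wasserstein_distance(
                a.positions[:, 0], b.positions[:, 0],
                a.intensities, b.intensities)
            assert w == pytest.approx(ref, abs=tol)

    def test_pruning_soundness(self, rng):
        # adding back an arc costlier than delta_max never changes the optimum
        a = normalize_spectrum(random_spectrum(rng, 6))
        b = normalize_spectrum(random_spectrum(rng, 6, prefix="q"))
        params = TransportParams(0.4, 0.4)
        edges = build_candidate_edges(a, b, params)
        base = netsimplex.solve(build_flow_network(a, b, edges, params)).cost
        far = []
        for i in range(a.n_peaks):
            for j in range(b.n_peaks):
                d = float(np.linalg.norm(a.positions[i] - b.positions[j]))
                if d > params.delta_max:
                    far.append((i, j, d))
        assert far, "fixture should contain at least one pruned pair"
        augmented = netsimplex.solve(
            build_flow_network(a, b, edges + far[:3], params)).cost
        assert augmented == base


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    na=st.integers(1, 8), nb=st.integers(1, 8),
    d_max=st.floats(0.05, 2.0), delta=st.floats(0.05, 2.0),
    seed=st.integers(0, 10 ** 6),
)
def test_conservation_and_truncation_property(na, nb, d_max, delta, seed):
    """Any instance: mass conserved, matches within d_max, W_tr <= delta."""
    rng = np.random.default_rng(seed)
    a = random_spectrum(rng, na)
    b = random_spectrum(rng, nb, prefix="q")
    params = TransportParams(d_max, delta, intensity_scale=10 ** 4)
    plan = solve_transport(a, b, params)
    # the mismatch cost is itself rounded at cost_scale resolution
    assert plan.total_cost <= delta + 1 / params.cost_scale
    assert all(d <= d_max + 1e-12 for _, _, _, d in plan.matched)
    an = normalize_spectrum(a)
    tol = 2 / params.intensity_scale
    for i, pid in enumerate(an.ids):
        total = plan.matched_mass_of_a(pid) + plan.unmatched_mass_a[pid]
        assert abs(total - an.intensities[i]) <= tol


def test_plan_serialization_echoes_parameters(spectrum_pair_1d):
    a, b = spectrum_pair_1d
    plan = solve_transport(a, b, TransportParams(5, 5))
    buf = io.StringIO()
    plan.write_tsv(buf)
    text = buf.getvalue()
    assert "# W_tr" in text and "# d_max\t5" in text
    assert "a0\tb0" in text
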
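"""Fragmentation entropy, Monte-Carlo entropy curves and integrated resilience."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiresil import (
    ComponentPartition,
    DisconnectedGraphError,
    MembershipError,
    ParameterError,
    component_partition,
    entropy_curve,
    isolate_nodes,
    msh_entropy,
    resilience,
)
from ppiresil.entropy import _m_of_f, _make_grid

from conftest import graph_from_edges, labelled


def closed_form_complete(n: int, m: int) -> float:
    """Entropy of K_n after isolating any m nodes: parts {n-m, 1 x m}.

    Independent hand evaluation of -(1/log n) * sum p log p.
    """
    if m >= n:
        return 1.0
    terms = 0.0
    big = (n - m) / n
    terms += big * math.log(big)
    terms += m * (1 / n) * math.log(1 / n)
    return -terms / math.log(n)


class TestMshEntropy:
    def test_intact_network_is_zero(self):
        assert msh_entropy(ComponentPartition((10,), 10)) == 0.0

    def test_fully_isolated_is_one(self):
        assert msh_entropy(ComponentPartition((1,) * 10, 10)) == 1.0

    def test_symmetric_halves(self):
        assert msh_entropy(ComponentPartition((2, 2), 4)) == pytest.approx(0.5, abs=1e-14)

    def test_nine_one_partition(self):
        # independent hand computation: -(0.9 ln 0.9 + 0.1 ln 0.1)/ln 10
        expected = -(0.9 * math.log(0.9) + 0.1 * math.log(0.1)) / math.log(10)
        assert msh_entropy(ComponentPartition((9, 1), 10)) == pytest.approx(expected, abs=1e-14)
        assert expected == pytest.approx(0.141182, abs=1e-6)

    def test_single_node_network_is_out_of_scope(self):
        with pytest.raises(ParameterError):
            msh_entropy(ComponentPartition((1,), 1))

    @pytest.mark.parametrize("sizes,total", [((2, 2), 5), ((0, 4), 4), ((), 0)])
    def test_invalid_partitions(self, sizes, total):
        with pytest.raises(ParameterError):
            ComponentPartition(sizes, total)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    sizes=st.lists(st.integers(1, 20), min_size=1, max_size=12).filter(
        lambda s: sum(s) >= 2
    ),
    data=st.data(),
)
def test_refinement_never_decreases_entropy(sizes, data):
    """Splitting one component into two nonempty parts raises H (strictly
    when the split part had size >= 2); H always stays within [0, 1]."""
    total = sum(sizes)
    h = msh_entropy(ComponentPartition(tuple(sizes), total))
    assert 0.0 <= h <= 1.0
    idx = data.draw(st.integers(0, len(sizes) - 1))
    if sizes[idx] < 2:
        return
    cut = data.draw(st.integers(1, sizes[idx] - 1))
    refined = list(sizes)
    refined[idx : idx + 1] = [cut, sizes[idx] - cut]
    h2 = msh_entropy(ComponentPartition(tuple(refined), total))
    assert h2 > h


class TestIsolateAndPartition:
    def test_isolating_star_hub_strands_every_leaf(self):
        star5 = labelled(nx.star_graph(4), "star5")
        out = isolate_nodes(star5, ["v00"])
        assert component_partition(out).sizes == (1, 1, 1, 1, 1)

    def test_isolating_nothing_is_identity(self, k6):
        out = isolate_nodes(k6, [])
        assert out.number_of_edges() == k6.number_of_edges()

    def test_isolating_everything_leaves_edgeless_graph(self, k6):
        out = isolate_nodes(k6, list(k6.nodes()))
        assert out.number_of_edges() == 0
        assert out.number_of_nodes() == 6

    def test_unknown_target(self, k6):
        with pytest.raises(MembershipError):
            isolate_nodes(k6, ["ghost"])

    def test_partition_examples(self, k6, path3):
        assert component_partition(k6).sizes == (6,)
        edgeless = nx.Graph()
        edgeless.add_nodes_from("abcde")
        assert component_partition(edgeless).sizes == (1,) * 5
        assert component_partition(isolate_nodes(path3, ["b"])).sizes == (1, 1, 1)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), data=st.data())
    def test_isolation_monotonicity(self, seed, data):
        """Nested isolation sets give nested entropy: H(S') >= H(S) for S ⊆ S'."""
        g = labelled(nx.gnp_random_graph(12, 0.25, seed=seed), "er")
        nodes = sorted(g.nodes())
        sub = data.draw(st.sets(st.sampled_from(nodes), max_size=8))
        extra = data.draw(st.sets(st.sampled_from(nodes), max_size=4))
        small = component_partition(isolate_nodes(g, sub))
        large = component_partition(isolate_nodes(g, sub | extra))
        assert msh_entropy(large) >= msh_entropy(small) - 1e-12


class TestEntropyCurve:
    def test_grid_and_endpoints(self, k10):
        curve = entropy_curve(k10, step=0.01, reps=3, seed=0)
        assert curve.grid[0] == 0.0 and curve.grid[-1] == 1.0
        assert np.all(np.diff(curve.grid) > 0)
        assert curve.mean_H[0] == 0.0  # intact network
        assert curve.mean_H[-1] == 1.0  # fully isolated
        assert np.all((curve.mean_H >= 0.0) & (curve.mean_H <= 1.0))

    @pytest.mark.parametrize("reps,seed", [(1, 0), (7, 123)])
    def test_complete_graph_matches_closed_form(self, k10, reps, seed):
        """Symmetry oracle: simulation equals the closed form for any reps/seed."""
        curve = entropy_curve(k10, step=0.01, reps=reps, seed=seed)
        for f, h in zip(curve.grid, curve.mean_H):
            assert h == pytest.approx(closed_form_complete(10, _m_of_f(f, 10)), abs=1e-12)

    def test_kernel_agrees_with_networkx_partition(self):
        """Dual route: the union-find kernel vs explicit networkx components."""
        rng = np.random.default_rng(5)
        for seed in range(10):
            g = labelled(nx.gnp_random_graph(15, 0.2, seed=seed), "er")
            g = nx.subgraph(g, max(nx.connected_components(g), key=len)).copy()
            if g.number_of_nodes() < 3:
                continue
            curve = entropy_curve(g, step=0.25, reps=4, seed=seed, keep_replicates=True)
            # recompute f=0 point independently
            h0 = msh_entropy(component_partition(g))
            assert curve.mean_H[0] == pytest.approx(h0, abs=1e-12)

    def test_disconnected_input_rejected(self):
        g = graph_from_edges(("a", "b"), ("c", "d"))
        with pytest.raises(DisconnectedGraphError):
            entropy_curve(g, step=0.5, reps=1, seed=0)

    def test_seed_determinism(self, k6):
        c1 = entropy_curve(k6, step=0.05, reps=10, seed=42)
        c2 = entropy_curve(k6, step=0.05, reps=10, seed=42)
        assert np.array_equal(c1.mean_H, c2.mean_H)
        assert np.array_equal(c1.sd_H, c2.sd_H)

    def test_rounding_convention(self):
        # m(f) = floor(f*N + 0.5): round half up, m(1) = N exactly
        assert _m_of_f(0.24, 2) == 0
        assert _m_of_f(0.25, 2) == 1
        assert _m_of_f(1.0, 2) == 2
        assert _m_of_f(0.35, 10) == 4

    def test_grid_covers_unit_interval_for_uneven_step(self):
        grid = _make_grid(0.3)
        assert grid[0] == 0.0 and grid[-1] == 1.0


class TestResilience:
    def test_single_edge_hand_computed(self, single_edge):
        """P2 at 1% steps: H jumps 0 -> 1 between f=0.24 and f=0.25; the
        trapezoid integral is 0.755, so R = 0.245 (hand computation)."""
        res = resilience(single_edge, step=0.01, reps=5, seed=0)
        assert res.value == pytest.approx(0.245, abs=1e-12)

    def test_complete_graph_matches_closed_form_integral(self, k10):
        grid = _make_grid(0.01)
        hs = [closed_form_complete(10, _m_of_f(f, 10)) for f in grid]
        expected = 1.0 - np.trapezoid(hs, grid)
        res = resilience(k10, step=0.01, reps=3, seed=9)
        assert res.value == pytest.approx(expected, abs=1e-12)

    def test_integration_rule_stability(self, k10):
        r1 = resilience(k10, step=0.01, reps=1, seed=0).value
        r2 = resilience(k10, step=0.005, reps=1, seed=0).value
        assert abs(r1 - r2) < 0.01

    def test_range(self, cycle6):
        res = resilience(cycle6, step=0.05, reps=20, seed=3)
        assert 0.0 <= res.value <= 1.0

    def test_serialization_roundtrip(self, k6, tmp_path):
        res = resilience(k6, step=0.1, reps=4, seed=1)
        res.curve.to_tsv(tmp_path / "c.tsv")
        res.to_json(tmp_path / "r.json")
        import json

        import pandas as pd

        frame = pd.read_csv(tmp_path / "c.tsv", sep="\t")
        assert list(frame.columns) == ["f", "mean_H", "sd_H", "reps"]
        assert np.allclose(frame["mean_H"], res.curve.mean_H)
        meta = json.loads((tmp_path / "r.json").read_text())
        assert meta["R"] == pytest.approx(res.value)
        assert meta["seed"] == 1
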
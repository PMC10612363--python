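import io
import itertools

import networkx as nx
import numpy as np
import pytest

from ystrkit.network import (
    HaplotypeNetwork,
    NetworkInput,
    export_network,
    import_network,
    median_joining,
    minimum_spanning_network,
    mp_prune,
    prepare_network_input,
)

from .conftest import int_panel, parse_text, table_text


def manhattan(u, v):
    return sum(abs(a - b) for a, b in zip(u, v))


def kruskal_mst_length(vectors):
    g = nx.Graph()
    for i, u in enumerate(vectors):
        for j in range(i + 1, len(vectors)):
            g.add_edge(i, j, weight=manhattan(u, vectors[j]))
    tree = nx.minimum_spanning_tree(g, weight="weight")
    return sum(d["weight"] for _, _, d in tree.edges(data=True))


def steiner_oracle(vectors):
    """Brute-force Steiner optimum over the allele bounding box: minimum MST
    length over the terminals plus up to k-2 extra lattice points."""
    dims = len(vectors[0])
    lo = [min(v[i] for v in vectors) for i in range(dims)]
    hi = [max(v[i] for v in vectors) for i in range(dims)]
    box = list(itertools.product(*[range(l, h + 1) for l, h in zip(lo, hi)]))
    candidates = [b for b in box if b not in set(vectors)]

    def mst_len(points):
        if len(points) < 2:
            return 0.0
        g = nx.Graph()
        for i, u in enumerate(points):
            for j in range(i + 1, len(points)):
                g.add_edge(i, j, weight=manhattan(u, points[j]))
        tree = nx.minimum_spanning_tree(g, weight="weight")
        return sum(d["weight"] for _, _, d in tree.edges(data=True))

    best = mst_len(vectors)
    for r in range(1, max(0, len(vectors) - 2) + 1):
        for extra in itertools.combinations(candidates, r):
            best = min(best, mst_len(list(vectors) + list(extra)))
    return best


class TestPrepareInput:
    def test_microvariant_rounded(self, panel27):
        sample = parse_text(table_text(panel27, [{"DYS458": "17.2"}]), panel27)
        entries, excluded, loci = prepare_network_input(sample)
        idx = loci.index("DYS458")
        assert entries[0].vector[idx] == 17
        assert excluded == []

    def test_half_up_rounding(self, panel27):
        # .3 microvariant at DYS458: 17.3 -> 17; dialect caps fractions at .3
        sample = parse_text(table_text(panel27, [{"DYS458": "17.3"}]), panel27)
        entries, _, loci = prepare_network_input(sample)
        assert entries[0].vector[loci.index("DYS458")] == 17

    def test_dual_copy_dropped(self, panel27):
        sample = parse_text(table_text(panel27, [{}]), panel27)
        _, _, loci = prepare_network_input(sample)
        assert "DYS385" not in loci and "DYF387S1" not in loci
        assert len(loci) == 23

    def test_identical_records_collapsed(self, panel27):
        sample = parse_text(table_text(panel27, [{}, {}]), panel27)
        entries, _, _ = prepare_network_input(sample)
        assert len(entries) == 1
        assert entries[0].multiplicity == 2

    def test_null_record_excluded(self, panel27):
        rows = [{"sample_id": "A"}, {"sample_id": "B", "DYS448": "-"}]
        sample = parse_text(table_text(panel27, rows), panel27)
        entries, excluded, _ = prepare_network_input(sample)
        assert excluded == ["B"]
        assert sum(e.multiplicity for e in entries) == 1

    def test_all_excluded_errors(self, panel27):
        sample = parse_text(table_text(panel27, [{"DYS448": "-"}]), panel27)
        with pytest.raises(ValueError):
            prepare_network_input(sample)


class TestMedianJoining:
    def test_single_locus_path(self):
        net = median_joining([(10,), (11,), (12,)], weights=[1.0])
        assert sorted(net.graph.edges) == [((10,), (11,)), ((11,), (12,))]
        assert net.median_nodes() == []

    def test_triplet_median_added(self):
        net = median_joining(
            [(10, 10, 10), (11, 11, 10), (11, 10, 11)], weights=[1.0] * 3
        )
        assert (11, 10, 10) in net.graph
        assert net.graph.nodes[(11, 10, 10)]["kind"] == "median"
        assert net.min_spanning_length() == 3.0  # MST over sampled alone is 4

    def test_star_founder_is_hub(self):
        founder = (10, 10, 10, 10)
        derived = [
            (11, 10, 10, 10),
            (9, 10, 10, 10),
            (10, 11, 10, 10),
            (10, 10, 9, 10),
            (10, 10, 10, 11),
        ]
        net = median_joining([founder] + derived, weights=[1.0] * 4)
        degrees = dict(net.graph.degree())
        assert degrees[founder] == len(derived)
        assert all(degrees[d] == 1 for d in derived)

    def test_single_vector_single_node(self):
        net = median_joining([(10, 11)], weights=[1.0, 1.0])
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_multiplicities_aggregated(self):
        entries = [
            NetworkInput((10,), 2, (("POP1", 2),)),
            NetworkInput((10,), 3, (("POP2", 3),)),
            NetworkInput((11,), 1),
        ]
        net = median_joining(entries, weights=[1.0])
        assert net.graph.nodes[(10,)]["multiplicity"] == 5
        assert net.graph.nodes[(10,)]["labels"] == {"POP1": 2, "POP2": 3}

    def test_edge_weights_recomputable(self):
        rng = np.random.default_rng(17)
        vecs = sorted({tuple(int(x) for x in rng.integers(10, 14, 3)) for _ in range(6)})
        weights = (1.0, 2.0, 0.5)
        net = median_joining(vecs, weights=weights)
        for u, v, d in net.graph.edges(data=True):
            assert d["weight"] == pytest.approx(
                sum(w * abs(a - b) for a, b, w in zip(u, v, weights))
            )

    def test_per_locus_steps_sum_to_weight(self):
        net = median_joining([(10, 10), (12, 11)], weights=[1.0, 1.0])
        for u, v, d in net.graph.edges(data=True):
            assert sum(abs(s) for s in d["steps"].values()) == pytest.approx(d["weight"])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            median_joining([])
        with pytest.raises(ValueError):
            median_joining([(10, 11), (10,)])
        with pytest.raises(ValueError):
            median_joining([(10,), (11,)], weights=[0.0])


class TestMsnContainsMst:
    @pytest.mark.parametrize("seed", range(5))
    def test_msn_contains_every_mst_edge_weight(self, seed):
        rng = np.random.default_rng(seed)
        vecs = sorted(
            {tuple(int(x) for x in rng.integers(10, 14, 3)) for _ in range(8)}
        )
        if len(vecs) < 3:
            pytest.skip("degenerate draw")
        msn = minimum_spanning_network(vecs, weights=[1.0] * 3, epsilon=0.0)
        # the MSN restricted to its own edges must achieve the Kruskal MST length
        tree = nx.minimum_spanning_tree(msn, weight="weight")
        got = sum(d["weight"] for _, _, d in tree.edges(data=True))
        assert got == pytest.approx(kruskal_mst_length(vecs))

    def test_epsilon_relaxation_adds_links(self):
        vecs = [(10, 10), (12, 10), (11, 12)]
        strict = minimum_spanning_network(vecs, weights=[1.0, 1.0], epsilon=0.0)
        relaxed = minimum_spanning_network(vecs, weights=[1.0, 1.0], epsilon=2.0)
        assert set(strict.edges) <= set(relaxed.edges)
        assert relaxed.number_of_edges() >= strict.number_of_edges()


class TestMpPrune:
    def test_tree_unchanged(self):
        net = median_joining([(10,), (11,), (12,)], weights=[1.0])
        pruned = mp_prune(net)
        assert sorted(pruned.graph.edges) == sorted(net.graph.edges)
        assert pruned.metadata["mp_exhaustive"] is True

    def test_square_keeps_all_optimal_sides(self):
        # 4 corners of a 2x2 box: all four side edges lie in some minimum
        # spanning structure; the (longer) diagonals must be absent
        corners = [(10, 10), (10, 12), (12, 12), (12, 10)]
        net = median_joining(corners, weights=[1.0, 1.0])
        pruned = mp_prune(net)
        edges = {frozenset(e) for e in pruned.graph.edges}
        sides = {
            frozenset(((10, 10), (10, 12))),
            frozenset(((10, 12), (12, 12))),
            frozenset(((12, 12), (12, 10))),
            frozenset(((12, 10), (10, 10))),
        }
        assert edges == sides

    def test_length_monotone(self):
        rng = np.random.default_rng(23)
        vecs = sorted({tuple(int(x) for x in rng.integers(10, 14, 4)) for _ in range(7)})
        net = median_joining(vecs, weights=[1.0] * 4)
        pruned = mp_prune(net)
        assert pruned.total_length <= net.total_length + 1e-9
        sampled = set(net.sampled_nodes())
        assert sampled <= set(pruned.graph.nodes)
        assert nx.is_connected(pruned.graph)


class TestSteinerOptimality:
    @pytest.mark.parametrize("seed", range(10))
    def test_small_instances_reach_steiner_optimum(self, seed):
        rng = np.random.default_rng(100 + seed)
        k = int(rng.integers(3, 6))
        dims = int(rng.integers(2, 5))
        vecs = sorted({tuple(int(x) for x in rng.integers(10, 13, dims)) for _ in range(k)})
        if len(vecs) < 2:
            pytest.skip("degenerate draw")
        net = mp_prune(median_joining(vecs, weights=[1.0] * dims))
        assert net.min_spanning_length() == pytest.approx(steiner_oracle(vecs))


class TestExport:
    def test_edge_table_rows(self):
        net = median_joining([(10,), (11,), (12,)], weights=[1.0])
        buf = io.StringIO()
        export_network(net, buf)
        edge_rows = [
            ln for ln in buf.getvalue().splitlines()
            if ln.startswith("EDGE\t") and not ln.startswith("EDGE\tu")
        ]
        assert len(edge_rows) == 2

    def test_tsv_roundtrip_isomorphic(self):
        rng = np.random.default_rng(31)
        vecs = sorted({tuple(int(x) for x in rng.integers(10, 14, 3)) for _ in range(6)})
        net = median_joining(vecs, weights=[1.0, 2.0, 1.0], loci=("A", "B", "C"))
        buf = io.StringIO()
        export_network(net, buf)
        buf.seek(0)
        back = import_network(buf)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert {frozenset(e) for e in back.graph.edges} == {
            frozenset(e) for e in net.graph.edges
        }
        assert back.loci == net.loci
        assert back.weights == net.weights

    def test_gml_export(self):
        net = median_joining([(10,), (12,)], weights=[1.0])
        buf = io.StringIO()
        export_network(net, buf, fmt="gml")
        assert "graph" in buf.getvalue()

    def test_unknown_format(self):
        net = median_joining([(10,), (12,)], weights=[1.0])
        with pytest.raises(ValueError):
            export_network(net, io.StringIO(), fmt="dot")

    def test_export_deterministic(self):
        vecs = [(10, 10), (11, 12), (12, 10), (11, 11)]
        out = []
        for _ in range(2):
            net = mp_prune(median_joining(vecs, weights=[1.0, 1.0]))
            buf = io.StringIO()
            export_network(net, buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]
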
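"""Graph simplification, degree extraction and the density filter."""

import numpy as np
import pytest

from sftest import (
    DegreeSequence,
    Edge,
    NetworkDataset,
    ValidationError,
    degree_sequence,
    density_filter,
    simplify_dataset,
)


def triangle():
    return NetworkDataset("triangle", [("a", "b"), ("b", "c"), ("c", "a")])


class TestSimplifyDataset:
    def test_simple_input_is_identity(self):
        out = simplify_dataset(triangle())
        assert len(out) == 1
        g = out[0]
        assert g.edges == frozenset(
            {frozenset(p) for p in [("a", "b"), ("b", "c"), ("c", "a")]})

    def test_weights_discarded_topology_unchanged(self):
        ds = NetworkDataset("w", [("a", "b", 3.5), ("b", "c", 0.1)],
                            flags={"weighted"})
        out = simplify_dataset(ds)
        assert len(out) == 1
        assert out[0].edges == frozenset(
            {frozenset(("a", "b")), frozenset(("b", "c"))})

    def test_multigraph_collapsed_and_self_loops_dropped(self):
        ds = NetworkDataset(
            "m", [("a", "b"), ("a", "b"), ("b", "b"), ("b", "c")],
            flags={"multigraph"})
        out = simplify_dataset(ds)
        assert out[0].edges == frozenset(
            {frozenset(("a", "b")), frozenset(("b", "c"))})

    def test_directed_yields_three_views_including_in_degrees(self):
        ds = NetworkDataset("d", [("a", "b"), ("c", "b"), ("b", "a")],
                            flags={"directed"})
        out = simplify_dataset(ds)
        assert len(out) == 3
        modes = {g.degree_mode for g in out}
        assert modes == {"in", "out", "undirected"}
        in_view = next(g for g in out if g.degree_mode == "in")
        seq = degree_sequence(in_view)
        # in-degrees: a<-b (1), b<-a,c (2), c (0)
        assert sorted(seq.degrees.tolist()) == [0, 1, 2]

    def test_bipartite_yields_one_sequence_per_class(self):
        part = {"u1": 0, "u2": 0, "v1": 1, "v2": 1, "v3": 1}
        ds = NetworkDataset(
            "b", [("u1", "v1"), ("u1", "v2"), ("u2", "v2"), ("u2", "v3")],
            flags={"bipartite"}, node_partition=part)
        out = simplify_dataset(ds)
        assert len(out) == 2
        seqs = sorted(degree_sequence(g).degrees.tolist() for g in out)
        assert seqs == [[1, 1, 2], [2, 2]]

    def test_multiplex_layers_plus_union(self):
        ds = NetworkDataset(
            "mx",
            [("a", "b", None, 1), ("b", "c", None, 1), ("a", "c", None, 2)],
            flags={"multiplex"})
        out = simplify_dataset(ds)
        assert len(out) == 3  # layer 1, layer 2, union
        provs = " | ".join(g.provenance for g in out)
        assert "layer union" in provs

    def test_temporal_slices_plus_union(self):
        ds = NetworkDataset(
            "t",
            [Edge("a", "b", timestamp=0.0), Edge("b", "c", timestamp=1.0)],
            flags={"temporal"})
        out = simplify_dataset(ds)
        assert len(out) == 3  # two slices + aggregated union

    def test_directed_multiplex_composition(self):
        ds = NetworkDataset(
            "dm",
            [Edge("a", "b", layer="x"), Edge("b", "a", layer="y")],
            flags={"directed", "multiplex"})
        out = simplify_dataset(ds)
        assert len(out) == 9  # (2 layers + union) x 3 direction views

    def test_idempotent_on_simple_graph(self):
        once = simplify_dataset(triangle())[0]
        again = simplify_dataset(
            NetworkDataset("again", [tuple(sorted(e)) for e in
                                     [tuple(x) for x in once.edges]]))[0]
        assert once.edges == again.edges

    def test_outputs_always_simple(self):
        ds = NetworkDataset(
            "mess",
            [("a", "a"), ("a", "b"), ("b", "a"), ("a", "b")],
            flags={"directed", "multigraph"})
        for g in simplify_dataset(ds):
            for e in g.edges:
                assert len(e) == 2  # no self-loops, sets deduplicate

    def test_bipartite_without_partition_fails(self):
        with pytest.raises(ValidationError):
            NetworkDataset("bad", [("a", "b")], flags={"bipartite"})

    def test_layer_flag_consistency_enforced(self):
        with pytest.raises(ValidationError):
            NetworkDataset("bad", [Edge("a", "b", layer=1)], flags=frozenset())


class TestDegreeSequence:
    def test_triangle_degrees(self):
        seq = degree_sequence(simplify_dataset(triangle())[0])
        assert seq.degrees.tolist() == [2, 2, 2]

    def test_star_degrees(self):
        ds = NetworkDataset("star", [("h", f"l{i}") for i in range(4)])
        seq = degree_sequence(simplify_dataset(ds)[0])
        assert sorted(seq.degrees.tolist()) == [1, 1, 1, 1, 4]

    def test_path_handshake_identity(self):
        ds = NetworkDataset("path", [("a", "b"), ("b", "c")])
        seq = degree_sequence(simplify_dataset(ds)[0])
        assert sorted(seq.degrees.tolist()) == [1, 1, 2]
        assert seq.degrees.sum() == 2 * 2

    def test_isolated_nodes_retained(self):
        ds = NetworkDataset("iso", [("a", "b")], nodes={"a", "b", "c"})
        seq = degree_sequence(simplify_dataset(ds)[0])
        assert sorted(seq.degrees.tolist()) == [0, 1, 1]

    def test_sorted_ascending(self):
        seq = DegreeSequence(np.array([5, 1, 3]))
        assert seq.degrees.tolist() == [1, 3, 5]

    def test_empty_graph_fails(self):
        from sftest.simplify import SimpleGraph

        g = SimpleGraph(frozenset(), frozenset(), "empty")
        with pytest.raises(ValidationError):
            degree_sequence(g)


class TestDensityFilter:
    @pytest.mark.parametrize(
        "mean,n,expected",
        [
            (1.5, 100, "too_sparse"),
            (11.0, 100, "too_dense"),  # sqrt(100) = 10
            (5.0, 100, "retain"),
            (2.0, 100, "too_sparse"),  # boundary excluded
            (10.0, 100, "too_dense"),  # boundary excluded
        ],
    )
    def test_filter_rule(self, mean, n, expected):
        # build an integer sequence with the exact target mean
        total = int(round(mean * n))
        degrees = np.full(n, total // n)
        degrees[: total - degrees.sum()] += 1
        seq = DegreeSequence(degrees)
        assert seq.mean_degree == pytest.approx(mean)
        assert density_filter(seq) == expected

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = DegreeSequence(rng.integers(0, 30, size=int(rng.integers(4, 50))))
            assert density_filter(seq) in {"retain", "too_sparse", "too_dense"}
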
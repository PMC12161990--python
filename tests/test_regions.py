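"""Region extraction: normalisation, embedding, graph, thresholding, Rand index."""

import itertools

import networkx as nx
import numpy as np
import pytest

from resort import (
    RunConfig,
    SpatialCounts,
    ValidationError,
    build_spot_graph,
    detect_regions,
    erode_assignment,
    extract_regions,
    normalize_log,
    pca_embed,
    rand_index,
    scenario,
    select_epsilon,
    simulate,
)
from resort.types import UNASSIGNED

from conftest import random_spatial_counts


def flood_fill_components(nodes, edges):
    """Independent oracle: BFS traversal of an undirected edge list."""
    adj = {n: [] for n in nodes}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            n = queue.pop()
            if n in comp:
                continue
            comp.add(n)
            queue.extend(m for m in adj[n] if m not in comp)
        seen |= comp
        comps.append(comp)
    return comps


class TestNormalizeLog:
    def test_library_size_invariance(self, rng):
        # equal libraries keep the median anchor fixed, so scaling one spot's
        # counts must leave its normalised profile unchanged
        base = rng.multinomial(100, np.ones(8) / 8, size=9)
        coords = np.column_stack([np.zeros(9, dtype=int), np.arange(9)])
        ids = [f"s{i}" for i in range(9)]
        genes = [f"g{j}" for j in range(8)]
        sc = SpatialCounts(base, genes, ids, coords)
        norm = normalize_log(sc)
        scaled_counts = base.copy()
        scaled_counts[0] *= 5
        scaled = SpatialCounts(scaled_counts, genes, ids, coords)
        assert np.allclose(normalize_log(scaled)[0], norm[0])

    def test_zero_library_spot_named_in_error(self, small_counts):
        counts = small_counts.counts.copy()
        counts[2] = 0
        bad = SpatialCounts(
            counts, small_counts.gene_ids, small_counts.spot_ids, small_counts.coords
        )
        with pytest.raises(ValidationError, match="s2"):
            normalize_log(bad)


class TestPcaEmbed:
    def test_duplicated_rows_get_identical_embeddings(self, rng):
        x = rng.normal(size=(10, 6))
        x[3] = x[7]
        emb = pca_embed(x, 3)
        assert np.allclose(emb[3], emb[7])

    def test_component_variances_are_ordered(self, rng):
        emb = pca_embed(rng.normal(size=(40, 8)), 4)
        var = emb.var(axis=0)
        assert np.all(np.diff(var) <= 1e-12)

    def test_low_rank_data_fully_captured(self, rng):
        basis = rng.normal(size=(2, 12))
        x = rng.normal(size=(30, 2)) @ basis
        emb = pca_embed(x, 2)
        # scores retain all the variance of the rank-2 data
        assert emb.var(axis=0).sum() == pytest.approx(
            (x - x.mean(0)).var(axis=0).sum(), rel=1e-9
        )

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValidationError, match="k_pcs"):
            pca_embed(rng.normal(size=(5, 3)), 4)


class TestSpotGraph:
    @staticmethod
    def _grid_coords(n_rows, n_cols):
        rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])

    def test_identical_embeddings_weight_one(self):
        emb = np.tile([1.0, 2.0, 3.0], (2, 1))
        g = build_spot_graph(emb, [[0, 0], [0, 1]], "grid4")
        assert g.edges[0, 1]["weight"] == pytest.approx(1.0)

    def test_opposite_embeddings_weight_minus_one(self):
        u = np.array([1.0, -2.0, 0.5])
        g = build_spot_graph(np.vstack([u, -u]), [[0, 0], [0, 1]], "grid4")
        assert g.edges[0, 1]["weight"] == pytest.approx(-1.0)

    def test_interior_spot_degree_per_scheme(self, rng):
        coords = self._grid_coords(5, 5)
        emb = rng.normal(size=(25, 3))
        center = 12  # (2, 2)
        assert build_spot_graph(emb, coords, "grid4").degree[center] == 4
        assert build_spot_graph(emb, coords, "grid8").degree[center] == 8
        assert build_spot_graph(emb, coords, "hex6").degree[center] == 6

    def test_single_spot_rejected(self):
        with pytest.raises(ValidationError, match="two spots"):
            build_spot_graph(np.ones((1, 3)), [[0, 0]], "grid4")


class TestSelectEpsilon:
    def test_retained_edges_non_increasing_in_epsilon(self, rng):
        coords = self._coords = TestSpotGraph._grid_coords(6, 6)
        g = build_spot_graph(rng.normal(size=(36, 4)), coords, "grid4")
        weights = sorted(w for _, _, w in g.edges(data="weight"))
        kept = [
            sum(1 for _, _, w in g.edges(data="weight") if w >= eps)
            for eps in weights
        ]
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_all_equal_weights_warns_and_returns_weight(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=0.7)
        g.add_edge(1, 2, weight=0.7)
        with pytest.warns(UserWarning, match="identical"):
            assert select_epsilon(g, 1) == pytest.approx(0.7)

    def test_two_block_fixture_separates(self):
        scen = scenario("two-block-regions", grid=(8, 16), seed=0)
        config = RunConfig(rng_seed=0, noise_sd=0.0, min_region_size=20)
        res = simulate(scen.reference, scen.layout, config)
        assignment, _ = detect_regions(res.counts, min_region_size=20)
        truth = scen.layout.region_label_per_spot()
        assert len(assignment.region_sizes) == 2
        assert rand_index(assignment.labels, truth) == pytest.approx(1.0)


class TestExtractRegions:
    @staticmethod
    def _random_graph(rng, n_nodes):
        g = nx.gnp_random_graph(n_nodes, 0.04, seed=int(rng.integers(2**31)))
        weighted = nx.Graph()
        weighted.add_nodes_from(g.nodes)
        for u, v in g.edges:
            weighted.add_edge(u, v, weight=float(rng.uniform(-1, 1)))
        return weighted

    def test_matches_flood_fill_oracle_on_random_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 200))
            g = self._random_graph(rng, n)
            eps = float(rng.uniform(-0.5, 0.5))
            m = int(rng.integers(1, 6))
            got = extract_regions(g, eps, m)
            kept = [(u, v) for u, v, w in g.edges(data="weight") if w >= eps]
            oracle = flood_fill_components(list(g.nodes), kept)
            by_label = {}
            for node, lab in zip(sorted(g.nodes), got.labels):
                by_label.setdefault(lab, set()).add(node)
            expected_big = {frozenset(c) for c in oracle if len(c) >= m}
            got_big = {
                frozenset(c) for lab, c in by_label.items() if lab != UNASSIGNED
            }
            assert got_big == expected_big

    def test_small_components_unassigned_at_default_m(self):
        g = nx.Graph()
        for u, v in itertools.pairwise(range(39)):
            g.add_edge(u, v, weight=1.0)
        got = extract_regions(g, 0.5, 40)
        assert set(got.labels) == {UNASSIGNED}
        got = extract_regions(g, 0.5, 39)
        assert set(got.labels) == {"R1"}

    def test_m_one_assigns_every_spot(self, rng):
        g = self._random_graph(rng, 50)
        got = extract_regions(g, 0.0, 1)
        assert UNASSIGNED not in set(got.labels)

    def test_raising_m_never_adds_spots(self, rng):
        g = self._random_graph(rng, 120)
        counts = [
            int(extract_regions(g, 0.0, m).assigned_mask.sum()) for m in (1, 5, 20, 60)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRandIndex:
    def test_identical_partitions(self):
        assert rand_index(list("aabb"), list("aabb")) == 1.0

    def test_hand_enumerated_pair_counts(self):
        # {a,a,b,b} vs {a,b,a,b}: of the 6 spot pairs only (0,2)-style splits
        # agree twice -> 2/6.
        assert rand_index(list("aabb"), list("abab")) == pytest.approx(1 / 3)

    def test_label_permutation_invariance(self):
        assert rand_index(list("xxxx"), list("yyyy")) == 1.0

    def test_bruteforce_pair_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 30))
            a = rng.integers(0, 3, size=n).astype(str)
            b = rng.integers(0, 3, size=n).astype(str)
            agree = sum(
                ((a[i] == a[j]) == (b[i] == b[j]))
                for i, j in itertools.combinations(range(n), 2)
            )
            assert rand_index(a, b, unassigned=None) == pytest.approx(
                agree / (n * (n - 1) / 2)
            )

    def test_unassigned_excluded_pairwise(self):
        a = ["x", "x", UNASSIGNED, "y"]
        b = ["p", "p", "q", UNASSIGNED]
        assert rand_index(a, b) == 1.0

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValidationError, match="different"):
            rand_index(["a"], ["a", "b"])


class TestErosion:
    def test_rim_abutting_unassigned_is_stripped(self):
        # a 3x3 labelled block inside an unassigned sea erodes to its centre
        coords = TestSpotGraph._grid_coords(5, 5)
        labels = np.asarray([UNASSIGNED] * 25, dtype=object)
        block = (
            (coords[:, 0] >= 1) & (coords[:, 0] <= 3)
            & (coords[:, 1] >= 1) & (coords[:, 1] <= 3)
        )
        labels[block] = "R1"
        from resort.types import RegionAssignment

        a = RegionAssignment(labels, [f"s{i}" for i in range(25)])
        eroded = erode_assignment(a, coords, depth=1)
        assert (eroded.labels == "R1").sum() == 1
        assert eroded.labels[12] == "R1"  # (2, 2)

    def test_interior_of_single_full_region_untouched(self):
        # with no unassigned neighbours there is no boundary evidence to erode
        coords = TestSpotGraph._grid_coords(4, 4)
        from resort.types import RegionAssignment

        a = RegionAssignment(["R1"] * 16, [f"s{i}" for i in range(16)])
        eroded = erode_assignment(a, coords, depth=1)
        assert np.all(eroded.labels == "R1")

    def test_region_never_fully_erased(self):
        coords = np.array([[0, 0], [0, 1]])
        from resort.types import RegionAssignment

        a = RegionAssignment(["R1", UNASSIGNED], ["s0", "s1"])
        eroded = erode_assignment(a, coords, depth=3)
        assert eroded.region_sizes == {"R1": 1}


def test_permutation_invariance_of_detection(rng):
    """Shuffling spot rows permutes the assignment but not the partition."""
    scen = scenario("two-block-regions", grid=(6, 12), seed=4)
    config = RunConfig(rng_seed=4, noise_sd=0.0)
    res = simulate(scen.reference, scen.layout, config)
    a1, _ = detect_regions(res.counts, min_region_size=10)
    perm = rng.permutation(res.counts.n_spots)
    shuffled = SpatialCounts(
        res.counts.counts[perm],
        res.counts.gene_ids,
        [res.counts.spot_ids[i] for i in perm],
        res.counts.coords[perm],
    )
    a2, _ = detect_regions(shuffled, min_region_size=10)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    assert rand_index(a1.labels, a2.labels[inv], unassigned=None) == 1.0
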
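"""Homogeneous spatial region extraction.

The approach combines molecular similarity and physical adjacency: spots are
library-normalised and log-transformed, embedded with PCA, and connected to
their grid neighbours with edge weights equal to the Pearson correlation of
their embeddings.  Low-weight edges are dropped at a threshold ε — selected
automatically from the edge-weight distribution unless given — and the
connected components with at least ``m`` spots become the molecular regions;
everything else is left unassigned.  Mixture spots between regions sit near
the centre of the embedding simplex where sampling noise dominates, so their
edges are weak and regions separate at the chosen ε.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import rand_score

from .types import UNASSIGNED, RegionAssignment, SpatialCounts, ValidationError

logger = logging.getLogger("resort")

_OFFSETS = {
    "grid4": [(-1, 0), (1, 0), (0, -1), (0, 1)],
    "grid8": [
        (-1, -1), (-1, 0), (-1, 1),
        (0, -1), (0, 1),
        (1, -1), (1, 0), (1, 1),
    ],
}


def _hex_offsets(row: int) -> list[tuple[int, int]]:
    # Offset ("odd-r") hexagonal layout on integer grid coordinates.
    if row % 2 == 0:
        return [(-1, -1), (-1, 0), (0, -1), (0, 1), (1, -1), (1, 0)]
    return [(-1, 0), (-1, 1), (0, -1), (0, 1), (1, 0), (1, 1)]


def normalize_log(sc: SpatialCounts) -> np.ndarray:
    """Library-size normalise and log-transform: log(1 + count / lib × scale).

    ``scale`` is the median spot library, so a typical spot keeps its counts'
    magnitude.  The result is invariant to scaling any spot's counts.
    """
    lib = sc.library_sizes()
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        ids = [sc.spot_ids[i] for i in zero[:10]]
        raise ValidationError(f"{zero.size} spots have zero library size: {ids}")
    scale = float(np.median(lib))
    return np.log1p(sc.counts / lib[:, None] * scale)


def pca_embed(expr: np.ndarray, k_pcs: int) -> np.ndarray:
    """First-``k`` principal-component scores of the normalised expression.

    Uses a deterministic sign convention: each component's largest-magnitude
    gene loading is made positive.
    """
    expr = np.asarray(expr, dtype=float)
    n, g = expr.shape
    if not 1 <= k_pcs <= min(n, g):
        raise ValidationError(
            f"k_pcs={k_pcs} out of range for a {n} x {g} matrix "
            f"(must be in [1, {min(n, g)}])"
        )
    pca = PCA(n_components=k_pcs, svd_solver="full")
    scores = pca.fit_transform(expr)
    flip = np.sign(
        pca.components_[
            np.arange(k_pcs), np.abs(pca.components_).argmax(axis=1)
        ]
    )
    flip[flip == 0] = 1.0
    return scores * flip


def build_spot_graph(
    embedding: np.ndarray,
    coords: np.ndarray,
    neighbor_scheme: str = "grid4",
) -> nx.Graph:
    """Graph over spots with edges between grid neighbours.

    Edge weight is the Pearson correlation of the two spots' k-dimensional
    embeddings (0 when an embedding row is constant).  Nodes are spot row
    indices, carrying their ``(row, col)`` coordinate as an attribute.
    """
    embedding = np.asarray(embedding, dtype=float)
    coords = np.asarray(coords, dtype=int)
    n = embedding.shape[0]
    if n < 2:
        raise ValidationError("need at least two spots to build a spot graph")
    if coords.shape != (n, 2):
        raise ValidationError("coords must be (n_spots, 2) and match the embedding")
    if embedding.shape[1] < 2:
        raise ValidationError(
            "embedding must have >= 2 components for a Pearson edge weight"
        )

    centered = embedding - embedding.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    z = np.zeros_like(centered)
    z[ok] = centered[ok] / norms[ok, None]

    index_of = {tuple(rc): i for i, rc in enumerate(map(tuple, coords))}
    g = nx.Graph()
    for i, rc in enumerate(map(tuple, coords)):
        g.add_node(i, coord=rc)
    for i, (r, c) in enumerate(map(tuple, coords)):
        if neighbor_scheme == "hex6":
            offsets = _hex_offsets(r)
        elif neighbor_scheme in _OFFSETS:
            offsets = _OFFSETS[neighbor_scheme]
        else:
            raise ValidationError(f"unknown neighbor scheme {neighbor_scheme!r}")
        for dr, dc in offsets:
            j = index_of.get((r + dr, c + dc))
            if j is None or j <= i:
                continue
            w = float(np.clip(z[i] @ z[j], -1.0, 1.0))
            g.add_edge(i, j, weight=w)
    return g


def _components_at(graph: nx.Graph, epsilon: float) -> list[set[int]]:
    kept = nx.Graph()
    kept.add_nodes_from(graph.nodes)
    kept.add_edges_from(
        (u, v) for u, v, w in graph.edges(data="weight") if w >= epsilon
    )
    return [set(c) for c in nx.connected_components(kept)]


def select_epsilon(
    graph: nx.Graph,
    m: int,
    epsilon_grid: Sequence[float] | None = None,
    coverage_tol: float = 0.05,
) -> float:
    """Pick the edge-weight threshold from the weight distribution.

    Candidates default to percentiles 50–99 of the edge weights.  For each
    candidate, coverage is the fraction of spots inside components of size
    ≥ ``m``.  Among candidates that split the tissue into at least two
    regions, the knee is the largest ε whose coverage is within
    ``coverage_tol`` of the best such coverage; if no candidate yields two
    regions, falls back to the maximum-coverage ε.
    """
    weights = np.asarray([w for _, _, w in graph.edges(data="weight")], dtype=float)
    if weights.size == 0:
        raise ValidationError("graph has no edges")
    if np.allclose(weights, weights[0]):
        warnings.warn(
            "all edge weights are identical; using that weight as epsilon",
            stacklevel=2,
        )
        return float(weights[0])
    if epsilon_grid is None:
        epsilon_grid = np.percentile(weights, np.arange(50, 100))
    candidates = np.unique(np.asarray(epsilon_grid, dtype=float))

    n = graph.number_of_nodes()
    coverage = np.empty(candidates.size)
    n_regions = np.empty(candidates.size, dtype=int)
    for i, eps in enumerate(candidates):
        comps = _components_at(graph, eps)
        big = [c for c in comps if len(c) >= m]
        coverage[i] = sum(len(c) for c in big) / n
        n_regions[i] = len(big)

    multi = np.flatnonzero(n_regions >= 2)
    if multi.size:
        best = coverage[multi].max()
        ok = multi[coverage[multi] >= best - coverage_tol]
        eps = float(candidates[ok].max())
    else:
        eps = float(candidates[coverage == coverage.max()].max())
    logger.info("selected epsilon=%.4f (m=%d)", eps, m)
    return eps


def extract_regions(graph: nx.Graph, epsilon: float, m: int) -> RegionAssignment:
    """Threshold the graph at ε and keep components with ≥ ``m`` spots.

    Region ids ``R1, R2, …`` are deterministic: ordered by component size
    descending, ties broken by the smallest member spot index.  Spots in
    smaller components are labelled unassigned.
    """
    if not -1.0 <= epsilon <= 1.0:
        raise ValidationError("epsilon must lie in [-1, 1]")
    if m < 1:
        raise ValidationError("m must be >= 1")
    comps = _components_at(graph, epsilon)
    big = sorted(
        (c for c in comps if len(c) >= m), key=lambda c: (-len(c), min(c))
    )
    nodes = sorted(graph.nodes)
    pos = {node: i for i, node in enumerate(nodes)}
    labels = np.asarray([UNASSIGNED] * len(nodes), dtype=object)
    for rank, comp in enumerate(big, start=1):
        for node in comp:
            labels[pos[node]] = f"R{rank}"
    spot_ids = [str(graph.nodes[node].get("spot_id", node)) for node in nodes]
    return RegionAssignment(labels=labels, spot_ids=spot_ids)


def rand_index(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    unassigned: str | None = UNASSIGNED,
) -> float:
    """Classic Rand index between two spot partitions (pair agreement rate).

    Spots labelled ``unassigned`` in either partition are excluded
    pairwise-consistently before counting.
    """
    a = np.asarray([str(x) for x in labels_a], dtype=object)
    b = np.asarray([str(x) for x in labels_b], dtype=object)
    if a.shape != b.shape:
        raise ValidationError(
            f"partitions cover different spot sets ({a.size} vs {b.size} spots)"
        )
    if unassigned is not None:
        keep = (a != unassigned) & (b != unassigned)
        a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValidationError("need at least two mutually assigned spots")
    return float(rand_score(a, b))


def erode_assignment(
    assignment: RegionAssignment,
    coords: np.ndarray,
    depth: int = 1,
    neighbor_scheme: str = "grid4",
) -> RegionAssignment:
    """Relabel region-boundary spots as unassigned.

    A spot on a region's rim abuts unassigned (likely-mixture) spots or a
    different region and is itself likely a partial mixture; ``depth`` rounds
    of erosion strip that rim before the remaining spots are used as
    reference material.  A region that erosion would erase entirely keeps its
    original spots.
    """
    coords = np.asarray(coords, dtype=int)
    if coords.shape != (len(assignment.spot_ids), 2):
        raise ValidationError("coords must align with the assignment's spots")
    if depth < 0:
        raise ValidationError("erosion depth must be >= 0")
    labels = assignment.labels.copy()
    pos = {tuple(rc): i for i, rc in enumerate(map(tuple, coords))}
    for _ in range(depth):
        boundary = []
        for i, (r, c) in enumerate(map(tuple, coords)):
            if labels[i] == UNASSIGNED:
                continue
            offsets = _hex_offsets(r) if neighbor_scheme == "hex6" else _OFFSETS[neighbor_scheme]
            for dr, dc in offsets:
                j = pos.get((r + dr, c + dc))
                if j is not None and labels[j] != labels[i]:
                    boundary.append(i)
                    break
        for i in boundary:
            labels[i] = UNASSIGNED
    for region_id in assignment.region_sizes:
        if not np.any(labels == region_id):
            labels[assignment.labels == region_id] = region_id
    return RegionAssignment(labels=labels, spot_ids=list(assignment.spot_ids))


def detect_regions(
    sc: SpatialCounts,
    k_pcs: int = 10,
    min_region_size: int = 40,
    epsilon: float | None = None,
    neighbor_scheme: str = "grid4",
) -> tuple[RegionAssignment, float]:
    """Full extraction: normalise → embed → graph → threshold → components.

    Returns the assignment and the ε actually used.
    """
    expr = normalize_log(sc)
    emb = pca_embed(expr, min(k_pcs, min(sc.n_spots, sc.n_genes)))
    graph = build_spot_graph(emb, sc.coords, neighbor_scheme)
    for node, sid in zip(sorted(graph.nodes), sc.spot_ids):
        graph.nodes[node]["spot_id"] = sid
    if epsilon is None:
        epsilon = select_epsilon(graph, min_region_size)
    assignment = extract_regions(graph, epsilon, min_region_size)
    logger.info(
        "detected %d regions covering %d/%d spots",
        len(assignment.region_sizes),
        int(assignment.assigned_mask.sum()),
        sc.n_spots,
    )
    return assignment, float(epsilon)
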
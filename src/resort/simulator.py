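"""Simulate spatial-transcriptomics samples with known cell-type composition.

The generative model places a few homogeneous tissue regions (circles and
rectangles) on a rectangular spot grid.  A spot inside a region is a pure
draw of that region's cell type.  A spot outside every region mixes the
region-level types with affinities equal to the inverse Euclidean distance to
the nearest spot of each region, plus Gaussian noise:

    A[s, r] = 1 / min_{s' in r} dist(s, s')  +  delta,   delta ~ N(0, sd)

Affinities are normalised to proportions, converted to integer per-spot cell
counts (floor of ``cells_per_spot`` × proportion, renormalised afterwards to
give the saved ground truth), and each spot's expression is formed by drawing
that many cells from a labelled single-cell reference and binomially thinning
their reads (default retention 10%) so spot libraries sit at Visium depth.
Optionally, a fraction of pure tumour spots receive artificial immune cells
(truncated-Gaussian proportions) to emulate immune infiltration.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import ConfigError, RunConfig
from .types import ProportionMatrix, SingleCellReference, SpatialCounts, ValidationError

logger = logging.getLogger("resort")

AFFINITY_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Region geometry


@dataclass(frozen=True)
class Circle:
    center_row: float
    center_col: float
    radius: float

    def mask(self, coords: np.ndarray) -> np.ndarray:
        d2 = (coords[:, 0] - self.center_row) ** 2 + (coords[:, 1] - self.center_col) ** 2
        return d2 <= self.radius**2

    def fits(self, n_rows: int, n_cols: int) -> bool:
        return (
            self.center_row - self.radius >= -0.5
            and self.center_row + self.radius <= n_rows - 0.5
            and self.center_col - self.radius >= -0.5
            and self.center_col + self.radius <= n_cols - 0.5
        )

    def to_dict(self) -> dict:
        return {
            "kind": "circle",
            "center": [self.center_row, self.center_col],
            "radius": self.radius,
        }


@dataclass(frozen=True)
class Rectangle:
    """Inclusive row/col bounds on the grid."""

    row0: int
    row1: int
    col0: int
    col1: int

    def mask(self, coords: np.ndarray) -> np.ndarray:
        return (
            (coords[:, 0] >= self.row0)
            & (coords[:, 0] <= self.row1)
            & (coords[:, 1] >= self.col0)
            & (coords[:, 1] <= self.col1)
        )

    def fits(self, n_rows: int, n_cols: int) -> bool:
        return (
            0 <= self.row0 <= self.row1 < n_rows and 0 <= self.col0 <= self.col1 < n_cols
        )

    def to_dict(self) -> dict:
        return {
            "kind": "rectangle",
            "rows": [self.row0, self.row1],
            "cols": [self.col0, self.col1],
        }


Shape = Circle | Rectangle


def shape_from_dict(d: dict) -> Shape:
    kind = d.get("kind")
    if kind == "circle":
        return Circle(float(d["center"][0]), float(d["center"][1]), float(d["radius"]))
    if kind == "rectangle":
        return Rectangle(
            int(d["rows"][0]), int(d["rows"][1]), int(d["cols"][0]), int(d["cols"][1])
        )
    raise ValidationError(f"unknown shape kind {kind!r}")


@dataclass
class RegionLayout:
    """A spot grid with pairwise-disjoint region shapes placed on it."""

    n_rows: int
    n_cols: int
    shapes: list[tuple[str, Shape]]
    coords: np.ndarray = field(init=False)
    masks: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid must have at least one row and column")
        rr, cc = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        self.coords = np.column_stack([rr.ravel(), cc.ravel()])
        shape_masks = []
        for region_type, shape in self.shapes:
            if not shape.fits(self.n_rows, self.n_cols):
                raise ValidationError(
                    f"shape {shape} for region {region_type!r} does not fit the "
                    f"{self.n_rows}x{self.n_cols} grid"
                )
            m = shape.mask(self.coords)
            if not m.any():
                raise ValidationError(
                    f"shape {shape} for region {region_type!r} covers no spot"
                )
            shape_masks.append(m)
        cover = np.zeros(self.n_spots, dtype=int)
        for m in shape_masks:
            cover += m.astype(int)
        collisions = np.flatnonzero(cover > 1)
        if collisions.size:
            coords = [tuple(int(x) for x in self.coords[i]) for i in collisions[:10]]
            raise ValidationError(
                f"{collisions.size} spots covered by more than one shape "
                f"(first collisions at {coords})"
            )
        # Merge shapes sharing a region type, preserving first-seen type order.
        self.masks = {}
        for (region_type, _), m in zip(self.shapes, shape_masks):
            if region_type in self.masks:
                self.masks[region_type] = self.masks[region_type] | m
            else:
                self.masks[region_type] = m

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def region_types(self) -> list[str]:
        return list(self.masks)

    def spot_ids(self) -> list[str]:
        width = len(str(self.n_spots - 1))
        return [f"spot_{i:0{width}d}" for i in range(self.n_spots)]

    def region_label_per_spot(self) -> np.ndarray:
        """Generating region per spot ('' for out-of-region spots)."""
        labels = np.asarray([""] * self.n_spots, dtype=object)
        for region_type, mask in self.masks.items():
            labels[mask] = region_type
        return labels

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "shapes": [
                dict(region=region_type, **shape.to_dict())
                for region_type, shape in self.shapes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionLayout":
        shapes = [(str(s["region"]), shape_from_dict(s)) for s in d["shapes"]]
        return cls(int(d["n_rows"]), int(d["n_cols"]), shapes)


def make_layout(
    n_rows: int, n_cols: int, shapes: Sequence[tuple[str, Shape]]
) -> RegionLayout:
    """Validate and build a region layout on an ``n_rows × n_cols`` grid."""
    return RegionLayout(n_rows, n_cols, list(shapes))


# ---------------------------------------------------------------------------
# Ground-truth proportions and cell counts


def ground_truth_proportions(
    layout: RegionLayout,
    noise_sd: float | Sequence[float],
    rng: np.random.Generator,
) -> ProportionMatrix:
    """Distance-based mixing proportions for every spot.

    In-region spots are pure (regions hold homogeneous cell populations, and
    the inverse-distance affinity is undefined at distance zero).  For every
    out-of-region spot the affinity to each region is the inverse distance to
    the region's nearest spot plus per-(spot, region) Gaussian noise, clipped
    below at a small positive floor, then normalised across regions.
    """
    region_types = layout.region_types
    n_regions = len(region_types)
    if n_regions < 1:
        raise ValidationError("layout must define at least one region")
    sds = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_regions,))
    if np.any(sds < 0):
        raise ConfigError("noise_sd must be >= 0")

    n_spots = layout.n_spots
    inside_any = np.zeros(n_spots, dtype=bool)
    affin = np.zeros((n_spots, n_regions))
    values = np.zeros((n_spots, n_regions))
    for j, region_type in enumerate(region_types):
        mask = layout.masks[region_type]
        inside_any |= mask
        tree = cKDTree(layout.coords[mask])
        dist, _ = tree.query(layout.coords)
        with np.errstate(divide="ignore"):
            affin[:, j] = 1.0 / dist
        values[mask, j] = 1.0

    outside = ~inside_any
    if outside.any():
        noise = rng.normal(0.0, 1.0, size=(int(outside.sum()), n_regions)) * sds
        a = np.clip(affin[outside] + noise, AFFINITY_FLOOR, None)
        values[outside] = a / a.sum(axis=1, keepdims=True)

    return ProportionMatrix(values, region_types, layout.spot_ids(), level="region")


def proportions_to_counts(
    p_tilde: ProportionMatrix, cells_per_spot: int
) -> tuple[np.ndarray, ProportionMatrix]:
    """Convert mixing ratios to integer per-spot cell counts.

    ``C[s, r] = floor(cells_per_spot * p̃[s, r])``; a spot whose counts all
    floor to zero receives one cell of its largest-proportion type (ties to
    the lowest type index).  The returned ground truth renormalises ``C``
    row-wise.
    """
    if cells_per_spot < 1:
        raise ConfigError("cells_per_spot must be >= 1")
    C = np.floor(cells_per_spot * p_tilde.values).astype(int)
    zero_rows = np.flatnonzero(C.sum(axis=1) == 0)
    if zero_rows.size:
        argmax = p_tilde.values[zero_rows].argmax(axis=1)
        C[zero_rows, argmax] = 1
    totals = C.sum(axis=1, keepdims=True)
    truth = ProportionMatrix(
        C / totals, list(p_tilde.type_ids), list(p_tilde.spot_ids), level="region"
    )
    return C, truth


# ---------------------------------------------------------------------------
# Expression sampling


def sample_spot_expression(
    ref: SingleCellReference,
    c_row: Sequence[int],
    type_ids: Sequence[str],
    downsample_rate: float,
    rng: np.random.Generator,
    with_replacement: bool = False,
    return_cells: bool = False,
):
    """Draw cells for one spot and thin their reads.

    For every region-level type ``r``, draws ``c_row[r]`` distinct cells of
    that type from the reference (without replacement unless overridden),
    retains each read of each drawn cell independently with probability
    ``downsample_rate`` (binomial thinning per gene), and returns the
    gene-wise sum.  With ``return_cells=True`` also returns the drawn cell
    indices, from which fine-level ground truth can be tallied.
    """
    if not 0.0 <= downsample_rate <= 1.0:
        raise ConfigError("downsample_rate must lie in [0, 1]")
    region_labels = ref.region_labels()
    chosen: list[np.ndarray] = []
    for type_id, c in zip(type_ids, c_row):
        c = int(c)
        if c == 0:
            continue
        pool = np.flatnonzero(region_labels == str(type_id))
        if c > pool.size and not with_replacement:
            raise ValidationError(
                f"spot requests {c} cells of type {type_id!r} but the reference "
                f"holds only {pool.size}; supply a larger reference or enable "
                "sample_with_replacement"
            )
        chosen.append(rng.choice(pool, size=c, replace=with_replacement))
    idx = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
    sub = ref.counts[idx]
    if downsample_rate >= 1.0:
        vec = sub.sum(axis=0)
    else:
        vec = rng.binomial(sub.astype(np.int64), downsample_rate).sum(axis=0)
    vec = np.asarray(vec, dtype=int)
    if return_cells:
        return vec, idx
    return vec


# ---------------------------------------------------------------------------
# Immune infiltration


def draw_infiltration_proportions(
    n: int,
    mu: float = 0.5,
    sigma: float = 0.2,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample infiltrated-spot immune proportions: N(mu, sigma) truncated to (0, 1).

    Out-of-range draws are rejected and redrawn; ``sigma=0`` returns the
    constant ``mu`` (which must then lie strictly inside (0, 1)).
    """
    rng = np.random.default_rng() if rng is None else rng
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    if sigma == 0:
        if not 0.0 < mu < 1.0:
            raise ConfigError("with sigma=0, mu must lie strictly in (0, 1)")
        return np.full(n, mu)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mu, sigma, size=max(n - filled, 16))
        keep = draw[(draw > 0.0) & (draw < 1.0)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def inject_infiltration(
    P: ProportionMatrix,
    C: np.ndarray,
    cancer_type: str,
    immune_type: str,
    fraction: float,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
) -> tuple[ProportionMatrix, np.ndarray, np.ndarray]:
    """Add immune cells to a random subset of pure tumour spots.

    Selects ``round(fraction × n_pure_cancer)`` pure-cancer spots uniformly
    without replacement; per selected spot draws an immune proportion
    ``q ~ N(mu, sigma)`` truncated to (0, 1) and substitutes
    ``max(1, floor(q × total_cells))`` cancer cells with immune cells, so the
    spot keeps its total cell count.  Ground truth is re-derived from the
    updated counts.  Returns ``(P', C', infiltrated_mask)``.
    """
    if cancer_type not in P.type_ids:
        raise ValidationError(f"cancer type {cancer_type!r} not among {P.type_ids}")
    if not 0.0 < fraction <= 1.0:
        raise ConfigError("infiltration fraction must lie in (0, 1]")
    C = np.asarray(C, dtype=int).copy()
    j_cancer = P.type_ids.index(cancer_type)
    totals = C.sum(axis=1)
    pure = np.flatnonzero((C[:, j_cancer] == totals) & (totals > 0))
    if pure.size == 0:
        raise ValidationError("no pure tumour spots available for infiltration")
    n_sel = int(round(fraction * pure.size))
    mask = np.zeros(P.n_spots, dtype=bool)
    type_ids = list(P.type_ids)
    if immune_type not in type_ids:
        type_ids.append(immune_type)
        C = np.column_stack([C, np.zeros(C.shape[0], dtype=int)])
    j_immune = type_ids.index(immune_type)
    if n_sel == 0:
        warnings.warn(
            "infiltration fraction selects zero spots; returning empty mask",
            stacklevel=2,
        )
    else:
        sel = rng.choice(pure, size=n_sel, replace=False)
        q = draw_infiltration_proportions(n_sel, mu, sigma, rng)
        n_imm = np.maximum(1, np.floor(q * totals[sel]).astype(int))
        C[sel, j_cancer] = totals[sel] - n_imm
        C[sel, j_immune] = n_imm
        mask[sel] = True
    new_totals = C.sum(axis=1, keepdims=True)
    P_new = ProportionMatrix(
        C / new_totals, type_ids, list(P.spot_ids), level="region"
    )
    return P_new, C, mask


# ---------------------------------------------------------------------------
# End-to-end simulation


@dataclass
class SimulationResult:
    counts: SpatialCounts
    truth_region: ProportionMatrix
    truth_fine: ProportionMatrix
    infiltration_mask: np.ndarray
    layout: RegionLayout
    cell_counts: np.ndarray  # spots × region types, aligned to truth_region


def simulate(
    ref: SingleCellReference,
    layout: RegionLayout,
    config: RunConfig,
    infiltrate: bool = False,
    cancer_type: str | None = None,
    immune_type: str | None = None,
) -> SimulationResult:
    """Run the full generative pipeline under one seed.

    Layout → affinity proportions → integer cell counts → (optional immune
    infiltration) → per-spot cell draws with read thinning.  Region-level
    ground truth is the renormalised cell-count table; fine-level ground
    truth tallies the fine labels of the actually drawn cells.
    """
    config.log_resolved()
    rng = config.rng()
    ref_regions = set(ref.region_types)
    missing = [t for t in layout.region_types if t not in ref_regions]
    if missing:
        raise ValidationError(
            f"layout region types {missing} are not covered by the reference "
            f"grouping (available: {sorted(ref_regions)})"
        )

    p_tilde = ground_truth_proportions(layout, config.noise_sd, rng)
    C, truth = proportions_to_counts(p_tilde, config.cells_per_spot)

    mask = np.zeros(layout.n_spots, dtype=bool)
    if infiltrate:
        if cancer_type is None or immune_type is None:
            raise ValidationError(
                "infiltration requires cancer_type and immune_type"
            )
        if immune_type not in ref_regions:
            raise ValidationError(
                f"immune type {immune_type!r} has no cells in the reference"
            )
        truth, C, mask = inject_infiltration(
            truth,
            C,
            cancer_type,
            immune_type,
            config.infiltration_fraction,
            config.infiltration_mu,
            config.infiltration_sigma,
            rng,
        )

    type_ids = truth.type_ids
    region_labels = ref.region_labels()
    pools = {t: np.flatnonzero(region_labels == t) for t in type_ids}
    fine_types = ref.fine_types
    fine_index = {t: j for j, t in enumerate(fine_types)}

    n_spots, n_genes = layout.n_spots, ref.n_genes
    counts = np.zeros((n_spots, n_genes), dtype=int)
    fine_counts = np.zeros((n_spots, len(fine_types)), dtype=int)
    rate = config.downsample_rate
    for s in range(n_spots):
        chosen: list[np.ndarray] = []
        for j, t in enumerate(type_ids):
            c = int(C[s, j])
            if c == 0:
                continue
            pool = pools[t]
            if c > pool.size and not config.sample_with_replacement:
                raise ValidationError(
                    f"spot {s} requests {c} cells of type {t!r} but the reference "
                    f"holds only {pool.size}; supply a larger reference or enable "
                    "sample_with_replacement"
                )
            chosen.append(rng.choice(pool, size=c, replace=config.sample_with_replacement))
        idx = np.concatenate(chosen)
        sub = ref.counts[idx]
        if rate >= 1.0:
            counts[s] = sub.sum(axis=0)
        else:
            counts[s] = rng.binomial(sub.astype(np.int64), rate).sum(axis=0)
        for i in idx:
            fine_counts[s, fine_index[ref.fine_type[i]]] += 1

    sc = SpatialCounts(
        counts=counts,
        gene_ids=list(ref.gene_ids),
        spot_ids=layout.spot_ids(),
        coords=layout.coords,
    )
    fine_totals = fine_counts.sum(axis=1, keepdims=True)
    truth_fine = ProportionMatrix(
        fine_counts / fine_totals, fine_types, layout.spot_ids(), level="fine"
    )
    logger.info(
        "simulated %d spots x %d genes (median library %.0f)",
        n_spots,
        n_genes,
        float(np.median(counts.sum(axis=1))),
    )
    return SimulationResult(sc, truth, truth_fine, mask, layout, C)
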
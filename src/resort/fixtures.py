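"""Synthetic single-cell references and ready-to-run simulation scenarios.

Fixture references emulate the structure of a real tumour single-cell
dataset: several fine cell types grouped into region-level types, an overdispersed
negative-binomial baseline, and disjoint planted marker genes per fine type
whose mean expression is scaled up by a fold factor.  The per-gene baseline
depth is calibrated so that, after the simulator's 10-cell capture and 10%
read thinning, spot libraries land at the magnitude of real Visium spots
(roughly 2×10³ counts over the 300-gene panel) — the premise of the
read-downsampling step.  An "external" variant
regenerates cells from the same type model and applies per-gene
multiplicative log-normal batch factors, emulating the platform effects that
an external reference carries relative to the profiled sample.

Nothing here claims distributional fidelity to any real dataset; fixtures
exist so every pipeline stage is testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .simulator import Circle, Rectangle, RegionLayout, make_layout
from .types import SingleCellReference, ValidationError


@dataclass
class FixtureSpec:
    """Parameters of the synthetic reference generator.

    ``fine_types`` and ``grouping`` define the type structure; each fine type
    gets ``markers_per_type`` disjoint marker genes whose negative-binomial
    mean is ``marker_fold`` times the baseline.  ``batch_sigma`` is the SD of
    the log-normal per-gene factors applied by the external-reference
    emulator.
    """

    fine_types: list[str]
    grouping: dict[str, str]
    n_genes: int = 300
    markers_per_type: int = 15
    marker_fold: float = 8.0
    base_mean: float = 5.0
    dispersion: float = 0.5
    cells_per_type: int = 150
    batch_sigma: float = 0.5

    def __post_init__(self) -> None:
        self.fine_types = [str(t) for t in self.fine_types]
        if len(set(self.fine_types)) != len(self.fine_types):
            raise ValidationError("fine types must be unique")
        missing = sorted(set(self.fine_types) - set(self.grouping))
        if missing:
            raise ValidationError(f"fine types without grouping: {missing}")
        if self.markers_per_type * len(self.fine_types) > self.n_genes:
            raise ValidationError(
                f"{self.markers_per_type} markers x {len(self.fine_types)} types "
                f"exceed {self.n_genes} genes; markers must be disjoint"
            )
        if self.marker_fold <= 0 or self.base_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("marker_fold, base_mean, dispersion must be > 0")
        if self.cells_per_type < 1:
            raise ValidationError("cells_per_type must be >= 1")
        if self.batch_sigma < 0:
            raise ValidationError("batch_sigma must be >= 0")

    @property
    def n_fine_types(self) -> int:
        return len(self.fine_types)

    @property
    def region_types(self) -> list[str]:
        seen: list[str] = []
        for t in self.fine_types:
            r = self.grouping[t]
            if r not in seen:
                seen.append(r)
        return seen

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def marker_genes_of(self, fine_type: str) -> list[str]:
        i = self.fine_types.index(str(fine_type))
        genes = self.gene_ids()
        lo = i * self.markers_per_type
        return genes[lo : lo + self.markers_per_type]

    def mean_matrix(self) -> np.ndarray:
        """Per-fine-type NB mean for every gene (types × genes)."""
        means = np.full((self.n_fine_types, self.n_genes), self.base_mean)
        for i in range(self.n_fine_types):
            lo = i * self.markers_per_type
            means[i, lo : lo + self.markers_per_type] *= self.marker_fold
        return means


def _nb_draw(
    mean: np.ndarray, dispersion: float, size: tuple, rng: np.random.Generator
) -> np.ndarray:
    # NB with var = mean + mean^2 / dispersion, numpy's (n, p) parametrisation.
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _generate(
    spec: FixtureSpec,
    rng: np.random.Generator,
    gene_factors: np.ndarray | None = None,
    id_prefix: str = "cell",
) -> SingleCellReference:
    means = spec.mean_matrix()
    if gene_factors is not None:
        means = means * gene_factors[None, :]
    blocks = []
    labels = []
    for i, t in enumerate(spec.fine_types):
        blocks.append(
            _nb_draw(means[i], spec.dispersion, (spec.cells_per_type, spec.n_genes), rng)
        )
        labels.extend([t] * spec.cells_per_type)
    counts = np.vstack(blocks)
    n_cells = counts.shape[0]
    width = len(str(n_cells - 1))
    return SingleCellReference(
        counts=counts,
        gene_ids=spec.gene_ids(),
        cell_ids=[f"{id_prefix}_{i:0{width}d}" for i in range(n_cells)],
        fine_type=np.asarray(labels, dtype=object),
        region_type_of=dict(spec.grouping),
    )


def make_reference(spec: FixtureSpec, rng: np.random.Generator) -> SingleCellReference:
    """Synthetic internal reference: NB baseline with planted markers."""
    return _generate(spec, rng, id_prefix="cell")


def make_external_reference(
    spec: FixtureSpec,
    internal_ref: SingleCellReference,
    rng: np.random.Generator,
) -> SingleCellReference:
    """Batch-shifted sibling of an internal reference.

    Regenerates cells from the same per-type model and multiplies every
    gene's mean by a log-normal factor exp(N(0, batch_sigma)) shared across
    cell types — the simplest mechanism giving a reference with the same
    type structure but systematic gene-level platform differences.
    """
    if internal_ref.gene_ids != spec.gene_ids():
        raise ValidationError("internal reference does not match the fixture spec")
    factors = np.exp(rng.normal(0.0, spec.batch_sigma, size=spec.n_genes))
    return _generate(spec, rng, gene_factors=factors, id_prefix="ext")


@dataclass
class Scenario:
    """A bundled reference + layout + config, ready for the simulator."""

    name: str
    reference: SingleCellReference
    external_reference: SingleCellReference
    layout: RegionLayout
    config: RunConfig
    spec: FixtureSpec
    cancer_type: str | None = None
    immune_type: str | None = None


def three_region_layout(n_rows: int, n_cols: int) -> RegionLayout:
    """Two circles (cancer, normal) and a rectangle (ductal), scaled to the grid."""
    s = min(n_rows, n_cols)
    return make_layout(
        n_rows,
        n_cols,
        [
            ("cancer", Circle(0.30 * n_rows, 0.30 * n_cols, 0.18 * s)),
            (
                "ductal",
                Rectangle(
                    int(0.58 * n_rows),
                    int(0.85 * n_rows),
                    int(0.06 * n_cols),
                    int(0.30 * n_cols),
                ),
            ),
            ("normal", Circle(0.72 * n_rows, 0.70 * n_cols, 0.15 * s)),
        ],
    )


def scenario(
    name: str,
    grid: tuple[int, int] | None = None,
    seed: int = 0,
) -> Scenario:
    """Build a named end-to-end test scenario.

    ``three-region``: the classic tumour layout — circular cancer and normal
    regions plus a rectangular ductal region, six fine types grouped 2:2:2.
    ``three-region-infiltrated``: the same layout plus an immune region-level
    type (two fine subtypes, no spatial region of its own) injected into 10%
    of pure tumour spots.  ``two-block-regions``: two rectangles tiling the
    grid with orthogonal profiles, the region-extraction oracle fixture.
    """
    rng = np.random.default_rng(seed)
    if name == "three-region":
        grid = grid or (50, 50)
        spec = FixtureSpec(
            fine_types=[
                "cancer_a", "cancer_b",
                "ductal_a", "ductal_b",
                "normal_a", "normal_b",
            ],
            grouping={
                "cancer_a": "cancer", "cancer_b": "cancer",
                "ductal_a": "ductal", "ductal_b": "ductal",
                "normal_a": "normal", "normal_b": "normal",
            },
        )
        layout = three_region_layout(*grid)
        config = RunConfig(rng_seed=seed)
        ref = make_reference(spec, rng)
        ext = make_external_reference(spec, ref, rng)
        return Scenario(name, ref, ext, layout, config, spec, cancer_type="cancer")
    if name == "three-region-infiltrated":
        grid = grid or (50, 50)
        spec = FixtureSpec(
            fine_types=[
                "cancer_a", "cancer_b",
                "ductal_a", "ductal_b",
                "normal_a", "normal_b",
                "immune_a", "immune_b",
            ],
            grouping={
                "cancer_a": "cancer", "cancer_b": "cancer",
                "ductal_a": "ductal", "ductal_b": "ductal",
                "normal_a": "normal", "normal_b": "normal",
                "immune_a": "immune", "immune_b": "immune",
            },
        )
        layout = three_region_layout(*grid)
        config = RunConfig(rng_seed=seed)
        ref = make_reference(spec, rng)
        ext = make_external_reference(spec, ref, rng)
        return Scenario(
            name, ref, ext, layout, config, spec,
            cancer_type="cancer", immune_type="immune",
        )
    if name == "two-block-regions":
        grid = grid or (10, 20)
        n_rows, n_cols = grid
        if n_cols < 2:
            raise ValidationError("two-block grid needs at least two columns")
        spec = FixtureSpec(
            fine_types=["alpha", "beta"],
            grouping={"alpha": "block_a", "beta": "block_b"},
        )
        half = n_cols // 2
        layout = make_layout(
            n_rows,
            n_cols,
            [
                ("block_a", Rectangle(0, n_rows - 1, 0, half - 1)),
                ("block_b", Rectangle(0, n_rows - 1, half, n_cols - 1)),
            ],
        )
        config = RunConfig(rng_seed=seed, noise_sd=0.0)
        ref = make_reference(spec, rng)
        ext = make_external_reference(spec, ref, rng)
        return Scenario(name, ref, ext, layout, config, spec)
    raise ValidationError(
        f"unknown scenario {name!r}; available: three-region, "
        "three-region-infiltrated, two-block-regions"
    )
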
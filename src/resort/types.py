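"""Core data model shared by every pipeline stage.

The four containers here are deliberately plain: integer count matrices with
ordered identifiers, validated eagerly so that downstream stages can assume
their invariants.  ``ProportionMatrix`` is the common currency of the
pipeline — every stage that emits cell-type proportions returns one, and its
row-stochastic invariant (rows sum to one) is checked on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"

ROW_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


def _as_str_list(values: Sequence, what: str) -> list[str]:
    out = [str(v) for v in values]
    if len(set(out)) != len(out):
        dupes = sorted({v for v in out if out.count(v) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return out


@dataclass
class SpatialCounts:
    """Spots × genes integer count matrix with per-spot grid coordinates.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per spot.
    gene_ids, spot_ids
        Ordered unique identifiers for columns and rows.
    coords
        ``(n_spots, 2)`` integer ``(row, col)`` grid positions, unique per
        spot.  Coordinates are 0-based; distances downstream are Euclidean
        on these raw integers.
    """

    counts: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D spots × genes matrix")
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at spot row {bad[0]}, gene column {bad[1]}"
            )
        n_spots, n_genes = self.counts.shape
        self.gene_ids = _as_str_list(self.gene_ids, "gene ids")
        self.spot_ids = _as_str_list(self.spot_ids, "spot ids")
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.spot_ids) != n_spots:
            raise ValidationError(
                f"{len(self.spot_ids)} spot ids for {n_spots} matrix rows"
            )
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.shape != (n_spots, 2):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match "
                f"{n_spots} spots (expected ({n_spots}, 2))"
            )
        seen: dict[tuple[int, int], str] = {}
        for sid, rc in zip(self.spot_ids, map(tuple, self.coords)):
            if rc in seen:
                raise ValidationError(
                    f"spots {seen[rc]!r} and {sid!r} share coordinate {rc}"
                )
            seen[rc] = sid

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1), dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpatialCounts):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.gene_ids == other.gene_ids
            and self.spot_ids == other.spot_ids
            and np.array_equal(self.coords, other.coords)
        )


@dataclass
class SingleCellReference:
    """Cells × genes counts with fine-type labels and a fine→region grouping.

    ``region_type_of`` maps every fine cell type to the coarse region-level
    type whose cells dominate a contiguous tissue region (e.g. fourteen fine
    types grouped into cancer / ductal / other-normal).
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    fine_type: np.ndarray
    region_type_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D cells × genes matrix")
        if np.any(self.counts < 0):
            raise ValidationError("reference counts must be non-negative")
        n_cells, n_genes = self.counts.shape
        self.gene_ids = _as_str_list(self.gene_ids, "gene ids")
        self.cell_ids = _as_str_list(self.cell_ids, "cell ids")
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        self.fine_type = np.asarray([str(t) for t in self.fine_type], dtype=object)
        if self.fine_type.shape != (n_cells,):
            raise ValidationError("one fine-type label required per cell")
        self.region_type_of = {str(k): str(v) for k, v in self.region_type_of.items()}
        missing = sorted(set(self.fine_type) - set(self.region_type_of))
        if missing:
            raise ValidationError(
                f"fine types with no region-level grouping entry: {missing}"
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def fine_types(self) -> list[str]:
        seen: list[str] = []
        for t in self.fine_type:
            if t not in seen:
                seen.append(t)
        return seen

    @property
    def region_types(self) -> list[str]:
        seen: list[str] = []
        for t in self.fine_type:
            r = self.region_type_of[t]
            if r not in seen:
                seen.append(r)
        return seen

    def region_labels(self) -> np.ndarray:
        """Per-cell region-level label derived through the grouping map."""
        return np.asarray([self.region_type_of[t] for t in self.fine_type], dtype=object)

    def cells_of_region_type(self, region_type: str) -> np.ndarray:
        return np.flatnonzero(self.region_labels() == region_type)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SingleCellReference):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and list(self.fine_type) == list(other.fine_type)
            and self.region_type_of == other.region_type_of
        )


@dataclass
class ProportionMatrix:
    """Spots × types row-stochastic matrix of cell-type proportions."""

    values: np.ndarray
    type_ids: list[str]
    spot_ids: list[str]
    level: str  # "region" or "fine"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("proportion values must be 2-D")
        self.type_ids = _as_str_list(self.type_ids, "type ids")
        self.spot_ids = _as_str_list(self.spot_ids, "spot ids")
        n_spots, n_types = self.values.shape
        if len(self.type_ids) != n_types:
            raise ValidationError(
                f"{len(self.type_ids)} type ids for {n_types} columns"
            )
        if len(self.spot_ids) != n_spots:
            raise ValidationError(
                f"{len(self.spot_ids)} spot ids for {n_spots} rows"
            )
        if self.level not in {"region", "fine"}:
            raise ValidationError(f"level must be 'region' or 'fine', got {self.level!r}")
        if np.any(self.values < -ROW_SUM_TOL) or np.any(self.values > 1 + ROW_SUM_TOL):
            raise ValidationError("proportions must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)
        if bad.size:
            raise ValidationError(
                f"{bad.size} proportion rows do not sum to 1 "
                f"(first offender: spot {self.spot_ids[bad[0]]!r}, sum {sums[bad[0]]:.12f})"
            )

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    def column(self, type_id: str) -> np.ndarray:
        try:
            j = self.type_ids.index(str(type_id))
        except ValueError:
            raise KeyError(f"type {type_id!r} not in {self.type_ids}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.spot_ids, columns=self.type_ids)

    def reorder_types(self, type_ids: Sequence[str]) -> "ProportionMatrix":
        """Return a copy with columns in the given order (must be a permutation)."""
        type_ids = [str(t) for t in type_ids]
        if sorted(type_ids) != sorted(self.type_ids):
            raise ValidationError(
                f"cannot reorder types {self.type_ids} as {type_ids}"
            )
        idx = [self.type_ids.index(t) for t in type_ids]
        return ProportionMatrix(self.values[:, idx], type_ids, list(self.spot_ids), self.level)


@dataclass
class RegionAssignment:
    """Per-spot region label or ``"unassigned"``, from component extraction."""

    labels: np.ndarray
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray([str(v) for v in self.labels], dtype=object)
        self.spot_ids = _as_str_list(self.spot_ids, "spot ids")
        if self.labels.shape != (len(self.spot_ids),):
            raise ValidationError("one region label required per spot")

    @property
    def region_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels:
            if lab != UNASSIGNED:
                sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    @property
    def assigned_mask(self) -> np.ndarray:
        return self.labels != UNASSIGNED

    @property
    def region_ids(self) -> list[str]:
        return sorted(self.region_sizes, key=lambda r: (-self.region_sizes[r], r))


@dataclass
class PseudoReference:
    """Region-labelled spot expression profiles used as the internal reference Ω.

    Every row is an ST spot that fell inside a detected homogeneous region,
    labelled with a region-level cell type; unassigned (likely-mixture) spots
    are excluded by construction.
    """

    profiles: np.ndarray
    labels: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    source: str = "pseudo-internal"

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles)
        if self.profiles.ndim != 2:
            raise ValidationError("profiles must be 2-D")
        self.labels = np.asarray([str(v) for v in self.labels], dtype=object)
        self.gene_ids = _as_str_list(self.gene_ids, "gene ids")
        self.spot_ids = _as_str_list(self.spot_ids, "spot ids")
        n_rows, n_genes = self.profiles.shape
        if self.labels.shape != (n_rows,):
            raise ValidationError("one region-level label required per Ω row")
        if len(self.gene_ids) != n_genes or len(self.spot_ids) != n_rows:
            raise ValidationError("id lengths do not match Ω dimensions")
        if n_rows == 0:
            raise ValidationError("Ω must contain at least one spot")

    @property
    def region_types(self) -> list[str]:
        seen: list[str] = []
        for t in self.labels:
            if t not in seen:
                seen.append(t)
        return seen
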
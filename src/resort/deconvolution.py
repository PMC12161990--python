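"""Pseudo-internal reference construction and proportion estimation.

The pseudo-internal reference Ω collects the expression of spots inside the
detected molecular regions — spots likely dominated by one region-level cell
type — and excludes everything unassigned (likely mixtures).  The built-in
solver library-normalises each spot and fits it by non-negative least squares
against per-type signature profiles on a marker gene set, renormalising the
coefficients to proportions.  Finer cell types that do not form spatial
regions are estimated in two steps: region-level proportions from Ω, then a
within-region split from an external reference ω, combined multiplicatively
(the proportion of subtype t is the product of its parent region proportion
and its within-region share).  Ω can also be exported as a labelled
reference for external deconvolution tools.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .types import (
    ProportionMatrix,
    PseudoReference,
    RegionAssignment,
    SingleCellReference,
    SpatialCounts,
    ValidationError,
)

logger = logging.getLogger("resort")

LFC_PSEUDO = 1e-5


def build_pseudo_reference(
    sc: SpatialCounts,
    assignment: RegionAssignment,
    region_type_map: Mapping[str, str],
) -> PseudoReference:
    """Assemble Ω from the spots inside labelled regions.

    ``region_type_map`` maps detected region ids (e.g. ``R1``) to
    region-level cell types; several regions may share a type, in which case
    their rows carry the merged label.  Unassigned spots are excluded.
    """
    if list(assignment.spot_ids) != list(sc.spot_ids):
        raise ValidationError("region assignment does not cover the ST spot set")
    region_type_map = {str(k): str(v) for k, v in region_type_map.items()}
    unknown = sorted(set(region_type_map) - set(assignment.region_sizes))
    if unknown:
        raise ValidationError(f"region_type_map names unknown regions: {unknown}")
    rows: list[int] = []
    labels: list[str] = []
    for i, lab in enumerate(assignment.labels):
        if lab in region_type_map:
            rows.append(i)
            labels.append(region_type_map[lab])
    mapped_types = sorted(set(region_type_map.values()))
    empty = sorted(set(mapped_types) - set(labels))
    if empty:
        raise ValidationError(
            f"region-level types with zero labelled spots: {empty}"
        )
    return PseudoReference(
        profiles=sc.counts[rows],
        labels=np.asarray(labels, dtype=object),
        gene_ids=list(sc.gene_ids),
        spot_ids=[sc.spot_ids[i] for i in rows],
    )


def _normalized_type_means(
    matrix: np.ndarray, labels: np.ndarray, gene_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-label mean of library-size-normalised rows (types × genes)."""
    matrix = np.asarray(matrix, dtype=float)
    lib = matrix.sum(axis=1, keepdims=True)
    if np.any(lib == 0):
        raise ValidationError("cannot normalise rows with zero library size")
    norm = matrix / lib
    types: list[str] = []
    for t in labels:
        if t not in types:
            types.append(t)
    means = np.vstack([norm[labels == t].mean(axis=0) for t in types])
    return pd.DataFrame(means, index=types, columns=list(gene_ids))


def mean_profiles(omega: PseudoReference) -> pd.DataFrame:
    """Per-region-type mean of library-normalised Ω rows, over all genes."""
    return _normalized_type_means(omega.profiles, omega.labels, omega.gene_ids)


def reference_profiles(
    ref: SingleCellReference, level: str = "fine", types: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-type mean profiles of a single-cell reference at fine or region level."""
    if level == "fine":
        labels = ref.fine_type
    elif level == "region":
        labels = ref.region_labels()
    else:
        raise ValidationError("level must be 'fine' or 'region'")
    profs = _normalized_type_means(ref.counts, labels, ref.gene_ids)
    if types is not None:
        types = [str(t) for t in types]
        missing = sorted(set(types) - set(profs.index))
        if missing:
            raise ValidationError(f"reference lacks types {missing}")
        profs = profs.loc[types]
    return profs


def select_signature_genes(profiles: pd.DataFrame, n_top: int = 200) -> list[str]:
    """Union of the top one-vs-rest log-fold-change genes per type."""
    if len(profiles) < 2:
        return [str(c) for c in profiles.columns]
    selected: set[str] = set()
    vals = profiles.to_numpy(float)
    for i in range(vals.shape[0]):
        rest = np.delete(vals, i, axis=0).mean(axis=0)
        lfc = np.log2((vals[i] + LFC_PSEUDO) / (rest + LFC_PSEUDO))
        order = np.argsort(lfc)[::-1][: min(n_top, vals.shape[1])]
        selected.update(profiles.columns[j] for j in order)
    # preserve the profile's gene order for determinism
    return [str(c) for c in profiles.columns if c in selected]


def region_profiles(omega: PseudoReference, n_top_genes: int = 200) -> pd.DataFrame:
    """Signature matrix (region types × marker genes) derived from Ω."""
    profs = mean_profiles(omega)
    return profs[select_signature_genes(profs, n_top_genes)]


def _nnls_proportions(
    y: np.ndarray, signatures: np.ndarray
) -> tuple[np.ndarray, bool]:
    coef, _ = nnls(signatures.T, y)
    total = coef.sum()
    if total <= 0:
        return np.full(signatures.shape[0], 1.0 / signatures.shape[0]), True
    return coef / total, False


def deconvolve_regions(
    sc: SpatialCounts, signatures: pd.DataFrame
) -> ProportionMatrix:
    """Estimate region-level proportions per spot by non-negative least squares.

    The spot profile is library-normalised on the signature gene set and fit
    against the signature rows; coefficients are renormalised to sum to one.
    Spots whose NNLS solution is identically zero fall back to uniform
    proportions with a logged warning.
    """
    if len(signatures) < 2:
        raise ValidationError("need at least two region-level signatures")
    genes = [g for g in signatures.columns if g in set(sc.gene_ids)]
    if not genes:
        raise ValidationError(
            "signature and ST gene sets do not intersect"
        )
    col = {g: j for j, g in enumerate(sc.gene_ids)}
    sub = sc.counts[:, [col[g] for g in genes]].astype(float)
    S = signatures[genes].to_numpy(float)

    values = np.empty((sc.n_spots, len(signatures)))
    n_degenerate = 0
    for s in range(sc.n_spots):
        y = sub[s]
        total = y.sum()
        y = y / total if total > 0 else y
        values[s], degenerate = _nnls_proportions(y, S)
        n_degenerate += degenerate
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} spots had an all-zero NNLS solution; "
            "assigned uniform proportions",
            stacklevel=2,
        )
    return ProportionMatrix(
        values, [str(t) for t in signatures.index], list(sc.spot_ids), level="region"
    )


def within_region_proportions(
    sc: SpatialCounts,
    external_ref: SingleCellReference,
    region_type: str,
    n_top_genes: int = 200,
) -> ProportionMatrix:
    """Split one region-level type into its fine subtypes, per spot.

    Fine-type signatures are per-subtype means of the external reference ω
    restricted to the subtypes of ``region_type``; each spot is fit against
    those signatures only and the shares renormalised so the subtypes of this
    region-level type sum to one.  A single-subtype region returns the
    constant 1.
    """
    subtypes = [
        t
        for t in external_ref.fine_types
        if external_ref.region_type_of[t] == str(region_type)
    ]
    if not subtypes:
        raise ValidationError(
            f"external reference has no fine types for region type {region_type!r}"
        )
    if len(subtypes) == 1:
        return ProportionMatrix(
            np.ones((sc.n_spots, 1)), subtypes, list(sc.spot_ids), level="fine"
        )
    profs = reference_profiles(external_ref, level="fine", types=subtypes)
    sigs = profs[select_signature_genes(profs, n_top_genes)]
    genes = [g for g in sigs.columns if g in set(sc.gene_ids)]
    if not genes:
        raise ValidationError("signature and ST gene sets do not intersect")
    col = {g: j for j, g in enumerate(sc.gene_ids)}
    sub = sc.counts[:, [col[g] for g in genes]].astype(float)
    S = sigs[genes].to_numpy(float)
    values = np.empty((sc.n_spots, len(subtypes)))
    for s in range(sc.n_spots):
        y = sub[s]
        total = y.sum()
        y = y / total if total > 0 else y
        values[s], _ = _nnls_proportions(y, S)
    return ProportionMatrix(values, subtypes, list(sc.spot_ids), level="fine")


def deconvolve_fine(
    region_props: ProportionMatrix,
    within_props_per_type: Mapping[str, ProportionMatrix],
) -> ProportionMatrix:
    """Two-step product estimator for fine-type proportions.

    The final proportion of subtype ``t`` with parent region-level type ``T``
    is the product of the spot's estimated ``T`` proportion and the
    within-``T`` share of ``t``.  Because each within-block is
    row-normalised, the fine-level rows sum to one exactly.
    """
    missing = sorted(set(within_props_per_type) - set(region_props.type_ids))
    if missing:
        raise ValidationError(
            f"fine-type blocks for region-level types absent from the "
            f"region estimate: {missing}"
        )
    uncovered = sorted(set(region_props.type_ids) - set(within_props_per_type))
    if uncovered:
        raise ValidationError(
            f"region-level types without a within-region block: {uncovered}"
        )
    blocks: list[np.ndarray] = []
    fine_ids: list[str] = []
    for T in region_props.type_ids:
        within = within_props_per_type[T]
        if list(within.spot_ids) != list(region_props.spot_ids):
            raise ValidationError(
                f"within-region block for {T!r} covers a different spot set"
            )
        blocks.append(region_props.column(T)[:, None] * within.values)
        fine_ids.extend(within.type_ids)
    return ProportionMatrix(
        np.hstack(blocks), fine_ids, list(region_props.spot_ids), level="fine"
    )


def match_regions_to_types(
    sc: SpatialCounts,
    assignment: RegionAssignment,
    signatures: pd.DataFrame,
) -> dict[str, str]:
    """Name detected regions by correlating their mean profile with signatures.

    For each detected region, the library-normalised mean expression over its
    spots is Pearson-correlated with each reference signature row on the
    common gene set; the best-matching type names the region.  Intended for
    real-data runs where no ground truth exists.
    """
    genes = [g for g in signatures.columns if g in set(sc.gene_ids)]
    if not genes:
        raise ValidationError("signature and ST gene sets do not intersect")
    col = {g: j for j, g in enumerate(sc.gene_ids)}
    sub = sc.counts[:, [col[g] for g in genes]].astype(float)
    S = signatures[genes].to_numpy(float)
    mapping: dict[str, str] = {}
    for region_id in assignment.region_ids:
        rows = np.flatnonzero(assignment.labels == region_id)
        prof = sub[rows]
        lib = prof.sum(axis=1, keepdims=True)
        lib[lib == 0] = 1.0
        mean = (prof / lib).mean(axis=0)
        cors = [float(np.corrcoef(mean, S[i])[0, 1]) for i in range(S.shape[0])]
        mapping[region_id] = str(signatures.index[int(np.argmax(cors))])
    return mapping


def name_regions_by_truth(
    assignment: RegionAssignment, truth_labels: Sequence[str]
) -> dict[str, str]:
    """Benchmark alignment: name each detected region by the majority
    ground-truth label of its spots (labels aligned by spot position).
    Evaluation plumbing only — does not alter the estimates."""
    truth = np.asarray([str(t) for t in truth_labels], dtype=object)
    if truth.shape[0] != len(assignment.spot_ids):
        raise ValidationError("truth labels do not cover the spot set")
    mapping: dict[str, str] = {}
    for region_id in assignment.region_ids:
        labs, counts = np.unique(
            truth[assignment.labels == region_id], return_counts=True
        )
        mapping[region_id] = str(labs[np.argmax(counts)])
    return mapping


def export_reference(
    omega: PseudoReference, out_dir: str | Path, format: str = "csv"
) -> dict[str, Path]:
    """Write Ω as a labelled reference consumable by external tools.

    ``format='csv'`` writes ``omega.csv`` (rows = spots, header = genes) and
    ``omega_labels.tsv``; ``format='mtx'`` writes a matrix-market triple in
    the genes × spots orientation plus id files.
    """
    from . import io as _io  # deferred to avoid a cycle at import time

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        matrix_path = out_dir / "omega.csv"
    elif format == "mtx":
        matrix_path = out_dir / "omega.mtx"
    else:
        raise ValidationError(f"unsupported export format {format!r}")
    _io._write_matrix(matrix_path, omega.profiles, omega.gene_ids, omega.spot_ids)
    labels_path = out_dir / "omega_labels.tsv"
    pd.DataFrame({"cell_id": omega.spot_ids, "fine_type": omega.labels}).to_csv(
        labels_path, sep="\t", index=False
    )
    grouping_path = out_dir / "omega_grouping.tsv"
    pd.DataFrame(
        {"fine_type": omega.region_types, "region_type": omega.region_types}
    ).to_csv(grouping_path, sep="\t", index=False)
    logger.info("exported pseudo-internal reference to %s", out_dir)
    return {"matrix": matrix_path, "labels": labels_path, "grouping": grouping_path}
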
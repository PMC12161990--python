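"""Thin orchestration of the full region-sorting pipeline.

Glue only: every step delegates to the stage modules.  The pipeline detects
molecular regions, names them, builds the pseudo-internal reference Ω,
derives a marker-gene signature matrix, and estimates region-level
proportions with the built-in NNLS solver.  Region-level types that never
form a spatial region (e.g. scattered immune cells) can be supplied as extra
signature rows taken from an external reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .deconvolution import (
    build_pseudo_reference,
    deconvolve_regions,
    match_regions_to_types,
    mean_profiles,
    name_regions_by_truth,
    reference_profiles,
    select_signature_genes,
    within_region_proportions,
    deconvolve_fine,
)
from .regions import detect_regions, erode_assignment
from .types import (
    ProportionMatrix,
    PseudoReference,
    RegionAssignment,
    SingleCellReference,
    SpatialCounts,
    ValidationError,
)


@dataclass
class ResortResult:
    assignment: RegionAssignment
    epsilon: float
    region_type_map: dict[str, str]
    omega: PseudoReference
    signatures: pd.DataFrame
    region_props: ProportionMatrix


def run_region_pipeline(
    sc: SpatialCounts,
    config: RunConfig,
    region_type_map: Mapping[str, str] | None = None,
    truth_region_labels: Sequence[str] | None = None,
    naming_signatures: pd.DataFrame | None = None,
    extra_signatures: pd.DataFrame | None = None,
    n_top_genes: int = 200,
    omega_erosion: int = 1,
) -> ResortResult:
    """Regions → Ω → signatures → region-level proportions.

    Detected regions must be named with region-level types: pass an explicit
    ``region_type_map``, or ``truth_region_labels`` (benchmark alignment by
    majority vote), or ``naming_signatures`` (reference profiles to correlate
    against — the real-data path).  ``extra_signatures`` rows (types × genes)
    are appended for types without a spatial region before gene selection.

    ``omega_erosion`` rounds of boundary erosion exclude each region's rim —
    the spots most likely to be partial mixtures — from Ω (the region
    assignment itself is reported unchanged).
    """
    assignment, epsilon = detect_regions(
        sc,
        k_pcs=config.k_pcs,
        min_region_size=config.min_region_size,
        epsilon=config.epsilon,
        neighbor_scheme=config.neighbor_scheme,
    )
    if not assignment.region_sizes:
        raise ValidationError(
            "no molecular regions detected; lower min_region_size or supply epsilon"
        )
    if region_type_map is None:
        if truth_region_labels is not None:
            region_type_map = name_regions_by_truth(assignment, truth_region_labels)
        elif naming_signatures is not None:
            region_type_map = match_regions_to_types(sc, assignment, naming_signatures)
        else:
            raise ValidationError(
                "detected regions are anonymous: supply region_type_map, "
                "truth_region_labels or naming_signatures"
            )
    region_type_map = dict(region_type_map)
    omega_assignment = (
        erode_assignment(
            assignment, sc.coords, omega_erosion, config.neighbor_scheme
        )
        if omega_erosion > 0
        else assignment
    )
    omega = build_pseudo_reference(sc, omega_assignment, region_type_map)
    profs = mean_profiles(omega)
    if extra_signatures is not None:
        extra = extra_signatures.loc[
            [t for t in extra_signatures.index if t not in profs.index]
        ]
        common = [g for g in profs.columns if g in set(extra.columns)]
        if not common:
            raise ValidationError("extra signatures share no genes with the sample")
        profs = pd.concat([profs[common], extra[common]])
    signatures = profs[select_signature_genes(profs, n_top_genes)]
    region_props = deconvolve_regions(sc, signatures)
    return ResortResult(
        assignment=assignment,
        epsilon=epsilon,
        region_type_map=region_type_map,
        omega=omega,
        signatures=signatures,
        region_props=region_props,
    )


def external_region_pipeline(
    sc: SpatialCounts,
    external_ref: SingleCellReference,
    n_top_genes: int = 200,
    types: Sequence[str] | None = None,
) -> ProportionMatrix:
    """Comparison arm: deconvolve directly against an external reference.

    Region-level signatures come from the external single-cell reference
    instead of Ω — the setting in which batch and platform effects between
    reference and sample degrade the estimates.
    """
    profs = reference_profiles(external_ref, level="region", types=types)
    signatures = profs[select_signature_genes(profs, n_top_genes)]
    return deconvolve_regions(sc, signatures)


def run_fine_pipeline(
    sc: SpatialCounts,
    region_props: ProportionMatrix,
    external_ref: SingleCellReference,
    n_top_genes: int = 200,
) -> ProportionMatrix:
    """Two-step refinement of a region-level estimate to fine types.

    For every region-level type in the estimate, the within-region subtype
    shares come from the external reference; the final fine proportions are
    the product of parent proportion and within-region share.
    """
    within = {
        T: within_region_proportions(sc, external_ref, T, n_top_genes)
        for T in region_props.type_ids
    }
    return deconvolve_fine(region_props, within)
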
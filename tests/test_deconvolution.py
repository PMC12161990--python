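"""Ω construction, signatures, NNLS estimation and the two-step refinement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resort import (
    ProportionMatrix,
    PseudoReference,
    SingleCellReference,
    SpatialCounts,
    ValidationError,
    build_pseudo_reference,
    deconvolve_fine,
    deconvolve_regions,
    export_reference,
    match_regions_to_types,
    mean_profiles,
    region_profiles,
    within_region_proportions,
)
from resort.io import read_reference
from resort.types import UNASSIGNED, RegionAssignment


def grid_counts(counts):
    counts = np.asarray(counts)
    n = counts.shape[0]
    return SpatialCounts(
        counts=counts,
        gene_ids=[f"g{j}" for j in range(counts.shape[1])],
        spot_ids=[f"s{i}" for i in range(n)],
        coords=np.column_stack([np.zeros(n, dtype=int), np.arange(n)]),
    )


@pytest.fixture
def two_type_omega():
    # equal-library signatures so read shares equal cell-type shares
    sig_a = np.array([80, 10, 5, 5, 0, 0], dtype=int)
    sig_b = np.array([0, 0, 5, 5, 10, 80], dtype=int)
    profiles = np.vstack([sig_a, sig_a, sig_b, sig_b])
    return PseudoReference(
        profiles=profiles,
        labels=["A", "A", "B", "B"],
        gene_ids=[f"g{j}" for j in range(6)],
        spot_ids=[f"o{i}" for i in range(4)],
    )


class TestBuildPseudoReference:
    @staticmethod
    def _setup(n_labeled=100, n_unassigned=20):
        n = n_labeled + n_unassigned
        rng = np.random.default_rng(1)
        sc = grid_counts(rng.integers(1, 10, size=(n, 5)))
        labels = np.asarray(
            ["R1"] * (n_labeled // 2) + ["R2"] * (n_labeled - n_labeled // 2)
            + [UNASSIGNED] * n_unassigned,
            dtype=object,
        )
        return sc, RegionAssignment(labels, sc.spot_ids)

    def test_unassigned_spots_excluded(self):
        sc, assignment = self._setup()
        omega = build_pseudo_reference(sc, assignment, {"R1": "x", "R2": "y"})
        assert len(omega.spot_ids) == 100
        assert omega.gene_ids == sc.gene_ids

    def test_two_regions_merge_into_one_type(self):
        sc, assignment = self._setup()
        omega = build_pseudo_reference(sc, assignment, {"R1": "x", "R2": "x"})
        assert set(omega.labels) == {"x"}
        assert len(omega.spot_ids) == 100

    def test_unmapped_type_with_zero_spots_errors(self):
        sc, assignment = self._setup()
        with pytest.raises(ValidationError, match="unknown regions"):
            build_pseudo_reference(sc, assignment, {"R9": "x"})


class TestRegionProfiles:
    def test_single_row_per_type_is_normalized_row(self, two_type_omega):
        omega = PseudoReference(
            profiles=two_type_omega.profiles[[0, 2]],
            labels=["A", "B"],
            gene_ids=two_type_omega.gene_ids,
            spot_ids=["o0", "o2"],
        )
        profs = mean_profiles(omega)
        row = two_type_omega.profiles[0]
        assert np.allclose(profs.loc["A"], row / row.sum())

    def test_duplicated_rows_change_nothing(self, two_type_omega):
        profs = mean_profiles(two_type_omega)
        row = two_type_omega.profiles[0]
        assert np.allclose(profs.loc["A"], row / row.sum())

    def test_planted_marker_is_selected(self, two_type_omega):
        sigs = region_profiles(two_type_omega, n_top_genes=2)
        assert "g0" in sigs.columns  # A-exclusive marker
        assert "g5" in sigs.columns  # B-exclusive marker


class TestDeconvolveRegions:
    def _sigs(self, two_type_omega):
        return region_profiles(two_type_omega, n_top_genes=6)

    def test_pure_spot_recovers_its_type(self, two_type_omega):
        sc = grid_counts(two_type_omega.profiles[[0, 2]] * 3)
        est = deconvolve_regions(sc, self._sigs(two_type_omega))
        assert est.values[0] == pytest.approx([1.0, 0.0], abs=1e-9)
        assert est.values[1] == pytest.approx([0.0, 1.0], abs=1e-9)

    @pytest.mark.parametrize("w", [0.5, 0.7])
    def test_noiseless_mixture_recovered_exactly(self, two_type_omega, w):
        a = two_type_omega.profiles[0].astype(float)
        b = two_type_omega.profiles[2].astype(float)
        mix = np.round(10 * (w * a + (1 - w) * b)).astype(int)  # both libs 100
        sc = grid_counts(mix[None, :])
        est = deconvolve_regions(sc, self._sigs(two_type_omega))
        assert est.values[0] == pytest.approx([w, 1 - w], abs=1e-6)

    def test_rows_sum_to_one_and_scale_invariance(self, two_type_omega, rng):
        counts = rng.integers(1, 50, size=(6, 6))
        sc = grid_counts(counts)
        est = deconvolve_regions(sc, self._sigs(two_type_omega))
        assert est.values.sum(axis=1) == pytest.approx(np.ones(6), abs=1e-9)
        scaled = grid_counts(counts * 7)
        est2 = deconvolve_regions(scaled, self._sigs(two_type_omega))
        assert np.allclose(est.values, est2.values, atol=1e-9)

    def test_disjoint_gene_sets_error(self, two_type_omega):
        sigs = self._sigs(two_type_omega).rename(columns=lambda g: f"other_{g}")
        sc = grid_counts(np.ones((2, 6), dtype=int))
        with pytest.raises(ValidationError, match="intersect"):
            deconvolve_regions(sc, sigs)


def _external_ref():
    rng = np.random.default_rng(7)
    # two fine subtypes of T plus one subtype of U, equal libraries
    t1 = np.array([60, 20, 10, 10, 0, 0])
    t2 = np.array([0, 10, 10, 20, 0, 60])
    u1 = np.array([10, 10, 30, 30, 10, 10])
    counts = np.vstack([t1, t1, t2, t2, u1, u1])
    return SingleCellReference(
        counts=counts,
        gene_ids=[f"g{j}" for j in range(6)],
        cell_ids=[f"c{i}" for i in range(6)],
        fine_type=["t1", "t1", "t2", "t2", "u1", "u1"],
        region_type_of={"t1": "T", "t2": "T", "u1": "U"},
    )


class TestWithinRegionProportions:
    def test_single_subtype_returns_constant_one(self):
        ref = _external_ref()
        sc = grid_counts(np.ones((3, 6), dtype=int))
        props = within_region_proportions(sc, ref, "U")
        assert props.type_ids == ["u1"]
        assert np.all(props.values == 1.0)

    def test_seventy_thirty_mixture_recovered(self):
        ref = _external_ref()
        t1 = ref.counts[0].astype(float)
        t2 = ref.counts[2].astype(float)
        mix = np.round(10 * (0.7 * t1 + 0.3 * t2)).astype(int)
        sc = grid_counts(mix[None, :])
        props = within_region_proportions(sc, ref, "T")
        assert props.values[0] == pytest.approx([0.7, 0.3], abs=1e-6)

    def test_unknown_region_type_errors(self):
        ref = _external_ref()
        sc = grid_counts(np.ones((1, 6), dtype=int))
        with pytest.raises(ValidationError, match="no fine types"):
            within_region_proportions(sc, ref, "Z")


class TestDeconvolveFine:
    @staticmethod
    def _region_props(values, types, n):
        return ProportionMatrix(values, types, [f"s{i}" for i in range(n)], "region")

    @staticmethod
    def _within(values, types, n):
        return ProportionMatrix(values, types, [f"s{i}" for i in range(n)], "fine")

    def test_direct_product(self):
        region = self._region_props([[0.6, 0.4]], ["T", "U"], 1)
        within = {
            "T": self._within([[0.5, 0.5]], ["t1", "t2"], 1),
            "U": self._within([[1.0]], ["u1"], 1),
        }
        fine = deconvolve_fine(region, within)
        assert fine.to_frame().loc["s0", "t1"] == pytest.approx(0.3)
        assert fine.to_frame().loc["s0", "u1"] == pytest.approx(0.4)

    def test_zero_region_zeroes_all_subtypes(self):
        region = self._region_props([[0.0, 1.0]], ["T", "U"], 1)
        within = {
            "T": self._within([[0.5, 0.5]], ["t1", "t2"], 1),
            "U": self._within([[1.0]], ["u1"], 1),
        }
        fine = deconvolve_fine(region, within)
        assert fine.to_frame().loc["s0", ["t1", "t2"]].tolist() == [0.0, 0.0]

    def test_missing_parent_errors(self):
        region = self._region_props([[1.0]], ["T"], 1)
        within = {
            "T": self._within([[1.0]], ["t1"], 1),
            "Z": self._within([[1.0]], ["z1"], 1),
        }
        with pytest.raises(ValidationError, match="absent"):
            deconvolve_fine(region, within)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mass_conservation_on_random_inputs(self, seed):
        """Product estimator keeps rows summing to 1 exactly (identity)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        region = self._region_props(
            rng.dirichlet(np.ones(3), size=n), ["T", "U", "V"], n
        )
        within = {
            "T": self._within(rng.dirichlet(np.ones(2), size=n), ["t1", "t2"], n),
            "U": self._within(rng.dirichlet(np.ones(4), size=n), list("uvwx"), n),
            "V": self._within(np.ones((n, 1)), ["v1"], n),
        }
        fine = deconvolve_fine(region, within)
        assert fine.values.sum(axis=1) == pytest.approx(np.ones(n), abs=1e-9)


class TestExportReference:
    @pytest.mark.parametrize("fmt", ["csv", "mtx"])
    def test_round_trip_preserves_labels(self, tmp_path, two_type_omega, fmt):
        paths = export_reference(two_type_omega, tmp_path, format=fmt)
        ref = read_reference(paths["matrix"], paths["labels"], paths["grouping"])
        assert sorted(ref.fine_type) == sorted(two_type_omega.labels)
        assert ref.counts.shape == two_type_omega.profiles.shape
        assert np.array_equal(ref.counts, two_type_omega.profiles)

    def test_unknown_format_rejected(self, tmp_path, two_type_omega):
        with pytest.raises(ValidationError, match="format"):
            export_reference(two_type_omega, tmp_path, format="xlsx")


def test_match_regions_to_types_by_profile(two_type_omega):
    profs = mean_profiles(two_type_omega)
    counts = np.vstack([two_type_omega.profiles[2]] * 3 + [two_type_omega.profiles[0]] * 3)
    sc = grid_counts(counts)
    assignment = RegionAssignment(
        ["R1"] * 3 + ["R2"] * 3, sc.spot_ids
    )
    mapping = match_regions_to_types(sc, assignment, profs)
    assert mapping == {"R1": "B", "R2": "A"}
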
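"""Group analytics: presentation, ANOVA, clustering, Venn, regions, consistency."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epiconserve.conservancy import ConservationMatrix, mismatch_matrix
from epiconserve.crossreactivity import (
    Region,
    classify_region_pattern,
    classify_regions,
    cluster_heatmap,
    conserved_fraction_per_species,
    consistency_check,
    group_presentation,
    merge_epitope_regions,
    mollusc_class_presentation,
    one_way_anova,
    total_region_residues,
    venn_partition,
)
from epiconserve.io_core import EpitopeRecord, GroupConfig, ValidationError
from epiconserve.synthetic_data import truth_oracle


def _matrix(data: dict, epitope_lengths=None) -> ConservationMatrix:
    df = pd.DataFrame(data).T.astype(float)
    return ConservationMatrix(data=df, epitope_lengths=epitope_lengths or {})


class TestGroupPresentation:
    def test_three_of_four_species_is_75_percent(self):
        matrix = _matrix({"e1": {"s1": 0.0, "s2": 1.0, "s3": 2.0, "s4": 5.0}})
        config = GroupConfig(groups={"mite": ["s1", "s2", "s3", "s4"]})
        pres = group_presentation(matrix, config, max_mismatch=2)
        assert pres.percent.at["e1", "mite"] == 75.0
        assert pres.group_sizes == {"mite": 4}

    def test_conserved_everywhere_is_100_in_all_groups(self):
        matrix = _matrix({"e1": {"s1": 0.0, "s2": 1.0, "s3": 2.0}})
        config = GroupConfig(groups={"mite": ["s1", "s2"], "mollusc": ["s3"]})
        pres = group_presentation(matrix, config, max_mismatch=2)
        assert (pres.percent.loc["e1"] == 100.0).all()

    def test_isoforms_collapse_by_species_minimum(self):
        matrix = _matrix({"e1": {"iso1": 5.0, "iso2": 1.0}})
        config = GroupConfig(
            groups={"mite": ["sp1"]}, species_of={"iso1": "sp1", "iso2": "sp1"}
        )
        pres = group_presentation(matrix, config, max_mismatch=2)
        assert pres.percent.at["e1", "mite"] == 100.0
        assert pres.group_sizes["mite"] == 1
        per_seq = group_presentation(matrix, config, max_mismatch=2, per_sequence=True)
        assert per_seq.percent.at["e1", "mite"] == 50.0

    def test_no_window_counts_as_not_conserved(self):
        matrix = _matrix({"e1": {"s1": np.nan, "s2": 0.0}})
        config = GroupConfig(groups={"mite": ["s1", "s2"]})
        pres = group_presentation(matrix, config, max_mismatch=2)
        assert pres.percent.at["e1", "mite"] == 50.0

    def test_matches_truth_oracle_on_simulated_family(
        self, small_family, small_epitopes
    ):
        prots = list(small_family.entries)
        matrix = mismatch_matrix(small_epitopes, prots)
        config = small_family.group_config()
        for threshold in (0, 1, 2, 4):
            truth = truth_oracle(prots, small_epitopes, threshold)
            pres = group_presentation(matrix, config, threshold)
            for eid in pres.percent.index:
                for g in pres.percent.columns:
                    assert pres.percent.at[eid, g] == pytest.approx(
                        truth.group_percent[eid][g]
                    )

    def test_empty_group_after_filtering_rejected(self):
        matrix = _matrix({"e1": {"s1": 0.0}})
        config = GroupConfig(groups={"mite": ["s1"], "mollusc": ["absent"]})
        with pytest.raises(ValidationError, match="no group assignment|no sequences"):
            group_presentation(matrix, config, 2)

    def test_mollusc_class_presentation(self):
        matrix = _matrix({"e1": {"b1": 0.0, "c1": 1.0, "g1": 9.0}})
        config = GroupConfig(
            groups={"mollusc": ["b1", "c1", "g1"]},
            mollusc_classes={"bivalve": ["b1"], "cephalopod": ["c1"], "gastropod": ["g1"]},
        )
        cls = mollusc_class_presentation(matrix, config, max_mismatch=2)
        assert cls.loc["e1"].to_dict() == {
            "bivalve": 100.0,
            "cephalopod": 100.0,
            "gastropod": 0.0,
        }


class TestConservedFractionPerSpecies:
    def test_identical_species_scores_one(self):
        matrix = _matrix({"e1": {"s1": 0.0}, "e2": {"s1": 0.0}})
        assert conserved_fraction_per_species(matrix, 2).at["s1"] == 1.0

    def test_all_sentinel_column_scores_zero(self):
        matrix = _matrix({"e1": {"s1": np.nan}, "e2": {"s1": np.nan}})
        assert conserved_fraction_per_species(matrix, 2).at["s1"] == 0.0

    def test_equals_direct_recount(self, small_family, small_epitopes):
        matrix = mismatch_matrix(small_epitopes, list(small_family.entries))
        fractions = conserved_fraction_per_species(matrix, 2)
        for acc in matrix.accessions:
            col = matrix.data[acc]
            want = sum(1 for v in col if not np.isnan(v) and v <= 2) / len(col)
            assert fractions.at[acc] == pytest.approx(want)


class TestOneWayAnova:
    def test_worked_toy_example(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert res.f == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_matches_textbook_sums_of_squares(self):
        samples = {"a": [0.1, 0.4, 0.5], "b": [0.7, 0.9, 0.6], "c": [0.2, 0.3, 0.35]}
        res = one_way_anova(samples)
        # independent computation straight from the definitional sums of squares
        values = [v for vs in samples.values() for v in vs]
        grand = sum(values) / len(values)
        ss_between = sum(
            len(vs) * (sum(vs) / len(vs) - grand) ** 2 for vs in samples.values()
        )
        ss_within = sum(
            (v - sum(vs) / len(vs)) ** 2 for vs in samples.values() for v in vs
        )
        f = (ss_between / 2) / (ss_within / 6)
        assert res.f == pytest.approx(f)

    def test_equal_means_give_zero_f(self):
        res = one_way_anova({"a": [1.0, 3.0], "b": [2.0, 2.0]})
        assert res.f == pytest.approx(0.0)

    def test_shift_invariance(self):
        base = {"a": [1.0, 2.0, 4.0], "b": [2.0, 5.0, 3.0]}
        shifted = {k: [v + 7.5 for v in vs] for k, vs in base.items()}
        assert one_way_anova(base).f == pytest.approx(one_way_anova(shifted).f)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValidationError, match="F undefined"):
            one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_arcsine_requires_fractions(self):
        with pytest.raises(ValidationError):
            one_way_anova({"a": [0.5, 2.0], "b": [0.1, 0.2]}, arcsine=True)


class TestClusterHeatmap:
    def test_identical_rows_merge_first_at_height_zero(self):
        matrix = _matrix(
            {"e1": {"a": 0.0, "b": 1.0}, "e2": {"a": 0.0, "b": 1.0}, "e3": {"a": 9.0, "b": 9.0}},
            epitope_lengths={"e1": 10, "e2": 10, "e3": 10},
        )
        res = cluster_heatmap(matrix)
        assert res.row_linkage[0, 2] == 0.0  # first merge height
        assert set(res.row_linkage[0, :2].astype(int)) == {0, 1}  # e1 with e2

    def test_matches_brute_force_average_linkage(self):
        values = {"e1": {"a": 0.0, "b": 1.0, "c": 2.0},
                  "e2": {"a": 1.0, "b": 1.0, "c": 2.0},
                  "e3": {"a": 9.0, "b": 8.0, "c": 0.0}}
        matrix = _matrix(values, epitope_lengths={k: 10 for k in values})
        res = cluster_heatmap(matrix)
        # brute force: average-linkage over hand-computed Manhattan distances
        rows = list(values)
        dist = {
            frozenset((i, j)): sum(
                abs(values[i][c] - values[j][c]) for c in ("a", "b", "c")
            )
            for i, j in itertools.combinations(rows, 2)
        }
        assert dist[frozenset(("e1", "e2"))] == 1.0  # first merge pair
        assert res.row_linkage[0, 2] == 1.0
        # second merge joins {e1,e2} with e3 at the average of the two distances
        expected = (dist[frozenset(("e1", "e3"))] + dist[frozenset(("e2", "e3"))]) / 2
        assert res.row_linkage[1, 2] == pytest.approx(expected)

    def test_row_permutation_gives_same_tree(self):
        values = {"e1": {"a": 0.0, "b": 1.0}, "e2": {"a": 4.0, "b": 1.0},
                  "e3": {"a": 9.0, "b": 8.0}}
        m1 = _matrix(values, epitope_lengths={k: 10 for k in values})
        permuted = {k: values[k] for k in ("e3", "e1", "e2")}
        m2 = _matrix(permuted, epitope_lengths={k: 10 for k in values})
        r1, r2 = cluster_heatmap(m1), cluster_heatmap(m2)
        heights1 = sorted(r1.row_linkage[:, 2])
        heights2 = sorted(r2.row_linkage[:, 2])
        assert heights1 == pytest.approx(heights2)
        assert r1.row_order in (r2.row_order, r2.row_order[::-1])

    def test_single_row_identity_ordering(self):
        matrix = _matrix({"e1": {"a": 0.0, "b": 1.0}}, epitope_lengths={"e1": 5})
        res = cluster_heatmap(matrix)
        assert res.row_order == ["e1"]

    def test_sentinels_imputed_as_length_plus_one(self):
        matrix = _matrix(
            {"e1": {"a": np.nan, "b": 0.0}, "e2": {"a": 6.0, "b": 0.0}},
            epitope_lengths={"e1": 5, "e2": 5},
        )
        res = cluster_heatmap(matrix)
        assert res.row_linkage[0, 2] == 0.0  # NaN -> 6 makes the rows identical


class TestVennPartition:
    def test_table1_yields_22_pan_epitopes(self, table1):
        part = venn_partition(table1.presentation)
        assert len(part.pan_epitopes) == 22

    def test_table2_yields_5_pan_epitopes(self, table2):
        part = venn_partition(table2.presentation)
        assert len(part.pan_epitopes) == 5

    def test_cells_partition_the_epitopes(self):
        percent = pd.DataFrame(
            {"crustacean": [100, 100, 0], "mollusc": [50, 0, 0]},
            index=["e1", "e2", "e3"],
        ).astype(float)
        part = venn_partition(percent)
        assert sum(part.cell_counts.values()) == 3
        assert part.groups_conserved["e3"] == frozenset()
        assert part.pan_epitopes == ("e1",)

    def test_threshold_shrinks_membership(self, table1):
        strict = venn_partition(table1.presentation, threshold=50.0)
        assert len(strict.pan_epitopes) < 22

    def test_empty_input_gives_empty_partition(self):
        percent = pd.DataFrame(columns=["crustacean", "mollusc"]).astype(float)
        part = venn_partition(percent)
        assert part.groups_conserved == {} and part.pan_epitopes == ()

    def test_pan_set_equals_intersection_of_per_group_sets(self, table1):
        part = venn_partition(table1.presentation)
        per_group = [
            {e for e in table1.presentation.index if table1.presentation.at[e, g] > 0}
            for g in table1.presentation.columns
        ]
        assert set(part.pan_epitopes) == set.intersection(*per_group)


class TestRegions:
    def test_published_spans_merge_to_seven_regions(self, table1):
        regions = merge_epitope_regions(list(table1.records))
        assert [(r.start, r.end) for r in regions] == [
            (1, 18), (85, 105), (115, 129), (144, 151),
            (154, 171), (187, 207), (241, 267),
        ]
        assert total_region_residues(regions) == 128

    def test_total_residues_matches_position_set_oracle(self, table1):
        regions = merge_epitope_regions(list(table1.records))
        covered = set()
        for r in table1.records:
            covered.update(range(r.start, r.end + 1))
        assert total_region_residues(regions) == len(covered)

    def test_single_epitope_is_its_own_region(self):
        e = EpitopeRecord("e1", "TM", "ACDEF", 10, 14)
        regions = merge_epitope_regions([e])
        assert [(regions[0].start, regions[0].end)] == [(10, 14)]

    def test_disjoint_epitopes_stay_separate(self):
        es = [
            EpitopeRecord("e1", "TM", "ACDEF", 1, 5),
            EpitopeRecord("e2", "TM", "GHIKL", 10, 14),
        ]
        regions = merge_epitope_regions(es)
        assert len(regions) == 2
        assert total_region_residues(regions) == 10

    def test_adjacent_epitopes_not_merged(self):
        es = [
            EpitopeRecord("e1", "TM", "ACDEF", 1, 5),
            EpitopeRecord("e2", "TM", "GHIKL", 6, 10),
        ]
        assert len(merge_epitope_regions(es)) == 2

    def test_order_independent_and_idempotent(self, table1):
        records = list(table1.records)
        forward = merge_epitope_regions(records)
        reverse = merge_epitope_regions(records[::-1])
        assert [(r.start, r.end) for r in forward] == [(r.start, r.end) for r in reverse]
        assert [set(r.epitope_ids) for r in forward] == [set(r.epitope_ids) for r in reverse]

    def test_missing_positions_rejected(self):
        with pytest.raises(ValidationError):
            merge_epitope_regions([EpitopeRecord("e1", "TM", "ACDEF")])


class TestRegionPatterns:
    region = Region(start=1, end=15, epitope_ids=("e1",))

    @pytest.mark.parametrize(
        "percentages,expected",
        [
            ({"bivalve": 93, "cephalopod": 100, "gastropod": 100}, "all_mollusc"),
            ({"bivalve": 0, "cephalopod": 100, "gastropod": 100}, "cephalopod_gastropod"),
            ({"bivalve": 80, "cephalopod": 100, "gastropod": 0}, "bivalve_cephalopod"),
            ({"bivalve": 0, "cephalopod": 0, "gastropod": 0}, "crustacean_only"),
            ({"bivalve": 100, "cephalopod": 0, "gastropod": 0}, "other"),
            ({"bivalve": 50, "cephalopod": 50, "gastropod": 50}, "crustacean_only"),
        ],
    )
    def test_rule_application(self, percentages, expected):
        assert classify_region_pattern(self.region, percentages) == expected

    def test_missing_class_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            classify_region_pattern(self.region, {"bivalve": 10, "cephalopod": 10})

    def test_classify_regions_uses_member_maximum(self):
        regions = [Region(start=1, end=20, epitope_ids=("e1", "e2"))]
        class_percent = pd.DataFrame(
            {"bivalve": [60.0, 0.0], "cephalopod": [0.0, 70.0], "gastropod": [80.0, 0.0]},
            index=["e1", "e2"],
        )
        out = classify_regions(regions, class_percent)
        assert out[0].pattern == "all_mollusc"


class TestConsistencyCheck:
    def test_agreeing_overlap_is_clean(self):
        a = EpitopeRecord("a", "TM", "LNRRIQLLEEDLERS", 88, 102)
        b = EpitopeRecord("b", "TM", "NRRIQLLEEDLERSEER", 89, 105)
        assert consistency_check([a, b]) == []

    def test_table1_conflicts_all_involve_the_misplaced_record(self, table1):
        conflicts = consistency_check(list(table1.records))
        assert conflicts  # the printed 241-260 record disagrees with its neighbours
        offender = next(
            r.epitope_id
            for r in table1.records
            if r.peptide == "KEVDRLEDELVNEKEKYKSI"
        )
        assert all(offender in (c.epitope_a, c.epitope_b) for c in conflicts)
        # no other pair conflicts
        others = [r for r in table1.records if r.epitope_id != offender]
        assert consistency_check(others) == []

    def test_single_record_is_clean(self):
        assert consistency_check([EpitopeRecord("a", "TM", "ACDEF", 1, 5)]) == []

    def test_mixed_allergens_rejected(self):
        a = EpitopeRecord("a", "TM", "ACDEF", 1, 5)
        b = EpitopeRecord("b", "AK", "ACDEF", 1, 5)
        with pytest.raises(ValidationError):
            consistency_check([a, b])
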
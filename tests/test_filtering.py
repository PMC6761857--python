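import numpy as np
import pytest

from sweepscan.filtering import (
    FilterReport,
    TsTvUndefinedError,
    VariantParseError,
    VariantRecord,
    apply_depth_filters,
    apply_hard_filters,
    classify_substitution,
    compute_tstv,
    intersect_callers,
    restrict_sites,
)

CLEAN_INFO = {"QD": 10.0, "FS": 5.0, "MQ": 50.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0, "DP": 20}


def record(pos=100, scaffold="scaf1", ref="A", alts=("G",), qual=100.0, **info_overrides):
    info = {**CLEAN_INFO, **info_overrides}
    return VariantRecord(scaffold=scaffold, pos=pos, ref=ref, alts=alts, qual=qual, info=info)


class TestHardFilters:
    def test_low_qd_removed(self):
        kept, report = apply_hard_filters([record(QD=1.9)])
        assert kept == []
        assert report.reasons[("scaf1", 100)] == ["hard_filter:QD"]

    def test_all_passing_retained(self):
        kept, _ = apply_hard_filters([record()])
        assert len(kept) == 1

    def test_fs_boundary_is_strict(self):
        # removal requires FS > 60, so FS == 60 passes
        kept, _ = apply_hard_filters([record(FS=60.0)])
        assert len(kept) == 1

    @pytest.mark.parametrize(
        "override, reason",
        [
            ({"FS": 60.1}, "FS"),
            ({"MQ": 39.9}, "MQ"),
            ({"MQRankSum": -12.6}, "MQRankSum"),
            ({"ReadPosRankSum": -8.1}, "ReadPosRankSum"),
        ],
    )
    def test_each_threshold(self, override, reason):
        kept, report = apply_hard_filters([record(**override)])
        assert kept == []
        assert report.reasons[("scaf1", 100)] == [f"hard_filter:{reason}"]

    def test_qual_boundary(self):
        kept, _ = apply_hard_filters([record(qual=29.9)])
        assert kept == []
        kept, _ = apply_hard_filters([record(qual=30.0)])
        assert len(kept) == 1

    def test_missing_annotation_never_removes(self):
        r = VariantRecord("scaf1", 5, "A", ("G",), qual=100.0, info={})
        kept, _ = apply_hard_filters([r])
        assert len(kept) == 1

    def test_malformed_info_raises_with_context(self):
        r = VariantRecord("scaf7", 123, "A", ("G",), qual=50.0, info={"QD": "oops"})
        with pytest.raises(VariantParseError, match="scaf7:123"):
            apply_hard_filters([r])

    def test_order_insensitive(self):
        records = [record(pos=p, QD=q) for p, q in [(1, 1.0), (2, 10.0), (3, 1.5), (4, 25.0)]]
        kept_fwd, _ = apply_hard_filters(records)
        kept_rev, _ = apply_hard_filters(records[::-1])
        assert {r.pos for r in kept_fwd} == {r.pos for r in kept_rev} == {2, 4}

    def test_idempotent(self):
        records = [record(pos=p, QD=q) for p, q in [(1, 1.0), (2, 10.0), (3, 25.0)]]
        once, _ = apply_hard_filters(records)
        twice, report = apply_hard_filters(once)
        assert twice == once
        assert report.stages[-1].n_removed == 0


class TestDepthFilters:
    def test_hand_computed_example(self):
        # DP = {10,10,10,10,4}: mean 8.8, sample SD ~2.683; only DP=4 fails (DP >= 5)
        records = [record(pos=i + 1, DP=d) for i, d in enumerate([10, 10, 10, 10, 4])]
        kept, report = apply_depth_filters(records)
        assert len(kept) == 4
        assert report.reasons[("scaf1", 5)] == ["DP-min"]

    def test_degenerate_sd_keeps_all(self):
        records = [record(pos=i + 1, DP=20) for i in range(6)]
        kept, _ = apply_depth_filters(records)
        assert len(kept) == 6

    def test_extreme_outlier_removed(self):
        records = [record(pos=i + 1, DP=10) for i in range(999)]
        records.append(record(pos=1000, DP=1000))
        dp = np.array([10.0] * 999 + [1000.0])
        mu, sd = dp.mean(), dp.std(ddof=1)
        assert 1000 > mu + 3 * sd  # sanity of the constructed vector
        kept, report = apply_depth_filters(records)
        assert len(kept) == 999
        assert report.reasons[("scaf1", 1000)] == ["DP-outlier"]

    def test_missing_dp_removed_with_reason(self):
        bad = VariantRecord("scaf1", 9, "A", ("G",), qual=50.0, info={"QD": 10.0})
        kept, report = apply_depth_filters([record(pos=1), bad, record(pos=2)])
        assert len(kept) == 2
        assert report.reasons[("scaf1", 9)] == ["DP-missing"]

    def test_two_pass_statistics_fixed_before_filtering(self):
        # the DP=4 record participates in the mean/SD even though it is removed
        records = [record(pos=i + 1, DP=d) for i, d in enumerate([10, 10, 10, 10, 4])]
        _, report = apply_depth_filters(records)
        # if stats were recomputed after removing DP=4, sigma would be 0 and
        # nothing else could fail; assert the stage saw all five inputs
        assert report.stages[-1].n_input == 5


class TestRestrictSites:
    def test_mtdna_scaffold_removed(self):
        r = record(scaffold="NC_009849.1")
        kept, report = restrict_sites([r])
        assert kept == []
        assert "excluded-scaffold" in report.reasons[("NC_009849.1", 100)]

    def test_multiallelic_removed(self):
        kept, _ = restrict_sites([record(alts=("T", "G"))])
        assert kept == []

    def test_indel_removed(self):
        kept, _ = restrict_sites([record(ref="AT", alts=("A",))])
        assert kept == []

    def test_biallelic_snp_retained(self):
        kept, _ = restrict_sites([record()])
        assert len(kept) == 1


class TestTsTv:
    def test_balanced(self):
        pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("A", "C"), ("T", "A"), ("G", "C")]
        records = [record(pos=i + 1, ref=a, alts=(b,)) for i, (a, b) in enumerate(pairs)]
        assert compute_tstv(records) == 1.0

    def test_two_to_one(self):
        pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "T"), ("C", "G")]
        records = [record(pos=i + 1, ref=a, alts=(b,)) for i, (a, b) in enumerate(pairs)]
        assert compute_tstv(records) == 2.0

    def test_empty_input_undefined(self):
        with pytest.raises(TsTvUndefinedError):
            compute_tstv([])

    def test_zero_transversions_carries_counts(self):
        with pytest.raises(TsTvUndefinedError) as exc:
            compute_tstv([record(ref="A", alts=("G",))])
        assert exc.value.transitions == 1
        assert exc.value.transversions == 0

    def test_symmetric_in_ref_alt(self):
        for a, b in [("A", "G"), ("C", "A"), ("T", "G")]:
            assert classify_substitution(a, b) == classify_substitution(b, a)


class TestReportInvariants:
    def test_stage_conservation(self, small_cohort):
        report = FilterReport()
        retained, _ = apply_hard_filters(small_cohort.records, report=report)
        retained, _ = apply_depth_filters(retained, report=report)
        retained, _ = restrict_sites(retained, report=report)
        for stage in report.stages:
            assert stage.n_input == stage.n_removed + stage.n_retained
            assert stage.n_removed >= 0
        assert report.stages[0].n_input == len(small_cohort.records)
        assert report.stages[-1].n_retained == len(retained)

    def test_removed_set_equals_simulator_truth(self, small_cohort):
        _, report = apply_hard_filters(small_cohort.records)
        removed = set(report.reasons)
        truth = {
            (row.scaffold, row.pos): row.filter
            for row in small_cohort.truth.failing_sites.itertuples(index=False)
        }
        assert removed == set(truth)
        for key, reasons in report.reasons.items():
            assert reasons == [f"hard_filter:{truth[key]}"]


class TestCallerIntersection:
    def test_genotypes_from_second_input(self):
        a = [record(pos=1), record(pos=2)]
        b1 = VariantRecord("scaf1", 1, "A", ("G",), qual=77.0, info=dict(CLEAN_INFO),
                           genotypes=((0, 1),))
        b3 = VariantRecord("scaf1", 3, "A", ("G",), qual=77.0, info=dict(CLEAN_INFO))
        kept, report = intersect_callers(a, [b1, b3])
        assert [r.pos for r in kept] == [1]
        assert kept[0].qual == 77.0
        assert kept[0].genotypes == ((0, 1),)
        assert report.stages[-1].n_removed == 1
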
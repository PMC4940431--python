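import numpy as np
import pytest

from panelcnv.calling import (
    CallingThresholds,
    apply_exclusion_list,
    cohort_annotate,
    ddpcr_call,
    flag_extreme_gc,
    segment_calls,
)
from panelcnv.errors import AlignmentError, ConfigError
from panelcnv.qc import FiveNumberSummary

from conftest import make_intervals


def simple_summary(lower, upper):
    return FiveNumberSummary(lower, lower / 2, 0.0, upper / 2, upper, 3.0)


def brute_force_runs(ratios, intervals, s, th):
    """Independent enumerator: test every contiguous run for eligibility and
    maximality."""
    gain_cut = max(th.gain_log2, s.upper_whisker)
    loss_cut = min(th.loss_log2, s.lower_whisker)

    def elig(i, t):
        v = ratios[i]
        if not np.isfinite(v):
            return False
        return v > gain_cut if t == "gain" else v < loss_cut

    n = len(ratios)
    found = []
    for t in ("gain", "loss"):
        minp = th.min_probes_gain if t == "gain" else th.min_probes_loss
        for i in range(n):
            for j in range(i, n):
                members = range(i, j + 1)
                if not all(
                    elig(k, t) and intervals[k].chrom == intervals[i].chrom
                    for k in members
                ):
                    continue
                left_open = i > 0 and elig(i - 1, t) and intervals[i - 1].chrom == intervals[i].chrom
                right_open = j < n - 1 and elig(j + 1, t) and intervals[j + 1].chrom == intervals[j].chrom
                if not left_open and not right_open and j - i + 1 >= minp:
                    found.append((t, i, j))
    return sorted(found)


class TestSegmentCalls:
    def test_two_interval_loss(self):
        ivs = make_intervals(4)
        calls = segment_calls(
            "s", np.array([0.0, -1.0, -1.0, 0.0]), ivs, simple_summary(-0.3, 0.3)
        )
        assert len(calls) == 1
        c = calls[0]
        assert (c.type, c.first_rank, c.last_rank) == ("loss", 1, 2)
        assert c.median_log2 == -1.0
        assert c.inferred_cn == pytest.approx(1.0)
        assert c.id == 1

    def test_all_neutral_no_calls(self):
        ivs = make_intervals(5)
        assert segment_calls("s", np.zeros(5), ivs, simple_summary(-0.3, 0.3)) == []

    def test_gain_requires_both_threshold_and_whisker(self):
        ivs = make_intervals(3)
        ratios = np.array([0.0, 0.45, 0.0])
        # exceeds the 0.40 threshold but not the 0.50 whisker: no call
        assert segment_calls("s", ratios, ivs, simple_summary(-0.5, 0.50)) == []
        # exceeds both: a single-interval gain, cn = 2 * 2^0.45
        calls = segment_calls("s", ratios, ivs, simple_summary(-0.5, 0.30))
        assert [c.type for c in calls] == ["gain"]

    def test_single_interval_gain_copy_number(self):
        ivs = make_intervals(1)
        calls = segment_calls("s", np.array([0.60]), ivs, simple_summary(-0.3, 0.3))
        assert calls[0].inferred_cn == pytest.approx(2 * 2 ** 0.6)  # ~3.03

    def test_loss_requires_both_threshold_and_whisker(self):
        ivs = make_intervals(3)
        ratios = np.array([0.0, -0.7, 0.0])
        assert segment_calls("s", ratios, ivs, simple_summary(-0.8, 0.5)) == []
        assert len(segment_calls("s", ratios, ivs, simple_summary(-0.4, 0.5))) == 1

    def test_chromosome_boundary_breaks_run(self):
        ivs = make_intervals(4, x_from=2)  # chr1,chr1,chrX,chrX
        ratios = np.array([-1.0, -1.0, -1.0, -1.0])
        calls = segment_calls("s", ratios, ivs, simple_summary(-0.3, 0.3))
        assert [(c.chrom, c.first_rank, c.last_rank) for c in calls] == [
            ("chr1", 0, 1), ("chrX", 2, 3),
        ]

    def test_masked_interval_breaks_run(self):
        ivs = make_intervals(3)
        ratios = np.array([-1.0, np.nan, -1.0])
        calls = segment_calls("s", ratios, ivs, simple_summary(-0.3, 0.3))
        assert [(c.first_rank, c.last_rank) for c in calls] == [(0, 0), (2, 2)]

    def test_min_probes_filters_short_runs(self):
        ivs = make_intervals(5)
        ratios = np.array([-1.0, 0.0, -1.0, -1.0, 0.0])
        th = CallingThresholds(min_probes_loss=2)
        calls = segment_calls("s", ratios, ivs, simple_summary(-0.3, 0.3), th)
        assert [(c.first_rank, c.last_rank) for c in calls] == [(2, 3)]

    def test_ids_ordered_by_genome_position(self):
        ivs = make_intervals(6)
        ratios = np.array([0.9, 0.0, -1.0, 0.0, 0.9, 0.0])
        calls = segment_calls("s", ratios, ivs, simple_summary(-0.3, 0.3))
        assert [(c.id, c.first_rank) for c in calls] == [(1, 0), (2, 2), (3, 4)]

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            segment_calls("s", np.zeros(3), make_intervals(4), simple_summary(-1, 1))

    def test_matches_brute_force_enumerator(self):
        rng = np.random.default_rng(1234)
        ivs = make_intervals(50, x_from=40)
        th = CallingThresholds()
        for _ in range(300):
            ratios = rng.normal(0, 0.5, 50)
            ratios[rng.random(50) < 0.05] = np.nan  # masked
            finite = ratios[np.isfinite(ratios)]
            from panelcnv.qc import five_number_summary

            s = five_number_summary(finite, 3.0)
            got = sorted(
                (c.type, c.first_rank, c.last_rank)
                for c in segment_calls("s", ratios, ivs, s, th)
            )
            assert got == brute_force_runs(ratios, ivs, s, th)

    def test_calls_never_overlap_within_sample(self):
        rng = np.random.default_rng(77)
        ivs = make_intervals(50)
        for _ in range(50):
            ratios = rng.normal(0, 0.6, 50)
            from panelcnv.qc import five_number_summary

            s = five_number_summary(ratios, 3.0)
            calls = segment_calls("s", ratios, ivs, s)
            covered = set()
            for c in calls:
                member = set(range(c.first_rank, c.last_rank + 1))
                assert not member & covered
                covered |= member


def _call(sample, first=0, last=0, type_="loss", chrom="chr1"):
    from panelcnv.calling import CNVCall

    return CNVCall(
        id=1, sample=sample, type=type_, chrom=chrom, first_rank=first,
        last_rank=last, start=1, end=2, first_label="a", last_label="b",
        n_intervals=last - first + 1, median_log2=-1.0 if type_ == "loss" else 0.6,
        inferred_cn=1.0,
    )


class TestCohortAnnotate:
    def test_three_of_hundred_is_recurrent(self):
        calls = {f"case{i}": [_call(f"case{i}")] for i in range(3)}
        calls.update({f"neg{i}": [] for i in range(97)})
        out = cohort_annotate(calls, n_cases=100)
        assert all(c.recurrent for c in out)

    def test_one_of_two_hundred_is_not(self):
        out = cohort_annotate({"case0": [_call("case0")]}, n_cases=200)
        assert not out[0].recurrent

    def test_gain_and_loss_are_distinct_unique_calls(self):
        calls = {
            f"case{i}": [_call(f"case{i}", type_="loss")] for i in range(3)
        }
        calls["g1"] = [_call("g1", type_="gain")]
        out = cohort_annotate(calls, n_cases=100)
        by_type = {c.type: c.recurrent for c in out}
        assert by_type == {"loss": True, "gain": False}

    def test_same_case_counted_once(self):
        # two identical calls in one case contribute one distinct case
        calls = {"case0": [_call("case0"), _call("case0")]}
        out = cohort_annotate(calls, n_cases=100)
        assert not any(c.recurrent for c in out)


class TestFlagExtremeGC:
    def test_low_gc_single_interval_flagged(self):
        c = _call("s", 0, 0)
        out = flag_extreme_gc([c], np.array([0.30]))
        assert out[0].gc_flag

    def test_mixed_gc_not_flagged(self):
        c = _call("s", 0, 1)
        out = flag_extreme_gc([c], np.array([0.40, 0.70]))
        assert not out[0].gc_flag

    def test_all_high_gc_flagged(self):
        c = _call("s", 0, 1)
        out = flag_extreme_gc([c], np.array([0.70, 0.80]))
        assert out[0].gc_flag

    def test_missing_gc_vector_leaves_flags_false(self):
        c = _call("s")
        out = flag_extreme_gc([c], None)
        assert not out[0].gc_flag


class TestDdpcr:
    def test_identity_correction(self):
        r = ddpcr_call(2.0, 1.0)
        assert r.normalized_cn == pytest.approx(2.0)
        assert r.verdict == "neutral"
        assert r.qc_ok

    def test_loss_below_threshold(self):
        assert ddpcr_call(1.0, 1.0).verdict == "loss"

    @pytest.mark.parametrize(
        "normalized,verdict",
        [(1.4999, "loss"), (1.5, "neutral"), (2.0, "neutral"),
         (2.5, "neutral"), (2.5001, "gain")],
    )
    def test_strict_boundaries(self, normalized, verdict):
        assert ddpcr_call(normalized, 1.0).verdict == verdict

    @pytest.mark.parametrize(
        "ratio,ok", [(0.85, False), (0.9, True), (1.0, True), (1.2, True), (1.25, False)]
    )
    def test_reference_ratio_qc_window(self, ratio, ok):
        assert ddpcr_call(2.0, ratio).qc_ok is ok

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ConfigError):
            ddpcr_call(2.0, 0.0)

    def test_rcc_scaling(self):
        # ratio 1.1 -> RCC 2.2; raw 2.2 -> 2.2/2.2*2 = 2.0
        assert ddpcr_call(2.2, 1.1).normalized_cn == pytest.approx(2.0)


class TestExclusionList:
    def test_single_exon_call_on_excluded_label_dropped(self):
        single = _call("s", 0, 0)
        single.first_label = "BAD_Exon1"
        multi = _call("s", 1, 3)
        multi.first_label = "BAD_Exon1"
        kept = apply_exclusion_list([single, multi], {"BAD_Exon1"})
        assert kept == [multi]
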
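import numpy as np
import pytest

from twinscan import (
    SubjectRecord,
    ValidationError,
    classify_rated_scan,
    classify_rs_run,
    classify_task_run,
    motion_stratum,
    scan_quality,
    scan_quantity,
    time_window_inclusion,
)
from twinscan.motion_metrics import RunMotionSummary, SubjectMotion
from twinscan.qc_rules import subject_qc


def summary(run_label="snat1", max_abs=0.0, frac03=0.0, frac05=0.0, n=142):
    return RunMotionSummary(
        run_label=run_label, n_volumes=n, mean_fd=0.1,
        mean_ad_x=0.1, mean_ad_y=0.1, mean_ad_z=0.1, mean_ad=0.1,
        max_abs_per_axis=max_abs,
        frac_flagged_03=frac03, frac_flagged_05=frac05,
    )


def record(completed=None, rating_t1=None, rating_dti=None, **kw):
    return SubjectRecord(
        subject_id=kw.get("subject_id", "P1T1"), pair_id="P1", birth_order=1,
        zygosity="MZ", completed=completed or {},
        rating_t1=rating_t1, rating_dti=rating_dti,
    )


ALL_RUNS = ("snat1", "snat2", "snat3", "pcg1", "pcg2", "t1", "dti1", "dti2", "rs")


def full_record(**kw):
    return record(completed={r: True for r in ALL_RUNS},
                  rating_t1=kw.pop("rating_t1", "Excellent"),
                  rating_dti=kw.pop("rating_dti", "Excellent"))


def clean_summaries(rs_frac03=0.0, rs_frac05=0.0, task_max=0.0):
    sums = {lab: summary(lab, max_abs=task_max) for lab in ALL_RUNS[:5]}
    sums["rs"] = summary("rs", frac03=rs_frac03, frac05=rs_frac05)
    return sums


class TestTaskRule:
    def test_zero_motion_included(self, thresholds):
        assert classify_task_run(summary(max_abs=0.0), thresholds)

    def test_boundary_strict_at_3mm(self, thresholds):
        assert classify_task_run(summary(max_abs=2.9), thresholds)
        assert not classify_task_run(summary(max_abs=3.0), thresholds)


class TestRestingStateRule:
    def test_zero_motion_included_everywhere(self, thresholds):
        s = summary("rs")
        for mode in ("stringent", "lenient", "ad3"):
            assert classify_rs_run(s, mode, thresholds)

    def test_twenty_percent_boundary(self, thresholds):
        # 142-volume run: 141 FD frames; 28 flagged ~ 19.9% in, 29 ~ 20.6% out
        assert classify_rs_run(summary("rs", frac03=28 / 141), "stringent", thresholds)
        assert not classify_rs_run(summary("rs", frac03=29 / 141), "stringent", thresholds)

    def test_stringent_implies_lenient(self, rng, thresholds):
        for _ in range(50):
            f05 = rng.uniform(0, 0.4)
            f03 = f05 + rng.uniform(0, 0.3)
            s = summary("rs", frac03=min(f03, 1), frac05=f05)
            if classify_rs_run(s, "stringent", thresholds):
                assert classify_rs_run(s, "lenient", thresholds)

    def test_unknown_stringency(self, thresholds):
        with pytest.raises(ValidationError):
            classify_rs_run(summary("rs"), "nope", thresholds)


class TestRatedScans:
    @pytest.mark.parametrize(
        "rating,stringency,included",
        [
            ("Excellent", "stringent", True),
            ("Good", "stringent", True),
            ("Doubtful", "stringent", False),
            ("Doubtful", "lenient", True),
            ("Failed", "stringent", False),
            ("Failed", "lenient", False),
        ],
    )
    def test_rule_table(self, rating, stringency, included):
        assert classify_rated_scan(rating, stringency) is included

    def test_unknown_rating(self):
        with pytest.raises(ValidationError):
            classify_rated_scan("Superb", "stringent")


class TestScanQuantity:
    def test_full_protocol(self, protocol):
        assert scan_quantity(full_record(), protocol) == 9

    def test_never_started(self, protocol):
        assert scan_quantity(record(), protocol) == 0

    def test_partial_enumeration(self, protocol):
        done = {r: True for r in ("snat1", "snat2", "snat3", "pcg1", "pcg2", "t1")}
        assert scan_quantity(record(completed=done), protocol) == 6

    def test_unknown_flag_rejected(self, protocol):
        with pytest.raises(ValidationError):
            scan_quantity(record(completed={"bogus": True}), protocol)


class TestScanQuality:
    def test_all_clean(self, protocol, thresholds):
        n, frac = scan_quality(full_record(), protocol, thresholds, clean_summaries())
        assert (n, frac) == (8, 1.0)

    def test_rs_excluded_only(self, protocol, thresholds):
        n, frac = scan_quality(
            full_record(), protocol, thresholds, clean_summaries(rs_frac03=0.5)
        )
        assert n == 7 and frac == pytest.approx(7 / 8)

    def test_partial_completion_full_quality(self, protocol, thresholds):
        done = {r: True for r in ("snat1", "snat2", "snat3", "pcg1")}
        rec = record(completed=done)
        sums = {lab: summary(lab) for lab in done}
        n, frac = scan_quality(rec, protocol, thresholds, sums)
        assert (n, frac) == (4, 1.0)

    def test_never_started_has_undefined_fraction(self, protocol, thresholds):
        n, frac = scan_quality(record(), protocol, thresholds, {})
        assert n == 0 and frac is None


class TestMotionStratum:
    @pytest.mark.parametrize(
        "fd,ad,expected",
        [
            (0.1, 0.5, "minimal"),
            (0.5, 2.0, "moderate"),
            (2.0, 10.0, "excessive"),
            (0.1, 2.0, "moderate"),  # minimal FD but moderate AD
            (0.3, 0.5, "moderate"),  # boundary is strict
        ],
    )
    def test_rule(self, thresholds, fd, ad, expected):
        subj = SubjectMotion("s", fd, ad, [])
        assert motion_stratum(subj, thresholds) == expected


class TestTimeWindows:
    def test_clean_session_all_windows(self, protocol, thresholds):
        rec, sums = full_record(), clean_summaries()
        for w in (30, 45, 60):
            assert time_window_inclusion(rec, protocol, thresholds, sums, w)

    def test_rs_failure_hits_only_60(self, protocol, thresholds):
        rec, sums = full_record(), clean_summaries(rs_frac03=0.5)
        assert time_window_inclusion(rec, protocol, thresholds, sums, 30)
        assert time_window_inclusion(rec, protocol, thresholds, sums, 45)
        assert not time_window_inclusion(rec, protocol, thresholds, sums, 60)

    def test_windows_nest(self, rng, protocol, thresholds):
        for _ in range(30):
            rec = full_record()
            sums = clean_summaries(
                rs_frac03=rng.uniform(0, 0.4), task_max=rng.uniform(0, 4)
            )
            if rng.random() < 0.3:
                rec.rating_t1 = "Failed"
            w = {m: time_window_inclusion(rec, protocol, thresholds, sums, m)
                 for m in (30, 45, 60)}
            assert w[60] <= w[45] <= w[30]

    def test_unsupported_window(self, protocol, thresholds):
        with pytest.raises(ValidationError):
            time_window_inclusion(full_record(), protocol, thresholds,
                                  clean_summaries(), 90)


class TestInclusionMonotonicity:
    def test_inflating_motion_never_adds_inclusions(self, rng, protocol, thresholds):
        """Pointwise-larger motion can only shrink every inclusion count."""
        for _ in range(20):
            base_max = rng.uniform(0, 4)
            frac03 = rng.uniform(0, 0.4)
            lam = rng.uniform(1.0, 3.0)
            sums_lo = clean_summaries(rs_frac03=frac03, task_max=base_max)
            sums_hi = clean_summaries(
                rs_frac03=min(1.0, frac03 * lam), task_max=base_max * lam
            )
            rec = full_record()
            n_lo, _ = scan_quality(rec, protocol, thresholds, sums_lo)
            n_hi, _ = scan_quality(rec, protocol, thresholds, sums_hi)
            assert n_hi <= n_lo

    def test_stringent_subset_of_lenient_ratings(self, protocol, thresholds):
        for rating_t1 in ("Excellent", "Good", "Doubtful", "Failed"):
            rec = full_record()
            rec.rating_t1 = rating_t1
            sums = clean_summaries()
            n_s, _ = scan_quality(rec, protocol, thresholds, sums, stringency="stringent")
            n_l, _ = scan_quality(rec, protocol, thresholds, sums, stringency="lenient")
            assert n_s <= n_l


def test_subject_qc_assembles_all_fields(protocol, thresholds):
    rec, sums = full_record(), clean_summaries()
    motion = SubjectMotion("P1T1", 0.2, 0.8, [])
    qc = subject_qc(rec, protocol, thresholds, sums, motion)
    assert qc.n_completed == 9 and qc.n_included == 8
    assert qc.included_fraction == 1.0
    assert qc.stratum == "minimal"
    assert qc.window_included == {30: True, 45: True, 60: True}
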
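"""Inclusion rules: motion thresholds, ratings, quantity/quality phenotypes.

Every threshold is applied as a strict inequality, exactly as stated in
the QC protocol: task-fMRI runs pass when maximum per-axis displacement
is < 3 mm; resting-state runs pass when the fraction of FD frames above
0.3 mm (stringent) or 0.5 mm (lenient) is < 20%; manually rated scans
pass when rated Excellent/Good (stringent) or Excellent/Good/Doubtful
(lenient).  Subject-level motion strata nest: minimal (mean FD < 0.3 mm
and mean AD < 1 mm) within moderate (mean FD < 1 mm and mean AD < 3 mm)
within all subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import InsufficientDataError, ValidationError
from .io_formats import RATING_LEVELS, ProtocolSpec, SubjectRecord
from .motion_metrics import RunMotionSummary, SubjectMotion

WINDOWS_MINUTES = (30, 45, 60)


@dataclass(frozen=True)
class QCThresholds:
    """All motion-QC cutoffs, in mm (fractions where noted)."""

    task_max_ad: float = 3.0
    rs_fd_stringent: float = 0.3
    rs_fd_lenient: float = 0.5
    rs_max_flagged_fraction: float = 0.20
    moderate_mean_fd: float = 1.0
    moderate_mean_ad: float = 3.0
    minimal_mean_fd: float = 0.3
    minimal_mean_ad: float = 1.0

    def __post_init__(self) -> None:
        vals = (
            self.task_max_ad,
            self.rs_fd_stringent,
            self.rs_fd_lenient,
            self.rs_max_flagged_fraction,
            self.moderate_mean_fd,
            self.moderate_mean_ad,
            self.minimal_mean_fd,
            self.minimal_mean_ad,
        )
        if any(v <= 0 for v in vals):
            raise ValidationError("all thresholds must be positive")
        if not (
            self.minimal_mean_fd < self.moderate_mean_fd
            and self.minimal_mean_ad < self.moderate_mean_ad
        ):
            raise ValidationError("minimal bounds must lie below moderate bounds")
        if not self.rs_fd_stringent < self.rs_fd_lenient:
            raise ValidationError("stringent FD cutoff must be below lenient")


@dataclass
class SubjectQC:
    """Per-subject quantity/quality phenotypes and stratum."""

    subject_id: str
    n_completed: int
    n_included: int
    included_fraction: float | None
    stratum: str  # excessive | moderate | minimal | none
    window_included: dict[int, bool]


def classify_task_run(summary: RunMotionSummary, thresholds: QCThresholds) -> bool:
    """Task-fMRI inclusion: maximum per-axis displacement strictly < 3 mm."""
    return summary.max_abs_per_axis < thresholds.task_max_ad


def classify_rs_run(
    summary: RunMotionSummary,
    stringency: str = "stringent",
    thresholds: QCThresholds = QCThresholds(),
) -> bool:
    """Resting-state inclusion by flagged-frame fraction (or the task rule).

    ``stringent`` uses the 0.3 mm flags, ``lenient`` the 0.5 mm flags,
    both against the < 20% cap; ``ad3`` applies the task-run 3 mm rule.
    """
    if stringency == "stringent":
        return summary.frac_flagged_03 < thresholds.rs_max_flagged_fraction
    if stringency == "lenient":
        return summary.frac_flagged_05 < thresholds.rs_max_flagged_fraction
    if stringency == "ad3":
        return classify_task_run(summary, thresholds)
    raise ValidationError(f"unknown RS stringency: {stringency!r}")


def classify_rated_scan(rating: str, stringency: str = "stringent") -> bool:
    """Manual 4-level rating to include/exclude. Failed never passes."""
    if rating not in RATING_LEVELS:
        raise ValidationError(f"unknown rating label: {rating!r}")
    if stringency == "stringent":
        return rating in ("Excellent", "Good")
    if stringency == "lenient":
        return rating in ("Excellent", "Good", "Doubtful")
    raise ValidationError(f"unknown stringency: {stringency!r}")


def scan_quantity(record: SubjectRecord, protocol: ProtocolSpec) -> int:
    """Number of completed protocol runs (0-9); never-scanned scores 0."""
    unknown = set(record.completed) - set(protocol.run_labels)
    if unknown:
        raise ValidationError(f"completion flags for unknown runs: {sorted(unknown)}")
    return sum(bool(record.completed.get(lab, False)) for lab in protocol.run_labels)


def _unit_completed(
    record: SubjectRecord, member_runs: tuple[str, ...]
) -> bool:
    return all(record.completed.get(lab, False) for lab in member_runs)


def _unit_included(
    unit_label: str,
    member_runs: tuple[str, ...],
    record: SubjectRecord,
    protocol: ProtocolSpec,
    thresholds: QCThresholds,
    summaries: Mapping[str, RunMotionSummary],
    stringency: str,
    rs_rule: str,
) -> bool:
    """Inclusion decision for one completed quality unit."""
    modality = {r.run_label: r.modality for r in protocol.runs}
    first = member_runs[0]
    if modality.get(unit_label) == "task_fmri":
        if unit_label not in summaries:
            return False
        return classify_task_run(summaries[unit_label], thresholds)
    if modality.get(unit_label) == "rs_fmri":
        if unit_label not in summaries:
            return False
        stringency_map = {"fd03": "stringent", "fd05": "lenient", "ad3": "ad3"}
        if rs_rule not in stringency_map:
            raise ValidationError(f"unknown rs_rule: {rs_rule!r}")
        return classify_rs_run(summaries[unit_label], stringency_map[rs_rule], thresholds)
    if modality.get(first) == "t1" or unit_label == "t1":
        return record.rating_t1 is not None and classify_rated_scan(
            record.rating_t1, stringency
        )
    if unit_label == "dti":
        return record.rating_dti is not None and classify_rated_scan(
            record.rating_dti, stringency
        )
    raise ValidationError(f"cannot classify quality unit {unit_label!r}")


def scan_quality(
    record: SubjectRecord,
    protocol: ProtocolSpec,
    thresholds: QCThresholds,
    summaries: Mapping[str, RunMotionSummary],
    stringency: str = "stringent",
    rs_rule: str = "fd03",
) -> tuple[int, float | None]:
    """(number of included quality units 0-8, included fraction).

    The denominator of the fraction is the number of *completed* quality
    units; incomplete units enter neither numerator nor denominator.  The
    fraction is ``None`` for a subject with no completed unit.
    """
    n_included = 0
    n_eligible = 0
    for unit_label, members in protocol.quality_units():
        if not _unit_completed(record, members):
            continue
        n_eligible += 1
        if _unit_included(
            unit_label, members, record, protocol, thresholds, summaries,
            stringency, rs_rule,
        ):
            n_included += 1
    fraction = n_included / n_eligible if n_eligible else None
    return n_included, fraction


def motion_stratum(subject: SubjectMotion, thresholds: QCThresholds) -> str:
    """Nested motion stratum from subject mean FD / mean AD (strict cuts)."""
    fd, ad = subject.mean_fd_over_runs, subject.mean_ad_over_runs
    if fd < thresholds.minimal_mean_fd and ad < thresholds.minimal_mean_ad:
        return "minimal"
    if fd < thresholds.moderate_mean_fd and ad < thresholds.moderate_mean_ad:
        return "moderate"
    return "excessive"


def _window_units(
    protocol: ProtocolSpec, window_minutes: int
) -> tuple[tuple[str, tuple[str, ...]], ...]:
    units = protocol.quality_units()
    task_units = tuple(u for u in units if u[0] in protocol.task_run_labels)
    if window_minutes == 30:
        return task_units[:4]
    if window_minutes == 45:
        t1_units = tuple(
            u for u in units
            if {r.run_label: r.modality for r in protocol.runs}.get(u[0]) == "t1"
        )
        return task_units + t1_units
    if window_minutes == 60:
        return units
    raise ValidationError(f"unsupported window: {window_minutes} minutes")


def time_window_inclusion(
    record: SubjectRecord,
    protocol: ProtocolSpec,
    thresholds: QCThresholds,
    summaries: Mapping[str, RunMotionSummary],
    window_minutes: int,
    stringency: str = "stringent",
    rs_rule: str = "fd03",
) -> bool:
    """True iff every quality unit inside the time window is included.

    The 30-minute window holds the first four task runs; 45 minutes adds
    the fifth task run and the anatomical scan; 60 minutes is the full
    8-unit session.  A unit that was not completed fails its window.
    """
    for unit_label, members in _window_units(protocol, window_minutes):
        if not _unit_completed(record, members):
            return False
        if not _unit_included(
            unit_label, members, record, protocol, thresholds, summaries,
            stringency, rs_rule,
        ):
            return False
    return True


def subject_qc(
    record: SubjectRecord,
    protocol: ProtocolSpec,
    thresholds: QCThresholds,
    summaries: Mapping[str, RunMotionSummary],
    subject_motion: SubjectMotion | None = None,
    stringency: str = "stringent",
    rs_rule: str = "fd03",
) -> SubjectQC:
    """Assemble the full per-subject QC record."""
    n_completed = scan_quantity(record, protocol)
    n_included, fraction = scan_quality(
        record, protocol, thresholds, summaries, stringency, rs_rule
    )
    stratum = (
        motion_stratum(subject_motion, thresholds) if subject_motion else "none"
    )
    windows = {
        w: time_window_inclusion(
            record, protocol, thresholds, summaries, w, stringency, rs_rule
        )
        for w in WINDOWS_MINUTES
    }
    return SubjectQC(
        subject_id=record.subject_id,
        n_completed=n_completed,
        n_included=n_included,
        included_fraction=fraction,
        stratum=stratum,
        window_included=windows,
    )
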
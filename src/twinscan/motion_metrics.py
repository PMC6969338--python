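"""Head-motion metrics from rigid-body motion parameters.

Two displacement summaries are computed per run:

* framewise displacement (FD): for each consecutive volume pair, the sum
  of absolute translation changes plus the absolute rotation changes
  converted to mm on a 50 mm sphere (small-angle arc length).  The run
  series has length N-1; the run mean is over those N-1 values.
* absolute displacement (AD): per volume and axis, the absolute
  difference between that volume's translation and the translation of a
  reference volume (default: the middle volume, index floor(N/2)).
  Rotations deliberately do not enter AD, which is reported per axis in
  mm.

Volumes whose FD exceeds a threshold are flagged as outliers (strict
inequality); the flagged fraction is taken over the N-1 FD frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, InsufficientDataError, ValidationError
from .io_formats import MotionTrace

DEFAULT_HEAD_RADIUS_MM = 50.0
STRINGENT_FD_MM = 0.3
LENIENT_FD_MM = 0.5


@dataclass
class RunMotionSummary:
    """FD/AD summaries and outlier fractions for one run."""

    run_label: str
    n_volumes: int
    mean_fd: float
    mean_ad_x: float
    mean_ad_y: float
    mean_ad_z: float
    mean_ad: float
    max_abs_per_axis: float
    frac_flagged_03: float
    frac_flagged_05: float


@dataclass
class SubjectMotion:
    """Unweighted subject means over the available fMRI runs."""

    subject_id: str
    mean_fd_over_runs: float
    mean_ad_over_runs: float
    per_run: list[RunMotionSummary] = field(default_factory=list)


def framewise_displacement(
    trace: MotionTrace, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Per-frame FD series (length n_volumes - 1) in mm.

    FD_t = sum_axes |dtranslation| + head_radius * sum_axes |drotation|.
    """
    if trace.n_volumes < 2:
        raise InsufficientDataError("FD needs at least 2 volumes")
    dtrans = np.diff(trace.translations, axis=0)
    drot = np.diff(trace.rotations, axis=0)
    return np.abs(dtrans).sum(axis=1) + head_radius * np.abs(drot).sum(axis=1)


def absolute_displacement(
    trace: MotionTrace, ref_index: int | None = None
) -> np.ndarray:
    """Per-axis absolute displacement (n_volumes, 3) in mm.

    The reference defaults to the middle volume, floor(N/2) 0-based.
    """
    if ref_index is None:
        ref_index = trace.n_volumes // 2
    if not 0 <= ref_index < trace.n_volumes:
        raise IndexError(f"ref_index {ref_index} out of range")
    return np.abs(trace.translations - trace.translations[ref_index])


def flag_outliers(
    fd_series: np.ndarray, threshold: float
) -> tuple[np.ndarray, float]:
    """Flag FD frames strictly above ``threshold``; return (flags, fraction)."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    fd_series = np.asarray(fd_series, dtype=float)
    if fd_series.size == 0:
        raise InsufficientDataError("empty FD series")
    flags = fd_series > threshold
    return flags, float(flags.mean())


def summarize_run(
    trace: MotionTrace,
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
    ref_index: int | None = None,
) -> RunMotionSummary:
    fd = framewise_displacement(trace, head_radius=head_radius)
    ad = absolute_displacement(trace, ref_index=ref_index)
    ax_means = ad.mean(axis=0)
    _, frac03 = flag_outliers(fd, STRINGENT_FD_MM)
    _, frac05 = flag_outliers(fd, LENIENT_FD_MM)
    return RunMotionSummary(
        run_label=trace.run_label,
        n_volumes=trace.n_volumes,
        mean_fd=float(fd.mean()),
        mean_ad_x=float(ax_means[0]),
        mean_ad_y=float(ax_means[1]),
        mean_ad_z=float(ax_means[2]),
        mean_ad=float(ax_means.mean()),
        max_abs_per_axis=float(ad.max()),
        frac_flagged_03=frac03,
        frac_flagged_05=frac05,
    )


def subject_mean_motion(
    subject_id: str, summaries: list[RunMotionSummary]
) -> SubjectMotion:
    """Unweighted means of run-level mean FD / mean AD over available runs.

    Only runs with a summary enter; absent runs are excluded, never
    imputed as zero.
    """
    if not summaries:
        raise InsufficientDataError("no fMRI run summaries for subject")
    return SubjectMotion(
        subject_id=subject_id,
        mean_fd_over_runs=float(np.mean([s.mean_fd for s in summaries])),
        mean_ad_over_runs=float(np.mean([s.mean_ad for s in summaries])),
        per_run=list(summaries),
    )


def cronbach_alpha(values: np.ndarray) -> float:
    """Cronbach's alpha for a runs x subjects table (runs are the items).

    Subjects (columns) with any missing value are dropped (listwise).
    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with sample (ddof=1) variances.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("values must be a 2-D runs x subjects table")
    complete = ~np.isnan(values).any(axis=0)
    values = values[:, complete]
    k, n = values.shape
    if k < 2:
        raise InsufficientDataError("alpha needs at least 2 runs (items)")
    if n < 3:
        raise InsufficientDataError("alpha needs at least 3 complete subjects")
    total_var = values.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("zero total variance: alpha undefined")
    item_var = values.var(axis=1, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
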
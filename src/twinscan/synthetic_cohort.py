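"""Synthetic twin-cohort generator.

Generates cohorts with the statistical structure the analysis pipeline
assumes, so every stage can be exercised end to end without any real
data: 256 same-sex twin pairs aged 7-9 with 55% monozygotic, a fixed
9-run scan protocol, twin-correlated head-motion propensity with
configurable A/C/E shares, per-run rigid-body motion traces, 4-level
structural ratings, 3-moment x 3-rater scanner-distress ratings, and
distress-modulated run attrition.

Motion propensity acts on the log scale: a subject's trace amplitudes
are all multiplied by exp(propensity), where propensity is drawn from
the ACE bivariate-normal pair model.  Motion is therefore non-negative
and right-skewed, as observed run summaries are; heritability on the
observed (mm) scale is attenuated relative to the generating shares on
the log scale.  Each trace is smooth autocorrelated jitter plus a slow
drift plus a Poisson spike process, and amplitudes grow linearly with
run position to emulate children tiring over the session.

All randomness flows from a single root seed through named substreams
(demographics, propensity, distress, attrition, ratings, traces), so
the stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats
from scipy.signal import lfilter

from .ace_model import PHI_DZ, PHI_MZ, TwinPairTable
from .errors import ValidationError
from .io_formats import (
    Cohort,
    MotionTrace,
    ProtocolSpec,
    RunSpec,
    SubjectRecord,
    default_protocol,
    distress_column,
    write_cohort_table,
    write_motion_par,
)

_HALF_NORMAL_MEAN = float(np.sqrt(2.0 / np.pi))  # E|N(0,1)|


@dataclass(frozen=True)
class MotionModel:
    """Generating model for the latent motion propensity and traces."""

    a2: float = 0.65
    c2: float = 0.0
    e2: float = 0.35
    propensity_sd: float = 1.0
    baseline_fd: float = 0.3  # expected run-mean FD (mm) at propensity 0, run 1
    drift_rate: float = 0.01  # mm per volume, slow z drift
    spike_rate: float = 0.01  # spike probability per frame
    spike_magnitude: float = 1.0  # mm per spike
    run_slope: float = 0.1  # amplitude multiplier per protocol position
    ar_coef: float = 0.8  # AR(1) coefficient of jitter increments
    run_scale_jitter_sd: float = 0.6  # log-sd of per-run amplitude jitter


@dataclass(frozen=True)
class DistressModel:
    """Generating model for tension/excitement ratings (1-6 smiley VAS)."""

    tension_means: tuple[float, float, float] = (3.84, 3.28, 2.62)
    excitement_means: tuple[float, float, float] = (4.72, 5.10, 4.95)
    sd: float = 1.2
    pair_share: float = 0.3  # shared-environment share of the distress trait
    trait_loading: float = 0.7  # corr(trait, single-moment score)
    tension_excitement_corr: float = -0.34
    rater_corr: float = 0.75
    bounds: tuple[float, float] = (1.0, 6.0)


@dataclass(frozen=True)
class AttritionModel:
    """Run-completion model: monotone dropout with a post-anatomy jump."""

    never_start_prob: float = 0.047
    base_hazard: float = 0.005  # per run, up to and including the T1
    post_t1_hazard: float = 0.03  # per run, after the T1
    tension_effect: float = 0.5  # log hazard ratio per SD of pre-MRI tension


@dataclass(frozen=True)
class RatingModel:
    """Marginal rating distributions and their link to motion propensity."""

    t1_probs: tuple[float, float, float, float] = (0.31, 0.43, 0.16, 0.10)
    dti_probs: tuple[float, float, float, float] = (0.86, 0.08, 0.04, 0.02)
    motion_corr: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    n_pairs: int = 256
    prop_mz: float = 0.55
    boy_fraction: float = 0.49
    age_range: tuple[float, float] = (7.0, 9.0)
    protocol: ProtocolSpec = field(default_factory=default_protocol)
    motion: MotionModel = field(default_factory=MotionModel)
    distress: DistressModel = field(default_factory=DistressModel)
    attrition: AttritionModel = field(default_factory=AttritionModel)
    ratings: RatingModel = field(default_factory=RatingModel)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_mz <= 1.0:
            raise ValidationError("prop_mz must be in [0, 1]")
        shares = (self.motion.a2, self.motion.c2, self.motion.e2)
        if any(s < 0 for s in shares) or abs(sum(shares) - 1.0) > 1e-9:
            raise ValidationError("motion a2/c2/e2 must be >= 0 and sum to 1")
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be positive")

    @property
    def n_mz_pairs(self) -> int:
        """Round-half-up count of MZ pairs."""
        return int(np.floor(self.n_pairs * self.prop_mz + 0.5))

    @property
    def n_dz_pairs(self) -> int:
        return self.n_pairs - self.n_mz_pairs


@dataclass
class SyntheticCohort:
    """A generated cohort: records, traces, and the latent propensities."""

    cohort: Cohort
    traces: dict[tuple[str, str], MotionTrace]
    propensities: dict[str, float]
    config: CohortConfig
    seed: int


# -- twin phenotypes --------------------------------------------------------


def _draw_pairs(
    rng: np.random.Generator,
    n: int,
    phi: float,
    a2: float,
    c2: float,
    e2: float,
    mu: float,
    total_var: float,
) -> np.ndarray:
    """Draw n twin pairs under the ACE covariance with genetic corr phi."""
    a1 = rng.standard_normal(n)
    a2_ = phi * a1 + np.sqrt(1.0 - phi * phi) * rng.standard_normal(n)
    c = rng.standard_normal(n)
    e1, e2_ = rng.standard_normal(n), rng.standard_normal(n)
    sd = np.sqrt(total_var)
    x = mu + sd * (np.sqrt(a2) * a1 + np.sqrt(c2) * c + np.sqrt(e2) * e1)
    y = mu + sd * (np.sqrt(a2) * a2_ + np.sqrt(c2) * c + np.sqrt(e2) * e2_)
    return np.column_stack([x, y])


def generate_twin_phenotypes(
    n_mz: int,
    n_dz: int,
    a2: float,
    c2: float,
    e2: float,
    mu: float = 0.0,
    total_var: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> TwinPairTable:
    """Draw a TwinPairTable from the bivariate-normal ACE pair model."""
    if min(a2, c2, e2) < 0 or abs(a2 + c2 + e2 - 1.0) > 1e-9:
        raise ValidationError("shares must be non-negative and sum to 1")
    if total_var <= 0:
        raise ValidationError("total_var must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mz = _draw_pairs(rng, n_mz, PHI_MZ, a2, c2, e2, mu, total_var)
    dz = _draw_pairs(rng, n_dz, PHI_DZ, a2, c2, e2, mu, total_var)
    return TwinPairTable(mz=mz, dz=dz)


# -- motion traces ----------------------------------------------------------


def generate_run_trace(
    rng: np.random.Generator,
    run: RunSpec,
    scale: float,
    motion: MotionModel,
    subject_id: str = "",
    tr_seconds: float = 2.2,
    head_radius: float = 50.0,
) -> MotionTrace:
    """One run's motion trace at a given amplitude scale.

    Increments are AR(1) jitter (translations in mm, rotations scaled
    down by the head radius so both contribute equally to FD), plus a
    constant z drift and occasional large spikes.  Every term is
    proportional to ``scale``, so expected FD and AD are linear in it and
    a zero scale yields an all-zero trace.
    """
    n_inc = run.nominal_volumes - 1
    sigma_t = motion.baseline_fd / (6.0 * _HALF_NORMAL_MEAN) * scale
    innov = rng.standard_normal((n_inc, 6))
    ar = motion.ar_coef
    incs = lfilter([np.sqrt(1.0 - ar * ar)], [1.0, -ar], innov, axis=0)
    incs[:, :3] *= sigma_t
    incs[:, 3:] *= sigma_t / head_radius
    incs[:, 2] += motion.drift_rate * scale
    spikes = rng.random(n_inc) < motion.spike_rate
    k = int(spikes.sum())
    if k:
        axes = rng.integers(0, 3, size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        incs[np.flatnonzero(spikes), axes] += signs * motion.spike_magnitude * scale
    path = np.vstack([np.zeros((1, 6)), np.cumsum(incs, axis=0)])
    return MotionTrace(
        subject_id=subject_id,
        run_label=run.run_label,
        translations=path[:, :3],
        rotations=path[:, 3:],
        tr_seconds=tr_seconds,
    )


def generate_motion_traces(
    records: list[SubjectRecord],
    propensities: dict[str, float],
    config: CohortConfig,
    seed: int | np.random.Generator,
) -> dict[tuple[str, str], MotionTrace]:
    """Traces for every completed fMRI run, keyed (subject_id, run_label)."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    motion = config.motion
    fmri = set(config.protocol.fmri_run_labels)
    traces: dict[tuple[str, str], MotionTrace] = {}
    for rec in records:
        base = np.exp(propensities[rec.subject_id])
        for pos, run in enumerate(config.protocol.runs):
            if run.run_label not in fmri or not rec.completed.get(run.run_label):
                continue
            jitter = np.exp(motion.run_scale_jitter_sd * rng.standard_normal())
            scale = base * (1.0 + motion.run_slope * pos) * jitter
            traces[(rec.subject_id, run.run_label)] = generate_run_trace(
                rng, run, scale, motion,
                subject_id=rec.subject_id,
                tr_seconds=config.protocol.tr_seconds,
            )
    return traces


# -- distress and attrition -------------------------------------------------


def _correlated_pair_traits(
    rng: np.random.Generator, n_pairs: int, pair_share: float, cross_corr: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two traits per subject (2 per pair), pair-shared share and cross-corr.

    Returns (trait_a, trait_b), each of shape (n_pairs, 2), standardized,
    with corr(a, b) = cross_corr within subject and corr across co-twins
    equal to pair_share for each trait.
    """
    def bivar(size):
        z1 = rng.standard_normal(size)
        z2 = cross_corr * z1 + np.sqrt(1.0 - cross_corr**2) * rng.standard_normal(size)
        return z1, z2

    sa, sb = bivar(n_pairs)  # pair-shared components
    ia, ib = bivar((n_pairs, 2))  # individual components
    w_s, w_i = np.sqrt(pair_share), np.sqrt(1.0 - pair_share)
    trait_a = w_s * sa[:, None] + w_i * ia
    trait_b = w_s * sb[:, None] + w_i * ib
    return trait_a, trait_b


def generate_distress_and_attrition(
    records: list[SubjectRecord],
    config: CohortConfig,
    seed: int | np.random.Generator,
    attrition_seed: int | np.random.Generator | None = None,
) -> None:
    """Fill distress ratings and run-completion flags in place.

    Tension falls and excitement rises across the three moments in
    expectation; rater scores are noisy copies of the child score (no
    parent rating after the scan); per-run completion is a monotone
    dropout process whose hazard jumps after the anatomical scan and
    rises with pre-MRI tension.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rng_att = attrition_seed
    if rng_att is None:
        rng_att = rng
    elif not isinstance(rng_att, np.random.Generator):
        rng_att = np.random.default_rng(rng_att)

    dm, am = config.distress, config.attrition
    n_pairs = len({r.pair_id for r in records})
    pair_index = {pid: i for i, pid in enumerate(sorted({r.pair_id for r in records}))}
    tension_tr, excite_tr = _correlated_pair_traits(
        rng, n_pairs, dm.pair_share, dm.tension_excitement_corr
    )
    lo, hi = dm.bounds
    lam = dm.trait_loading
    timepoints = ("pre_sim", "pre_mri", "post_mri")

    z_tension_pre_mri: dict[str, float] = {}
    for rec in records:
        i = pair_index[rec.pair_id]
        j = rec.birth_order - 1
        for scale_name, trait, means in (
            ("tension", tension_tr[i, j], dm.tension_means),
            ("excitement", excite_tr[i, j], dm.excitement_means),
        ):
            for tp, mean in zip(timepoints, means):
                z_child = lam * trait + np.sqrt(1.0 - lam * lam) * rng.standard_normal()
                child = float(np.clip(mean + dm.sd * z_child, lo, hi))
                rec.distress[distress_column(scale_name, "child", tp)] = child
                for rater in ("researcher", "parent"):
                    if rater == "parent" and tp == "post_mri":
                        continue
                    z_r = dm.rater_corr * z_child + np.sqrt(
                        1.0 - dm.rater_corr**2
                    ) * rng.standard_normal()
                    rec.distress[distress_column(scale_name, rater, tp)] = float(
                        np.clip(mean + dm.sd * z_r, lo, hi)
                    )
                if scale_name == "tension" and tp == "pre_mri":
                    z_tension_pre_mri[rec.subject_id] = z_child

    t1_pos = next(
        i for i, r in enumerate(config.protocol.runs) if r.modality == "t1"
    )
    for rec in records:
        z = z_tension_pre_mri[rec.subject_id]
        modifier = float(np.exp(am.tension_effect * z))
        never = rng_att.random() < min(1.0, am.never_start_prob * modifier)
        alive = not never
        for pos, run in enumerate(config.protocol.runs):
            if not alive:
                rec.completed[run.run_label] = False
                continue
            base = am.base_hazard if pos <= t1_pos else am.post_t1_hazard
            if rng_att.random() < min(1.0, base * modifier):
                alive = False
                rec.completed[run.run_label] = False
            else:
                rec.completed[run.run_label] = True


def _assign_ratings(
    records: list[SubjectRecord],
    propensities: dict[str, float],
    config: CohortConfig,
    rng: np.random.Generator,
) -> None:
    """Draw 4-level ratings linked to motion propensity via a latent probit."""
    rm = config.ratings
    sd = config.motion.propensity_sd
    from .io_formats import RATING_LEVELS

    def draw(probs: tuple[float, ...], z_prop: float) -> str:
        cuts = stats.norm.ppf(np.cumsum(probs[:-1]))
        latent = rm.motion_corr * z_prop + np.sqrt(
            1.0 - rm.motion_corr**2
        ) * rng.standard_normal()
        return RATING_LEVELS[int(np.searchsorted(cuts, latent))]

    dti_runs = tuple(r.run_label for r in config.protocol.runs if r.modality == "dti")
    for rec in records:
        z = propensities[rec.subject_id] / sd if sd > 0 else 0.0
        if rec.completed.get("t1"):
            rec.rating_t1 = draw(rm.t1_probs, z)
        if dti_runs and all(rec.completed.get(lab) for lab in dti_runs):
            rec.rating_dti = draw(rm.dti_probs, z)


# -- whole-cohort generation ------------------------------------------------


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort; optionally write it to disk.

    When ``out_dir`` is given, emits ``cohort.tsv``, one ``.par`` motion
    file per completed fMRI run under ``par/``, and a ``config.yaml``
    echo — exactly the formats the readers in :mod:`twinscan.io_formats`
    consume.  Deterministic given (config, seed).
    """
    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("demographics", "propensity", "distress", "attrition", "ratings", "traces"),
            ss.spawn(6),
        )
    }

    n_mz, n_dz = config.n_mz_pairs, config.n_dz_pairs
    rng_demo = streams["demographics"]
    records: list[SubjectRecord] = []
    for i in range(config.n_pairs):
        pid = f"P{i + 1:04d}"
        zyg = "MZ" if i < n_mz else "DZ"
        age = float(rng_demo.uniform(*config.age_range))
        sex = "M" if rng_demo.random() < config.boy_fraction else "F"
        for order in (1, 2):
            records.append(
                SubjectRecord(
                    subject_id=f"{pid}T{order}",
                    pair_id=pid,
                    birth_order=order,
                    zygosity=zyg,
                    age=age,
                    sex=sex,
                )
            )

    m = config.motion
    prop_pairs = generate_twin_phenotypes(
        n_mz, n_dz, m.a2, m.c2, m.e2,
        mu=0.0, total_var=m.propensity_sd**2, seed=streams["propensity"],
    )
    propensities: dict[str, float] = {}
    all_pairs = np.vstack([prop_pairs.mz, prop_pairs.dz])
    for i in range(config.n_pairs):
        propensities[f"P{i + 1:04d}T1"] = float(all_pairs[i, 0])
        propensities[f"P{i + 1:04d}T2"] = float(all_pairs[i, 1])

    generate_distress_and_attrition(
        records, config, streams["distress"], attrition_seed=streams["attrition"]
    )
    _assign_ratings(records, propensities, config, streams["ratings"])
    traces = generate_motion_traces(records, propensities, config, streams["traces"])

    cohort = Cohort(records=records)
    result = SyntheticCohort(
        cohort=cohort, traces=traces, propensities=propensities,
        config=config, seed=seed,
    )
    if out_dir is not None:
        write_synthetic_cohort(result, out_dir)
    return result


def config_to_dict(config: CohortConfig) -> dict:
    """Config as a plain, YAML-serializable mapping."""
    def plain(obj):
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        return obj

    return plain(dataclasses.asdict(config))


def write_synthetic_cohort(result: SyntheticCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "par").mkdir(parents=True, exist_ok=True)
    write_cohort_table(result.cohort, out / "cohort.tsv", result.config.protocol)
    for (sid, run_label), trace in sorted(result.traces.items()):
        write_motion_par(trace, out / "par" / f"{sid}_{run_label}.par")
    echo = {"seed": result.seed, "config": config_to_dict(result.config)}
    (out / "config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
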
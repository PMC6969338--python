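"""End-to-end orchestration: simulate/load -> metrics -> QC -> twin stats -> ACE.

The pipeline runs the three-stratum analysis (all / moderate / minimal
motion) for the two quantitative motion phenotypes (subject mean FD and
mean AD over fMRI runs) plus the scan-quantity (0-9 completed runs) and
scan-quality (included fraction) phenotypes: within-twin correlations by
zygosity, the MZ-vs-DZ Fisher r-to-z comparison, and the maximum-
likelihood ACE decomposition with profile-likelihood CIs.  Subjects are
filtered into strata before pairing, so a pair enters a stratum only
when both twins qualify.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ace_model import TwinPairTable, fit_ace
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    TwinScanError,
    ValidationError,
)
from .io_formats import (
    Cohort,
    MotionTrace,
    ProtocolSpec,
    read_cohort_table,
    read_motion_par,
    write_report,
)
from .motion_metrics import RunMotionSummary, subject_mean_motion, summarize_run
from .qc_rules import QCThresholds, motion_stratum, subject_qc
from .synthetic_cohort import CohortConfig, config_to_dict, generate_cohort
from .twin_stats import fisher_z_compare, within_twin_correlation

log = logging.getLogger("twinscan.pipeline")

MOTION_PHENOTYPES = ("mean_fd", "mean_ad")
STRATA = ("all", "moderate", "minimal")


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort_dir: str | None = None  # load an existing cohort instead of simulating
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    stringency: str = "stringent"
    rs_rule: str = "fd03"

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("seed", "cohort_dir", "stringency", "rs_rule"):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "thresholds" in cfg:
            kwargs["thresholds"] = QCThresholds(**cfg["thresholds"])
        if "cohort" in cfg:
            sub = dict(cfg["cohort"])
            from .synthetic_cohort import (
                AttritionModel,
                DistressModel,
                MotionModel,
                RatingModel,
            )

            for name, klass in (
                ("motion", MotionModel),
                ("distress", DistressModel),
                ("attrition", AttritionModel),
                ("ratings", RatingModel),
            ):
                if name in sub:
                    sub[name] = klass(**sub[name])
            kwargs["cohort"] = CohortConfig(**sub)
        return cls(**kwargs)

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "cohort_dir": self.cohort_dir,
            "cohort": config_to_dict(self.cohort),
            "thresholds": dataclasses.asdict(self.thresholds),
            "stringency": self.stringency,
            "rs_rule": self.rs_rule,
        }
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineReport:
    run_motion: pd.DataFrame
    subject_qc: pd.DataFrame
    twin_correlations: pd.DataFrame
    ace: pd.DataFrame
    provenance: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "run_motion": self.run_motion,
            "subject_qc": self.subject_qc,
            "twin_correlations": self.twin_correlations,
            "ace": self.ace,
        }

    def write(self, path: str | Path) -> None:
        """Write all tables plus the provenance block; no partial output."""
        try:
            write_report(self.tables(), path, summary=self.provenance)
        except Exception:
            for f in Path(path).glob("*.tsv"):
                f.unlink(missing_ok=True)
            raise


# -- cohort loading ---------------------------------------------------------


def load_cohort_dir(
    path: str | Path, protocol: ProtocolSpec | None = None
) -> tuple[Cohort, dict[tuple[str, str], MotionTrace]]:
    """Read a cohort directory written by the simulator (or hand-built)."""
    from .io_formats import default_protocol

    path = Path(path)
    protocol = protocol or default_protocol()
    cohort = read_cohort_table(path / "cohort.tsv", protocol)
    traces: dict[tuple[str, str], MotionTrace] = {}
    fmri = set(protocol.fmri_run_labels)
    for rec in cohort.records:
        for lab in fmri:
            par = path / "par" / f"{rec.subject_id}_{lab}.par"
            if rec.completed.get(lab) and par.exists():
                traces[(rec.subject_id, lab)] = read_motion_par(
                    par, subject_id=rec.subject_id, run_label=lab,
                    tr_seconds=protocol.tr_seconds,
                )
    return cohort, traces


# -- phenotype assembly -----------------------------------------------------


def summarize_cohort_runs(
    traces: dict[tuple[str, str], MotionTrace]
) -> dict[str, dict[str, RunMotionSummary]]:
    """Per-subject {run_label: RunMotionSummary} for all available traces."""
    out: dict[str, dict[str, RunMotionSummary]] = {}
    for (sid, lab), trace in traces.items():
        out.setdefault(sid, {})[lab] = summarize_run(trace)
    return out


def compute_phenotypes(
    cohort: Cohort,
    summaries: dict[str, dict[str, RunMotionSummary]],
    protocol: ProtocolSpec,
    thresholds: QCThresholds,
    stringency: str = "stringent",
    rs_rule: str = "fd03",
) -> pd.DataFrame:
    """Per-subject phenotype table: motion means, quantity, quality, stratum."""
    rows = []
    for rec in cohort.records:
        subj_sum = summaries.get(rec.subject_id, {})
        fmri_sums = [
            subj_sum[lab] for lab in protocol.fmri_run_labels if lab in subj_sum
        ]
        motion = (
            subject_mean_motion(rec.subject_id, fmri_sums) if fmri_sums else None
        )
        qc = subject_qc(
            rec, protocol, thresholds, subj_sum, motion, stringency, rs_rule
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "pair_id": rec.pair_id,
                "birth_order": rec.birth_order,
                "zygosity": rec.zygosity,
                "mean_fd": motion.mean_fd_over_runs if motion else np.nan,
                "mean_ad": motion.mean_ad_over_runs if motion else np.nan,
                "quantity": qc.n_completed,
                "n_included": qc.n_included,
                "quality_fraction": (
                    qc.included_fraction if qc.included_fraction is not None else np.nan
                ),
                "stratum": qc.stratum,
                "window_30": qc.window_included[30],
                "window_45": qc.window_included[45],
                "window_60": qc.window_included[60],
            }
        )
    return pd.DataFrame(rows)


def _stratum_mask(pheno: pd.DataFrame, stratum: str) -> pd.Series:
    """Strata nest: 'moderate' admits minimal+moderate, 'all' admits everyone."""
    if stratum == "all":
        return pd.Series(True, index=pheno.index)
    if stratum == "moderate":
        return pheno["stratum"].isin(["minimal", "moderate"])
    if stratum == "minimal":
        return pheno["stratum"] == "minimal"
    raise ValidationError(f"unknown stratum: {stratum!r}")


def build_pair_table(
    pheno: pd.DataFrame, phenotype: str, stratum: str = "all"
) -> TwinPairTable:
    """Complete twin pairs for one phenotype within a motion stratum.

    A pair contributes only when both twins have a non-missing value and
    both fall inside the stratum.
    """
    sub = pheno[_stratum_mask(pheno, stratum) & pheno[phenotype].notna()]
    groups: dict[str, list[np.ndarray]] = {"MZ": [], "DZ": []}
    for pid, g in sub.groupby("pair_id"):
        if len(g) != 2:
            continue
        g = g.sort_values("birth_order")
        groups[g["zygosity"].iloc[0]].append(g[phenotype].to_numpy(dtype=float))
    return TwinPairTable(
        mz=np.array(groups["MZ"]).reshape(-1, 2),
        dz=np.array(groups["DZ"]).reshape(-1, 2),
    )


# -- report assembly --------------------------------------------------------


def _run_motion_table(
    cohort: Cohort,
    summaries: dict[str, dict[str, RunMotionSummary]],
    protocol: ProtocolSpec,
    thresholds: QCThresholds,
    stringency: str,
    rs_rule: str,
) -> pd.DataFrame:
    """Per-run motion means, for all subjects and for included subjects."""
    from .qc_rules import classify_rs_run, classify_task_run

    modality = {r.run_label: r.modality for r in protocol.runs}
    stringency_map = {"fd03": "stringent", "fd05": "lenient", "ad3": "ad3"}
    rows = []
    for lab in protocol.fmri_run_labels:
        sums = [s[lab] for s in summaries.values() if lab in s]
        if not sums:
            continue
        if modality[lab] == "task_fmri":
            included = [s for s in sums if classify_task_run(s, thresholds)]
        else:
            included = [
                s for s in sums
                if classify_rs_run(s, stringency_map[rs_rule], thresholds)
            ]
        for group, subset in (("all", sums), ("included", included)):
            if not subset:
                continue
            rows.append(
                {
                    "run_label": lab,
                    "group": group,
                    "n": len(subset),
                    "mean_fd": float(np.mean([s.mean_fd for s in subset])),
                    "sd_fd": float(np.std([s.mean_fd for s in subset], ddof=1))
                    if len(subset) > 1 else np.nan,
                    "mean_ad": float(np.mean([s.mean_ad for s in subset])),
                    "mean_ad_x": float(np.mean([s.mean_ad_x for s in subset])),
                    "mean_ad_y": float(np.mean([s.mean_ad_y for s in subset])),
                    "mean_ad_z": float(np.mean([s.mean_ad_z for s in subset])),
                }
            )
    return pd.DataFrame(rows)


def _genetic_tables(pheno: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Twin-correlation/Fisher-z table and ACE table over phenotype x stratum."""
    corr_rows, ace_rows = [], []
    cells = [(p, s) for p in MOTION_PHENOTYPES for s in STRATA]
    cells += [("quantity", "all"), ("quality_fraction", "all")]
    for phenotype, stratum in cells:
        pairs = build_pair_table(pheno, phenotype, stratum)
        row = {
            "phenotype": phenotype,
            "stratum": stratum,
            "n_mz": pairs.n_mz,
            "n_dz": pairs.n_dz,
        }
        try:
            rmz = within_twin_correlation(pairs, "MZ")
            rdz = within_twin_correlation(pairs, "DZ")
            fz = fisher_z_compare(rmz.r, rmz.n, rdz.r, rdz.n)
            corr_rows.append(
                {
                    **row,
                    "r_mz": rmz.r, "p_mz": rmz.p,
                    "r_dz": rdz.r, "p_dz": rdz.p,
                    "fisher_z": fz.z, "fisher_p": fz.p,
                }
            )
        except (InsufficientDataError, ValidationError) as exc:
            log.warning("correlations skipped for %s/%s: %s", phenotype, stratum, exc)
            corr_rows.append({**row, "r_mz": np.nan, "p_mz": np.nan,
                              "r_dz": np.nan, "p_dz": np.nan,
                              "fisher_z": np.nan, "fisher_p": np.nan})
        try:
            est = fit_ace(pairs, ci=True)
            ace_rows.append(
                {
                    **row,
                    "a2": est.a2, "c2": est.c2, "e2": est.e2,
                    "a2_lo": est.ci["a2"][0], "a2_hi": est.ci["a2"][1],
                    "c2_lo": est.ci["c2"][0], "c2_hi": est.ci["c2"][1],
                    "e2_lo": est.ci["e2"][0], "e2_hi": est.ci["e2"][1],
                    "loglik": est.loglik, "converged": est.converged,
                }
            )
        except (InsufficientDataError, DegenerateDataError) as exc:
            log.warning("ACE fit skipped for %s/%s: %s", phenotype, stratum, exc)
            ace_rows.append({**row, "a2": np.nan, "c2": np.nan, "e2": np.nan,
                             "a2_lo": np.nan, "a2_hi": np.nan,
                             "c2_lo": np.nan, "c2_hi": np.nan,
                             "e2_lo": np.nan, "e2_hi": np.nan,
                             "loglik": np.nan, "converged": False})
    return pd.DataFrame(corr_rows), pd.DataFrame(ace_rows)


def run_pipeline(config: PipelineConfig | None = None) -> PipelineReport:
    """Execute the full analysis and return the report tables.

    Deterministic under a fixed (config, seed).  Any stage failure is
    re-raised with the stage name attached.
    """
    config = config or PipelineConfig()
    stage = "simulate"
    try:
        protocol = config.cohort.protocol
        if config.cohort_dir:
            stage = "load"
            cohort, traces = load_cohort_dir(config.cohort_dir, protocol)
        else:
            sim = generate_cohort(config.cohort, seed=config.seed)
            cohort, traces = sim.cohort, sim.traces
        log.info("cohort: %d subjects, %d traces", len(cohort), len(traces))

        stage = "metrics"
        summaries = summarize_cohort_runs(traces)

        stage = "qc"
        pheno = compute_phenotypes(
            cohort, summaries, protocol, config.thresholds,
            config.stringency, config.rs_rule,
        )
        for stratum in STRATA:
            log.info("stratum %s: %d subjects", stratum,
                     int(_stratum_mask(pheno, stratum).sum()))
        run_motion = _run_motion_table(
            cohort, summaries, protocol, config.thresholds,
            config.stringency, config.rs_rule,
        )

        stage = "twinstats"
        corr, ace = _genetic_tables(pheno)
    except TwinScanError as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "n_subjects": len(cohort),
        "n_complete_pairs": len(cohort.complete_pairs()),
    }
    return PipelineReport(
        run_motion=run_motion,
        subject_qc=pheno,
        twin_correlations=corr,
        ace=ace,
        provenance=provenance,
    )
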
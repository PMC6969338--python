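"""Readers and writers for the pipeline's plain-text formats.

Three formats are handled here:

* rigid-body motion parameters: the de-facto 6-column text format produced
  by volume-registration tools, one row per volume.  Column convention is
  configurable; the default is rotations (radians) in columns 1-3 and
  translations (mm) in columns 4-6 (``par_order="rot_first"``).
* the cohort phenotype table: a TSV with one row per child carrying pair
  membership, zygosity, run-completion flags, structural ratings and
  scanner-distress ratings.
* report output: named result tables written as TSV plus a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError

# -- protocol ---------------------------------------------------------------

ZYGOSITIES = ("MZ", "DZ")
RATING_LEVELS = ("Excellent", "Good", "Doubtful", "Failed")
DISTRESS_TIMEPOINTS = ("pre_sim", "pre_mri", "post_mri")
DISTRESS_RATERS = ("child", "researcher", "parent")
DISTRESS_SCALES = ("tension", "excitement")


@dataclass(frozen=True)
class RunSpec:
    """One run of the fixed scan protocol."""

    run_label: str
    modality: str  # task_fmri | t1 | dti | rs_fmri
    nominal_volumes: int
    nominal_minutes: float


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered scan protocol with the quantity and quality denominators.

    The default is a 60-minute pediatric protocol: three runs of a social
    feedback task (SNAT), two runs of a prosocial game task (PCG), a 3DT1
    anatomical scan, two diffusion runs, and a closing resting-state run.
    Scan *quantity* counts all 9 runs.  Scan *quality* counts 8 rated
    units: the two diffusion runs receive a single joint rating and are
    merged into one unit.
    """

    runs: tuple[RunSpec, ...]
    quantity_denominator: int = 9
    quality_denominator: int = 8
    tr_seconds: float = 2.2

    def __post_init__(self) -> None:
        labels = [r.run_label for r in self.runs]
        if len(set(labels)) != len(labels):
            raise ValidationError("protocol run labels must be unique")
        if self.quantity_denominator != len(self.runs):
            raise ValidationError(
                "quantity_denominator must equal the number of protocol runs"
            )
        if self.quality_denominator > self.quantity_denominator:
            raise ValidationError("quality_denominator cannot exceed quantity")

    @property
    def run_labels(self) -> tuple[str, ...]:
        return tuple(r.run_label for r in self.runs)

    @property
    def task_run_labels(self) -> tuple[str, ...]:
        return tuple(r.run_label for r in self.runs if r.modality == "task_fmri")

    @property
    def fmri_run_labels(self) -> tuple[str, ...]:
        """Task and resting-state runs: the runs with motion traces."""
        return tuple(
            r.run_label for r in self.runs if r.modality in ("task_fmri", "rs_fmri")
        )

    def quality_units(self) -> tuple[tuple[str, tuple[str, ...]], ...]:
        """Rated quality units in protocol order: (unit label, member runs).

        Task and resting-state runs are one unit each; all DTI runs are
        merged into a single jointly-rated unit.
        """
        units: list[tuple[str, tuple[str, ...]]] = []
        dti = tuple(r.run_label for r in self.runs if r.modality == "dti")
        dti_done = False
        for r in self.runs:
            if r.modality == "dti":
                if not dti_done:
                    units.append(("dti", dti))
                    dti_done = True
            else:
                units.append((r.run_label, (r.run_label,)))
        return tuple(units)


def default_protocol() -> ProtocolSpec:
    """The fixed 9-run, 60-minute protocol used throughout."""
    return ProtocolSpec(
        runs=(
            RunSpec("snat1", "task_fmri", 148, 5.43),
            RunSpec("snat2", "task_fmri", 142, 5.21),
            RunSpec("snat3", "task_fmri", 141, 5.17),
            RunSpec("pcg1", "task_fmri", 136, 4.99),
            RunSpec("pcg2", "task_fmri", 136, 4.99),
            RunSpec("t1", "t1", 1, 6.0),
            RunSpec("dti1", "dti", 35, 5.0),
            RunSpec("dti2", "dti", 35, 5.0),
            RunSpec("rs", "rs_fmri", 142, 5.21),
        )
    )


# -- motion traces ----------------------------------------------------------


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters for one run.

    rotations are in radians, translations in mm; both are (n_volumes, 3)
    arrays with rows in acquisition order.
    """

    subject_id: str
    run_label: str
    rotations: np.ndarray
    translations: np.ndarray
    tr_seconds: float = 2.2

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.rotations.shape != self.translations.shape:
            raise ValidationError("rotations and translations must share shape")
        if self.rotations.ndim != 2 or self.rotations.shape[1] != 3:
            raise ValidationError("motion parameters must be (n_volumes, 3)")
        if not (np.isfinite(self.rotations).all() and np.isfinite(self.translations).all()):
            raise ValidationError("motion parameters must be finite")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.rotations.shape[0]


def read_motion_par(
    path: str | Path,
    subject_id: str = "",
    run_label: str = "",
    tr_seconds: float = 2.2,
    par_order: str = "rot_first",
) -> MotionTrace:
    """Read a 6-column motion-parameter text file.

    ``par_order`` selects the column dialect: ``"rot_first"`` (default)
    maps columns 1-3 to rotations in radians and 4-6 to translations in
    mm; ``"trans_first"`` reverses the two blocks.
    """
    if par_order not in ("rot_first", "trans_first"):
        raise ValidationError(f"unknown par_order: {par_order!r}")
    path = Path(path)
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 fields, found {len(fields)}"
                )
            try:
                rows.append([float(tok) for tok in fields])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric token") from exc
    if not rows:
        raise ParseError(f"{path}: no motion rows")
    arr = np.asarray(rows, dtype=float)
    if par_order == "rot_first":
        rot, trans = arr[:, :3], arr[:, 3:]
    else:
        trans, rot = arr[:, :3], arr[:, 3:]
    return MotionTrace(
        subject_id=subject_id or path.stem,
        run_label=run_label,
        rotations=rot,
        translations=trans,
        tr_seconds=tr_seconds,
    )


def write_motion_par(
    trace: MotionTrace, path: str | Path, par_order: str = "rot_first"
) -> None:
    """Write a trace in the 6-column text format (6 significant digits)."""
    if par_order not in ("rot_first", "trans_first"):
        raise ValidationError(f"unknown par_order: {par_order!r}")
    blocks = (
        (trace.rotations, trace.translations)
        if par_order == "rot_first"
        else (trace.translations, trace.rotations)
    )
    data = np.hstack(blocks)
    lines = ["  ".join(f"{v:.6g}" for v in row) for row in data]
    Path(path).write_text("\n".join(lines) + "\n")


# -- cohort table -----------------------------------------------------------


def distress_column(scale: str, rater: str, timepoint: str) -> str:
    return f"{scale}_{rater}_{timepoint}"


def distress_columns() -> tuple[str, ...]:
    """All distress-rating columns; parents do not rate the post-MRI moment."""
    cols = []
    for scale in DISTRESS_SCALES:
        for rater in DISTRESS_RATERS:
            for tp in DISTRESS_TIMEPOINTS:
                if rater == "parent" and tp == "post_mri":
                    continue
                cols.append(distress_column(scale, rater, tp))
    return tuple(cols)


@dataclass
class SubjectRecord:
    """One child: identity, completion flags, ratings and distress scores.

    Missing optional values are ``None`` (never silently zero).
    """

    subject_id: str
    pair_id: str
    birth_order: int
    zygosity: str
    age: float | None = None
    sex: str | None = None
    completed: dict[str, bool] = field(default_factory=dict)
    rating_t1: str | None = None
    rating_dti: str | None = None
    distress: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValidationError(f"unknown zygosity code: {self.zygosity!r}")
        if self.birth_order not in (1, 2):
            raise ValidationError(f"birth_order must be 1 or 2, got {self.birth_order}")
        for rating in (self.rating_t1, self.rating_dti):
            if rating is not None and rating not in RATING_LEVELS:
                raise ValidationError(f"unknown rating label: {rating!r}")


@dataclass
class Cohort:
    """A set of subject records with pair bookkeeping.

    Pairs with a number of members different from two are retained but
    flagged incomplete and excluded from every pairwise statistic.
    """

    records: list[SubjectRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.subject_id in seen:
                raise ValidationError(f"duplicate twin id: {rec.subject_id}")
            seen.add(rec.subject_id)

    def by_pair(self) -> dict[str, list[SubjectRecord]]:
        pairs: dict[str, list[SubjectRecord]] = {}
        for rec in self.records:
            pairs.setdefault(rec.pair_id, []).append(rec)
        return pairs

    @property
    def incomplete_pair_ids(self) -> tuple[str, ...]:
        return tuple(
            pid for pid, members in self.by_pair().items() if len(members) != 2
        )

    def complete_pairs(self) -> list[tuple[SubjectRecord, SubjectRecord]]:
        """Complete pairs ordered by pair id, members by birth order."""
        out = []
        for pid, members in sorted(self.by_pair().items()):
            if len(members) != 2:
                continue
            members = sorted(members, key=lambda r: r.birth_order)
            mixed = {m.zygosity for m in members}
            if len(mixed) != 1:
                raise ValidationError(f"pair {pid} has inconsistent zygosity")
            out.append((members[0], members[1]))
        return out

    def __len__(self) -> int:
        return len(self.records)


REQUIRED_COHORT_COLUMNS = ("subject_id", "pair_id", "birth_order", "zygosity")


def read_cohort_table(
    path: str | Path, protocol: ProtocolSpec | None = None
) -> Cohort:
    """Read a cohort phenotype TSV into a :class:`Cohort`."""
    protocol = protocol or default_protocol()
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "pair_id": str})
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    flag_cols = [f"completed_{lab}" for lab in protocol.run_labels]
    for c in df.columns:
        if c.startswith("completed_") and c not in flag_cols:
            raise ValidationError(f"completion flag for unknown run: {c}")
    records = []
    for _, row in df.iterrows():
        completed = {
            lab: bool(row[f"completed_{lab}"])
            for lab in protocol.run_labels
            if f"completed_{lab}" in df.columns and pd.notna(row[f"completed_{lab}"])
        }
        distress = {
            col: float(row[col])
            for col in distress_columns()
            if col in df.columns and pd.notna(row[col])
        }
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                pair_id=str(row["pair_id"]),
                birth_order=int(row["birth_order"]),
                zygosity=str(row["zygosity"]),
                age=float(row["age"]) if "age" in df.columns and pd.notna(row["age"]) else None,
                sex=str(row["sex"]) if "sex" in df.columns and pd.notna(row["sex"]) else None,
                completed=completed,
                rating_t1=str(row["rating_t1"])
                if "rating_t1" in df.columns and pd.notna(row["rating_t1"])
                else None,
                rating_dti=str(row["rating_dti"])
                if "rating_dti" in df.columns and pd.notna(row["rating_dti"])
                else None,
                distress=distress,
            )
        )
    return Cohort(records=records)


def cohort_to_frame(cohort: Cohort, protocol: ProtocolSpec | None = None) -> pd.DataFrame:
    """Flatten a cohort to the TSV column layout (deterministic order)."""
    protocol = protocol or default_protocol()
    rows = []
    for rec in cohort.records:
        row: dict[str, object] = {
            "subject_id": rec.subject_id,
            "pair_id": rec.pair_id,
            "birth_order": rec.birth_order,
            "zygosity": rec.zygosity,
            "age": rec.age,
            "sex": rec.sex,
        }
        for lab in protocol.run_labels:
            row[f"completed_{lab}"] = int(rec.completed.get(lab, False))
        row["rating_t1"] = rec.rating_t1
        row["rating_dti"] = rec.rating_dti
        for col in distress_columns():
            row[col] = rec.distress.get(col)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_table(
    cohort: Cohort, path: str | Path, protocol: ProtocolSpec | None = None
) -> None:
    cohort_to_frame(cohort, protocol).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


# -- reports and config -----------------------------------------------------


def write_report(
    tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    summary: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write named result tables as TSV (plus a JSON summary) to a directory.

    Output is deterministic: tables are written in sorted-name order with
    fixed column order and 6-significant-digit floats, so re-running on
    identical inputs yields byte-identical files.
    """
    if not tables:
        raise ValidationError("no tables to write")
    for name, df in tables.items():
        if df.empty:
            raise ValidationError(f"table {name!r} is empty")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        dest = outdir / f"{name}.tsv"
        tables[name].to_csv(dest, sep="\t", index=False, float_format="%.6g")
        written.append(dest)
    if summary is not None:
        dest = outdir / "summary.json"
        dest.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(dest)
    return written


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON; JSON is a YAML subset) config mapping."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValidationError("config root must be a mapping")
    return cfg
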
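"""Readers, writers and validation for on-disk artifacts.

Every format dialect used by the pipeline is decided here and nowhere else:

* expression — tab-separated text, first column gene IDs, header row sample
  IDs, nonnegative finite values (an already background-corrected and
  quantile-normalized log2-like matrix, e.g. RMA output);
* clinical — CSV, UTF-8, one row per subject, header required;
* events — CSV, one row per ventilation interval; per-subject fields
  (death day, PICU survival) are repeated on each of the subject's rows and
  must be consistent;
* reports — JSON for machines plus TSV summary tables.

Days are real-valued, measured from ARDS onset (day 0); ventilation
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

FOLLOWUP_DAY = 28.0

VASOPRESSOR_COLUMNS = (
    "dopamine",
    "dobutamine",
    "epinephrine",
    "norepinephrine",
    "phenylephrine",
    "milrinone",
    "vasopressin",
)

ETIOLOGY_CATEGORIES = (
    "infectious pneumonia",
    "nonpulmonary sepsis",
    "aspiration",
    "trauma",
    "other",
)

CLINICAL_REQUIRED = (
    "subject_id",
    "age",
    "sex",
    "prism_iii",
    "nonpulm_organ_failures",
    "immunocompromised",
    "stem_cell_transplant",
    "etiology_direct",
    "etiology_infectious",
    "etiology_category",
    "anc",
    "alc",
    "pf_onset",
    "pf_24h",
    "oi_onset",
    "oi_24h",
)


@dataclass
class ExpressionMatrix:
    """Genes x samples nonnegative expression values with ID axes."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene ID: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample ID: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subjects_by_genes(self) -> np.ndarray:
        """Transposed view (samples x genes), the clustering orientation."""
        return self.values.T

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class EventRecord:
    """Ventilation course and vital status for one subject."""

    subject_id: str
    intervals: list[tuple[float, float]]
    death_day: float | None
    picu_survivor: bool
    followup_day: float = FOLLOWUP_DAY

    def __post_init__(self):
        ivs = sorted((float(a), float(b)) for a, b in self.intervals)
        for a, b in ivs:
            if not (b > a):
                raise ValidationError(
                    f"{self.subject_id}: interval end {b} must exceed start {a}"
                )
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ValidationError(
                    f"{self.subject_id}: overlapping ventilation intervals "
                    f"[{a1},{b1}) and [{a2},{b2})"
                )
        if ivs and ivs[0][0] != 0.0:
            raise ValidationError(
                f"{self.subject_id}: first ventilation interval must start at "
                f"day 0 (ARDS onset), got {ivs[0][0]}"
            )
        if self.picu_survivor and self.death_day is not None:
            raise ValidationError(
                f"{self.subject_id}: death_day present for a PICU survivor"
            )
        if not self.picu_survivor and self.death_day is None:
            raise ValidationError(
                f"{self.subject_id}: nonsurvivor must carry a death_day"
            )
        if self.death_day is not None and self.death_day > self.followup_day:
            raise ValidationError(
                f"{self.subject_id}: death_day {self.death_day} beyond the "
                f"{self.followup_day}-day horizon"
            )
        self.intervals = ivs


@dataclass
class EventHistory:
    """Per-subject competing-risk event data, horizon fixed at day 28."""

    records: dict[str, EventRecord] = field(default_factory=dict)

    def __post_init__(self):
        for sid, rec in self.records.items():
            if sid != rec.subject_id:
                raise ValidationError(f"record keyed {sid!r} has id {rec.subject_id!r}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.records)

    def __getitem__(self, subject_id: str) -> EventRecord:
        return self.records[subject_id]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# expression TSV


def read_expression(path) -> ExpressionMatrix:
    """Parse a genes x samples TSV (first column gene IDs, header samples)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError("empty expression file", line=1)
        sample_ids = header.split("\t")[1:]
        if not sample_ids:
            raise ParseError("header carries no sample IDs", line=1)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ParseError(
                    f"expected {len(sample_ids) + 1} fields, got {len(parts)}",
                    line=lineno,
                )
            gid = parts[0]
            if gid in seen:
                raise ParseError(f"duplicate gene ID {gid!r}", line=lineno)
            seen.add(gid)
            try:
                vals = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"non-numeric cell: {exc}", line=lineno) from None
            gene_ids.append(gid)
            rows.append(vals)
    if not gene_ids:
        raise ParseError("expression file has no gene rows", line=2)
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# clinical CSV


def _coerce_bool(series: pd.Series, name: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, True: True, False: False, 1: True, 0: False,
    }
    out = []
    for v in series:
        key = v.strip().lower() if isinstance(v, str) else v
        if isinstance(key, float) and key in (0.0, 1.0):
            key = int(key)
        if key not in mapping:
            raise SchemaError(f"column {name!r}: non-boolean value {v!r}")
        out.append(mapping[key])
    return pd.Series(out, index=series.index, dtype=bool)


def read_clinical(path) -> pd.DataFrame:
    """Read and validate the per-subject clinical covariate table.

    Returns a DataFrame with one row per subject; vasopressor dose columns
    absent from the file (or left blank) default to 0.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    return validate_clinical(df)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing required columns: {missing}")
    df = df.copy()
    dup = _first_duplicate(list(df["subject_id"]))
    if dup is not None:
        raise SchemaError(f"duplicate subject_id: {dup!r}")
    bad_sex = set(df["sex"]) - {"female", "male"}
    if bad_sex:
        raise SchemaError(f"sex values outside {{female, male}}: {sorted(bad_sex)}")
    bad_cat = set(df["etiology_category"]) - set(ETIOLOGY_CATEGORIES)
    if bad_cat:
        raise SchemaError(f"unknown etiology_category values: {sorted(bad_cat)}")
    for col in ("immunocompromised", "stem_cell_transplant",
                "etiology_direct", "etiology_infectious"):
        df[col] = _coerce_bool(df[col], col)
    for col in VASOPRESSOR_COLUMNS:
        if col not in df.columns:
            df[col] = 0.0
        df[col] = pd.to_numeric(df[col]).fillna(0.0)
    numeric = ["age", "prism_iii", "nonpulm_organ_failures", "anc", "alc",
               "pf_onset", "pf_24h", "oi_onset", "oi_24h", *VASOPRESSOR_COLUMNS]
    for col in numeric:
        vals = pd.to_numeric(df[col])
        if vals.isna().any():
            raise SchemaError(f"column {col!r} has missing values (no imputation)")
        if not np.all(np.isfinite(vals)):
            raise SchemaError(f"column {col!r} has non-finite values")
        if (vals < 0).any():
            raise SchemaError(f"column {col!r} has negative values")
        df[col] = vals
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# events CSV (long format: one row per ventilation interval)

EVENTS_REQUIRED = ("subject_id", "interval_start", "interval_end",
                   "death_day", "picu_survivor")


def read_events(path) -> EventHistory:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in EVENTS_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"events table missing required columns: {missing}")
    records: dict[str, EventRecord] = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        deaths = set(grp["death_day"].tolist())
        survs = set(_coerce_bool(grp["picu_survivor"], "picu_survivor"))
        if len(survs) != 1:
            raise ValidationError(f"{sid}: inconsistent picu_survivor across rows")
        death_vals = {d for d in deaths if not (isinstance(d, float) and math.isnan(d))}
        if len(death_vals) > 1:
            raise ValidationError(f"{sid}: inconsistent death_day across rows")
        death_day = float(next(iter(death_vals))) if death_vals else None
        intervals = list(zip(grp["interval_start"].astype(float),
                             grp["interval_end"].astype(float)))
        records[sid] = EventRecord(
            subject_id=sid,
            intervals=intervals,
            death_day=death_day,
            picu_survivor=bool(next(iter(survs))),
        )
    return EventHistory(records)


def write_events(events: EventHistory, path) -> None:
    rows = []
    for rec in events:
        for a, b in rec.intervals:
            rows.append({
                "subject_id": rec.subject_id,
                "interval_start": a,
                "interval_end": b,
                "death_day": rec.death_day if rec.death_day is not None else "",
                "picu_survivor": rec.picu_survivor,
            })
    pd.DataFrame(rows, columns=list(EVENTS_REQUIRED)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# alignment and reports


def align_subjects(expression: ExpressionMatrix, clinical: pd.DataFrame,
                   events: EventHistory) -> list[str]:
    """Check the three tables share one subject-ID set; return the
    expression-column order (the canonical subject order downstream)."""
    expr_ids = set(expression.sample_ids)
    clin_ids = set(clinical["subject_id"])
    ev_ids = set(events.subject_ids)
    if expr_ids != clin_ids or expr_ids != ev_ids:
        msg = []
        for name, ids in (("clinical", clin_ids), ("events", ev_ids)):
            only_expr = sorted(expr_ids - ids)
            only_other = sorted(ids - expr_ids)
            if only_expr:
                msg.append(f"subjects in expression but not {name}: {only_expr[:5]}")
            if only_other:
                msg.append(f"subjects in {name} but not expression: {only_other[:5]}")
        raise ValidationError("subject-ID misalignment: " + "; ".join(msg))
    return list(expression.sample_ids)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        return super().default(o)


def write_report(results: dict, outdir) -> None:
    """Emit a machine-readable JSON report plus TSV summaries.

    Any DataFrame value in ``results`` is additionally written as
    ``<key>.tsv`` next to ``report.json``.
    """
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(outdir / f"{key}.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, cls=_ReportEncoder)
        fh.write("\n")
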
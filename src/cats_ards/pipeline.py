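"""End-to-end orchestration: simulate/load -> cluster -> characterize ->
model -> differential expression -> report.

Characterization and outcome models always use the *discovered* subtype
labels, never the planted truth (the discovery step is blind to clinical
data and outcomes); planted labels exist only inside test assertions. All
randomness flows from the single config seed through named substreams
recorded in the manifest, and rerunning an identical config writes
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clinical as clin
from . import cluster as cl
from . import dataio, de, outcomes, stats
from .errors import ConfigError, SeparationError
from .synthetic import SimulationConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger("cats_ards")


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on."""

    output_dir: str
    paths: dict | None = None            # expression / clinical / events
    simulation: SimulationConfig | None = None
    k_max: int = cl.DEFAULT_K_MAX
    B: int = cl.DEFAULT_B
    n_init: int = cl.DEFAULT_N_INIT
    min_cluster_size: int = cl.DEFAULT_MIN_CLUSTER_SIZE
    selection_rule: str = "parsimonious"
    adjustments: tuple[str, ...] = ("unadjusted", "prism", "immunocompromised",
                                    "prism_immunocompromised")
    fc_threshold: float = de.DEFAULT_FC_THRESHOLD
    q_threshold: float = de.DEFAULT_Q_THRESHOLD
    de_min_value: float = de.DEFAULT_MIN_VALUE
    de_min_samples: int = de.DEFAULT_MIN_SAMPLES
    seed: int = 0

    def __post_init__(self):
        if (self.paths is None) == (self.simulation is None):
            raise ConfigError(
                "exactly one of 'paths' and 'simulation' must be given")
        if self.paths is not None:
            missing = {"expression", "clinical", "events"} - set(self.paths)
            if missing:
                raise ConfigError(f"paths block missing {sorted(missing)}")
        if not (1 <= self.k_max):
            raise ConfigError("k_max must be >= 1")
        if self.B < 2:
            raise ConfigError("B must be >= 2")
        if not (0 < self.q_threshold <= 1):
            raise ConfigError("q_threshold must lie in (0, 1]")
        if self.fc_threshold < 1:
            raise ConfigError("fc_threshold must be >= 1")
        for preset in self.adjustments:
            if preset not in outcomes.ADJUSTMENT_PRESETS:
                raise ConfigError(f"unknown adjustment preset {preset!r}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "adjustments" in raw:
            raw["adjustments"] = tuple(raw["adjustments"])
        return cls(**raw)

    def cluster_seed(self) -> int:
        return int(np.random.SeedSequence([self.seed, 101]).generate_state(1)[0]
                   % (2**31 - 1))


@dataclass
class PipelineResult:
    selected_k: int
    labels: pd.Series
    gap_curve: cl.GapCurve
    audit: cl.SelectionAudit
    characterization: pd.DataFrame
    models: pd.DataFrame
    de_tables: dict
    manifest: dict = field(repr=False, default_factory=dict)


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        cohort = generate_cohort(config.simulation)
        return cohort.expression, cohort.clinical, cohort.events
    expression = dataio.read_expression(config.paths["expression"])
    clinical = dataio.read_clinical(config.paths["clinical"])
    events = dataio.read_events(config.paths["events"])
    return expression, clinical, events


def competing_risk_frame(events: dataio.EventHistory,
                         subject_order) -> pd.DataFrame:
    """Per-subject (time, event) observations for the extubation analysis
    plus derived ventilation outcomes."""
    rows = []
    for sid in subject_order:
        rec = events[sid]
        t, ev = clin.first_liberation_time(rec)
        rows.append({
            "subject_id": sid,
            "time": t,
            "event": ev,
            "died": not rec.picu_survivor,
            "ventilator_days": clin.ventilator_days(rec),
            "vfd28": clin.vfd28(rec),
        })
    return pd.DataFrame(rows).set_index("subject_id")


def _fit_models(labels, clinical_idx, cr: pd.DataFrame,
                adjustments) -> pd.DataFrame:
    frames = []
    for preset in adjustments:
        try:
            logi = outcomes.mortality_model(
                labels, clinical_idx, cr["died"].to_numpy(), adjust=preset)
            t = logi.to_frame()
            t.insert(0, "model", "mortality_logistic")
            t.insert(0, "adjustment", preset)
            t = t.rename(columns={"odds_ratio": "estimate"})
            frames.append(t)
        except SeparationError as exc:
            logger.warning("logistic (%s) skipped: %s", preset, exc)
        fg = outcomes.extubation_model(
            labels, clinical_idx, cr["time"].to_numpy(),
            cr["event"].to_numpy(), adjust=preset)
        t = fg.to_frame()
        t.insert(0, "model", "extubation_fine_gray")
        t.insert(0, "adjustment", preset)
        t = t.rename(columns={"subdistribution_hazard_ratio": "estimate"})
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    t_start = time.perf_counter()
    expression, clinical_tab, events = _load_inputs(config)
    clinical_tab = dataio.validate_clinical(clinical_tab)
    subject_order = dataio.align_subjects(expression, clinical_tab, events)
    logger.info("inputs: %d genes x %d subjects", expression.n_genes,
                expression.n_samples)

    # --- subtype discovery (blind to clinical data) ---
    t0 = time.perf_counter()
    X = expression.subjects_by_genes()
    curve = cl.gap_statistic(X, k_max=config.k_max, B=config.B,
                             seed=config.cluster_seed(), n_init=config.n_init)
    audit = cl.select_k(curve, min_cluster_size=config.min_cluster_size,
                        rule=config.selection_rule)
    k = audit.selected_k
    labels = pd.Series(curve.clusterings[k].labels, index=subject_order,
                       name="subtype")
    logger.info("selected k=%d (audit: %s) in %.1fs", k, audit,
                time.perf_counter() - t0)

    # --- characterization ---
    characterization = stats.characterize(clinical_tab, labels)

    # --- outcome models ---
    cr = competing_risk_frame(events, subject_order)
    clinical_idx = clinical_tab.set_index("subject_id").loc[subject_order]
    models = _fit_models(labels.to_numpy(), clinical_idx, cr,
                         config.adjustments)

    # --- differential expression ---
    de_tables = de.de_all_subtypes(
        expression, labels.to_numpy(), fc_threshold=config.fc_threshold,
        q_threshold=config.q_threshold, min_value=config.de_min_value,
        min_samples=config.de_min_samples)

    manifest = {
        "seed": config.seed,
        "substream_seeds": {"cluster": config.cluster_seed()},
        "k_max": config.k_max,
        "B": config.B,
        "n_init": config.n_init,
        "min_cluster_size": config.min_cluster_size,
        "selection_rule": config.selection_rule,
        "selected_k": k,
        "selection_audit": {
            "global_max_k": audit.global_max_k,
            "candidate_set": audit.candidate_set,
            "eliminated_by_size": audit.eliminated_by_size,
            "rule": audit.rule,
        },
        "adjustments": list(config.adjustments),
        "n_subjects": expression.n_samples,
        "n_genes": expression.n_genes,
        "simulation": (config.simulation.to_dict()
                       if config.simulation is not None else None),
    }
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t_start)
    return PipelineResult(
        selected_k=k, labels=labels, gap_curve=curve, audit=audit,
        characterization=characterization, models=models,
        de_tables=de_tables, manifest=manifest,
    )


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(result: PipelineResult, config: PipelineConfig) -> pathlib.Path:
    """Write the report bundle; returns the output directory."""
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.labels.rename("subtype").rename_axis("subject_id").to_csv(
        outdir / "labels.csv")
    result.gap_curve.to_frame().to_csv(outdir / "gap_curve.tsv", sep="\t",
                                       index=False)
    result.characterization.to_csv(outdir / "characterization.tsv", sep="\t",
                                   index=False)
    result.models.to_csv(outdir / "models.tsv", sep="\t", index=False)
    for subtype, table in result.de_tables.items():
        table.to_csv(outdir / f"de_subtype_{subtype}.tsv", sep="\t",
                     index=False)
    manifest = dict(result.manifest)
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
    }
    manifest["outputs"]["labels.csv"] = _sha256(outdir / "labels.csv")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
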
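"""Synthetic pediatric-ARDS cohorts with planted transcriptomic subtypes.

The generator emulates the statistical structure the analysis assumes: a
log2-scale expression matrix with k latent subtypes marked by disjoint
blocks of informative genes; subtype-linked clinical covariates
(immunocompromise prevalence, leukocyte counts, 24-h oxygenation); and
competing-risk ventilation outcomes (extubation alive vs death by day 28,
administrative censoring at the 28-day horizon). Defaults mirror a
96-subject cohort with three subtypes of sizes 31/29/36, subtype
immunocompromise prevalences of 32/48/14% and 28-day mortality of
32/24/8%.

Subjects are apportioned to subtypes deterministically by largest
remainder, so group sizes are exact, and all randomness flows from the
single config seed through named substreams: identical configs give
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import (
    ETIOLOGY_CATEGORIES,
    FOLLOWUP_DAY,
    EventHistory,
    EventRecord,
    ExpressionMatrix,
)
from .errors import ConfigError

_SUBSTREAMS = {"expression": 0, "clinical": 1, "outcomes": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Expression effect sizes and noise are on the log2 scale;
    ``extubation_rate`` is the baseline daily rate of the exponential
    extubation-time law and ``death_time_rate`` the (truncated) daily rate
    for death times on (0, 28].
    """

    n_subjects: int = 96
    n_genes: int = 2000
    k_true: int = 3
    n_informative: int = 200
    effect_size: float = 2.0
    noise_sd: float = 1.0
    subtype_proportions: tuple[float, ...] = (31 / 96, 29 / 96, 36 / 96)
    immunocompromised_prev: tuple[float, ...] = (0.32, 0.48, 0.14)
    death_prob_28d: tuple[float, ...] = (0.32, 0.24, 0.08)
    extubation_rate: float = 0.10
    death_time_rate: float = 0.15
    reintubation_prob: float = 0.10
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.k_true < 1:
            raise ConfigError(f"k_true must be >= 1, got {self.k_true}")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ConfigError(
                f"n_informative must lie in [0, n_genes], got {self.n_informative}")
        if self.effect_size < 0:
            raise ConfigError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        for name in ("subtype_proportions", "immunocompromised_prev",
                     "death_prob_28d"):
            vec = getattr(self, name)
            if len(vec) != self.k_true:
                raise ConfigError(
                    f"{name} must have length k_true={self.k_true}, "
                    f"got {len(vec)}")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ConfigError("subtype_proportions must sum to 1")
        if any(p < 0 for p in self.subtype_proportions):
            raise ConfigError("subtype_proportions must be nonnegative")
        for name in ("immunocompromised_prev", "death_prob_28d"):
            if any(not (0 <= p <= 1) for p in getattr(self, name)):
                raise ConfigError(f"{name} entries must lie in [0, 1]")
        for name in ("extubation_rate", "death_time_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (0 <= self.reintubation_prob <= 1):
            raise ConfigError("reintubation_prob must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _SUBSTREAMS[stream]]))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    events: EventHistory
    true_labels: pd.Series  # subject_id -> subtype 1..k_true
    config: SimulationConfig = field(repr=False, default=None)


def largest_remainder_counts(proportions, n: int) -> np.ndarray:
    """Apportion n subjects to groups by the largest-remainder method
    (ties broken toward the earlier group)."""
    props = np.asarray(proportions, dtype=float)
    quotas = props * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def assign_labels(config: SimulationConfig) -> pd.Series:
    counts = largest_remainder_counts(config.subtype_proportions,
                                      config.n_subjects)
    labels = np.repeat(np.arange(1, config.k_true + 1), counts)
    return pd.Series(labels, index=_subject_ids(config.n_subjects),
                     name="subtype")


def generate_expression(config: SimulationConfig):
    """Planted-subtype log2 expression matrix.

    Each subtype owns a disjoint block of ``n_informative / k_true`` genes
    whose mean is shifted by +``effect_size`` in that subtype; the
    remaining genes are exchangeable across subtypes. Gene baselines are
    uniform over ``baseline_mean_range`` with i.i.d. Gaussian noise of SD
    ``noise_sd``; values are floored at 0 to stay on a nonnegative
    log2-like scale.

    Returns ``(ExpressionMatrix, true_labels)``.
    """
    rng = config.rng("expression")
    labels = assign_labels(config)
    lab = labels.to_numpy()
    baseline = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    mean = np.tile(baseline[:, None], (1, config.n_subjects))
    block = config.n_informative // config.k_true
    for k in range(config.k_true):
        genes = slice(k * block, (k + 1) * block)
        mean[genes, lab == k + 1] += config.effect_size
    values = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
    np.maximum(values, 0.0, out=values)
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    matrix = ExpressionMatrix(gene_ids, list(labels.index), values)
    return matrix, labels


# lognormal location shifts (log scale) per subtype for leukocyte counts;
# chosen to give modest rank eta-squared effect sizes (single digits %)
_ANC_BASE_MEDIAN = 6000.0   # cells/uL
_ALC_BASE_MEDIAN = 1500.0   # cells/uL
_ANC_SHIFTS = (0.0, -0.3, 0.2)
_ALC_SHIFTS = (0.3, -0.3, 0.0)
_PF24_MEDIANS = (179.0, 236.0, 252.0)   # persistent hypoxemia in subtype 1
_OI24_MEDIANS = (9.8, 5.7, 6.0)


def _per_subtype(values, k: int):
    vals = list(values)
    if len(vals) >= k:
        return vals[:k]
    return vals + [vals[-1]] * (k - len(vals))


def generate_clinical(true_labels: pd.Series,
                      config: SimulationConfig) -> pd.DataFrame:
    """Subtype-linked clinical covariate table.

    Immunocompromise is Bernoulli per subtype with the configured
    prevalences; ANC/ALC are lognormal with subtype-specific location
    shifts; PRISM III is Poisson and independent of subtype; 24-h
    oxygenation reflects persistent hypoxemia in subtype 1.
    """
    rng = config.rng("clinical")
    lab = true_labels.to_numpy()
    n = len(lab)
    k = config.k_true
    prev = np.asarray(config.immunocompromised_prev)[lab - 1]
    immuno = rng.random(n) < prev
    sct = immuno & (rng.random(n) < 0.5)
    anc_shift = np.asarray(_per_subtype(_ANC_SHIFTS, k))[lab - 1]
    alc_shift = np.asarray(_per_subtype(_ALC_SHIFTS, k))[lab - 1]
    anc = np.exp(np.log(_ANC_BASE_MEDIAN) + anc_shift + rng.normal(0, 0.6, n))
    alc = np.exp(np.log(_ALC_BASE_MEDIAN) + alc_shift + rng.normal(0, 0.6, n))
    age = 18.0 * rng.beta(1.2, 1.5, n)
    sex = np.where(rng.random(n) < 0.4, "female", "male")
    prism = rng.poisson(12.0, n)
    nonpulm = np.minimum(rng.poisson(1.5, n), 5)
    cat = rng.choice(ETIOLOGY_CATEGORIES, size=n,
                     p=[0.55, 0.20, 0.10, 0.03, 0.12])
    direct = np.isin(cat, ["infectious pneumonia", "aspiration", "trauma"])
    infectious = np.isin(cat, ["infectious pneumonia", "nonpulmonary sepsis"])
    pf_onset = np.exp(np.log(150.0) + rng.normal(0, 0.4, n))
    oi_onset = np.exp(np.log(11.5) + rng.normal(0, 0.5, n))
    pf24_med = np.asarray(_per_subtype(_PF24_MEDIANS, k))[lab - 1]
    oi24_med = np.asarray(_per_subtype(_OI24_MEDIANS, k))[lab - 1]
    pf_24h = np.exp(np.log(pf24_med) + rng.normal(0, 0.35, n))
    oi_24h = np.exp(np.log(oi24_med) + rng.normal(0, 0.45, n))
    on_pressors = rng.random(n) < 0.6
    epi = np.where(on_pressors, rng.exponential(0.06, n), 0.0)
    dopa = np.where(rng.random(n) < 0.3, rng.exponential(4.0, n), 0.0)
    milr = np.where(rng.random(n) < 0.2, rng.exponential(0.4, n), 0.0)
    return pd.DataFrame({
        "subject_id": true_labels.index,
        "age": age,
        "sex": sex,
        "prism_iii": prism,
        "nonpulm_organ_failures": nonpulm,
        "immunocompromised": immuno,
        "stem_cell_transplant": sct,
        "etiology_direct": direct,
        "etiology_infectious": infectious,
        "etiology_category": cat,
        "anc": anc,
        "alc": alc,
        "pf_onset": pf_onset,
        "pf_24h": pf_24h,
        "oi_onset": oi_onset,
        "oi_24h": oi_24h,
        "dopamine": dopa,
        "dobutamine": 0.0,
        "epinephrine": epi,
        "norepinephrine": 0.0,
        "phenylephrine": 0.0,
        "milrinone": milr,
        "vasopressin": 0.0,
    })


def _truncated_exponential(rng, rate: float, upper: float, size: int):
    """Inverse-CDF draw from Exp(rate) truncated to (0, upper]."""
    u = rng.random(size)
    cdf_upper = -np.expm1(-rate * upper)
    return -np.log1p(-u * cdf_upper) / rate


def generate_outcomes(true_labels: pd.Series, config: SimulationConfig,
                      *, death_beta=None, death_covariates=None) -> EventHistory:
    """Competing-risk ventilation course per subject.

    Death by day 28 occurs with probability 1 - (1 - p_k)^exp(beta'x)
    (p_k the subtype's configured 28-day death probability; beta 0 unless
    ``death_beta``/``death_covariates`` are given), with death times from
    an exponential law truncated to (0, 28]. The remaining subjects draw
    extubation times from Exp(extubation_rate); times beyond day 28 leave
    the subject administratively censored while ventilated. A fraction of
    extubated survivors is re-intubated after a sustained (> 24 h) gap.
    """
    rng = config.rng("outcomes")
    lab = true_labels.to_numpy()
    n = len(lab)
    p_base = np.asarray(config.death_prob_28d)[lab - 1]
    if death_beta is None:
        p_death = p_base
    else:
        eta = np.asarray(death_covariates, dtype=float) @ np.asarray(death_beta)
        p_death = 1.0 - (1.0 - p_base) ** np.exp(eta)
    dies = rng.random(n) < p_death
    death_times = _truncated_exponential(rng, config.death_time_rate,
                                         FOLLOWUP_DAY, n)
    ext_times = rng.exponential(1.0 / config.extubation_rate, n)
    reintub = rng.random(n) < config.reintubation_prob
    gap = 1.0 + rng.exponential(2.0, n)     # always > 24 h: sustained liberation
    dur = rng.exponential(3.0, n)
    records = {}
    for i, sid in enumerate(true_labels.index):
        if dies[i]:
            t = float(death_times[i])
            records[sid] = EventRecord(sid, [(0.0, max(t, 1e-6))],
                                       death_day=t, picu_survivor=False)
        elif ext_times[i] >= FOLLOWUP_DAY:
            records[sid] = EventRecord(sid, [(0.0, FOLLOWUP_DAY)],
                                       death_day=None, picu_survivor=True)
        else:
            t = float(max(ext_times[i], 1e-6))
            intervals = [(0.0, t)]
            if reintub[i]:
                start = t + float(gap[i])
                if start < FOLLOWUP_DAY:
                    intervals.append((start, start + float(dur[i])))
            records[sid] = EventRecord(sid, intervals, death_day=None,
                                       picu_survivor=True)
    return EventHistory(records)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate expression, clinical and event tables sharing one ordered
    subject-ID set, plus the planted subtype labels."""
    expression, labels = generate_expression(config)
    clinical = generate_clinical(labels, config)
    events = generate_outcomes(labels, config)
    return SyntheticCohort(expression=expression, clinical=clinical,
                           events=events, true_labels=labels, config=config)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write the three tables plus a JSON sidecar echoing the config."""
    import json
    import pathlib

    from . import dataio

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataio.write_expression(cohort.expression, outdir / "expression.tsv")
    dataio.write_clinical(cohort.clinical, outdir / "clinical.csv")
    dataio.write_events(cohort.events, outdir / "events.csv")
    cohort.true_labels.rename_axis("subject_id").to_csv(
        outdir / "true_labels.csv")
    with open(outdir / "simulation_config.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def simulate_fine_gray_cohort(n: int, beta, *, p_base: float = 0.6,
                              rate: float = 0.10, horizon: float = FOLLOWUP_DAY,
                              competing_rate: float = 0.15, seed: int = 0,
                              covariate: str = "binary"):
    """Direct Fine-Gray simulation for parameter-recovery studies.

    The event of interest follows the proportional subdistribution-hazards
    model F1(t | x) = 1 - (1 - p_base (1 - exp(-rate t)))^exp(beta'x) (the
    standard indirect parameterization); subjects escaping event 1 receive
    the competing event at an Exp(competing_rate) time; everything is
    administratively censored at ``horizon``. Returns
    ``(times, events, X)`` with events coded 0/1/2.
    """
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = len(beta)
    if covariate == "binary":
        X = rng.binomial(1, 0.5, size=(n, p)).astype(float)
    elif covariate == "normal":
        X = rng.normal(0.0, 1.0, size=(n, p))
    else:
        raise ConfigError(f"unknown covariate kind {covariate!r}")
    expeta = np.exp(X @ beta)
    p_event1 = 1.0 - (1.0 - p_base) ** expeta
    u = rng.random(n)
    is1 = u < p_event1
    # conditional inverse-CDF for event-1 times given event 1 occurs
    v = rng.random(n)
    w = 1.0 - (1.0 - v * p_event1) ** (1.0 / expeta)
    t1 = -np.log1p(-np.clip(w / p_base, 0.0, 1.0 - 1e-12)) / rate
    t2 = rng.exponential(1.0 / competing_rate, n)
    times = np.where(is1, t1, t2)
    events = np.where(is1, 1, 2)
    censored = times > horizon
    times = np.minimum(times, horizon)
    events = np.where(censored, 0, events)
    times = np.maximum(times, 1e-9)
    return times, events, X
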
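"""Subtype-vs-clinical characterization statistics.

Categorical variables are compared across subtypes with the Freeman-Halton
generalization of Fisher's exact test (full enumeration of r x c tables
with the observed margins); continuous variables with the Kruskal-Wallis
rank test, reporting the rank-based eta-squared effect size; multiplicity
is controlled, where requested, with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .errors import DomainError

#: relative tolerance absorbing floating-point ties in the "probability at
#: most that of the observed table" comparison
_FH_REL_TOL = 1e-7


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None
    effect_size: float | None = None


def _table_log_prob_const(row_margins, col_margins, n):
    return (
        np.sum(gammaln(np.asarray(row_margins) + 1))
        + np.sum(gammaln(np.asarray(col_margins) + 1))
        - gammaln(n + 1)
    )


def _row_compositions(total, bounds):
    """All ways to split ``total`` over cells with per-cell upper bounds."""
    if len(bounds) == 1:
        if total <= bounds[0]:
            yield (total,)
        return
    lo = max(0, total - sum(bounds[1:]))
    hi = min(total, bounds[0])
    for first in range(lo, hi + 1):
        for rest in _row_compositions(total - first, bounds[1:]):
            yield (first, *rest)


def fisher_exact_rxc(counts, *, budget: int = 10_000_000) -> TestResult:
    """Freeman-Halton exact test for an r x c contingency table.

    The p-value is the total multivariate-hypergeometric probability of all
    tables sharing the observed margins whose probability does not exceed
    that of the observed table (up to a 1 + 1e-7 relative tolerance for
    floating-point ties). Enumeration is exact; ``budget`` caps the number
    of tables visited.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DomainError("contingency table must be at least 2 x 2")
    if np.any(counts < 0):
        raise DomainError("counts must be nonnegative")
    row_margins = counts.sum(axis=1)
    col_margins = counts.sum(axis=0)
    if np.any(row_margins == 0) or np.any(col_margins == 0):
        raise DomainError("degenerate table: a margin is zero")
    n = int(counts.sum())
    const = _table_log_prob_const(row_margins, col_margins, n)

    def log_prob(cells_gammaln_sum):
        return const - cells_gammaln_sum

    obs_logp = log_prob(float(np.sum(gammaln(counts + 1))))
    cutoff = obs_logp + np.log1p(_FH_REL_TOL)

    r = counts.shape[0]
    visited = 0
    total_p = 0.0

    def recurse(row_idx, col_remaining, acc_gammaln):
        nonlocal visited, total_p
        if row_idx == r - 1:
            # last row forced by the remaining column margins
            visited += 1
            if visited > budget:
                raise DomainError(
                    f"enumeration budget {budget} exceeded; consider a "
                    "Monte-Carlo approximation for this table"
                )
            lp = log_prob(acc_gammaln + float(np.sum(gammaln(col_remaining + 1))))
            if lp <= cutoff:
                total_p += np.exp(lp)
            return
        for row in _row_compositions(int(row_margins[row_idx]),
                                     tuple(int(c) for c in col_remaining)):
            row_arr = np.asarray(row)
            recurse(
                row_idx + 1,
                col_remaining - row_arr,
                acc_gammaln + float(np.sum(gammaln(row_arr + 1))),
            )

    recurse(0, col_margins.copy(), 0.0)
    return TestResult(statistic=float(np.exp(obs_logp)),
                      p_value=float(min(total_p, 1.0)))


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected) with rank-based eta-squared."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise DomainError("kruskal_wallis requires >= 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise DomainError("every group must be non-empty")
    if np.all(values == values[0]):
        # all observations identical: no evidence of any group effect
        return TestResult(statistic=0.0, p_value=1.0, df=len(labels) - 1,
                          effect_size=0.0)
    h, p = sps.kruskal(*samples)
    k = len(labels)
    n = len(values)
    eff = eta_squared(values, groups) if n > k else None
    return TestResult(statistic=float(h), p_value=float(p), df=k - 1,
                      effect_size=eff)


def eta_squared(values, groups, *, method: str = "rank") -> float:
    """Effect size for a k-group comparison, in [0, 1].

    ``method="rank"`` (default) gives the rank-based eta-squared
    eta2_H = (H - k + 1) / (n - k), floored at 0, consistent with
    Kruskal-Wallis testing; ``method="anova"`` gives the classical
    between/total sum-of-squares ratio.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = len(labels)
    n = len(values)
    if k < 2:
        raise DomainError("eta_squared requires >= 2 groups")
    if n <= k:
        raise DomainError(f"need n > k groups, got n={n}, k={k}")
    samples = [values[groups == g] for g in labels]
    if method == "rank":
        if np.all(values == values[0]):
            return 0.0
        h, _ = sps.kruskal(*samples)
        return float(max(0.0, (h - k + 1) / (n - k)))
    if method == "anova":
        grand = values.mean()
        ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ss_total = float(np.sum((values - grand) ** 2))
        return float(ss_between / ss_total) if ss_total > 0 else 0.0
    raise DomainError(f"unknown eta_squared method {method!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up: enforce monotonicity from the largest p downward
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Table-1-style characterization


def _fmt_median_iqr(x) -> str:
    x = np.asarray(x, dtype=float)
    med, lo, hi = np.percentile(x, [50, 25, 75])
    return f"{med:g} [{lo:g}, {hi:g}]"


def characterize(clinical: pd.DataFrame, labels: pd.Series,
                 continuous: list[str] | None = None,
                 categorical: list[str] | None = None) -> pd.DataFrame:
    """Summarize clinical variables by subtype, demographics-table style.

    Continuous rows report median [IQR] per subtype with the
    Kruskal-Wallis p-value and rank eta-squared; categorical (boolean)
    rows report n (%) per subtype with the Freeman-Halton Fisher p-value.
    ``labels`` must be indexed by subject_id.
    """
    if continuous is None:
        continuous = ["age", "prism_iii", "nonpulm_organ_failures", "anc",
                      "alc", "pf_onset", "pf_24h", "oi_onset", "oi_24h"]
    if categorical is None:
        categorical = ["immunocompromised", "stem_cell_transplant",
                       "etiology_direct", "etiology_infectious"]
    df = clinical.set_index("subject_id").loc[labels.index]
    grp = labels.to_numpy()
    subtype_levels = sorted(pd.unique(grp))
    rows = []
    for var in continuous:
        vals = df[var].to_numpy(dtype=float)
        res = kruskal_wallis(vals, grp)
        row = {"variable": var, "kind": "continuous",
               "p_value": res.p_value, "effect_size": res.effect_size}
        for lev in subtype_levels:
            row[f"subtype_{lev}"] = _fmt_median_iqr(vals[grp == lev])
        rows.append(row)
    for var in categorical:
        flags = df[var].astype(bool).to_numpy()
        counts = np.array([
            [int(flags[grp == lev].sum()) for lev in subtype_levels],
            [int((~flags[grp == lev]).sum()) for lev in subtype_levels],
        ])
        if counts.sum(axis=1).min() == 0:
            p_cat = float("nan")  # variable constant across the cohort
        else:
            p_cat = fisher_exact_rxc(counts).p_value
        row = {"variable": var, "kind": "categorical",
               "p_value": p_cat, "effect_size": None}
        for j, lev in enumerate(subtype_levels):
            n_lev = counts[:, j].sum()
            row[f"subtype_{lev}"] = f"{counts[0, j]} ({100 * counts[0, j] / n_lev:.0f}%)"
        rows.append(row)
    return pd.DataFrame(rows)
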
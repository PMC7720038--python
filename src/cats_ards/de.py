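"""Subtype gene-signature extraction.

The pipeline mirrors the classical microarray gating sequence: quantile
normalization, an expression filter (value >= 10 in >= 10 samples), a
one-vs-rest per-gene test on the log2-scale values, and twofold /
FDR-q < 0.1 gates on the resulting fold changes. The per-gene test is a
Welch two-sample t; fold changes are mean differences on the log2 scale,
so "twofold" means |log2FC| >= 1 (boundary inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataio import ExpressionMatrix
from .errors import DomainError
from .stats import bh_adjust

DEFAULT_MIN_VALUE = 10.0
DEFAULT_MIN_SAMPLES = 10
DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_Q_THRESHOLD = 0.1


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample's value distribution onto the mean of the
    per-sample sorted vectors.

    After the operation all columns share an identical sorted vector;
    within-column rank ties receive the mean of the tied quantile
    targets. Idempotent.
    """
    values = matrix.values
    n_genes = values.shape[0]
    sorted_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        ranks = sps.rankdata(values[:, j], method="average")  # 1..n, ties averaged
        # average ranks may be half-integers: interpolate between targets
        out[:, j] = np.interp(ranks, np.arange(1, n_genes + 1), sorted_means)
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), out)


def filter_expressed(matrix: ExpressionMatrix,
                     min_value: float = DEFAULT_MIN_VALUE,
                     min_samples: int = DEFAULT_MIN_SAMPLES) -> list[str]:
    """Genes expressed at >= ``min_value`` in >= ``min_samples`` samples."""
    if min_value < 0 or min_samples < 0:
        raise DomainError("filter thresholds must be >= 0")
    keep = (matrix.values >= min_value).sum(axis=1) >= min_samples
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


def de_one_vs_rest(matrix: ExpressionMatrix, labels, subtype) -> pd.DataFrame:
    """Per-gene Welch t contrast of one subtype against all others.

    ``labels`` is aligned with ``matrix.sample_ids``. Returns a DataFrame
    with gene_id, log2_fold_change (subtype mean minus rest mean),
    statistic, p_value and BH q_value across the genes tested.
    """
    labels = np.asarray(labels)
    if len(labels) != matrix.n_samples:
        raise DomainError("labels must align with matrix samples")
    in_grp = labels == subtype
    if in_grp.sum() < 2 or (~in_grp).sum() < 2:
        raise DomainError(
            f"subtype {subtype!r} and its complement each need >= 2 samples")
    a = matrix.values[:, in_grp]
    b = matrix.values[:, ~in_grp]
    stat, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes carry no evidence
    stat = np.where(np.isnan(stat), 0.0, stat)
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "log2_fold_change": lfc,
        "statistic": stat,
        "p_value": p,
        "q_value": bh_adjust(p),
    })


def select_degs(results: pd.DataFrame,
                fc_threshold: float = DEFAULT_FC_THRESHOLD,
                q_threshold: float = DEFAULT_Q_THRESHOLD):
    """Split significant genes into up- and downregulated lists.

    up:   q < q_threshold and log2FC >= +log2(fc_threshold)
    down: q < q_threshold and log2FC <= -log2(fc_threshold)
    """
    if len(results) == 0:
        return [], []
    log_fc = np.log2(fc_threshold)
    sig = results["q_value"] < q_threshold
    up = results.loc[sig & (results["log2_fold_change"] >= log_fc), "gene_id"]
    down = results.loc[sig & (results["log2_fold_change"] <= -log_fc), "gene_id"]
    return list(up), list(down)


def de_all_subtypes(matrix: ExpressionMatrix, labels,
                    fc_threshold: float = DEFAULT_FC_THRESHOLD,
                    q_threshold: float = DEFAULT_Q_THRESHOLD,
                    min_value: float = DEFAULT_MIN_VALUE,
                    min_samples: int = DEFAULT_MIN_SAMPLES) -> dict:
    """Filter, contrast every subtype one-vs-rest, and gate the results."""
    kept = filter_expressed(matrix, min_value, min_samples)
    sub = matrix.subset_genes(kept)
    out = {}
    for subtype in sorted(pd.unique(np.asarray(labels))):
        res = de_one_vs_rest(sub, labels, subtype)
        up, down = select_degs(res, fc_threshold, q_threshold)
        res = res.copy()
        res["direction"] = np.where(
            res["gene_id"].isin(up), "up",
            np.where(res["gene_id"].isin(down), "down", "ns"))
        out[int(subtype)] = res
    return out
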
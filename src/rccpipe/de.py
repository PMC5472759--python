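"""Normalization and differential expression.

Counts are upper-quartile normalized (each sample scaled so the 75th
percentile of its nonzero counts equals the across-sample mean of those
percentiles), log2-transformed with a pseudocount, and compared between two
groups with a Welch two-sample t-test.  Genes are called differentially
expressed when they change more than two-fold and survive Benjamini-
Hochberg control of the false discovery rate at 5% — thresholds are
configurable but those are the defaults used throughout.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .types import COUNTS, LOG2, ExpressionMatrix


def upper_quartile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample so its nonzero-count upper quartile is constant.

    The common target is the across-sample mean of the per-sample 75th
    percentiles of nonzero counts, which makes the operation idempotent.
    Within-sample gene ordering is unchanged (pure rescaling).
    """
    if m.scale != COUNTS:
        raise ValidationError("upper-quartile normalization expects counts")
    values = m.values
    uq = np.empty(values.shape[1])
    for j, sample in enumerate(m.sample_ids):
        nonzero = values[:, j][values[:, j] > 0]
        if nonzero.size == 0:
            raise ValidationError(f"sample {sample!r} has no nonzero counts")
        uq[j] = np.percentile(nonzero, 75)
    target = uq.mean()
    scaled = values * (target / uq)
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=m.gene_ids, columns=m.sample_ids), COUNTS
    )


def log2_with_pseudocount(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """value -> log2(value + pseudocount); retags the matrix as log2 scale."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if (m.values < 0).any():
        raise ValidationError("log transform expects non-negative input")
    return ExpressionMatrix(
        pd.DataFrame(
            np.log2(m.values + pseudocount), index=m.gene_ids, columns=m.sample_ids
        ),
        LOG2,
    )


def median_center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's across-sample median; idempotent."""
    centred = m.data.sub(m.data.median(axis=1), axis=0)
    return ExpressionMatrix(centred, m.scale)


def _check_groups(m: ExpressionMatrix, group1: Sequence[str], group2: Sequence[str]) -> None:
    overlap = set(group1) & set(group2)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)}")
    if len(group1) < 2 or len(group2) < 2:
        raise ValidationError("each group needs at least 2 samples")
    missing = [s for s in [*group1, *group2] if s not in m.data.columns]
    if missing:
        raise ValidationError(f"unknown sample identifiers: {missing}")


def _welch(
    m: ExpressionMatrix, group1: Sequence[str], group2: Sequence[str]
) -> pd.DataFrame:
    """Welch t (group2 minus group1), degrees of freedom and two-sided p.

    Degenerate genes: both groups constant with equal means -> t=0, p=1;
    constant with unequal means -> t=+/-inf, p=0.
    """
    _check_groups(m, group1, group2)
    x = m.data[list(group1)].to_numpy()
    y = m.data[list(group2)].to_numpy()
    n1, n2 = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se2 = vx / n1 + vy / n2
    diff = my - mx
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((vx / n1) ** 2 / (n1 - 1) + (vy / n2) ** 2 / (n2 - 1))
    zero_se = se2 == 0
    t[zero_se & (diff == 0)] = 0.0
    t[zero_se & (diff > 0)] = np.inf
    t[zero_se & (diff < 0)] = -np.inf
    df[zero_se] = n1 + n2 - 2
    p = np.where(
        np.isinf(t), 0.0, 2 * scipy.stats.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df)
    )
    p[zero_se & (diff == 0)] = 1.0
    return pd.DataFrame(
        {"t": t, "df": df, "p": p, "log2fc": diff}, index=m.gene_ids
    )


def welch_t(
    m: ExpressionMatrix, group1: Sequence[str], group2: Sequence[str]
) -> pd.Series:
    """Per-gene Welch (unequal-variance) t-statistic, group2 minus group1."""
    return _welch(m, group1, group2)["t"]


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    m: ExpressionMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    fc_threshold: float = 2.0,
    fdr: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-fold / FDR differential-expression calls between two groups.

    Counts-scale input is upper-quartile normalized and log2(x+pseudocount)
    transformed first; log2 input is used as-is.  The fold-change filter is
    applied to the difference of group means on the log2 scale
    (|log2fc| > log2(fc_threshold)); significance is the BH-adjusted Welch
    two-sided p below ``fdr``.  Returns a per-gene table with columns
    log2fc, t, p, q and call in {up, down, none}.
    """
    if fc_threshold <= 0:
        raise ValidationError("fc_threshold must be positive")
    if m.scale == COUNTS:
        m = log2_with_pseudocount(upper_quartile_normalize(m), pseudocount)
    stats = _welch(m, group1, group2)
    q = bh_adjust(stats["p"].to_numpy())
    lfc_cut = math.log2(fc_threshold)
    call = np.full(len(stats), "none", dtype=object)
    call[(stats["log2fc"].to_numpy() > lfc_cut) & (q < fdr)] = "up"
    call[(stats["log2fc"].to_numpy() < -lfc_cut) & (q < fdr)] = "down"
    return pd.DataFrame(
        {
            "log2fc": stats["log2fc"],
            "t": stats["t"],
            "p": stats["p"],
            "q": q,
            "call": call,
        },
        index=stats.index,
    )


def overlap_counts(
    a_up: Iterable[str],
    a_down: Iterable[str],
    b_up: Iterable[str],
    b_down: Iterable[str],
) -> pd.DataFrame:
    """Venn counts of two up/down DE gene lists.

    Rows ``up`` and ``down``; columns ``both``, ``a_only``, ``b_only``.
    A gene present in both the up and down list of one comparison is a
    validation error.
    """
    a_up, a_down = set(a_up), set(a_down)
    b_up, b_down = set(b_up), set(b_down)
    for label, up, down in (("a", a_up, a_down), ("b", b_up, b_down)):
        clash = up & down
        if clash:
            raise ValidationError(
                f"list {label}: genes in both up and down: {sorted(clash)[:5]}"
            )
    rows = {}
    for direction, a, b in (("up", a_up, b_up), ("down", a_down, b_down)):
        rows[direction] = {
            "both": len(a & b),
            "a_only": len(a - b),
            "b_only": len(b - a),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def top_variable_genes(m: ExpressionMatrix, fraction: float) -> list[str]:
    """Top ceil(fraction*N) genes by across-sample variance, ties by id."""
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    if m.shape[0] == 0:
        raise ValidationError("empty expression matrix")
    var = m.data.var(axis=1, ddof=1)
    order = (
        pd.DataFrame({"var": var, "gene": var.index})
        .sort_values(["var", "gene"], ascending=[False, True], kind="mergesort")
        .index
    )
    k = math.ceil(fraction * m.shape[0])
    return list(order[:k])
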
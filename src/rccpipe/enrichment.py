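"""Ranked-list gene-set analysis and per-sample signature activation calls.

The procedure: rank all genes by the between-group Welch t-statistic; for
each gene set, test whether its members' (normalized) ranks are uniformly
distributed along the list with a one-sample two-sided Kolmogorov-Smirnov
statistic; control the K-S p-values across sets with Benjamini-Hochberg at
5% FDR; then rank the surviving sets by the area under the set-recovery
curve restricted to the top 10% of the list (normalized so a set wholly at
the very top scores close to 1, and random placement scores about
fraction/2).  Sets with a normalized partial AUC above 0.25 are flagged as
top signatures.

Signature activation: a per-sample score is the mean of the gene-wise
median-centred log2 values over the signature's genes; the score is
standardized across the cohort and samples more than 1 s.d. above the mean
(z > 1) are called activated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .de import bh_adjust, median_center_genes, welch_t
from .errors import EmptySetError, ValidationError
from .types import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("rccpipe")

# exact K-S null up to this many set members, asymptotic Kolmogorov beyond
_EXACT_KS_MAX = 35


@dataclass
class RankedList:
    """Genes ordered by descending t-statistic (ties: lexicographic by id)."""

    genes: list[str]
    t: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.t):
            raise ValidationError("genes and t-statistics differ in length")
        if np.isnan(self.t).any():
            raise ValidationError("ranked list contains NaN t-statistics")
        if (np.diff(self.t) > 0).any():
            raise ValidationError("t-statistics must be non-increasing")

    @property
    def N(self) -> int:
        return len(self.genes)

    def ranks_of(self, set_genes: Iterable[str]) -> np.ndarray:
        """1-based positions of the set members present in the list."""
        index = {g: i + 1 for i, g in enumerate(self.genes)}
        return np.sort([index[g] for g in set_genes if g in index])


def rank_by_t(t: pd.Series) -> RankedList:
    """Order genes by descending t; exact ties broken by gene identifier."""
    if t.isna().any():
        bad = t.index[t.isna()][0]
        raise ValidationError(f"missing t-statistic for gene {bad!r}")
    frame = pd.DataFrame({"t": t.to_numpy(), "gene": t.index.astype(str)})
    frame = frame.sort_values(["t", "gene"], ascending=[False, True], kind="mergesort")
    return RankedList(list(frame["gene"]), frame["t"].to_numpy())


def ks_uniformity(r: RankedList, set_genes: Iterable[str]) -> tuple[float, float]:
    """Two-sided one-sample K-S of member ranks against Uniform(0,1).

    Member ranks r_i map to u_i = r_i / N.  D is the supremum gap between
    the empirical CDF of {u_i} and the uniform CDF.  The p-value uses the
    exact two-sided null for m <= 35 members and the asymptotic Kolmogorov
    distribution beyond.
    """
    ranks = r.ranks_of(set_genes)
    m = ranks.size
    if m == 0:
        raise EmptySetError("no set genes present in the ranked list")
    u = ranks / r.N
    i = np.arange(1, m + 1)
    d_plus = np.max(i / m - u)
    d_minus = np.max(u - (i - 1) / m)
    d = max(d_plus, d_minus, 0.0)
    if m > _EXACT_KS_MAX:
        p = float(scipy.special.kolmogorov(math.sqrt(m) * d))
    else:
        p = float(scipy.stats.kstwo.sf(d, m))
    return float(d), min(max(p, 0.0), 1.0)


def partial_auc_top(
    r: RankedList, set_genes: Iterable[str], fraction: float = 0.10
) -> float:
    """Normalized area under the set-recovery curve over the top of the list.

    Walking positions j = 1..k (k = ceil(fraction*N)), the recovery at j is
    the fraction of the set's in-list members seen so far; the score is the
    mean recovery over the k positions, i.e. the step-function area on a
    unit square.  Range [0,1]; under random placement the expectation is
    about fraction/2.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    ranks = r.ranks_of(set_genes)
    m = ranks.size
    if m == 0:
        raise EmptySetError("no set genes present in the ranked list")
    k = math.ceil(fraction * r.N)
    hits = np.zeros(k)
    in_top = ranks[ranks <= k]
    np.add.at(hits, in_top - 1, 1)
    tpr = np.cumsum(hits) / m
    return float(tpr.mean())


def enrich(
    m: ExpressionMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    collection: GeneSetCollection,
    fdr: float = 0.05,
    fraction: float = 0.10,
    auc_min: float = 0.25,
    direction: str = "up",
) -> pd.DataFrame:
    """Full gene-set analysis between two sample groups.

    Ranks genes by Welch t (group2 vs group1; ``direction="down"`` flips
    the ranking for the opposite contrast), applies the K-S uniformity test
    per set, BH-adjusts across all tested sets, and computes the top-
    fraction partial AUC for every set.  Output rows are sorted with
    K-S-passing sets first, by descending partial AUC.  Sets with no genes
    in the matrix are reported with n_in_list=0 and no statistics.
    """
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    t = welch_t(m, group1, group2)
    if direction == "down":
        t = -t
    ranked = rank_by_t(t)
    names, n_in, ds, ps, aucs = [], [], [], [], []
    for s in collection:
        ranks = ranked.ranks_of(s.genes)
        names.append(s.name)
        n_in.append(int(ranks.size))
        if ranks.size == 0:
            ds.append(np.nan)
            ps.append(np.nan)
            aucs.append(np.nan)
            continue
        d, p = ks_uniformity(ranked, s.genes)
        ds.append(d)
        ps.append(p)
        aucs.append(partial_auc_top(ranked, s.genes, fraction))
    result = pd.DataFrame(
        {"n_in_list": n_in, "D": ds, "p_ks": ps, "auc_top": aucs}, index=names
    )
    tested = result["p_ks"].notna()
    q = np.full(len(result), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_adjust(result.loc[tested, "p_ks"].to_numpy())
    result["q_ks"] = q
    result["pass_ks"] = (result["q_ks"] < fdr).fillna(False)
    result["pass_auc"] = (result["auc_top"] > auc_min).fillna(False)
    result = result.sort_values(
        ["pass_ks", "auc_top"], ascending=[False, False], kind="mergesort"
    )
    return result[["n_in_list", "D", "p_ks", "q_ks", "auc_top", "pass_ks", "pass_auc"]]


def signature_scores(
    m: ExpressionMatrix,
    signature: Iterable[str],
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-sample signature score, cohort z-score and activation call.

    Raw score: mean of the gene-wise median-centred values over the
    signature genes present in the matrix.  z standardizes the raw scores
    across the cohort (sample s.d.); a sample is activated when z exceeds
    ``threshold`` (default 1 s.d. above the cohort mean).  A zero-variance
    cohort yields all z = 0 and no activations, with a warning.
    """
    signature = list(signature)
    present = [g for g in signature if g in m.data.index]
    if not present:
        raise EmptySetError("no signature genes present in the matrix")
    if len(present) < len(signature):
        logger.warning(
            "signature: %d of %d genes absent from matrix",
            len(signature) - len(present),
            len(signature),
        )
    centred = median_center_genes(m.subset_genes(present))
    raw = centred.data.mean(axis=0)
    sd = raw.std(ddof=1) if len(raw) > 1 else 0.0
    if sd == 0 or np.isnan(sd):
        logger.warning("signature score cohort has zero variance; no activations")
        z = pd.Series(0.0, index=raw.index)
    else:
        z = (raw - raw.mean()) / sd
    return pd.DataFrame(
        {"raw": raw, "z": z, "activated": z > threshold}, index=raw.index
    )
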
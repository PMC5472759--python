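"""Cross-species transcriptome comparison by centroid correlation.

Mouse expression is mapped onto human gene space through a homolog table
(strict 1:1 pairs only), dataset-constant offsets are removed by per-cohort
gene-wise median centring, cohort centroids are the per-gene median over the
cohort's samples, and cohorts are compared by the Pearson correlation of
their centroids.  Co-clustering uses average-linkage agglomeration on
1 - centred Pearson correlation between samples over a high-variance gene
filter.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .de import median_center_genes, top_variable_genes
from .errors import NoOverlapError, UndefinedCorrelationError, ValidationError
from .types import ExpressionMatrix, HomologMap

logger = logging.getLogger("rccpipe")


def collapse_homologs(m: ExpressionMatrix, hmap: HomologMap) -> ExpressionMatrix:
    """Rename source-species genes to their 1:1 homolog target identifiers.

    Only pairs whose source and target each occur exactly once in the map
    are used; genes without a usable pair are dropped (count logged).  An
    empty result raises ``NoOverlapError``.
    """
    usable = {s: t for s, t in hmap.one_to_one()}
    keep = [g for g in m.gene_ids if g in usable]
    if not keep:
        raise NoOverlapError("no matrix gene has a 1:1 homolog in the map")
    dropped = len(m.gene_ids) - len(keep)
    if dropped:
        logger.info("homolog collapse dropped %d genes without a 1:1 pair", dropped)
    data = m.data.loc[keep].copy()
    data.index = [usable[g] for g in keep]
    return ExpressionMatrix(data, m.scale)


def adjust_batches(cohorts: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Remove cohort-constant offsets and concatenate cohorts.

    Each gene is median-centred within each cohort, so every gene's
    within-cohort median is 0 afterwards; any expression shift constant
    within a cohort (e.g. a species- or platform-wide offset) is removed
    exactly.  All cohorts must share the same gene space.
    """
    if not cohorts:
        raise ValidationError("no cohorts given")
    reference = set(cohorts[0].gene_ids)
    for c in cohorts[1:]:
        missing = reference.symmetric_difference(c.gene_ids)
        if missing:
            raise ValidationError(
                f"gene-space mismatch between cohorts: {sorted(missing)[:10]}"
            )
    centred = [median_center_genes(c).data.loc[cohorts[0].gene_ids] for c in cohorts]
    combined = pd.concat(centred, axis=1)
    if combined.columns.duplicated().any():
        dupes = combined.columns[combined.columns.duplicated()]
        raise ValidationError(f"duplicate sample identifiers across cohorts: {list(dupes[:5])}")
    return ExpressionMatrix(combined, cohorts[0].scale)


def centroid(m: ExpressionMatrix, cohort_samples: Sequence[str]) -> pd.Series:
    """Per-gene median over a sample cohort (even size: midpoint of the two)."""
    if len(cohort_samples) == 0:
        raise ValidationError("empty cohort")
    missing = [s for s in cohort_samples if s not in m.data.columns]
    if missing:
        raise ValidationError(f"unknown samples: {missing[:5]}")
    return m.data[list(cohort_samples)].median(axis=1)


def centroid_correlations(
    a: Mapping[str, pd.Series], b: Mapping[str, pd.Series]
) -> pd.DataFrame:
    """Pearson correlation between every centroid in ``a`` and in ``b``.

    Centroids are aligned on their shared gene space; a zero-variance
    centroid makes the correlation undefined and raises.
    """
    if not a or not b:
        raise ValidationError("centroid collections must be non-empty")
    shared = None
    for name, c in {**dict(a), **dict(b)}.items():
        shared = c.index if shared is None else shared.intersection(c.index)
    if shared is None or len(shared) < 2:
        raise NoOverlapError("fewer than 2 genes shared across centroids")
    out = pd.DataFrame(index=list(a), columns=list(b), dtype=float)
    vectors_a = {k: v.loc[shared].to_numpy() for k, v in a.items()}
    vectors_b = {k: v.loc[shared].to_numpy() for k, v in b.items()}
    for name, v in {**vectors_a, **vectors_b}.items():
        if np.std(v) == 0:
            raise UndefinedCorrelationError(
                f"centroid {name!r} has zero variance over the shared genes"
            )
    for ka, va in vectors_a.items():
        for kb, vb in vectors_b.items():
            out.loc[ka, kb] = np.corrcoef(va, vb)[0, 1]
    return out


def average_linkage_cluster(
    m: ExpressionMatrix,
    gene_filter_fraction: float = 1.0,
    n_clusters: int = 2,
) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage clustering of samples on centred correlation distance.

    Genes are filtered to the top ``gene_filter_fraction`` by across-sample
    variance; the sample-sample distance is 1 - Pearson correlation (which
    centres each profile).  Returns the scipy linkage matrix and flat
    cluster labels from cutting the tree at ``n_clusters``.
    """
    if m.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    genes = top_variable_genes(m, gene_filter_fraction)
    x = m.data.loc[genes].to_numpy().T  # samples x genes
    sd = x.std(axis=1)
    if (sd == 0).any():
        # constant samples have undefined correlation; treat them as
        # zero-distance to each other and maximal to varying samples
        corr = np.ones((x.shape[0], x.shape[0]))
        ok = sd > 0
        if ok.any():
            corr_ok = np.corrcoef(x[ok])
            corr[np.ix_(ok, ok)] = corr_ok
            corr[np.ix_(ok, ~ok)] = 0.0
            corr[np.ix_(~ok, ok)] = 0.0
    else:
        corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    labels = sch.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return linkage, pd.Series(labels, index=m.sample_ids, name="cluster")
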
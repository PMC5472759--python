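"""Gene-level copy-number summaries and minimal-common-region extraction.

Copy values are on the segmented-copy scale (diploid ~ 2).  A sample is
"altered" at a region when its copy value crosses the threshold in the
stated direction at the region's peak gene (the gene with the extreme
cohort mean, which anchors the region so multi-peak chromosomes do not
conflate).  Each altered sample contributes its maximal run of consecutive
genes beyond threshold containing that peak; the minimal common region
(MCR) is the intersection of those runs — the genes altered in every
altered sample, i.e. the candidate drivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoSignalError, ValidationError
from .types import CopyNumberTable

logger = logging.getLogger("rccpipe")


def mean_gene_cn(table: CopyNumberTable) -> pd.DataFrame:
    """Per-gene mean copy value across samples, ordered by genomic position.

    Missing values are ignored within a gene; genes with all values missing
    are excluded with a warning.  Columns: chromosome, start, end, mean.
    """
    table = table.sorted_by_position()
    means = table.values.mean(axis=1, skipna=True)
    dropped = means.index[means.isna()]
    if len(dropped):
        logger.warning(
            "excluding %d genes with all-missing copy values: %s",
            len(dropped),
            list(dropped[:5]),
        )
    out = table.positions.copy()
    out["mean"] = means
    return out[out["mean"].notna()]


@dataclass
class MCRResult:
    """Outcome of minimal-common-region extraction."""

    genes: list[str]
    chromosome: str | None
    peak_gene: str | None
    altered_samples: list[str]
    sample_runs: dict[str, tuple[str, str]] = field(default_factory=dict)
    diagnostics: str = ""

    @property
    def empty(self) -> bool:
        return not self.genes


def _beyond(values: np.ndarray, direction: str, threshold: float) -> np.ndarray:
    return values > threshold if direction == "gain" else values < threshold


def minimal_common_region(
    table: CopyNumberTable, direction: str, threshold: float
) -> MCRResult:
    """Intersection of per-sample altered runs around the cohort peak gene.

    ``direction`` is "gain" (values above ``threshold``) or "loss" (below).
    The peak is the gene with the maximum (gain) or minimum (loss) cohort
    mean.  Altered samples are those beyond threshold at the peak gene; a
    sample altered elsewhere on the peak's chromosome but not at the peak
    contributes no run, which empties the intersection and is reported in
    the diagnostics rather than raised.
    """
    if direction not in ("gain", "loss"):
        raise ValidationError("direction must be 'gain' or 'loss'")
    table = table.sorted_by_position()
    matrix = table.values.to_numpy()
    any_beyond = _beyond(matrix, direction, threshold)
    altered_mask = any_beyond.any(axis=0)
    if not altered_mask.any():
        raise NoSignalError(
            f"no sample has a gene beyond threshold {threshold} ({direction})"
        )
    means = np.nanmean(matrix, axis=1)
    peak_idx = int(np.argmax(means) if direction == "gain" else np.argmin(means))
    genes = table.gene_ids
    peak_gene = genes[peak_idx]
    chrom = str(table.positions["chromosome"].iloc[peak_idx])
    on_chrom = (table.positions["chromosome"].astype(str) == chrom).to_numpy()
    chrom_idx = np.where(on_chrom)[0]
    peak_pos = int(np.where(chrom_idx == peak_idx)[0][0])

    samples = table.sample_ids
    chrom_beyond = any_beyond[on_chrom, :]
    altered_cols = [j for j in range(len(samples)) if chrom_beyond[:, j].any()]
    altered_samples = [samples[j] for j in altered_cols]
    runs: dict[str, tuple[int, int]] = {}
    missing_peak: list[str] = []
    for j in altered_cols:
        sample = samples[j]
        beyond = chrom_beyond[:, j]
        if not beyond[peak_pos]:
            missing_peak.append(sample)
            continue
        lo = peak_pos
        while lo > 0 and beyond[lo - 1]:
            lo -= 1
        hi = peak_pos
        while hi < beyond.size - 1 and beyond[hi + 1]:
            hi += 1
        runs[sample] = (lo, hi)
    sample_runs = {
        s: (genes[chrom_idx[lo]], genes[chrom_idx[hi]]) for s, (lo, hi) in runs.items()
    }
    if not runs and not missing_peak:
        diag = f"no altered samples on chromosome {chrom!r} of peak gene {peak_gene!r}"
        logger.warning(diag)
        return MCRResult([], chrom, peak_gene, altered_samples, {}, diag)
    if missing_peak:
        diag = (
            f"{len(missing_peak)} altered sample(s) not altered at peak gene "
            f"{peak_gene!r}: {missing_peak[:5]}; intersection empty"
        )
        logger.warning(diag)
        return MCRResult([], chrom, peak_gene, altered_samples, sample_runs, diag)
    lo = max(r[0] for r in runs.values())
    hi = min(r[1] for r in runs.values())
    mcr_genes = [genes[i] for i in chrom_idx[lo : hi + 1]]
    return MCRResult(mcr_genes, chrom, peak_gene, altered_samples, sample_runs)


def percentile_rank(region_means: pd.Series, query: str) -> float:
    """Fraction of the other region genes with mean strictly below the query.

    ``region_means`` maps gene id to its cohort mean copy value within a
    region of at least two genes.  Returns a value in [0, 1]; all-equal
    means give 0 by the strict comparison.
    """
    if query not in region_means.index:
        raise ValidationError(f"query gene {query!r} not in region")
    if len(region_means) < 2:
        raise ValidationError("region must contain at least 2 genes")
    others = region_means.drop(query)
    return float((others < region_means[query]).mean())
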
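"""Synthetic cohorts with the statistical structure the analyses assume.

Each generator emulates one input class of the pipeline:

* two-group RNA-seq count matrices (negative-binomial counts, log-normal
  library sizes, one planted up-shifted gene list) for normalization/DE;
* a gene-set cohort (Gaussian log2 values, disjoint sets, one set shifted
  in group 2) for the ranked-list enrichment procedure;
* two species sharing latent subtype centroids with species-constant
  offsets and a partly non-1:1 homolog map, for centroid correlation;
* a copy-number cohort with a planted focal amplicon whose intersection
  across altered samples is the recoverable minimal common region, plus an
  extra-gained driver gene;
* exponential survival times whose hazard depends on genotype class, with
  independent exponential censoring and stage/grade covariates associated
  with genotype.

Every generator is deterministic given the spec's seed and returns a truth
object sufficient to score downstream recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import (
    COUNTS,
    LOG2,
    CopyNumberTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    HomologMap,
)

__all__ = [
    "SimulationSpec",
    "simulate_two_group_counts",
    "simulate_gene_set_cohort",
    "simulate_cross_species",
    "simulate_copy_number",
    "simulate_survival",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Shared knobs for the synthetic cohorts.

    ``dispersion`` is the negative-binomial overdispersion (variance
    mu + dispersion * mu^2); ``effect_log2fc`` is the shift applied to the
    planted signal genes (log2 fold change for counts, s.d. units for the
    Gaussian gene-set cohort); ``hazard_ratios`` maps genotype labels to
    multiplicative hazards against the baseline.
    """

    n_genes: int = 5000
    n_samples_per_group: int = 10
    seed: int = 0
    dispersion: float = 0.1
    base_mean: float = 100.0
    effect_log2fc: float = 1.0
    signal_set_size: int = 100
    censor_rate: float = 0.2
    hazard_ratios: Mapping[str, float] = field(
        default_factory=lambda: {"V": 1.0, "VM": 2.0, "VIM": 3.0}
    )

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ValidationError("n_genes and n_samples_per_group must be positive")
        if self.signal_set_size <= 0:
            raise ValidationError("signal_set_size must be positive")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if self.base_mean <= 0:
            raise ValidationError("base_mean must be positive")
        if not 0 <= self.censor_rate <= 1:
            raise ValidationError("censor_rate must lie in [0, 1]")
        if any(h <= 0 for h in self.hazard_ratios.values()):
            raise ValidationError("hazard ratios must be positive")

    def with_seed(self, seed: int) -> "SimulationSpec":
        return replace(self, seed=seed)


def _gene_ids(n: int, prefix: str = "gene") -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n: int, prefix: str) -> list[str]:
    return [f"{prefix}{i}" for i in range(1, n + 1)]


def simulate_two_group_counts(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, list[str]]:
    """Negative-binomial count matrix with a planted up-shifted gene list.

    Counts for gene g, sample s are gamma-Poisson with mean
    base_mean * libsize_s (libsize log-normal, sd 0.2 on the log scale);
    signal genes' means are multiplied by 2**effect_log2fc in group 2.
    Returns the counts matrix (group1 then group2 columns) and the signal
    gene identifiers.
    """
    if spec.signal_set_size > spec.n_genes:
        raise ValidationError("signal_set_size exceeds n_genes")
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    n = spec.n_samples_per_group
    samples = _sample_ids(n, "ctrl_") + _sample_ids(n, "case_")
    signal = sorted(rng.choice(genes, size=spec.signal_set_size, replace=False))
    signal_mask = np.isin(genes, signal)
    libsize = np.exp(rng.normal(0.0, 0.2, size=2 * n))
    mean = np.tile(spec.base_mean * libsize, (spec.n_genes, 1))
    mean[signal_mask, n:] *= 2.0**spec.effect_log2fc
    shape = 1.0 / spec.dispersion
    lam = rng.gamma(shape, mean * spec.dispersion, size=mean.shape)
    counts = rng.poisson(lam).astype(float)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), COUNTS
    )
    return matrix, list(signal)


def simulate_gene_set_cohort(
    spec: SimulationSpec, collection_size: int
) -> tuple[ExpressionMatrix, GeneSetCollection, str]:
    """Gaussian log2 cohort with one activated gene set among nulls.

    Values are gene-baseline + N(0, 1); the members of exactly one of
    ``collection_size`` disjoint random sets (each of signal_set_size
    genes) are shifted up by ``effect_log2fc`` standard deviations in
    group 2.  Returns (matrix, collection, activated set name).
    """
    if collection_size < 2:
        raise ValidationError("collection_size must be >= 2")
    if collection_size * spec.signal_set_size > spec.n_genes:
        raise ValidationError(
            "collection_size * signal_set_size exceeds n_genes; "
            "disjoint sets are impossible"
        )
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    n = spec.n_samples_per_group
    samples = _sample_ids(n, "ctrl_") + _sample_ids(n, "case_")
    baseline = rng.normal(6.0, 1.0, size=spec.n_genes)
    values = baseline[:, None] + rng.normal(0.0, 1.0, size=(spec.n_genes, 2 * n))
    shuffled = rng.permutation(spec.n_genes)
    width = len(str(collection_size))
    sets = []
    for i in range(collection_size):
        members = shuffled[
            i * spec.signal_set_size : (i + 1) * spec.signal_set_size
        ]
        sets.append(
            GeneSet(
                f"SET{i + 1:0{width}d}",
                "synthetic",
                sorted(genes[j] for j in members),
            )
        )
    activated = sets[int(rng.integers(collection_size))].name
    collection = GeneSetCollection(sets)
    mask = np.isin(genes, collection[activated].genes)
    values[mask, n:] += spec.effect_log2fc
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), LOG2
    )
    return matrix, collection, activated


def simulate_cross_species(
    spec: SimulationSpec,
    n_subtypes: int = 2,
    batch_shift: float = 1.0,
    frac_one_to_one: float = 0.8,
    subtype_sd: float = 3.0,
    noise_sd: float = 1.0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, HomologMap, pd.Series]:
    """Two species sharing latent subtype centroids.

    Each latent gene i has a per-subtype centroid value ~ N(0, subtype_sd);
    a sample is its subtype centroid + N(0, noise_sd) noise + a species-
    and gene-specific offset ~ N(0, batch_shift) constant within the
    species (removable by per-cohort median centring).  The default
    subtype_sd/noise_sd = 3 is the signal-to-noise regime the recovery
    tests target.  The homolog map covers ``frac_one_to_one`` of genes
    with clean 1:1 pairs; remaining source genes map many-to-one onto
    shared targets and are dropped by the strict 1:1 collapse.

    Returns (source matrix, target matrix, homolog map, truth labels
    indexed by sample id with values ``subtype1``..).
    """
    if n_subtypes < 2:
        raise ValidationError("n_subtypes must be >= 2")
    if not 0 < frac_one_to_one <= 1:
        raise ValidationError("frac_one_to_one must lie in (0, 1]")
    rng = np.random.default_rng(spec.seed)
    g = spec.n_genes
    n = spec.n_samples_per_group
    src_genes = [f"mGene{i}" for i in range(1, g + 1)]
    tgt_genes = [f"HGENE{i}" for i in range(1, g + 1)]
    centroids = rng.normal(0.0, subtype_sd, size=(g, n_subtypes))
    offsets = {
        "source": rng.normal(0.0, batch_shift, size=g),
        "target": rng.normal(0.0, batch_shift, size=g),
    }

    def _cohort(species: str, gene_names: list[str]) -> tuple[pd.DataFrame, dict]:
        cols, labels = {}, {}
        prefix = "m" if species == "source" else "h"
        for k in range(n_subtypes):
            for j in range(1, n + 1):
                sid = f"{prefix}_s{k + 1}_{j}"
                cols[sid] = (
                    centroids[:, k]
                    + offsets[species]
                    + rng.normal(0.0, noise_sd, size=g)
                )
                labels[sid] = f"subtype{k + 1}"
        return pd.DataFrame(cols, index=gene_names), labels

    src_frame, src_labels = _cohort("source", src_genes)
    tgt_frame, tgt_labels = _cohort("target", tgt_genes)

    n_clean = int(round(frac_one_to_one * g))
    clean = rng.choice(g, size=n_clean, replace=False)
    clean_set = set(clean.tolist())
    pairs = [(src_genes[i], tgt_genes[i]) for i in sorted(clean_set)]
    # remaining source genes map many-to-one onto arbitrary clean targets,
    # breaking target uniqueness so the 1:1 filter drops them
    leftovers = [i for i in range(g) if i not in clean_set]
    if leftovers:
        if not clean_set:
            raise ValidationError("frac_one_to_one too small: no 1:1 pairs")
        targets = rng.choice(sorted(clean_set), size=len(leftovers))
        pairs += [(src_genes[i], tgt_genes[t]) for i, t in zip(leftovers, targets)]
    hmap = HomologMap(list(dict.fromkeys(pairs)))
    truth = pd.Series({**src_labels, **tgt_labels}, name="subtype")
    return (
        ExpressionMatrix(src_frame, LOG2),
        ExpressionMatrix(tgt_frame, LOG2),
        hmap,
        truth,
    )


def simulate_copy_number(
    spec: SimulationSpec,
    amplicon: tuple[int, int],
    driver: str,
    n_altered: int = 5,
    sigma: float = 0.05,
    gain: float = 1.5,
    driver_extra: float = 1.0,
    driver_extra_fraction: float = 0.5,
    pad: int = 10,
    chromosome: str = "8",
) -> tuple[CopyNumberTable, dict]:
    """Copy-number cohort with a planted focal amplicon and driver gene.

    Genes lie on one chromosome at 1 Mb spacing.  Baseline copy values are
    N(2, sigma); the default sigma keeps baseline noise several standard
    deviations below the default calling threshold (2 + 0.3) so the
    planted interval intersection is the only region signal.  Each of ``n_altered`` samples gains ``gain`` over an
    interval containing the amplicon (0-based inclusive gene indices),
    extended on each side by up to ``pad`` genes; at least one sample's
    interval starts and one ends exactly at the amplicon boundary, so the
    intersection of the sampled intervals is exactly the amplicon.  The
    driver gene receives an extra ``driver_extra`` gain in
    ``driver_extra_fraction`` of the altered samples.

    Returns (table, truth) where truth records the planted amplicon genes,
    per-sample intervals, altered samples and the driver.
    """
    lo, hi = amplicon
    if not (0 <= lo <= hi < spec.n_genes):
        raise ValidationError("amplicon interval outside gene range")
    if not 0 <= driver_extra_fraction <= 1:
        raise ValidationError("driver_extra_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    if driver not in genes[lo : hi + 1]:
        raise ValidationError(f"driver {driver!r} must lie inside the amplicon")
    n_samples = 2 * spec.n_samples_per_group
    if n_altered > n_samples:
        raise ValidationError("n_altered exceeds the cohort size")
    samples = _sample_ids(n_samples, "cn_")
    positions = pd.DataFrame(
        {
            "chromosome": chromosome,
            "start": np.arange(spec.n_genes) * 1_000_000 + 1,
            "end": np.arange(spec.n_genes) * 1_000_000 + 500_000,
        },
        index=genes,
    )
    values = rng.normal(2.0, sigma, size=(spec.n_genes, n_samples))
    altered = sorted(rng.choice(n_samples, size=n_altered, replace=False).tolist())
    intervals: dict[str, tuple[int, int]] = {}
    if n_altered > 0:
        left = rng.integers(0, pad + 1, size=n_altered)
        right = rng.integers(0, pad + 1, size=n_altered)
        left[rng.integers(n_altered)] = 0
        right[rng.integers(n_altered)] = 0
        for ext_l, ext_r, j in zip(left, right, altered):
            a = max(0, lo - int(ext_l))
            b = min(spec.n_genes - 1, hi + int(ext_r))
            values[a : b + 1, j] += gain
            intervals[samples[j]] = (a, b)
        n_extra = int(round(driver_extra_fraction * n_altered))
        extra = rng.choice(altered, size=n_extra, replace=False)
        d_idx = genes.index(driver)
        for j in extra:
            values[d_idx, j] += driver_extra
    truth = {
        "amplicon": (lo, hi),
        "amplicon_genes": genes[lo : hi + 1],
        "driver": driver,
        "altered_samples": [samples[j] for j in altered],
        "intervals": intervals,
    }
    table = CopyNumberTable(positions, pd.DataFrame(values, index=genes, columns=samples))
    return table, truth


def simulate_survival(
    spec: SimulationSpec,
    genotypes: Sequence[str],
    baseline_hazard: float = 1.0 / 1000.0,
) -> pd.DataFrame:
    """Exponential survival cohort with genotype-dependent hazards.

    ``genotypes`` assigns one label per sample; the event hazard is
    baseline_hazard * hazard_ratios[label].  Censoring is an independent
    exponential tuned so the expected censored fraction matches
    ``censor_rate`` (rate mean_hazard * c / (1 - c)); censor_rate 0 means
    no censoring.  Stage and grade are drawn 1-4 with probabilities tilted
    toward higher values for higher-hazard genotypes so that Cox
    adjustment is exercised.  Returns a clinical table with columns time,
    event, stage, grade, genotype.
    """
    missing = sorted({g for g in genotypes if g not in spec.hazard_ratios})
    if missing:
        raise ValidationError(f"genotypes without a hazard ratio: {missing}")
    if len(genotypes) == 0:
        raise ValidationError("empty genotype list")
    rng = np.random.default_rng(spec.seed)
    hr = np.array([spec.hazard_ratios[g] for g in genotypes], dtype=float)
    lam = baseline_hazard * hr
    event_time = rng.exponential(1.0 / lam)
    if spec.censor_rate > 0:
        mu = lam.mean() * spec.censor_rate / (1.0 - spec.censor_rate)
        censor_time = rng.exponential(1.0 / mu, size=len(genotypes))
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(len(genotypes), dtype=int)
    base_probs = np.array([0.4, 0.3, 0.2, 0.1])
    levels = np.arange(4)

    def _ordinal(h: float) -> int:
        w = base_probs * h ** (0.5 * levels)
        return int(rng.choice(4, p=w / w.sum())) + 1

    stage = np.array([_ordinal(h) for h in hr])
    grade = np.array([_ordinal(h) for h in hr])
    samples = _sample_ids(len(genotypes), "pt_")
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "stage": stage,
            "grade": grade,
            "genotype": list(genotypes),
        },
        index=samples,
    )
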
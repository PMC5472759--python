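"""V/VM/VIM genotype calls and stage-frequency tabulation.

ccRCC samples are stratified by three alteration flags: VHL inactivation,
MYC activation and CDKN2A deletion.  V = VHL alone; VM = VHL + MYC;
VIM = VHL + MYC + CDKN2A.  Every other combination — including VHL with
CDKN2A loss but no MYC activation, and all VHL-intact samples — falls in
"other", so the four labels partition any cohort.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

logger = logging.getLogger("rccpipe")

FLAG_COLUMNS = ("vhl_inactivated", "myc_activated", "cdkn2a_deleted")
GENOTYPE_LABELS = ("V", "VM", "VIM", "other")
_STAGE_LABELS = {1: "I", 2: "II", 3: "III", 4: "IV"}


def classify_genotype(profiles: pd.DataFrame) -> pd.Series:
    """Map per-sample alteration flags to a genotype label.

    ``profiles`` must carry boolean columns vhl_inactivated, myc_activated
    and cdkn2a_deleted with no missing values (unknown flags must be
    resolved upstream or the sample excluded).  Returns a per-sample label
    in {V, VM, VIM, other}; the labels are mutually exclusive and
    exhaustive.
    """
    for col in FLAG_COLUMNS:
        if col not in profiles.columns:
            raise ValidationError(f"alteration profile missing column {col!r}")
        if profiles[col].isna().any():
            bad = profiles.index[profiles[col].isna()][0]
            raise ValidationError(f"missing {col} flag for sample {bad!r}")
    vhl = profiles["vhl_inactivated"].astype(bool)
    myc = profiles["myc_activated"].astype(bool)
    cdkn2a = profiles["cdkn2a_deleted"].astype(bool)
    label = pd.Series("other", index=profiles.index, dtype=object)
    label[vhl & ~myc & ~cdkn2a] = "V"
    label[vhl & myc & ~cdkn2a] = "VM"
    label[vhl & myc & cdkn2a] = "VIM"
    return label


def frequency_by_stage(clinical: pd.DataFrame, flag: str) -> pd.DataFrame:
    """Fraction of samples carrying ``flag`` within each TNM stage I-IV.

    Samples with missing stage are excluded.  Stages with zero samples are
    reported as absent with a warning.  Returns a table indexed by stage
    with columns n (samples), n_flag and frequency.
    """
    if flag not in clinical.columns:
        raise ValidationError(f"unknown flag column {flag!r}")
    if "stage" not in clinical.columns:
        raise ValidationError("clinical table has no stage column")
    staged = clinical[clinical["stage"].notna()]
    if staged.empty:
        raise ValidationError("no samples with a recorded stage")
    rows = {}
    for stage in (1, 2, 3, 4):
        sub = staged[staged["stage"] == stage]
        if sub.empty:
            logger.warning("stage %s has no samples", _STAGE_LABELS[stage])
            continue
        n_flag = int(sub[flag].astype(bool).sum())
        rows[_STAGE_LABELS[stage]] = {
            "n": len(sub),
            "n_flag": n_flag,
            "frequency": n_flag / len(sub),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def chisq_enrichment(counts: Sequence[Sequence[float]] | np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2 x k table.

    Returns (statistic, p) with k-1 degrees of freedom.  A zero expected
    cell count is a validation error — merge sparse categories first.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValidationError("expected a 2 x k contingency table with k >= 2")
    if (table < 0).any():
        raise ValidationError("contingency counts must be non-negative")
    expected = scipy.stats.contingency.expected_freq(table)
    if (expected <= 0).any():
        raise ValidationError(
            "zero expected cell count; merge categories before testing"
        )
    stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)
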
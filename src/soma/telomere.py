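"""Relative telomere-length estimation and association testing.

Telomere content is proxied by the number of reads containing a run of telomeric
repeat units (default TTAGGG, the canonical human repeat; either strand). Counts
are normalized by each sample's mean genomic coverage, and the relative telomere
length is the log2 ratio of the tumor's normalized count to the matched normal's:

    log2_ratio = log2( (tumor_reads / tumor_cov) / (normal_reads / normal_cov) )

Group differences (e.g. mutated vs wild-type for a telomere-maintenance gene) are
assessed with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError, revcomp

DEFAULT_MOTIF = "TTAGGG"


def count_motif_reads(
    reads: Iterable[str], motif: str = DEFAULT_MOTIF, min_tandem_copies: int = 5
) -> int:
    """Number of reads containing >= ``min_tandem_copies`` contiguous copies of the
    telomeric motif on either strand (the reverse complement is searched too)."""
    if not motif:
        raise ValidationError("motif must be non-empty")
    fwd = motif.upper() * min_tandem_copies
    rev = revcomp(motif.upper()) * min_tandem_copies
    n = 0
    for read in reads:
        r = read.upper()
        if fwd in r or rev in r:
            n += 1
    return n


@dataclass(frozen=True)
class TelomereEstimate:
    """Tumor/normal motif read counts, mean coverages and the log2 relative TL."""

    sample_id: str
    tumor_motif_reads: int
    normal_motif_reads: int
    tumor_mean_cov: float
    normal_mean_cov: float
    log2_ratio: float


def relative_tl(
    tumor_count: int,
    tumor_cov: float,
    normal_count: int,
    normal_cov: float,
    sample_id: str = "",
) -> TelomereEstimate:
    """Coverage-normalized log2 tumor/normal telomere ratio (closed form)."""
    if min(tumor_count, normal_count) <= 0 or min(tumor_cov, normal_cov) <= 0:
        raise ValidationError(
            "undefined ratio: counts and coverages must all be positive"
        )
    ratio = (tumor_count / tumor_cov) / (normal_count / normal_cov)
    return TelomereEstimate(
        sample_id=sample_id,
        tumor_motif_reads=int(tumor_count),
        normal_motif_reads=int(normal_count),
        tumor_mean_cov=float(tumor_cov),
        normal_mean_cov=float(normal_cov),
        log2_ratio=math.log2(ratio),
    )


def estimates_from_table(table: pd.DataFrame) -> list[TelomereEstimate]:
    """Estimates from a count table with columns sample, tumor_count, tumor_cov,
    normal_count, normal_cov."""
    required = {"sample", "tumor_count", "tumor_cov", "normal_count", "normal_cov"}
    if not required.issubset(table.columns):
        raise ValidationError(f"count table needs columns {sorted(required)}")
    return [
        relative_tl(
            int(r.tumor_count), float(r.tumor_cov), int(r.normal_count),
            float(r.normal_cov), sample_id=str(r.sample),
        )
        for r in table.itertuples(index=False)
    ]


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    direction: str        # "shorter", "longer" or "none" (mutated vs wild-type)
    n_mutated: int
    n_wildtype: int
    median_mutated: float
    median_wildtype: float


def tl_group_test(
    estimates: Sequence[TelomereEstimate], mutated: Mapping[str, bool] | Sequence[bool]
) -> GroupTestResult:
    """Two-sided Mann-Whitney U comparison of relative TL between mutated and
    wild-type samples.

    Exact p-value for combined n <= 20 without ties, normal approximation with tie
    correction otherwise. Direction reports whether the mutated group's median TL
    is shorter or longer than wild-type.
    """
    values = np.array([e.log2_ratio for e in estimates], dtype=float)
    if isinstance(mutated, Mapping):
        labels = np.array([bool(mutated[e.sample_id]) for e in estimates])
    else:
        labels = np.asarray(list(mutated), dtype=bool)
    x, y = values[labels], values[~labels]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (len(values) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    mx, my = float(np.median(x)), float(np.median(y))
    if mx < my:
        direction = "shorter"
    elif mx > my:
        direction = "longer"
    else:
        direction = "none"
    return GroupTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
        n_mutated=int(len(x)),
        n_wildtype=int(len(y)),
        median_mutated=mx,
        median_wildtype=my,
    )


def estimates_to_frame(estimates: Sequence[TelomereEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": e.sample_id,
                "tumor_motif_reads": e.tumor_motif_reads,
                "normal_motif_reads": e.normal_motif_reads,
                "tumor_mean_cov": e.tumor_mean_cov,
                "normal_mean_cov": e.normal_mean_cov,
                "log2_ratio": e.log2_ratio,
            }
            for e in estimates
        ]
    )
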
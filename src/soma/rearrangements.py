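"""Rearrangement signatures: 32-category classification, breakpoint clustering
statistics, catalogs and consensus clustering of exposure profiles.

Structural variants are classified by type (Del, Dup, Inv, T = inter-chromosomal
translocation), size bin (non-translocations only: 1-10 kb, 10-100 kb,
100 kb-1 Mb, 1-10 Mb, >10 Mb) and whether their breakpoints are clustered,
yielding 2 x (3x5 + 1) = 32 categories. A breakpoint is clustered when some 1 Mb
genomic window containing it holds >=10 of that sample's breakpoints; an SV is
clustered when either of its ends is. Per-chromosome statistics flag non-random
breakpoint distributions (one-sample Kolmogorov-Smirnov vs uniform, P < 1e-5),
outlier breakpoint rates (above Q75 + 1.5*IQR with a 35-breakpoint floor) and
high translocation counts (>=10). Rearrangement signatures are extracted from the
32-channel catalog with the same NMF core used for substitution signatures, and
per-sample signature proportions are grouped by subsampled consensus clustering
(pItem = pFeature = 0.9, Pearson distance, average linkage).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import GenomeIndex, SvRecord, ValidationError

logger = logging.getLogger("soma")

SIZE_BINS = ("1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")
_SIZE_EDGES = (1e3, 1e4, 1e5, 1e6, 1e7)  # half-open [low, high)
SV_TYPE_LABELS = {"DEL": "Del", "DUP": "Dup", "INV": "Inv", "TRA": "T"}

#: the fixed 32-category layout: clustered block first, Del/Dup/Inv x 5 bins, then T
CATEGORIES_32: tuple[str, ...] = tuple(
    f"{clust}:{label}" + (f":{size}" if size else "")
    for clust in ("clustered", "non-clustered")
    for label, sizes in (("Del", SIZE_BINS), ("Dup", SIZE_BINS), ("Inv", SIZE_BINS), ("T", (None,)))
    for size in sizes
)
CATEGORY_INDEX = {c: i for i, c in enumerate(CATEGORIES_32)}


def size_bin(span: int) -> str:
    """Half-open size bins; sub-kb spans fold into the lowest bin with a warning."""
    if span < _SIZE_EDGES[0]:
        logger.warning("SV span %d bp < 1 kb; folded into the 1-10kb bin", span)
        return SIZE_BINS[0]
    for low, high, label in zip(_SIZE_EDGES, _SIZE_EDGES[1:], SIZE_BINS):
        if low <= span < high:
            return label
    return SIZE_BINS[-1]


def classify_sv(sv: SvRecord, clustered: bool) -> str:
    """Assign an SV its single 32-category label."""
    prefix = "clustered" if clustered else "non-clustered"
    label = SV_TYPE_LABELS[sv.sv_type]
    if sv.sv_type == "TRA":
        return f"{prefix}:T"
    return f"{prefix}:{label}:{size_bin(sv.span)}"


# ---------------------------------------------------------------------------
# Clustered-breakpoint window rule
# ---------------------------------------------------------------------------

def _flag_positions(positions: np.ndarray, window: int, min_count: int) -> np.ndarray:
    """Two-pointer sweep: position i is flagged iff some window of length
    ``window`` containing it holds >= min_count of the positions."""
    n = len(positions)
    flags = np.zeros(n, dtype=bool)
    order = np.argsort(positions, kind="stable")
    pos = positions[order]
    mark = np.zeros(n + 1, dtype=int)
    a = 0
    for b in range(n):
        while pos[b] - pos[a] > window:
            a += 1
        if b - a + 1 >= min_count:
            mark[a] += 1
            mark[b + 1] -= 1
    covered = np.cumsum(mark[:-1]) > 0
    flags[order] = covered
    return flags


def flag_clustered_breakpoints(
    svs: Sequence[SvRecord], window: int = 1_000_000, min_count: int = 10
) -> tuple[list[tuple[bool, bool]], list[bool]]:
    """Per-SV breakpoint clustered flags and the per-SV clustered status (OR).

    Breakpoints are pooled per (sample, chromosome); each SV contributes one
    breakpoint per side. Returns (per-SV (end1, end2) flags, per-SV clustered).
    """
    keyed: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for i, sv in enumerate(svs):
        keyed.setdefault((sv.sample_id, sv.chrom1), []).append((sv.pos1, i, 0))
        keyed.setdefault((sv.sample_id, sv.chrom2), []).append((sv.pos2, i, 1))
    end_flags = [[False, False] for _ in svs]
    for (sample, chrom), entries in keyed.items():
        positions = np.array([p for p, _, _ in entries], dtype=np.int64)
        flags = _flag_positions(positions, window, min_count)
        for flag, (_, i, side) in zip(flags, entries):
            end_flags[i][side] = bool(flag)
    pair_flags = [tuple(f) for f in end_flags]
    sv_flags = [f[0] or f[1] for f in end_flags]
    return pair_flags, sv_flags


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

def build_rearrangement_catalog(
    svs: Sequence[SvRecord],
    window: int = 1_000_000,
    min_count: int = 10,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Samples x 32 rearrangement catalog; row sums equal per-sample SV counts.

    ``samples`` fixes the row set (samples without SVs get a zero row); by default
    rows appear in order of first occurrence in ``svs``.
    """
    _, clustered = flag_clustered_breakpoints(svs, window=window, min_count=min_count)
    samples = list(samples) if samples is not None else []
    rows: dict[str, np.ndarray] = {s: np.zeros(32, dtype=np.int64) for s in samples}
    for sv, cl in zip(svs, clustered):
        if sv.sample_id not in rows:
            rows[sv.sample_id] = np.zeros(32, dtype=np.int64)
            samples.append(sv.sample_id)
        rows[sv.sample_id][CATEGORY_INDEX[classify_sv(sv, cl)]] += 1
    data = np.vstack([rows[s] for s in samples]) if samples else np.zeros((0, 32), int)
    return pd.DataFrame(data, index=samples, columns=list(CATEGORIES_32))


# ---------------------------------------------------------------------------
# Per-chromosome statistics
# ---------------------------------------------------------------------------

def ks_uniform_pvalue(positions: np.ndarray, length: float) -> float:
    """Exact one-sample KS p-value of positions against Uniform(0, length)."""
    x = np.sort(np.asarray(positions, dtype=float)) / float(length)
    n = len(x)
    grid = np.arange(1, n + 1) / n
    d = max(np.max(grid - x), np.max(x - (grid - 1 / n)))
    return float(np.clip(stats.kstwo.sf(d, n), 0.0, 1.0))


def chromosome_nonrandomness_test(
    positions: Sequence[int], chrom_length: int, alpha: float = 1e-5,
    min_breakpoints: int = 5,
) -> tuple[float, bool]:
    """Test whether breakpoints are non-randomly placed along a chromosome.

    One-sample Kolmogorov-Smirnov test against Uniform(0, length); a chromosome is
    flagged clustered at the stringent threshold P < 1e-5. Fewer than
    ``min_breakpoints`` positions report p = 1 (never flagged).
    """
    positions = np.asarray(list(positions), dtype=float)
    if np.any((positions < 0) | (positions > chrom_length)):
        raise ValidationError("breakpoint position outside chromosome")
    if len(positions) < min_breakpoints:
        return 1.0, False
    p = ks_uniform_pvalue(positions, chrom_length)
    return p, p < alpha


def outlier_chromosomes(
    breakpoint_counts: Mapping[str, int],
    genome: GenomeIndex,
    min_breakpoints: int = 35,
) -> set[str]:
    """Chromosomes whose breakpoints/Mb rate exceeds Q75 + 1.5*IQR for the sample.

    Rates are computed over every chromosome of the genome index (zero where no
    breakpoints); quantiles use linear interpolation (type 7). A flagged
    chromosome must also carry at least ``min_breakpoints`` breakpoints. Requires
    >=4 chromosomes with at least one breakpoint, else nothing is flagged.
    """
    if sum(1 for c in genome.names if breakpoint_counts.get(c, 0) > 0) < 4:
        return set()
    rates = {
        c: breakpoint_counts.get(c, 0) / (genome.length(c) / 1e6) for c in genome.names
    }
    values = np.array(list(rates.values()))
    q25, q75 = np.percentile(values, [25, 75])
    cutoff = q75 + 1.5 * (q75 - q25)
    return {
        c for c, rate in rates.items()
        if rate > cutoff and breakpoint_counts.get(c, 0) >= min_breakpoints
    }


def high_translocation_chromosomes(
    svs: Sequence[SvRecord], min_tra: int = 10
) -> set[str]:
    """Chromosomes with >= ``min_tra`` translocation breakpoints (a TRA counts once
    for each of its two chromosomes). Call per sample."""
    counts: dict[str, int] = {}
    for sv in svs:
        if sv.sv_type != "TRA":
            continue
        counts[sv.chrom1] = counts.get(sv.chrom1, 0) + 1
        counts[sv.chrom2] = counts.get(sv.chrom2, 0) + 1
    return {c for c, n in counts.items() if n >= min_tra}


def breakpoint_cluster_report(
    svs: Sequence[SvRecord], genome: GenomeIndex,
    window: int = 1_000_000, min_count: int = 10,
    nonrandom_alpha: float = 1e-5, outlier_min: int = 35, min_tra: int = 10,
) -> pd.DataFrame:
    """Per (sample, chromosome) summary of all breakpoint-clustering statistics."""
    by_sample: dict[str, list[SvRecord]] = {}
    for sv in svs:
        by_sample.setdefault(sv.sample_id, []).append(sv)
    rows = []
    for sample, sample_svs in sorted(by_sample.items()):
        positions: dict[str, list[int]] = {}
        for sv in sample_svs:
            positions.setdefault(sv.chrom1, []).append(sv.pos1)
            positions.setdefault(sv.chrom2, []).append(sv.pos2)
        counts = {c: len(p) for c, p in positions.items()}
        outliers = outlier_chromosomes(counts, genome, min_breakpoints=outlier_min)
        high_tra = high_translocation_chromosomes(sample_svs, min_tra=min_tra)
        tra_counts: dict[str, int] = {}
        for sv in sample_svs:
            if sv.sv_type == "TRA":
                tra_counts[sv.chrom1] = tra_counts.get(sv.chrom1, 0) + 1
                tra_counts[sv.chrom2] = tra_counts.get(sv.chrom2, 0) + 1
        for chrom in genome.names:
            pos = positions.get(chrom, [])
            p, flagged = chromosome_nonrandomness_test(
                pos, genome.length(chrom), alpha=nonrandom_alpha
            )
            rows.append(
                {
                    "sample": sample,
                    "chrom": chrom,
                    "n_breakpoints": len(pos),
                    "breakpoints_per_mb": len(pos) / (genome.length(chrom) / 1e6),
                    "nonrandom_p": p,
                    "nonrandom_flag": flagged,
                    "outlier_flag": chrom in outliers,
                    "n_translocations": tra_counts.get(chrom, 0),
                    "high_translocation_flag": chrom in high_tra,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Consensus clustering of exposure profiles
# ---------------------------------------------------------------------------

@dataclass
class ConsensusClusteringResult:
    consensus: dict[int, pd.DataFrame]          # k -> samples x samples in [0,1]
    assignments: dict[int, pd.Series]           # k -> cluster label per sample
    cluster_consensus: dict[int, np.ndarray]    # k -> mean within-cluster consensus
    chosen_k: int | None


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between rows; degenerate rows -> distance 1."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    safe = norms.copy()
    safe[safe == 0] = 1.0
    corr = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    d = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def consensus_cluster(
    exposures: pd.DataFrame,
    k_range: Sequence[int] = range(2, 7),
    p_item: float = 0.9,
    p_feature: float = 0.9,
    reps: int = 1000,
    seed: int = 0,
    consensus_threshold: float = 0.8,
) -> ConsensusClusteringResult:
    """Subsampled consensus clustering of per-sample signature proportions.

    Features are mean-centered (constant features dropped with a warning). Each of
    ``reps`` repetitions subsamples ceil(p_item * n) samples and ceil(p_feature * p)
    features, clusters them by average linkage on 1 - Pearson correlation, and
    accumulates co-assignment frequencies into a consensus matrix per k. The final
    assignment cuts an average-linkage tree of (1 - consensus) at k. ``chosen_k``
    is the largest k whose minimum per-cluster mean consensus is >=
    ``consensus_threshold`` (None if no k qualifies); the full report is kept so a
    caller can choose differently. Deterministic under ``seed``.
    """
    n = exposures.shape[0]
    if n < 6:
        raise ValidationError(f"need >= 6 samples, got {n}")
    X = exposures.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [str(c) for c, k in zip(exposures.columns, keep) if not k]
        warnings.warn(f"dropping constant feature(s) after centering: {dropped}")
        X = X[:, keep]
    if X.shape[1] < 2:
        # all samples indistinguishable: every pair always co-clusters
        warnings.warn("degenerate input: samples are indistinguishable after centering")
        ones = pd.DataFrame(
            np.ones((n, n)), index=exposures.index, columns=exposures.index
        )
        return ConsensusClusteringResult(
            consensus={k: ones.copy() for k in k_range},
            assignments={
                k: pd.Series(np.ones(n, dtype=int), index=exposures.index)
                for k in k_range
            },
            cluster_consensus={k: np.array([1.0]) for k in k_range},
            chosen_k=None,
        )
    rng = np.random.default_rng(seed)
    n_items = int(np.ceil(p_item * n))
    n_feats = max(int(np.ceil(p_feature * X.shape[1])), 2)
    k_range = list(k_range)
    hit = {k: np.zeros((n, n)) for k in k_range}
    both = np.zeros((n, n))
    for _ in range(reps):
        items = np.sort(rng.choice(n, size=n_items, replace=False))
        feats = np.sort(rng.choice(X.shape[1], size=n_feats, replace=False))
        both[np.ix_(items, items)] += 1
        D = _pearson_distance(X[np.ix_(items, feats)])
        Z = hierarchy.average(squareform(D, checks=False))
        for k in k_range:
            labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            hit[k][np.ix_(items, items)] += same
    result_consensus: dict[int, pd.DataFrame] = {}
    assignments: dict[int, pd.Series] = {}
    cluster_consensus: dict[int, np.ndarray] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in k_range:
            M = np.where(both > 0, hit[k] / np.maximum(both, 1), 0.0)
            np.fill_diagonal(M, 1.0)
            M = (M + M.T) / 2
            Z = hierarchy.average(squareform(1.0 - M, checks=False))
            labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
            means = []
            for c in np.unique(labels):
                members = np.flatnonzero(labels == c)
                if len(members) == 1:
                    means.append(1.0)
                else:
                    sub = M[np.ix_(members, members)]
                    iu = np.triu_indices(len(members), k=1)
                    means.append(float(sub[iu].mean()))
            result_consensus[k] = pd.DataFrame(
                M, index=exposures.index, columns=exposures.index
            )
            assignments[k] = pd.Series(labels, index=exposures.index)
            cluster_consensus[k] = np.array(means)
    chosen = None
    for k in sorted(k_range):
        if cluster_consensus[k].min() >= consensus_threshold:
            chosen = k
    return ConsensusClusteringResult(
        consensus=result_consensus,
        assignments=assignments,
        cluster_consensus=cluster_consensus,
        chosen_k=chosen,
    )
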
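"""Kataegis detection: inter-mutation distances, piecewise constant fitting, calling.

Kataegis is localized substitution hypermutation, typically APOBEC-driven C>T/C>G
runs at TpC context. Detection follows the rainfall-plot methodology: order each
sample's SNVs by chromosome and position, compute inter-mutation distances (IMD),
segment log10(IMD) by exact penalized least-squares piecewise constant fitting
(PCF), and call every segment covering >=6 consecutive mutations with mean IMD
<=1000 bp. Segmentation runs per chromosome.

PCF here is an exact O(n^2) dynamic program: it minimizes
``sum of squared residuals + gamma * n_segments`` over all segmentations with
segments of at least ``kmin`` points. Defaults gamma=25, kmin=2 follow the
segmentation convention of the breast-cancer rainfall methodology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SnvRecord
from .signatures import ContextSource, build_96_catalog

logger = logging.getLogger("soma")


# ---------------------------------------------------------------------------
# Inter-mutation distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImdSeries:
    """Ordered mutation positions and IMDs for one (sample, chromosome)."""

    sample_id: str
    chrom: str
    positions: tuple[int, ...]     # sorted, deduplicated
    imd: tuple[int, ...]           # len == len(positions) - 1


def compute_imd(snvs: Sequence[SnvRecord]) -> list[ImdSeries]:
    """Per (sample, chromosome) sorted positions and distances to the previous
    mutation. Duplicate (sample, chrom, pos) entries are dropped with a warning;
    the first mutation of a chromosome has no IMD."""
    by_key: dict[tuple[str, str], set[int]] = {}
    n_dupes = 0
    seen: set[tuple[str, str, int]] = set()
    for r in snvs:
        key = (r.sample_id, r.chrom, r.pos)
        if key in seen:
            n_dupes += 1
            continue
        seen.add(key)
        by_key.setdefault((r.sample_id, r.chrom), set()).add(r.pos)
    if n_dupes:
        logger.warning("compute_imd: dropped %d duplicate position(s)", n_dupes)
    out = []
    for (sample, chrom), posset in sorted(by_key.items()):
        pos = tuple(sorted(posset))
        imd = tuple(b - a for a, b in zip(pos, pos[1:]))
        out.append(ImdSeries(sample, chrom, pos, imd))
    return out


# ---------------------------------------------------------------------------
# Piecewise constant fitting (exact DP)
# ---------------------------------------------------------------------------

def pcf_fit(y: np.ndarray, gamma: float = 25.0, kmin: int = 2) -> list[tuple[int, int]]:
    """Exact least-squares segmentation of ``y`` into constant-mean segments.

    Minimizes sum of within-segment squared deviations plus ``gamma`` per segment,
    every segment containing at least ``kmin`` points. Returns half-open index
    pairs (start, end) covering ``y``. Series shorter than ``2 * kmin`` cannot be
    split and return a single segment.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        return []
    if n < 2 * kmin:
        return [(0, n)]
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = 0.0
    for j in range(kmin, n + 1):
        i = np.arange(0, j - kmin + 1)
        s = c1[j] - c1[i]
        q = c2[j] - c2[i]
        m = j - i
        # within-segment sum of squared deviations, clipped against rounding
        sse = np.maximum(q - s * s / m, 0.0)
        costs = best[i] + sse + gamma
        am = int(np.argmin(costs))
        best[j], prev[j] = costs[am], i[am]
    segments = []
    j = n
    while j > 0:
        i = prev[j]
        segments.append((i, j))
        j = i
    return segments[::-1]


def pcf_segment(
    series: ImdSeries, gamma: float = 25.0, kmin: int = 2
) -> list[dict]:
    """Segment a chromosome's IMD series on the log10 scale.

    Returns per-segment dicts with IMD index range (half-open), number of covered
    mutations (m IMDs span m+1 mutations; the chromosome's first mutation belongs
    to the first segment) and the arithmetic mean of the raw IMDs.
    """
    y = np.log10(np.asarray(series.imd, dtype=float))
    segs = pcf_fit(y, gamma=gamma, kmin=kmin)
    out = []
    raw = np.asarray(series.imd, dtype=float)
    for start, end in segs:
        out.append(
            {
                "sample_id": series.sample_id,
                "chrom": series.chrom,
                "imd_start": start,
                "imd_end": end,
                "n_mutations": end - start + 1,
                "mean_imd": float(raw[start:end].mean()),
                "first_pos": series.positions[start],
                "last_pos": series.positions[end],
            }
        )
    return out


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KataegisSegment:
    """A called kataegis locus: >=6 consecutive mutations, mean IMD <= 1000 bp."""

    sample_id: str
    chrom: str
    start: int            # position of the first mutation (1-based)
    end: int              # position of the last mutation
    n_mutations: int
    mean_imd: float


def call_kataegis(
    segments: Sequence[dict],
    min_mutations: int = 6,
    max_mean_imd: float = 1000.0,
) -> list[KataegisSegment]:
    """Apply the calling rule to PCF segments and merge adjacent called segments.

    A segment of m IMDs covers m+1 mutations; it is called iff m+1 >= min_mutations
    and mean(IMD) <= max_mean_imd. Adjacent called segments on a chromosome merge
    into one locus, whose mean IMD is recomputed as (end-start)/(n-1).
    """
    calls: list[KataegisSegment] = []
    by_key: dict[tuple[str, str], list[dict]] = {}
    for seg in segments:
        by_key.setdefault((seg["sample_id"], seg["chrom"]), []).append(seg)
    for (sample, chrom), segs in sorted(by_key.items()):
        segs = sorted(segs, key=lambda s: s["imd_start"])
        run: list[dict] = []
        for seg in segs + [None]:
            hit = (
                seg is not None
                and seg["n_mutations"] >= min_mutations
                and seg["mean_imd"] <= max_mean_imd
            )
            adjacent = bool(run) and seg is not None and seg["imd_start"] == run[-1]["imd_end"]
            if hit and (not run or adjacent):
                run.append(seg)
                continue
            if run:
                start = run[0]["first_pos"]
                end = run[-1]["last_pos"]
                n = run[-1]["imd_end"] - run[0]["imd_start"] + 1
                calls.append(
                    KataegisSegment(
                        sample_id=sample, chrom=chrom, start=start, end=end,
                        n_mutations=n, mean_imd=(end - start) / (n - 1),
                    )
                )
                run = []
            if hit:
                run.append(seg)
    return calls


def detect_kataegis(
    snvs: Sequence[SnvRecord],
    gamma: float = 25.0,
    kmin: int = 2,
    min_mutations: int = 6,
    max_mean_imd: float = 1000.0,
) -> list[KataegisSegment]:
    """End-to-end: IMDs -> per-chromosome PCF -> calling rule -> merged loci."""
    segments: list[dict] = []
    for series in compute_imd(snvs):
        if len(series.imd) == 0:
            continue
        segments.extend(pcf_segment(series, gamma=gamma, kmin=kmin))
    return call_kataegis(segments, min_mutations=min_mutations, max_mean_imd=max_mean_imd)


# ---------------------------------------------------------------------------
# Context profiling and exports
# ---------------------------------------------------------------------------

def kataegis_context_profile(
    calls: Sequence[KataegisSegment],
    snvs: Sequence[SnvRecord],
    context_source: ContextSource,
) -> tuple[pd.DataFrame, float]:
    """96-channel catalog of the SNVs inside called loci, plus the fraction of all
    cohort SNVs that fall inside a call."""
    intervals: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for c in calls:
        intervals.setdefault((c.sample_id, c.chrom), []).append((c.start, c.end))
    inside = [
        r for r in snvs
        if any(
            s <= r.pos <= e
            for s, e in intervals.get((r.sample_id, r.chrom), [])
        )
    ]
    fraction = len(inside) / len(snvs) if snvs else 0.0
    catalog = build_96_catalog(inside, context_source)
    return catalog, fraction


def calls_to_frame(calls: Sequence[KataegisSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id, "chrom": c.chrom, "start": c.start,
                "end": c.end, "n_mutations": c.n_mutations, "mean_imd": c.mean_imd,
            }
            for c in calls
        ],
        columns=["sample", "chrom", "start", "end", "n_mutations", "mean_imd"],
    )


def write_calls_bed(calls: Sequence[KataegisSegment], path: str) -> None:
    """Loci as BED (0-based half-open), one line per call."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.sample_id}\t{c.n_mutations}\n")


def rainfall_table(snvs: Sequence[SnvRecord]) -> pd.DataFrame:
    """Rainfall-plot export: per mutation, its position and log10 distance to the
    previous mutation on the chromosome (first mutation omitted)."""
    rows = []
    for series in compute_imd(snvs):
        for pos, d in zip(series.positions[1:], series.imd):
            rows.append(
                {
                    "sample": series.sample_id, "chrom": series.chrom,
                    "pos": pos, "imd": d, "log10_imd": float(np.log10(d)),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "imd", "log10_imd"])
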
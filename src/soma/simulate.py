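"""Synthetic cohorts with machine-readable ground truth for every pipeline stage.

The generator emulates the inputs of a tumor/normal whole-genome study: SNVs drawn
from mixtures of trinucleotide signatures at configured exposures, planted
kataegis loci (runs of closely spaced C>T/C>G mutations at TpC context),
structural variants with planted 32-category profiles (clustered events placed so
the >=10-breakpoints-in-1-Mb rule verifiably fires; non-clustered events isolated
by more than the window), tumor/normal telomere motif read counts at known log2
ratios, and a toy tumor/normal record set spanning every filter-rule branch.

No reference genome is needed: "uniform-context" mode synthesizes the required
trinucleotide at each drawn position and records it in a sidecar context table
consumed by the catalog builder.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    BASES,
    GenerationError,
    GenomeIndex,
    SnvRecord,
    SvRecord,
    ValidationError,
    revcomp,
)
from .signatures import CHANNELS_96, TableContext, parse_channel
from .rearrangements import CATEGORIES_32, _SIZE_EDGES, SIZE_BINS


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything needed to score downstream stages, JSON-serializable."""

    exposures: dict[str, list[float]] = field(default_factory=dict)
    signature_ids: list[str] = field(default_factory=list)
    kataegis_intervals: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    sv_categories: dict[str, dict[str, int]] = field(default_factory=dict)
    sv_event_labels: list[str] = field(default_factory=list)
    telomere_log2_ratios: dict[str, float] = field(default_factory=dict)
    filter_verdicts: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        gt = cls(**raw)
        gt.kataegis_intervals = {
            s: [tuple(iv) for iv in ivs] for s, ivs in gt.kataegis_intervals.items()
        }
        return gt


def default_genome(n_chroms: int = 4, length: int = 150_000_000) -> GenomeIndex:
    """A convenient synthetic genome: ``n_chroms`` chromosomes of equal length."""
    return GenomeIndex(tuple((f"chr{i + 1}", length) for i in range(n_chroms)))


# ---------------------------------------------------------------------------
# SNV cohorts from signature mixtures
# ---------------------------------------------------------------------------

@dataclass
class SnvSimulationConfig:
    """Cohort of SNVs drawn i.i.d. from the mixture sum_k e_k * S_k per sample."""

    signature_profiles: pd.DataFrame     # K x 96, rows sum to 1
    exposures: np.ndarray                # n_samples x K, rows on the simplex
    mutations_per_sample: int | Sequence[int] = 2000
    genome: GenomeIndex = field(default_factory=default_genome)
    seed: int = 0
    tumor_depth: int = 60

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if self.exposures.ndim != 2:
            raise ValidationError("exposures must be n_samples x K")
        if self.exposures.shape[1] != self.signature_profiles.shape[0]:
            raise ValidationError("exposure columns must match number of signatures")
        if np.any(np.abs(self.exposures.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("each exposure row must sum to 1")
        if list(self.signature_profiles.columns) != list(CHANNELS_96):
            raise ValidationError("signature profiles must use the 96-channel layout")

    @property
    def n_samples(self) -> int:
        return self.exposures.shape[0]


@dataclass
class SnvCohort:
    records: list[SnvRecord]
    context: TableContext
    truth: GroundTruth
    context_table: dict[tuple[str, int], str]

    def records_for(self, sample_id: str) -> list[SnvRecord]:
        return [r for r in self.records if r.sample_id == sample_id]


def _draw_positions(
    genome: GenomeIndex, n: int, rng: np.random.Generator,
    occupied: set[tuple[str, int]],
) -> list[tuple[str, int]]:
    """n distinct positions uniform over the genome (2 <= pos <= len-1 so a
    trinucleotide context exists), avoiding ``occupied``."""
    names = genome.names
    lengths = np.array([genome.length(c) for c in names], dtype=np.int64)
    cum = np.cumsum(lengths)
    out: list[tuple[str, int]] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 50 * n + 1000:
            raise GenerationError("genome too small for requested mutation count")
        offset = int(rng.integers(0, cum[-1]))
        ci = int(np.searchsorted(cum, offset, side="right"))
        pos = int(offset - (cum[ci - 1] if ci else 0)) + 1
        pos = min(max(pos, 2), int(lengths[ci]) - 1)
        key = (names[ci], pos)
        if key in occupied:
            continue
        occupied.add(key)
        out.append(key)
    return out


def simulate_snv_cohort(cfg: SnvSimulationConfig) -> SnvCohort:
    """Simulate the cohort; returns records, the sidecar context table and truth.

    Each mutation's channel is drawn from the sample's signature mixture; its
    position is uniform over the genome (without replacement); with probability
    1/2 the record is written on the purine strand, so the catalog builder's
    strand canonicalization is exercised.
    """
    rng = np.random.default_rng(cfg.seed)
    profiles = cfg.signature_profiles.to_numpy(dtype=float)
    loads = (
        [int(cfg.mutations_per_sample)] * cfg.n_samples
        if np.isscalar(cfg.mutations_per_sample)
        else [int(x) for x in cfg.mutations_per_sample]
    )
    if len(loads) != cfg.n_samples:
        raise ValidationError("mutations_per_sample list must match n_samples")
    context_table: dict[tuple[str, int], str] = {}
    occupied: set[tuple[str, int]] = set()
    records: list[SnvRecord] = []
    truth = GroundTruth(
        signature_ids=[str(i) for i in cfg.signature_profiles.index],
    )
    parsed = [parse_channel(c) for c in CHANNELS_96]
    for s in range(cfg.n_samples):
        sample_id = f"S{s + 1:03d}"
        mixture = cfg.exposures[s] @ profiles
        mixture = np.clip(mixture, 0, None)
        mixture = mixture / mixture.sum()
        channels = rng.choice(96, size=loads[s], p=mixture)
        positions = _draw_positions(cfg.genome, loads[s], rng, occupied)
        flips = rng.random(loads[s]) < 0.5
        for ch_i, (chrom, pos), flip in zip(channels, positions, flips):
            ref, alt, five, three = parsed[ch_i]
            ctx = five + ref + three
            if flip:
                ref, alt, ctx = revcomp(ref), revcomp(alt), revcomp(ctx)
            context_table[(chrom, pos)] = ctx
            alt_count = int(rng.binomial(cfg.tumor_depth, 0.4))
            records.append(
                SnvRecord(
                    sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    tumor_depth=cfg.tumor_depth, tumor_alt_count=alt_count,
                    normal_alt_count=0,
                    vaf=alt_count / cfg.tumor_depth,
                )
            )
        truth.exposures[sample_id] = [float(x) for x in cfg.exposures[s]]
    return SnvCohort(
        records=records,
        context=TableContext(context_table),
        truth=truth,
        context_table=context_table,
    )


# ---------------------------------------------------------------------------
# Kataegis planting
# ---------------------------------------------------------------------------

@dataclass
class KataegisPlantConfig:
    """Planted hypermutation loci: runs of C>T / C>G mutations at TpC context."""

    n_loci: int = 3
    mutations_per_locus: int | tuple[int, int] = 8   # fixed, or inclusive range
    max_imd: int = 300
    class_weights: Mapping[str, float] = field(
        default_factory=lambda: {"C>T": 0.6, "C>G": 0.4}
    )
    #: minimum distance between two planted loci; defaults to 10 * max_imd.
    #: Benchmarks that score per-locus sensitivity should set this to many times
    #: the background inter-mutation spacing, so that segmentation treats each
    #: planted locus as an independent target instead of (correctly) merging
    #: neighbouring loci into one region of elevated density.
    min_locus_separation: int | None = None

    def __post_init__(self) -> None:
        lo = (
            self.mutations_per_locus
            if isinstance(self.mutations_per_locus, int)
            else self.mutations_per_locus[0]
        )
        if lo < 2:
            raise ValidationError("mutations_per_locus must be >= 2")
        if self.max_imd < 1:
            raise ValidationError("max_imd must be >= 1")
        if not set(self.class_weights) <= {"C>T", "C>G"}:
            raise ValidationError("class weights must be over {C>T, C>G}")


def plant_kataegis(
    records: Sequence[SnvRecord],
    context_table: dict[tuple[str, int], str],
    cfg: KataegisPlantConfig,
    genome: GenomeIndex,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[SnvRecord], dict[str, list[tuple[str, int, int]]]]:
    """Insert kataegis loci into existing per-sample records.

    Loci are placed at least ``10 * max_imd`` away from every existing mutation of
    the sample, and at least ``min_locus_separation`` (default ``10 * max_imd``)
    away from each other; within a locus consecutive spacings are uniform on
    [1, max_imd]. Returns (augmented records, truth intervals per sample).
    ``context_table`` is updated in place with the planted contexts.
    """
    rng = np.random.default_rng(seed)
    records = list(records)
    if sample_ids is None:
        sample_ids = sorted({r.sample_id for r in records})
    truth: dict[str, list[tuple[str, int, int]]] = {}
    classes = sorted(cfg.class_weights)
    weights = np.array([cfg.class_weights[c] for c in classes], dtype=float)
    weights = weights / weights.sum()
    sep = 10 * cfg.max_imd
    locus_sep = max(sep, cfg.min_locus_separation or 0)
    for sample_id in sample_ids:
        sample_positions: dict[str, list[int]] = {}
        for r in records:
            if r.sample_id == sample_id:
                sample_positions.setdefault(r.chrom, []).append(r.pos)
        for v in sample_positions.values():
            v.sort()
        locus_spans: dict[str, list[tuple[int, int]]] = {}
        intervals: list[tuple[str, int, int]] = []
        for _ in range(cfg.n_loci):
            if isinstance(cfg.mutations_per_locus, int):
                m = cfg.mutations_per_locus
            else:
                lo, hi = cfg.mutations_per_locus
                m = int(rng.integers(lo, hi + 1))
            spacings = rng.integers(1, cfg.max_imd + 1, size=m - 1)
            span = int(spacings.sum())
            placed = False
            for _try in range(2000):
                chrom = genome.names[int(rng.integers(len(genome.names)))]
                length = genome.length(chrom)
                if length < span + 2 * sep + 4:
                    continue
                start = int(rng.integers(sep + 2, length - span - sep - 1))
                occ = sample_positions.setdefault(chrom, [])
                lo_i = bisect.bisect_left(occ, start - sep)
                hi_i = bisect.bisect_right(occ, start + span + sep)
                if lo_i != hi_i:
                    continue
                if any(
                    start - locus_sep <= e and start + span + locus_sep >= s
                    for s, e in locus_spans.get(chrom, [])
                ):
                    continue
                positions = start + np.concatenate([[0], np.cumsum(spacings)])
                subs = rng.choice(len(classes), size=m, p=weights)
                three = rng.choice(len(BASES), size=m)
                for pos, sub_i, t_i in zip(positions, subs, three):
                    ref, alt = classes[sub_i].split(">")
                    ctx = "T" + ref + BASES[t_i]
                    context_table[(chrom, int(pos))] = ctx
                    records.append(
                        SnvRecord(
                            sample_id=sample_id, chrom=chrom, pos=int(pos),
                            ref=ref, alt=alt, tumor_depth=60,
                            tumor_alt_count=24, vaf=0.4,
                        )
                    )
                    bisect.insort(occ, int(pos))
                intervals.append((chrom, int(positions[0]), int(positions[-1])))
                locus_spans.setdefault(chrom, []).append((start, start + span))
                placed = True
                break
            if not placed:
                raise GenerationError(
                    "genome too small to honor kataegis locus separation"
                )
        truth[sample_id] = intervals
    return records, truth


def simulate_kataegis_cohort(
    genome: GenomeIndex,
    background_rate_per_mb: float = 1.0,
    n_loci: int = 5,
    mutations_per_locus: int | tuple[int, int] = (6, 20),
    max_imd: int = 300,
    seed: int = 0,
    sample_id: str = "S001",
    locus_separation_in_spacings: float = 20.0,
) -> tuple[list[SnvRecord], dict[tuple[str, int], str], list[tuple[str, int, int]]]:
    """One sample: uniform background at ``background_rate_per_mb`` plus planted
    loci. Returns (records, context table, truth intervals).

    Planted loci are kept ``locus_separation_in_spacings`` background
    inter-mutation spacings apart so each is an independently resolvable target
    (segmentation merges loci separated by only a handful of background points,
    which would measure placement collisions rather than detector sensitivity).
    """
    rng = np.random.default_rng(seed)
    n_bg = int(round(background_rate_per_mb * genome.total_length() / 1e6))
    occupied: set[tuple[str, int]] = set()
    positions = _draw_positions(genome, n_bg, rng, occupied)
    context_table: dict[tuple[str, int], str] = {}
    records = []
    for chrom, pos in positions:
        context_table[(chrom, pos)] = "ACA"
        records.append(
            SnvRecord(
                sample_id=sample_id, chrom=chrom, pos=pos, ref="C", alt="A",
                tumor_depth=60, tumor_alt_count=24, vaf=0.4,
            )
        )
    mean_spacing = 1e6 / background_rate_per_mb if background_rate_per_mb > 0 else 0
    cfg = KataegisPlantConfig(
        n_loci=n_loci, mutations_per_locus=mutations_per_locus, max_imd=max_imd,
        min_locus_separation=int(locus_separation_in_spacings * mean_spacing),
    )
    records, truth = plant_kataegis(
        records, context_table, cfg, genome,
        seed=int(rng.integers(2**31 - 1)), sample_ids=[sample_id],
    )
    return records, context_table, truth[sample_id]


# ---------------------------------------------------------------------------
# SV cohorts with planted 32-category profiles
# ---------------------------------------------------------------------------

@dataclass
class SvSimulationConfig:
    """Per-sample requested counts for each of the 32 rearrangement categories.

    ``counts`` is either one mapping (shared by all samples) or a list of
    mappings, category label -> count. Clustered events of a sample are placed in
    one uniformly positioned 1 Mb window per sample; non-clustered breakpoints are
    separated from every other event's breakpoints by more than the window.
    """

    counts: Mapping[str, int] | Sequence[Mapping[str, int]]
    n_samples: int = 1
    genome: GenomeIndex = field(default_factory=default_genome)
    seed: int = 0
    window: int = 1_000_000
    min_count: int = 10

    def per_sample_counts(self) -> list[dict[str, int]]:
        if isinstance(self.counts, Mapping):
            out = [dict(self.counts) for _ in range(self.n_samples)]
        else:
            out = [dict(c) for c in self.counts]
        for counts in out:
            for cat in counts:
                if cat not in CATEGORIES_32:
                    raise ValidationError(f"unknown SV category {cat!r}")
        return out


_BIN_RANGES = {
    label: (int(lo), int(hi) - 1)
    for label, lo, hi in zip(SIZE_BINS, _SIZE_EDGES, list(_SIZE_EDGES[1:]) + [3e7])
}
_TYPE_TOKENS = {"Del": "DEL", "Dup": "DUP", "Inv": "INV", "T": "TRA"}


class _IsolationMap:
    """Per-chromosome reserved breakpoint positions with a minimum-distance rule."""

    def __init__(self, window: int):
        self.window = window
        self._pos: dict[str, list[int]] = {}

    def ok(self, chrom: str, pos: int, slack: Sequence[int] = ()) -> bool:
        occ = self._pos.get(chrom, [])
        i = bisect.bisect_left(occ, pos)
        for j in (i - 1, i):
            if 0 <= j < len(occ):
                q = occ[j]
                if abs(q - pos) <= self.window and q not in slack:
                    return False
        return True

    def add(self, chrom: str, pos: int) -> None:
        bisect.insort(self._pos.setdefault(chrom, []), pos)


def _parse_category(cat: str) -> tuple[bool, str, str | None]:
    parts = cat.split(":")
    clustered = parts[0] == "clustered"
    sv_type = _TYPE_TOKENS[parts[1]]
    return clustered, sv_type, (parts[2] if len(parts) > 2 else None)


def simulate_sv_cohort(cfg: SvSimulationConfig) -> tuple[list[SvRecord], GroundTruth]:
    """Generate the cohort; every event's (type, size bin, clustered) truth label
    equals the label the classifier assigns, by construction."""
    rng = np.random.default_rng(cfg.seed)
    counts_per_sample = cfg.per_sample_counts()
    records: list[SvRecord] = []
    truth = GroundTruth()
    for s, counts in enumerate(counts_per_sample):
        sample_id = f"S{s + 1:03d}"
        iso = _IsolationMap(cfg.window)
        clustered_cats = [
            (cat, n) for cat, n in sorted(counts.items()) if n > 0 and cat.startswith("clustered")
        ]
        nonclustered_cats = [
            (cat, n) for cat, n in sorted(counts.items()) if n > 0 and cat.startswith("non-")
        ]
        sample_records: list[tuple[SvRecord, str]] = []
        if clustered_cats:
            in_window_bp = 0
            for cat, n in clustered_cats:
                _, sv_type, size = _parse_category(cat)
                if sv_type == "TRA":
                    in_window_bp += n
                else:
                    hi = _BIN_RANGES[size][0]
                    in_window_bp += 2 * n if _BIN_RANGES[size][1] < cfg.window else n
            if in_window_bp < cfg.min_count:
                raise GenerationError(
                    f"clustered request yields only {in_window_bp} in-window "
                    f"breakpoints (< {cfg.min_count}); the window rule cannot fire"
                )
            cluster_chrom = cfg.genome.names[0]
            clen = cfg.genome.length(cluster_chrom)
            # leave room downstream of the window for the longest clustered span
            max_span = max(
                (
                    _BIN_RANGES[_parse_category(cat)[2]][1]
                    for cat, _ in clustered_cats
                    if _parse_category(cat)[1] != "TRA"
                ),
                default=0,
            )
            hi_w0 = clen - 2 * cfg.window - max_span
            if clen < 3 * cfg.window or hi_w0 <= cfg.window:
                raise GenerationError(
                    "chromosome too short for the cluster window and its events"
                )
            w0 = int(rng.integers(cfg.window, hi_w0))
            for cat, n in clustered_cats:
                _, sv_type, size = _parse_category(cat)
                for _ in range(n):
                    for _try in range(5000):
                        if sv_type == "TRA":
                            pos1 = w0 + int(rng.integers(0, cfg.window))
                            others = [c for c in cfg.genome.names if c != cluster_chrom]
                            if not others:
                                raise GenerationError("TRA needs >= 2 chromosomes")
                            pos2, chrom2 = _place_isolated(rng, cfg.genome, others, iso)
                            iso.add(cluster_chrom, pos1)
                            iso.add(chrom2, pos2)
                            sv = SvRecord(sample_id, cluster_chrom, pos1, chrom2,
                                          pos2, "TRA")
                        else:
                            lo, hi = _BIN_RANGES[size]
                            span = int(rng.integers(lo, hi + 1))
                            if span < cfg.window:
                                pos1 = w0 + int(rng.integers(0, cfg.window - span))
                                pos2 = pos1 + span
                                iso.add(cluster_chrom, pos2)
                            else:
                                pos1 = w0 + int(rng.integers(0, cfg.window))
                                pos2 = pos1 + span
                                if pos2 >= clen - 1 or not iso.ok(cluster_chrom, pos2):
                                    continue
                                iso.add(cluster_chrom, pos2)
                            iso.add(cluster_chrom, pos1)
                            sv = SvRecord(sample_id, cluster_chrom, pos1,
                                          cluster_chrom, pos2, sv_type)
                        sample_records.append((sv, cat))
                        break
                    else:
                        raise GenerationError(
                            f"could not place clustered {cat} event"
                        )
        for cat, n in nonclustered_cats:
            _, sv_type, size = _parse_category(cat)
            for _ in range(n):
                for _try in range(5000):
                    if sv_type == "TRA":
                        c1 = cfg.genome.names[int(rng.integers(len(cfg.genome.names)))]
                        others = [c for c in cfg.genome.names if c != c1]
                        if not others:
                            raise GenerationError("TRA needs >= 2 chromosomes")
                        p1 = int(rng.integers(cfg.window + 1, cfg.genome.length(c1) - cfg.window))
                        if not iso.ok(c1, p1):
                            continue
                        p2, c2 = _place_isolated(rng, cfg.genome, others, iso)
                        iso.add(c1, p1)
                        iso.add(c2, p2)
                        sv = SvRecord(sample_id, c1, p1, c2, p2, "TRA")
                    else:
                        lo, hi = _BIN_RANGES[size]
                        span = int(rng.integers(lo, hi + 1))
                        c1 = cfg.genome.names[int(rng.integers(len(cfg.genome.names)))]
                        clen = cfg.genome.length(c1)
                        if clen < span + 2 * cfg.window + 4:
                            continue
                        p1 = int(rng.integers(cfg.window + 1, clen - span - cfg.window))
                        p2 = p1 + span
                        if not (iso.ok(c1, p1, slack=[p2]) and iso.ok(c1, p2, slack=[p1])):
                            continue
                        iso.add(c1, p1)
                        iso.add(c1, p2)
                        sv = SvRecord(sample_id, c1, p1, c1, p2, sv_type)
                    sample_records.append((sv, cat))
                    break
                else:
                    raise GenerationError(
                        f"could not place non-clustered {cat} event with "
                        f">{cfg.window} bp isolation"
                    )
        records.extend(sv for sv, _ in sample_records)
        truth.sv_event_labels.extend(cat for _, cat in sample_records)
        cat_counts = {c: 0 for c in CATEGORIES_32}
        for _, cat in sample_records:
            cat_counts[cat] += 1
        truth.sv_categories[sample_id] = {c: n for c, n in cat_counts.items() if n}
    return records, truth


def _place_isolated(
    rng: np.random.Generator, genome: GenomeIndex, chroms: Sequence[str],
    iso: _IsolationMap, tries: int = 5000,
) -> tuple[int, str]:
    for _ in range(tries):
        c = chroms[int(rng.integers(len(chroms)))]
        p = int(rng.integers(iso.window + 1, genome.length(c) - iso.window))
        if iso.ok(c, p):
            return p, c
    raise GenerationError("could not place isolated breakpoint")


# ---------------------------------------------------------------------------
# Telomere counts
# ---------------------------------------------------------------------------

def simulate_telomere_counts(
    log2_ratio: float,
    normal_count: int = 2000,
    tumor_cov: float = 60.0,
    normal_cov: float = 30.0,
    noise: bool = False,
    seed: int = 0,
    sample_id: str = "S001",
) -> tuple[dict, float]:
    """Tumor/normal motif counts at a known log2 relative telomere length.

    Noise-free: tumor_count = normal_count * (tumor_cov / normal_cov) *
    2**log2_ratio, rounded. With ``noise``, both counts are Poisson draws around
    their expectations. Returns (estimator inputs, truth log2 ratio).
    """
    if tumor_cov <= 0 or normal_cov <= 0:
        raise ValidationError("coverages must be positive")
    if normal_count <= 0:
        raise ValidationError("normal_count must be positive")
    expected_tumor = normal_count * (tumor_cov / normal_cov) * 2.0 ** log2_ratio
    if noise:
        rng = np.random.default_rng(seed)
        tumor_count = max(int(rng.poisson(expected_tumor)), 1)
        normal_draw = max(int(rng.poisson(normal_count)), 1)
    else:
        tumor_count = int(round(expected_tumor))
        normal_draw = int(normal_count)
    inputs = {
        "sample": sample_id,
        "tumor_count": tumor_count,
        "tumor_cov": float(tumor_cov),
        "normal_count": normal_draw,
        "normal_cov": float(normal_cov),
    }
    return inputs, float(log2_ratio)


# ---------------------------------------------------------------------------
# Filter toyset
# ---------------------------------------------------------------------------

def make_filter_toyset() -> tuple[
    list[SnvRecord],
    list[dict],
    dict[tuple[str, int], tuple[int, ...]],
]:
    """Toy tumor/normal records exercising every filter branch.

    Returns (records, expected verdicts, panel-of-normals pileups). Each expected
    verdict lists the tiered reasons that must fire, whether the population-AF
    and panel-of-normals filters exclude the record, and the overall verdict.
    """

    def rec(pos, depth, alt, normal_alt=0, pop_af=None):
        return SnvRecord(
            sample_id="TOY", chrom="chr1", pos=pos, ref="C", alt="T",
            tumor_depth=depth, tumor_alt_count=alt, normal_alt_count=normal_alt,
            vaf=alt / depth if depth else 0.0, population_af=pop_af,
        )

    records = [
        rec(1000, 9, 5),                      # depth only (vaf .556)
        rec(2000, 19, 2),                     # vaf .105: low_vaf_low_depth only
        rec(3000, 100, 4),                    # vaf .04: very_low_vaf only
        rec(4000, 25, 4),                     # vaf .16: few_alt_reads only
        rec(5000, 60, 15, normal_alt=3),      # vaf .25: normal_contamination_3 only
        rec(6000, 100, 18, normal_alt=2),     # vaf .18: normal_contamination_2 only
        rec(7000, 9, 1, normal_alt=3),        # vaf .111: four clauses fire
        rec(8000, 60, 21, pop_af=0.02),       # tiered-clean, common in population
        rec(9000, 60, 21, pop_af=0.01),       # AF boundary: kept (strict >)
        rec(10_000, 60, 21),                  # clean but recurrent in normals (PoN)
        rec(11_000, 60, 21),                  # PoN near-miss: only one normal >= 3
        rec(12_000, 60, 21, pop_af=0.0001),   # kept
        rec(13_000, 80, 40),                  # kept
    ]
    expected = [
        {"tiered": ("depth",), "population": False, "pon": False},
        {"tiered": ("low_vaf_low_depth",), "population": False, "pon": False},
        {"tiered": ("very_low_vaf",), "population": False, "pon": False},
        {"tiered": ("few_alt_reads",), "population": False, "pon": False},
        {"tiered": ("normal_contamination_3",), "population": False, "pon": False},
        {"tiered": ("normal_contamination_2",), "population": False, "pon": False},
        {
            "tiered": (
                "depth", "low_vaf_low_depth",
                "normal_contamination_3", "normal_contamination_2",
            ),
            "population": False, "pon": False,
        },
        {"tiered": (), "population": True, "pon": False},
        {"tiered": (), "population": False, "pon": False},
        {"tiered": (), "population": False, "pon": True},
        {"tiered": (), "population": False, "pon": False},
        {"tiered": (), "population": False, "pon": False},
        {"tiered": (), "population": False, "pon": False},
    ]
    for e in expected:
        e["overall"] = (
            "excluded" if (e["tiered"] or e["population"] or e["pon"]) else "kept"
        )
    pileups = {
        ("chr1", 10_000): (3, 3, 0),
        ("chr1", 11_000): (3, 2, 2),
    }
    return records, expected, pileups


# ---------------------------------------------------------------------------
# Two-population genotype cohorts (for QC / pruning / PCA)
# ---------------------------------------------------------------------------

def simulate_two_population_genotypes(
    n_per_pop: int = 50,
    n_variants: int = 200,
    fst: float = 0.1,
    seed: int = 0,
    spacing_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Balding-Nichols two-population genotype dosages.

    Ancestral frequencies are uniform on [0.1, 0.9]; each population's frequency
    is Beta-distributed around it with divergence ``fst``; genotypes are
    Binomial(2, p). Variants are placed ``spacing_bp`` apart on one chromosome.

    Returns (dosages samples x variants, population labels (0/1), variant
    positions frame with chrom/pos).
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_variants)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    geno = np.zeros((2 * n_per_pop, n_variants))
    for pop in (0, 1):
        p_pop = rng.beta(a, b)
        rows = slice(pop * n_per_pop, (pop + 1) * n_per_pop)
        geno[rows] = rng.binomial(2, p_pop, size=(n_per_pop, n_variants))
    variants = [f"v{i + 1}" for i in range(n_variants)]
    samples = [f"P{pop}_{i + 1}" for pop in (0, 1) for i in range(n_per_pop)]
    dosages = pd.DataFrame(geno, index=samples, columns=variants)
    labels = np.repeat([0, 1], n_per_pop)
    positions = pd.DataFrame(
        {"chrom": "chr1", "pos": [spacing_bp * (i + 1) for i in range(n_variants)]},
        index=variants,
    )
    return dosages, labels, positions
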
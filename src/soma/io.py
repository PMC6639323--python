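"""Readers/writers for the formats the pipeline touches and the shared data model.

Internal coordinates are 1-based inclusive (VCF convention). BEDPE input, which is
0-based half-open, is converted at the boundary; converting back yields the original
intervals. Copy-number input is a simple per-gene table (gene, total CN, minor CN) —
segmented calls are out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("soma")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
BASES = ("A", "C", "G", "T")
SV_TYPES = ("DEL", "DUP", "INV", "TRA")

#: accepted case-insensitive aliases for SV type tokens
_SV_ALIASES = {
    "DEL": "DEL", "DELETION": "DEL",
    "DUP": "DUP", "DUPLICATION": "DUP", "TDUP": "DUP",
    "INV": "INV", "INVERSION": "INV",
    "TRA": "TRA", "TRANSLOCATION": "TRA", "CTX": "TRA", "BND": "TRA",
}


class SomaError(Exception):
    """Base class for pipeline errors."""


class ParseError(SomaError):
    """A file could not be parsed."""


class ValidationError(SomaError):
    """An input violated a documented invariant."""


class ConfigurationError(SomaError):
    """Required configuration (e.g. an annotation key) is missing."""


class GenerationError(SomaError):
    """A synthetic cohort could not be generated under the given constraints."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Genome index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths (bp), as in a FASTA .fai index.

    The pipeline is genome-build agnostic; the build is carried as metadata only.
    """

    entries: tuple[tuple[str, int], ...]
    build: str | None = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate chromosome name(s): {dupes}")
        for name, length in self.entries:
            if length <= 0:
                raise ValidationError(f"non-positive length for {name}: {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    def length(self, chrom: str) -> int:
        try:
            return dict(self.entries)[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome: {chrom}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in dict(self.entries)

    def total_length(self) -> int:
        return sum(l for _, l in self.entries)


def read_genome_index(path: str | Path) -> GenomeIndex:
    """Read a FAI file (>=2 tab-separated columns: name, length)."""
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected >=2 tab-separated columns")
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: length {parts[1]!r} is not an integer"
                ) from None
            entries.append((parts[0], length))
    if not entries:
        logger.warning("genome index %s is empty", path)
    return GenomeIndex(tuple(entries))


def write_genome_index(index: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in index.entries:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# SNV / SV records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnvRecord:
    """A single-nucleotide somatic variant with tumor/normal read support.

    ``vaf`` is recomputed from ``tumor_alt_count / tumor_depth`` whenever depth > 0;
    an annotation value is only a fallback (removes caller-specific rounding).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_depth: int = 0
    tumor_alt_count: int = 0
    normal_alt_count: int = 0
    vaf: float = 0.0
    population_af: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValidationError(f"position must be 1-based positive, got {self.pos}")
        if not (0 <= self.tumor_alt_count <= self.tumor_depth or self.tumor_depth == 0):
            raise ValidationError(
                f"alt count {self.tumor_alt_count} exceeds depth {self.tumor_depth}"
            )
        if self.tumor_depth > 0:
            expected = self.tumor_alt_count / self.tumor_depth
            if abs(self.vaf - expected) > 1e-9:
                object.__setattr__(self, "vaf", expected)
        if not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"vaf out of [0,1]: {self.vaf}")

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SvRecord:
    """A two-breakpoint rearrangement: DEL, DUP, INV or inter-chromosomal TRA."""

    sample_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValidationError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type == "TRA":
            if self.chrom1 == self.chrom2:
                raise ValidationError(
                    f"TRA requires distinct chromosomes, got {self.chrom1} twice"
                )
        else:
            if self.chrom1 != self.chrom2:
                raise ValidationError(
                    f"{self.sv_type} must be intra-chromosomal "
                    f"({self.chrom1} != {self.chrom2})"
                )
            if self.pos2 <= self.pos1:
                raise ValidationError(
                    f"{self.sv_type} requires pos2 > pos1, got {self.pos1}..{self.pos2}"
                )

    @property
    def span(self) -> int | None:
        """Event size in bp; None for translocations."""
        if self.sv_type == "TRA":
            return None
        return self.pos2 - self.pos1

    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.chrom1, self.pos1), (self.chrom2, self.pos2)


# ---------------------------------------------------------------------------
# Copy-number categories
# ---------------------------------------------------------------------------

CN_CATEGORIES = ("deletion", "loss", "neutral_or_gain", "amplification", "cnLOH")


def categorize_copy_number(cn: int, minor_allele: int | None = None) -> str:
    """Map a total copy number (plus optional minor allele) to its category.

    CN 0 -> deletion (homozygous), CN 1 -> loss, CN >= 6 -> amplification;
    CN >= 2 with minor allele 0 -> copy-neutral LOH; anything else neutral_or_gain.
    """
    if cn < 0:
        raise ValidationError(f"copy number must be >= 0, got {cn}")
    if cn == 0:
        return "deletion"
    if cn == 1:
        return "loss"
    if cn >= 6:
        return "amplification"
    if minor_allele is not None and minor_allele == 0:
        return "cnLOH"
    return "neutral_or_gain"


def read_copy_number_table(path: str | Path) -> pd.DataFrame:
    """Read a per-gene copy-number TSV (gene, total_cn, minor_cn) and categorize.

    ``minor_cn`` may be NA; categories follow :func:`categorize_copy_number`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "total_cn"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    minor = df["minor_cn"] if "minor_cn" in df.columns else pd.Series([None] * len(df))
    df["category"] = [
        categorize_copy_number(int(cn), None if pd.isna(m) else int(m))
        for cn, m in zip(df["total_cn"], minor)
    ]
    return df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_snv_vcf(
    path: str | Path,
    sample_id: str,
    tumor_sample: str = "TUMOR",
    normal_sample: str | None = "NORMAL",
    ad_key: str = "AD",
    pop_af_key: str = "POP_AF",
) -> tuple[list[SnvRecord], dict[str, int]]:
    """Read biallelic SNVs from a VCF into :class:`SnvRecord` objects.

    Multi-allelic lines are split into one record per alternate allele; non-SNV
    alleles (indels, symbolic) are skipped and tallied. Tumor depth/alt counts come
    from the per-sample ``AD`` FORMAT field (configurable); the population allele
    frequency from the ``pop_af_key`` INFO field when present.

    Returns (records, skip tally).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if tumor_sample not in samples:
        raise ConfigurationError(
            f"tumor sample {tumor_sample!r} not in VCF samples {samples}"
        )
    t_idx = samples.index(tumor_sample)
    n_idx = samples.index(normal_sample) if normal_sample in samples else None

    records: list[SnvRecord] = []
    skipped = {"non_snv": 0, "missing_ad": 0}
    for var in vcf:
        if var.REF is None or len(var.REF) != 1 or var.REF not in BASES:
            skipped["non_snv"] += len(var.ALT)
            continue
        try:
            ad = var.format(ad_key)
        except KeyError:
            ad = None
        if ad is None:
            raise ConfigurationError(
                f"FORMAT key {ad_key!r} absent at {var.CHROM}:{var.POS}; "
                f"available: {sorted(var.FORMAT)}"
            )
        pop_af = var.INFO.get(pop_af_key)
        for alt_i, alt in enumerate(var.ALT):
            if len(alt) != 1 or alt not in BASES:
                skipped["non_snv"] += 1
                continue
            t_ad = ad[t_idx]
            depth = int(sum(max(int(x), 0) for x in t_ad))
            alt_count = int(max(int(t_ad[alt_i + 1]), 0)) if len(t_ad) > alt_i + 1 else 0
            normal_alt = 0
            if n_idx is not None:
                n_ad = ad[n_idx]
                if len(n_ad) > alt_i + 1:
                    normal_alt = int(max(int(n_ad[alt_i + 1]), 0))
            records.append(
                SnvRecord(
                    sample_id=sample_id,
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    tumor_depth=depth,
                    tumor_alt_count=alt_count,
                    normal_alt_count=normal_alt,
                    vaf=alt_count / depth if depth > 0 else 0.0,
                    population_af=float(pop_af) if pop_af is not None else None,
                )
            )
    return records, skipped


def write_snv_vcf(
    records: Sequence[SnvRecord],
    path: str | Path,
    genome: GenomeIndex | None = None,
    normal_alt_depth: int = 60,
) -> None:
    """Write SnvRecords as a deterministic two-sample (TUMOR, NORMAL) VCF 4.2 file.

    Records sharing a position are emitted on separate lines (biallelic layout).
    Byte-identical output for identical input is guaranteed.
    """
    lines = ["##fileformat=VCFv4.2", "##source=soma"]
    if genome is not None:
        for name, length in genome.entries:
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Population allele frequency">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL"
    )
    order = {n: i for i, n in enumerate(genome.names)} if genome is not None else {}
    recs = sorted(records, key=lambda r: (order.get(r.chrom, 1 << 30), r.chrom, r.pos, r.alt))
    for r in recs:
        info = "." if r.population_af is None else f"POP_AF={r.population_af:.6g}"
        t_ref = r.tumor_depth - r.tumor_alt_count
        n_ref = max(normal_alt_depth - r.normal_alt_count, 0)
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\tAD\t"
            f"{t_ref},{r.tumor_alt_count}\t{n_ref},{r.normal_alt_count}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def normalize_sv_type(token: str) -> str:
    try:
        return _SV_ALIASES[token.strip().upper()]
    except KeyError:
        raise ValidationError(f"unknown SV type token {token!r}") from None


def read_sv_bedpe(
    path: str | Path, sample_id: str, genome: GenomeIndex | None = None
) -> list[SvRecord]:
    """Read a 10-column BEDPE (0-based half-open) into 1-based SvRecords.

    Breakpoint position = interval start + 1. The type token (column 11 when present,
    else column 7 "name") is matched case-insensitively against common aliases;
    a BND with its mate on another chromosome is treated as TRA.
    """
    records: list[SvRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise ParseError(f"{path}: line {lineno}: expected >=7 BEDPE columns")
            chrom1, chrom2 = f[0], f[3]
            try:
                pos1 = int(f[1]) + 1
                pos2 = int(f[4]) + 1
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from None
            token = f[10] if len(f) > 10 else f[6]
            sv_type = normalize_sv_type(token)
            if sv_type == "TRA" and chrom1 == chrom2:
                raise ValidationError(
                    f"{path}: line {lineno}: TRA with both ends on {chrom1}"
                )
            if genome is not None:
                for c in (chrom1, chrom2):
                    if c not in genome:
                        raise ValidationError(f"{path}: line {lineno}: unknown chromosome {c}")
            records.append(
                SvRecord(sample_id, chrom1, pos1, chrom2, pos2, sv_type)
            )
    return records


def write_sv_bedpe(records: Sequence[SvRecord], path: str | Path) -> None:
    """Write SvRecords as 11-column BEDPE (0-based half-open, type in column 11)."""
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            fh.write(
                f"{r.chrom1}\t{r.pos1 - 1}\t{r.pos1}\t{r.chrom2}\t{r.pos2 - 1}\t{r.pos2}"
                f"\tsv{i}\t.\t+\t-\t{r.sv_type}\n"
            )


# ---------------------------------------------------------------------------
# Named matrices (TSV round trip)
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a named real matrix as TSV; NaN becomes "NA". Round-trips to 12 sig figs."""
    if matrix.index.has_duplicates:
        raise ValidationError("duplicate row names")
    if matrix.columns.has_duplicates:
        raise ValidationError("duplicate column names")
    matrix.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g", index_label="")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_matrix_tsv` ("NA" -> missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index.name = None
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise ValidationError("duplicate row names")
    if df.columns.has_duplicates:
        raise ValidationError("duplicate column names")
    return df
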
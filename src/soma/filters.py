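"""Somatic variant filtering, genotype assignment and ancestry-PCA preprocessing.

The tiered exclusion rules remove likely artifacts from tumor/normal SNV calls
using read depth, variant allele fraction (VAF) and alt support in the matched
normal; further filters remove variants common in the population (gnomAD-style
allele frequency > 0.01) and recurrent panel-of-normals artifacts. For ancestry
analysis, genotypes are assigned from VAF (0/0 if VAF <= 0.2, 0/1 if
0.2 < VAF < 0.8, 1/1 if VAF >= 0.8; missing below 10x coverage), QC'd on
missingness and minor allele frequency, LD-pruned (r^2 > 0.2 within 50 kb), and
decomposed by PCA.

Clause boundaries are implemented with the printed strict/non-strict operators
verbatim, even where the clauses overlap oddly — fidelity over elegance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ConfigurationError, SnvRecord, ValidationError

logger = logging.getLogger("soma")

#: tiered exclusion reasons, in rule order
FILTER_REASONS = (
    "depth",
    "low_vaf_low_depth",
    "very_low_vaf",
    "few_alt_reads",
    "normal_contamination_3",
    "normal_contamination_2",
)


@dataclass(frozen=True)
class FilterVerdict:
    record: SnvRecord
    verdict: str                      # "kept" | "excluded"
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict == "excluded" and not self.reasons:
            raise ValidationError("excluded verdict requires at least one reason")
        if self.verdict == "kept" and self.reasons:
            raise ValidationError("kept verdict must have no reasons")


def _tiered_reasons(r: SnvRecord) -> tuple[str, ...]:
    reasons = []
    if r.tumor_depth < 10:
        reasons.append("depth")
    if r.vaf < 0.20 and r.tumor_depth < 20:
        reasons.append("low_vaf_low_depth")
    if r.vaf < 0.05:
        reasons.append("very_low_vaf")
    if r.vaf > 0.15 and r.tumor_alt_count < 5:
        reasons.append("few_alt_reads")
    if r.vaf < 0.30 and r.normal_alt_count >= 3:
        reasons.append("normal_contamination_3")
    if r.normal_alt_count >= 2 and r.vaf < 0.20:
        reasons.append("normal_contamination_2")
    return tuple(reasons)


def apply_tiered_filters(
    records: Sequence[SnvRecord],
) -> tuple[list[FilterVerdict], dict[str, int]]:
    """Apply the six tiered depth/VAF exclusion clauses.

    A record is excluded iff ANY clause holds; all firing reasons are listed in
    rule order. Clauses (tumor depth D, tumor VAF f, tumor alt reads a_t, normal
    alt reads a_n): D < 10; f < 0.20 & D < 20; f < 0.05; f > 0.15 & a_t < 5;
    f < 0.30 & a_n >= 3; a_n >= 2 & f < 0.20.
    """
    verdicts = []
    tally = {reason: 0 for reason in FILTER_REASONS}
    for r in records:
        reasons = _tiered_reasons(r)
        for reason in reasons:
            tally[reason] += 1
        verdicts.append(
            FilterVerdict(r, "excluded" if reasons else "kept", reasons)
        )
    return verdicts, tally


def population_af_filter(
    records: Sequence[SnvRecord], max_af: float = 0.01
) -> list[FilterVerdict]:
    """Exclude variants common in the population: AF strictly > ``max_af``.

    A missing population AF is treated as 0 (kept)."""
    out = []
    for r in records:
        af = r.population_af if r.population_af is not None else 0.0
        if af > max_af:
            out.append(FilterVerdict(r, "excluded", ("common_population",)))
        else:
            out.append(FilterVerdict(r, "kept"))
    return out


def panel_of_normals_filter(
    records: Sequence[SnvRecord],
    normal_pileups: Mapping[tuple[str, int], Sequence[int]],
    min_alt: int = 3,
    min_normals: int = 2,
) -> list[FilterVerdict]:
    """Exclude positions where >= ``min_normals`` unrelated normal samples each
    show >= ``min_alt`` alternate-allele reads (recurrent artifact). Positions
    absent from the pileup table count as zero everywhere."""
    out = []
    for r in records:
        counts = normal_pileups.get((r.chrom, r.pos), ())
        n_hot = sum(1 for c in counts if c >= min_alt)
        if n_hot >= min_normals:
            out.append(FilterVerdict(r, "excluded", ("panel_of_normals",)))
        else:
            out.append(FilterVerdict(r, "kept"))
    return out


# ---------------------------------------------------------------------------
# Genotype assignment and QC for ancestry analysis
# ---------------------------------------------------------------------------

def assign_genotype(vaf: float, coverage: int, min_coverage: int = 10) -> str:
    """VAF-threshold genotype: 0/0 if VAF <= 0.2, 0/1 if 0.2 < VAF < 0.8,
    1/1 if VAF >= 0.8; "missing" below ``min_coverage``."""
    if not 0.0 <= vaf <= 1.0:
        raise ValidationError(f"vaf out of [0,1]: {vaf}")
    if coverage < min_coverage:
        return "missing"
    if vaf <= 0.2:
        return "0/0"
    if vaf < 0.8:
        return "0/1"
    return "1/1"


GENOTYPE_DOSAGE = {"0/0": 0.0, "0/1": 1.0, "1/1": 2.0, "missing": np.nan}


def genotypes_to_dosage(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Map genotype strings (samples x variants) to 0/1/2 dosages (NaN = missing)."""
    return genotypes.apply(lambda col: col.map(GENOTYPE_DOSAGE)).astype(float)


def variant_qc(
    dosages: pd.DataFrame, max_missing: float = 0.1, min_maf: float = 0.05
) -> tuple[list[str], dict[str, int]]:
    """Drop variants with missingness > ``max_missing`` or MAF < ``min_maf``.

    MAF is computed over non-missing calls; an all-missing variant is dropped and
    tallied. Returns (retained variant names, drop tally).
    """
    retained = []
    tally = {"missingness": 0, "maf": 0, "all_missing": 0}
    n = dosages.shape[0]
    for variant in dosages.columns:
        col = dosages[variant].to_numpy(dtype=float)
        miss = np.isnan(col).mean()
        obs = col[~np.isnan(col)]
        if len(obs) == 0:
            tally["all_missing"] += 1
            continue
        if miss > max_missing:
            tally["missingness"] += 1
            continue
        p = obs.mean() / 2.0
        maf = min(p, 1.0 - p)
        if maf < min_maf:
            tally["maf"] += 1
            continue
        retained.append(str(variant))
    return retained, tally


def ld_prune(
    dosages: pd.DataFrame,
    positions: Mapping[str, tuple[str, int]] | pd.DataFrame,
    r2_max: float = 0.2,
    window_bp: int = 50_000,
) -> tuple[list[str], dict[str, int]]:
    """Greedy left-to-right LD pruning.

    Variants are scanned in (chrom, position) order; a variant is removed when its
    squared Pearson correlation of dosages with any already-retained variant
    within ``window_bp`` on the same chromosome exceeds ``r2_max``. Zero-variance
    variants are removed first. Missing dosages are mean-imputed for the
    correlation. Deterministic. ``positions`` maps variant -> (chrom, pos) (or a
    DataFrame with chrom/pos columns indexed by variant).
    """
    if isinstance(positions, pd.DataFrame):
        positions = {
            str(v): (str(row["chrom"]), int(row["pos"]))
            for v, row in positions.iterrows()
        }
    tally = {"zero_variance": 0, "ld": 0}
    order = sorted(dosages.columns, key=lambda v: positions[str(v)])
    imputed: dict[str, np.ndarray] = {}
    for v in order:
        col = dosages[v].to_numpy(dtype=float)
        if np.isnan(col).any():
            m = np.nanmean(col)
            col = np.where(np.isnan(col), m, col)
        imputed[str(v)] = col
    retained: list[str] = []
    for v in order:
        v = str(v)
        col = imputed[v]
        if np.std(col) == 0:
            tally["zero_variance"] += 1
            continue
        chrom, pos = positions[v]
        hit = False
        for u in reversed(retained):
            uc, up = positions[u]
            if uc != chrom:
                continue
            if abs(pos - up) > window_bp:
                break
            r = np.corrcoef(col, imputed[u])[0, 1]
            if r * r > r2_max:
                hit = True
                break
        if hit:
            tally["ld"] += 1
        else:
            retained.append(v)
    return retained, tally


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class GenotypePca:
    """PCA of a standardized genotype dosage matrix.

    Components are ordered by explained variance; each component's sign is fixed
    by making its largest-magnitude loading positive, so repeated runs are
    byte-identical.
    """

    loadings: pd.DataFrame          # variants x components
    mean: pd.Series
    scale: pd.Series
    explained_variance: np.ndarray

    def transform(self, dosages: pd.DataFrame) -> pd.DataFrame:
        X = dosages[self.mean.index].to_numpy(dtype=float)
        col_mean = self.mean.to_numpy()
        inds = np.where(np.isnan(X))
        X[inds] = col_mean[inds[1]]
        Z = (X - col_mean) / self.scale.to_numpy()
        coords = Z @ self.loadings.to_numpy()
        return pd.DataFrame(
            coords, index=dosages.index,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        )


def pca_genotypes(
    dosages: pd.DataFrame,
    n_components: int | None = None,
    reference: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, GenotypePca]:
    """PCA on a (samples x variants) dosage matrix.

    Missing calls are mean-imputed per variant; columns are standardized
    (zero-variance columns dropped); the sample covariance is eigendecomposed via
    SVD. When ``reference`` is given, the axes are fit on the reference genotypes
    and the study samples are projected onto them (the merged mode is simply
    passing the concatenated matrix as ``dosages``).

    Returns (sample coordinates, fitted model).
    """
    fit_on = reference if reference is not None else dosages
    if fit_on.shape[1] < 2:
        raise ValidationError("need at least 2 variants for PCA")
    X = fit_on.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    scale = X.std(axis=0, ddof=0)
    keep = scale > 0
    if not keep.all():
        logger.warning("pca_genotypes: dropping %d zero-variance variant(s)", (~keep).sum())
    X = X[:, keep]
    if X.shape[1] < 2:
        raise ValidationError("fewer than 2 informative variants for PCA")
    col_mean, scale = col_mean[keep], scale[keep]
    Z = (X - col_mean) / scale
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    if n_components is None:
        n_components = min(10, Vt.shape[0])
    Vt = Vt[:n_components]
    s = s[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    variants = [str(c) for c, k in zip(fit_on.columns, keep) if k]
    model = GenotypePca(
        loadings=pd.DataFrame(
            Vt.T, index=variants, columns=[f"PC{i + 1}" for i in range(Vt.shape[0])]
        ),
        mean=pd.Series(col_mean, index=variants),
        scale=pd.Series(scale, index=variants),
        explained_variance=(s ** 2) / max(Z.shape[0] - 1, 1),
    )
    coords = model.transform(dosages[variants])
    return coords, model
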
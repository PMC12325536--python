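"""Smoking-heaviness polygenic risk score construction.

p-value thresholding, greedy LD clumping against a dosage panel, allele
harmonization between summary statistics and the counted alleles of the
panel, and weighted scoring with mean imputation of missing dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError, StructuralError

__all__ = [
    "SummaryStatRecord",
    "ClumpResult",
    "HarmonizeReport",
    "dosage_r2",
    "clump",
    "harmonize",
    "compute_prs",
    "variance_explained",
]

VALID_ALLELES = frozenset("ACGT")
PALINDROMIC = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class SummaryStatRecord:
    """One GWAS summary-statistics row (effect of the effect allele on
    cigarettes/day)."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ParameterError(
                f"{self.snp_id}: alleles must be single characters in ACGT")
        if self.effect_allele == self.other_allele:
            raise ParameterError(f"{self.snp_id}: effect and other allele identical")
        if self.pos < 1:
            raise ParameterError(f"{self.snp_id}: position must be >= 1 (1-based)")
        if self.se <= 0:
            raise ParameterError(f"{self.snp_id}: se must be positive")
        if not 0.0 < self.p <= 1.0:
            raise ParameterError(f"{self.snp_id}: p must lie in (0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in PALINDROMIC


@dataclass
class ClumpResult:
    """Index SNPs retained by greedy clumping; ``removed`` maps each
    absorbed SNP to the index that absorbed it; ``skipped`` lists SNPs
    excluded for zero dosage variance."""

    index_snps: list[str]
    removed: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def report_frame(self, stats: Mapping[str, SummaryStatRecord] | None = None) -> pd.DataFrame:
        rows = [{"snp_id": s, "role": "index", "absorbed_by": ""} for s in self.index_snps]
        rows += [{"snp_id": s, "role": "absorbed", "absorbed_by": idx}
                 for s, idx in sorted(self.removed.items())]
        rows += [{"snp_id": s, "role": "skipped", "absorbed_by": ""} for s in self.skipped]
        return pd.DataFrame(rows, columns=["snp_id", "role", "absorbed_by"])


def dosage_r2(a, b) -> float:
    """Squared Pearson correlation of two dosage vectors on complete pairs.

    Invariant to allele-coding flips: r²(2−a, b) = r²(a, b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise DegenerateDataError("need at least 2 complete pairs for r²")
    if a.std() == 0.0 or b.std() == 0.0:
        raise DegenerateDataError("zero dosage variance; r² undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _sort_key(rec: SummaryStatRecord):
    # ascending p; ties broken by (chrom, pos, snp_id) for determinism
    return (rec.p, str(rec.chrom), rec.pos, rec.snp_id)


def clump(
    stats: Sequence[SummaryStatRecord],
    dosage_panel: pd.DataFrame,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.001,
    window_kb: float = 1000.0,
) -> ClumpResult:
    """Greedy LD clumping of summary statistics against a dosage panel.

    Repeatedly takes the smallest-p remaining SNP as an index and absorbs
    all remaining SNPs on the same chromosome within ``window_kb`` whose
    dosage r² with the index exceeds ``r2_thresh``. SNPs with
    ``p > p_thresh`` never become indices or survivors. r² is computed on
    the supplied panel, so values are panel-dependent.
    """
    if dosage_panel.shape[0] < 2 and len(stats) > 0:
        raise StructuralError("dosage panel needs at least 2 individuals")
    missing = [r.snp_id for r in stats if r.snp_id not in dosage_panel.columns]
    if missing:
        raise StructuralError(f"SNPs absent from dosage panel: {missing}")

    candidates, skipped = [], []
    for rec in stats:
        if rec.p > p_thresh:
            continue
        col = dosage_panel[rec.snp_id].to_numpy(dtype=float)
        if np.nanstd(col) == 0.0:
            warnings.warn(f"{rec.snp_id}: zero dosage variance; skipped from clumping")
            skipped.append(rec.snp_id)
            continue
        candidates.append(rec)
    candidates.sort(key=_sort_key)

    index_snps: list[str] = []
    removed: dict[str, str] = {}
    remaining = list(candidates)
    while remaining:
        index = remaining.pop(0)
        index_snps.append(index.snp_id)
        keep = []
        for rec in remaining:
            if (str(rec.chrom) == str(index.chrom)
                    and abs(rec.pos - index.pos) <= window_kb * 1000.0
                    and dosage_r2(dosage_panel[index.snp_id],
                                  dosage_panel[rec.snp_id]) > r2_thresh):
                removed[rec.snp_id] = index.snp_id
            else:
                keep.append(rec)
        remaining = keep
    return ClumpResult(index_snps=index_snps, removed=removed, skipped=skipped)


@dataclass
class HarmonizeReport:
    kept: dict[str, float]          # snp_id -> aligned weight
    flipped: list[str]
    dropped: dict[str, str]         # snp_id -> reason

    def frame(self) -> pd.DataFrame:
        rows = [{"snp_id": s, "weight": w,
                 "action": "flipped" if s in self.flipped else "kept"}
                for s, w in self.kept.items()]
        rows += [{"snp_id": s, "weight": np.nan, "action": f"dropped: {r}"}
                 for s, r in self.dropped.items()]
        return pd.DataFrame(rows, columns=["snp_id", "weight", "action"])


def harmonize(
    stats: Sequence[SummaryStatRecord],
    counted_alleles: Mapping[str, str],
) -> HarmonizeReport:
    """Align summary-statistic betas to the panel's counted alleles.

    If the counted allele equals the other allele the beta sign is flipped;
    strand-ambiguous (A/T, C/G) SNPs and allele mismatches are dropped with
    the reason recorded, never fatally.
    """
    kept: dict[str, float] = {}
    flipped: list[str] = []
    dropped: dict[str, str] = {}
    for rec in stats:
        if rec.is_palindromic:
            dropped[rec.snp_id] = "palindromic (strand-ambiguous) allele pair"
            continue
        counted = counted_alleles.get(rec.snp_id)
        if counted is None:
            dropped[rec.snp_id] = "not present in panel"
        elif counted == rec.effect_allele:
            kept[rec.snp_id] = rec.beta
        elif counted == rec.other_allele:
            kept[rec.snp_id] = -rec.beta
            flipped.append(rec.snp_id)
        else:
            dropped[rec.snp_id] = (
                f"allele mismatch (counted {counted}, "
                f"stats {rec.effect_allele}/{rec.other_allele})")
    return HarmonizeReport(kept=kept, flipped=flipped, dropped=dropped)


def compute_prs(
    dosages: pd.DataFrame, weights: Mapping[str, float],
    weighted: bool = True,
) -> pd.Series:
    """Per-individual score ``sum_j w_j * dosage_ij``.

    Missing dosages are imputed with the column mean (2 × allele frequency).
    With ``weighted=False`` the score is the plain count of effect alleles
    across the weighted-in SNPs (sign of the weight still orients the
    counted allele).
    """
    snps = list(weights)
    missing_cols = [s for s in snps if s not in dosages.columns]
    if missing_cols:
        raise StructuralError(f"dosage columns missing for SNPs: {missing_cols}")
    mat = dosages[snps].to_numpy(dtype=float)
    col_means = np.nanmean(mat, axis=0) if mat.size else np.zeros(len(snps))
    idx = np.where(np.isnan(mat))
    mat[idx] = np.take(col_means, idx[1])
    w = np.array([weights[s] for s in snps], dtype=float)
    if not weighted:
        w = np.sign(w)
    return pd.Series(mat @ w, index=dosages.index, name="PRS")


def variance_explained(predictor, phenotype) -> float:
    """R² from the simple linear regression of phenotype on predictor
    (the squared Pearson correlation), on complete pairs."""
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DegenerateDataError("need at least 3 complete pairs for R²")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DegenerateDataError("zero variance; R² undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
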
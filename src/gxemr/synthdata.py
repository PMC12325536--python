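"""Synthetic mother-offspring cohorts for the proxy GxE MR design.

The generator produces trios of parental genotypes under Hardy-Weinberg
equilibrium, transmits one allele per parent to the offspring (so the
mother-offspring dosage correlation is 0.5 under random mating), and layers
on top of the genotypes a maternal smoking model, a binary handedness
outcome and a birthweight positive control:

* smoking initiation: ``P(smoked) = expit(logit(init_base)
  + init_per_allele * allele_count + conf_on_init * U)`` — the genotype ->
  initiation path is what turns smoking status into a collider when a latent
  confounder ``U`` also feeds initiation;
* smoking heaviness among smokers: ``cigs/day = exposure_mean
  + sum_j w_j G_mj + N(0, exposure_sd)``, truncated at zero; undefined
  (missing) for non-smokers;
* handedness: ``P(left) = expit(outcome_base_logit
  + causal_beta * cigs * smoked + pleiotropy_beta * offspring allele count
  + conf_on_outcome * U)`` — the causal path acts only through cigarettes
  actually smoked, the pleiotropic path acts through the offspring genome
  regardless of maternal smoking;
* birthweight: ``bw_base + bw_theta * cigs * smoked
  + conf_on_birthweight * U + N(0, bw_sd)``.

Early-life covariates (sex, multiple birth, breastfeeding, birth year/month,
country, Townsend score) are drawn from UK-Biobank-like marginals and are
independent of genotype, so they serve as negative controls for the
exchangeability checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SequencingError, StructuralError

__all__ = [
    "SimParams",
    "Cohort",
    "draw_parental_genotypes",
    "transmit",
    "simulate_exposure",
    "simulate_outcomes",
    "generate_cohort",
    "weight_for_r2",
    "ukb_preset",
    "check_mendelian",
]

#: logit of the left-handedness prevalence in the UK Biobank genetic subset (9.82%)
LEFT_HANDED_BASE_LOGIT = float(np.log(0.0982 / (1 - 0.0982)))

#: UK-Biobank-like covariate marginals (fractions / moments at baseline)
FEMALE_FRACTION = 0.545
MULTIPLE_BIRTH_FRACTION = 0.0225
BREASTFED_FRACTION = 0.712
BIRTH_YEAR_RANGE = (1937, 1965)  # inclusive; uniform -> mean 1951
COUNTRY_LEVELS = ("England", "Wales", "Scotland", "Northern Ireland",
                  "Republic of Ireland", "Elsewhere")
COUNTRY_PROBS = (0.8424, 0.0479, 0.0858, 0.0049, 0.0006, 0.0184)

PHENOTYPE_COLUMNS = [
    "maternal_smoked", "cigs_per_day", "left_handed", "birthweight_kg",
    "sex", "multiple_birth", "breastfed", "birth_year", "birth_month",
    "country", "townsend", "confounder_u",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated mother-offspring cohort.

    ``snp_weights`` are per-allele effects on cigarettes/day among smokers;
    ``causal_beta`` is the log-odds of left-handedness per cigarette/day
    (active only when the mother smoked); ``pleiotropy_beta`` is the direct
    log-odds per offspring effect allele, bypassing smoking entirely.
    ``init_per_allele`` opens the genotype -> smoking-initiation path that,
    together with ``conf_on_init``, produces collider bias on stratification.
    """

    n_pairs: int
    allele_freqs: tuple[float, ...] = (0.33,)
    snp_weights: tuple[float, ...] = (0.86,)
    exposure_mean: float = 13.0
    exposure_sd: float = 9.0
    init_base: float = 0.306
    init_per_allele: float = 0.0
    confounder_sd: float = 1.0
    conf_on_init: float = 0.0
    conf_on_outcome: float = 0.0
    conf_on_birthweight: float = 0.0
    outcome_base_logit: float = LEFT_HANDED_BASE_LOGIT
    causal_beta: float = 0.0
    pleiotropy_beta: float = 0.0
    bw_base: float = 3.33
    bw_theta: float = 0.0
    bw_sd: float = 0.5
    spousal_corr: float = 0.0
    snp_ids: tuple[str, ...] | None = None
    effect_alleles: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele_freqs", tuple(float(f) for f in self.allele_freqs))
        object.__setattr__(self, "snp_weights", tuple(float(w) for w in self.snp_weights))
        if self.n_pairs < 0:
            raise ParameterError(f"n_pairs must be non-negative, got {self.n_pairs}")
        if len(self.allele_freqs) != len(self.snp_weights):
            raise StructuralError(
                f"{len(self.allele_freqs)} allele frequencies but "
                f"{len(self.snp_weights)} SNP weights")
        for f in self.allele_freqs:
            if not 0.0 < f < 1.0:
                raise ParameterError(f"allele frequency {f} outside (0, 1)")
        if not 0.0 < self.init_base < 1.0:
            raise ParameterError(f"init_base {self.init_base} outside (0, 1)")
        for name in ("exposure_sd", "confounder_sd", "bw_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not 0.0 <= self.spousal_corr < 1.0:
            raise ParameterError("spousal_corr must lie in [0, 1)")
        if self.snp_ids is not None:
            object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
            if len(self.snp_ids) != self.n_snps:
                raise StructuralError("snp_ids length does not match allele_freqs")
        if self.effect_alleles is not None:
            object.__setattr__(self, "effect_alleles", tuple(self.effect_alleles))
            if len(self.effect_alleles) != self.n_snps:
                raise StructuralError("effect_alleles length does not match allele_freqs")

    @property
    def n_snps(self) -> int:
        return len(self.allele_freqs)

    def resolved_snp_ids(self) -> tuple[str, ...]:
        if self.snp_ids is not None:
            return self.snp_ids
        return tuple(f"snp{j + 1}" for j in range(self.n_snps))

    def resolved_effect_alleles(self) -> tuple[str, ...]:
        if self.effect_alleles is not None:
            return self.effect_alleles
        return ("A",) * self.n_snps

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Cohort:
    """One simulated (or loaded) mother-offspring cohort.

    ``phenotypes`` holds one row per offspring; dosage matrices are
    ``(n, n_snps)`` effect-allele counts. Parental haplotypes are retained so
    Mendelian consistency remains checkable after generation.
    """

    phenotypes: pd.DataFrame
    offspring_dosage: np.ndarray
    maternal_dosage: np.ndarray
    paternal_dosage: np.ndarray
    snp_ids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    maternal_haplotypes: np.ndarray | None = None
    paternal_haplotypes: np.ndarray | None = None
    offspring_haplotypes: np.ndarray | None = None
    params: SimParams | None = None

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    def dosage_frame(self, which: str = "offspring") -> pd.DataFrame:
        mat = {"offspring": self.offspring_dosage,
               "maternal": self.maternal_dosage,
               "paternal": self.paternal_dosage}[which]
        return pd.DataFrame(mat, columns=list(self.snp_ids),
                            index=self.phenotypes.index)

    def to_frame(self) -> pd.DataFrame:
        """Phenotypes plus offspring dosage columns, one row per offspring."""
        return pd.concat([self.phenotypes, self.dosage_frame()], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def write_raw(self, path) -> None:
        """Write offspring dosages in the PLINK ``.raw`` additive dialect."""
        from .io import write_raw
        write_raw(path, self.dosage_frame(), dict(zip(self.snp_ids, self.effect_alleles)),
                  sex=self.phenotypes["sex"].to_numpy() if self.n else None)


def draw_parental_genotypes(
    freqs: Sequence[float], n: int, rng: np.random.Generator,
    spousal_corr: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw maternal and paternal haplotype pairs under HWE.

    Returns two ``(n, n_snps, 2)`` 0/1 arrays. Each allele is an independent
    Bernoulli(freq) draw; with ``spousal_corr = s`` each paternal allele is,
    with probability ``s``, a copy of the corresponding maternal allele
    (giving a spousal dosage correlation of ``s``), else an independent draw.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ParameterError("freqs must be a non-empty 1-D sequence")
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        bad = freqs[(freqs <= 0.0) | (freqs >= 1.0)]
        raise ParameterError(f"allele frequencies outside (0, 1): {bad.tolist()}")
    if not 0.0 <= spousal_corr < 1.0:
        raise ParameterError("spousal_corr must lie in [0, 1)")
    m = freqs.size
    maternal = (rng.random((n, m, 2)) < freqs[None, :, None]).astype(np.int8)
    paternal = (rng.random((n, m, 2)) < freqs[None, :, None]).astype(np.int8)
    if spousal_corr > 0.0 and n > 0:
        copy = rng.random((n, m, 2)) < spousal_corr
        paternal = np.where(copy, maternal, paternal).astype(np.int8)
    return maternal, paternal


def transmit(
    maternal_haplotypes: np.ndarray, paternal_haplotypes: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one allele per parent per SNP; return offspring haplotypes.

    The returned ``(n, n_snps, 2)`` array stores the maternally transmitted
    allele at index 0 and the paternally transmitted allele at index 1, so
    Mendelian consistency can be verified against the retained parents.
    """
    mh = np.asarray(maternal_haplotypes)
    ph = np.asarray(paternal_haplotypes)
    if mh.shape != ph.shape or mh.ndim != 3 or mh.shape[-1] != 2:
        raise StructuralError(
            f"parental haplotype shapes {mh.shape} and {ph.shape} must match "
            "and be (n, n_snps, 2)")
    n, m, _ = mh.shape
    pick_m = rng.integers(0, 2, size=(n, m))
    pick_p = rng.integers(0, 2, size=(n, m))
    rows = np.arange(n)[:, None]
    cols = np.arange(m)[None, :]
    offspring = np.stack([mh[rows, cols, pick_m], ph[rows, cols, pick_p]], axis=2)
    return offspring.astype(np.int8)


def simulate_exposure(
    maternal_dosage: np.ndarray, u: np.ndarray, params: SimParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate maternal smoking status and cigarettes/day.

    Initiation depends on the total effect-allele count (the collider path
    when ``init_per_allele != 0``) and on the confounder; heaviness among
    smokers is the weighted dosage plus Gaussian noise around
    ``exposure_mean``, truncated at zero. ``cigs_per_day`` is NaN exactly for
    non-smokers.
    """
    if params.exposure_sd < 0:
        raise ParameterError("exposure_sd must be non-negative")
    dosage = np.asarray(maternal_dosage, dtype=float)
    n = dosage.shape[0]
    allele_count = dosage.sum(axis=1)
    from scipy.special import expit, logit

    eta = logit(params.init_base) + params.init_per_allele * allele_count \
        + params.conf_on_init * np.asarray(u, dtype=float)
    smoked = (rng.random(n) < expit(eta)).astype(np.int8)
    genetic = dosage @ np.asarray(params.snp_weights, dtype=float)
    heaviness = params.exposure_mean + genetic + rng.normal(0.0, params.exposure_sd, size=n)
    heaviness = np.maximum(heaviness, 0.0)
    cigs = np.where(smoked == 1, heaviness, np.nan)
    return smoked, cigs


def simulate_outcomes(
    offspring_dosage: np.ndarray, smoked: np.ndarray, cigs: np.ndarray,
    u: np.ndarray, params: SimParams, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate left-handedness and birthweight given the exposure fields."""
    smoked = np.asarray(smoked)
    cigs = np.asarray(cigs, dtype=float)
    if smoked.shape != cigs.shape:
        raise SequencingError("smoking status and cigarettes/day have mismatched shapes")
    if np.any((smoked == 1) & ~np.isfinite(cigs)):
        raise SequencingError("cigs_per_day missing for a smoking mother; "
                              "run simulate_exposure first")
    from scipy.special import expit

    dosage = np.asarray(offspring_dosage, dtype=float)
    n = dosage.shape[0]
    cigs_eff = np.where(smoked == 1, cigs, 0.0)
    eta = (params.outcome_base_logit
           + params.causal_beta * cigs_eff
           + params.pleiotropy_beta * dosage.sum(axis=1)
           + params.conf_on_outcome * np.asarray(u, dtype=float))
    left_handed = (rng.random(n) < expit(eta)).astype(np.int8)
    bw = (params.bw_base + params.bw_theta * cigs_eff
          + params.conf_on_birthweight * np.asarray(u, dtype=float)
          + rng.normal(0.0, params.bw_sd, size=n))
    # enforce positivity; never binds at realistic parameter values
    bw = np.maximum(bw, 0.2)
    return left_handed, bw


def generate_cohort(params: SimParams) -> Cohort:
    """Generate a fully populated cohort; bit-identical for identical
    (params, seed)."""
    rng = np.random.default_rng(params.seed)
    n = params.n_pairs
    mh, ph = draw_parental_genotypes(params.allele_freqs, n, rng,
                                     spousal_corr=params.spousal_corr)
    oh = transmit(mh, ph, rng)
    u = rng.normal(0.0, params.confounder_sd, size=n)
    smoked, cigs = simulate_exposure(mh.sum(axis=2), u, params, rng)
    left, bw = simulate_outcomes(oh.sum(axis=2), smoked, cigs, u, params, rng)

    sex = (rng.random(n) < 1.0 - FEMALE_FRACTION).astype(np.int8)  # 1 = male
    multiple = (rng.random(n) < MULTIPLE_BIRTH_FRACTION).astype(np.int8)
    breastfed = (rng.random(n) < BREASTFED_FRACTION).astype(np.int8)
    birth_year = rng.integers(BIRTH_YEAR_RANGE[0], BIRTH_YEAR_RANGE[1] + 1, size=n)
    birth_month = rng.integers(1, 13, size=n)
    country = rng.choice(COUNTRY_LEVELS, size=n, p=COUNTRY_PROBS) if n else \
        np.array([], dtype=object)
    townsend = rng.normal(0.0, 1.0, size=n)

    phenotypes = pd.DataFrame({
        "maternal_smoked": smoked.astype(int),
        "cigs_per_day": cigs,
        "left_handed": left.astype(int),
        "birthweight_kg": bw,
        "sex": sex.astype(int),
        "multiple_birth": multiple.astype(int),
        "breastfed": breastfed.astype(int),
        "birth_year": birth_year.astype(int),
        "birth_month": birth_month.astype(int),
        "country": country,
        "townsend": townsend,
        "confounder_u": u,
    }, columns=PHENOTYPE_COLUMNS)

    return Cohort(
        phenotypes=phenotypes,
        offspring_dosage=oh.sum(axis=2).astype(np.int8),
        maternal_dosage=mh.sum(axis=2).astype(np.int8),
        paternal_dosage=ph.sum(axis=2).astype(np.int8),
        snp_ids=params.resolved_snp_ids(),
        effect_alleles=params.resolved_effect_alleles(),
        maternal_haplotypes=mh,
        paternal_haplotypes=ph,
        offspring_haplotypes=oh,
        params=params,
    )


def weight_for_r2(freq: float, target_r2: float, exposure_sd: float) -> float:
    """Per-allele weight so a single SNP explains ``target_r2`` of the
    exposure variance among smokers.

    Solves ``w^2 * 2p(1-p) = target_r2 / (1 - target_r2) * exposure_sd^2``.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ParameterError("target_r2 must lie in (0, 1)")
    var_g = 2.0 * freq * (1.0 - freq)
    return float(np.sqrt(target_r2 / (1.0 - target_r2) * exposure_sd**2 / var_g))


def ukb_preset(n_pairs: int = 50_000, seed: int = 0, **overrides) -> SimParams:
    """UK-Biobank-like single-SNP scenario: rs16969968-style variant at
    frequency 0.33 explaining ~0.4% of cigarettes/day among smokers, 30.6%
    smoking mothers, 9.8% left-handed baseline."""
    base = dict(
        n_pairs=n_pairs,
        allele_freqs=(0.33,),
        snp_weights=(weight_for_r2(0.33, 0.004, 9.0),),
        exposure_mean=13.0,
        exposure_sd=9.0,
        init_base=0.306,
        snp_ids=("rs16969968",),
        effect_alleles=("A",),
        seed=seed,
    )
    base.update(overrides)
    return SimParams(**base)


def check_mendelian(cohort: Cohort) -> bool:
    """Every offspring allele is a member of the source parent's pair."""
    if cohort.offspring_haplotypes is None or cohort.maternal_haplotypes is None:
        raise SequencingError("haplotypes not retained; cannot check Mendelian consistency")
    oh, mh, ph = (cohort.offspring_haplotypes, cohort.maternal_haplotypes,
                  cohort.paternal_haplotypes)
    from_mother = (oh[:, :, 0] == mh[:, :, 0]) | (oh[:, :, 0] == mh[:, :, 1])
    from_father = (oh[:, :, 1] == ph[:, :, 0]) | (oh[:, :, 1] == ph[:, :, 1])
    return bool(np.all(from_mother) and np.all(from_father))
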
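"""Proxy gene-by-environment Mendelian randomization engine.

The offspring's genotype proxies the (unobserved) maternal genotype for
smoking heaviness. The cohort is stratified on maternal smoking during
pregnancy; within each stratum the instrument-outcome association is
estimated by logistic regression, and the instrument-exposure association
(the shared Wald denominator) by linear regression of cigarettes/day on the
instrument among smoking mothers. The per-stratum Wald ratio

    beta_IV = beta_GY / beta_GX

carries a first-order delta-method standard error; because maternal smoking
heaviness cannot act in the unexposed stratum, its Wald ratio estimates the
pleiotropic bias, and the corrected causal effect is the between-stratum
difference with independent-strata SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import DegenerateDataError, ParameterError, StructuralError, \
    WeakInstrumentWarning

__all__ = [
    "StratumAssociation",
    "WaldEstimate",
    "CorrectedEstimate",
    "ProxyMRResult",
    "stratify",
    "genetic_association",
    "wald_ratio",
    "pleiotropy_correct",
    "run_proxy_mr",
    "control_checks",
]

Z95 = scipy.stats.norm.ppf(0.975)
#: |beta_gx| / se_gx below this (an F < 10 equivalent) triggers a warning
WEAK_INSTRUMENT_T = 3.16


@dataclass
class StratumAssociation:
    """Instrument coefficient within one maternal-smoking stratum
    (log-odds for logistic family, raw slope for linear)."""

    stratum: str
    instrument: str
    beta: float
    se: float
    p: float
    n: int
    family: str = "logistic"
    covariate_set: str = "unadjusted"
    converged: bool = True

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ParameterError("stratum association needs n > 0")
        if self.se <= 0:
            raise ParameterError("stratum association needs se > 0")


@dataclass
class WaldEstimate:
    """Instrumental-variable estimate: log-odds of left-handedness per
    cigarette/day smoked by the mother."""

    beta_iv: float
    se_iv: float
    ci_low: float
    ci_high: float
    stratum: str = ""
    instrument: str = ""

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta_iv <= self.ci_high:
            raise ParameterError("Wald CI must bracket the point estimate")

    @property
    def p(self) -> float:
        return float(2.0 * scipy.stats.norm.sf(abs(self.beta_iv) / self.se_iv))


@dataclass
class CorrectedEstimate:
    """Pleiotropy-corrected causal effect: exposed-stratum Wald estimate
    minus the unexposed-stratum (no-relevance) estimate."""

    beta_corrected: float
    se: float
    ci_low: float
    ci_high: float
    instrument: str = ""

    @property
    def p(self) -> float:
        return float(2.0 * scipy.stats.norm.sf(abs(self.beta_corrected) / self.se))


def stratify(
    df: pd.DataFrame, column: str = "maternal_smoked",
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Split on maternal smoking status; rows with missing status are
    dropped and counted. Returns (exposed, unexposed, n_dropped)."""
    if column not in df.columns:
        raise StructuralError(f"column {column!r} not in cohort")
    status = pd.to_numeric(df[column], errors="coerce")
    dropped = int(status.isna().sum())
    exposed = df[status == 1]
    unexposed = df[status == 0]
    return exposed, unexposed, dropped


def genetic_association(
    instrument, outcome, covariates: pd.DataFrame | None = None,
    family: str = "logistic", stratum: str = "", instrument_label: str = "",
    covariate_set: str | None = None,
) -> StratumAssociation:
    """Per-unit-instrument coefficient with Wald SE and two-sided p, on
    complete cases, optionally adjusted for covariates."""
    if family not in ("logistic", "linear"):
        raise ParameterError(f"unknown family {family!r}")
    inst = pd.Series(np.asarray(instrument, dtype=float), name="instrument")
    y = pd.Series(np.asarray(outcome, dtype=float), name="y")
    parts = [y, inst]
    if covariates is not None:
        cov = covariates.reset_index(drop=True).astype(float)
        parts = [y, inst, cov]
    data = pd.concat([p.reset_index(drop=True) if isinstance(p, pd.Series) else p
                      for p in parts], axis=1).dropna()
    if len(data) < 3:
        raise DegenerateDataError("fewer than 3 complete cases for association")
    X = sm.add_constant(data.drop(columns="y"), has_constant="add")
    yv = data["y"].to_numpy()
    converged = True
    with np.errstate(all="ignore"):
        if family == "logistic":
            if not np.isin(yv, (0.0, 1.0)).all():
                raise ParameterError("logistic family requires a binary outcome")
            res = sm.Logit(yv, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        else:
            res = sm.OLS(yv, X).fit()
    return StratumAssociation(
        stratum=stratum, instrument=instrument_label,
        beta=float(res.params["instrument"]), se=float(res.bse["instrument"]),
        p=float(res.pvalues["instrument"]), n=int(len(data)), family=family,
        covariate_set=covariate_set or ("adjusted" if covariates is not None
                                        else "unadjusted"),
        converged=converged)


def wald_ratio(
    beta_gy: float, se_gy: float, beta_gx: float, se_gx: float,
    stratum: str = "", instrument: str = "",
    weak_t: float = WEAK_INSTRUMENT_T,
) -> WaldEstimate:
    """Wald ratio ``beta_gy / beta_gx`` with first-order delta-method SE

        se_iv = sqrt(se_gy²/beta_gx² + beta_gy²·se_gx²/beta_gx⁴)

    and 95% normal CI. Numerator-denominator covariance is ignored (they
    come from different subsets). ``beta_gx = 0`` raises; a weak instrument
    (|beta_gx|/se_gx < weak_t, an F < 10 equivalent) warns.
    """
    if beta_gx == 0.0:
        raise ParameterError("beta_gx is zero: Wald ratio undefined")
    if se_gy <= 0 or se_gx <= 0:
        raise ParameterError("standard errors must be positive")
    if abs(beta_gx) / se_gx < weak_t:
        warnings.warn(
            f"weak instrument: |beta_gx|/se_gx = {abs(beta_gx) / se_gx:.2f} < {weak_t}",
            WeakInstrumentWarning)
    beta_iv = beta_gy / beta_gx
    se_iv = float(np.sqrt(se_gy**2 / beta_gx**2
                          + beta_gy**2 * se_gx**2 / beta_gx**4))
    return WaldEstimate(beta_iv=float(beta_iv), se_iv=se_iv,
                        ci_low=float(beta_iv - Z95 * se_iv),
                        ci_high=float(beta_iv + Z95 * se_iv),
                        stratum=stratum, instrument=instrument)


def pleiotropy_correct(
    exposed: WaldEstimate, unexposed: WaldEstimate,
) -> CorrectedEstimate:
    """Subtract the unexposed-stratum (pleiotropy-only) Wald estimate from
    the exposed-stratum estimate; SE combines the strata as independent
    (disjoint individuals): ``sqrt(se_exposed² + se_unexposed²)``."""
    if exposed.instrument != unexposed.instrument:
        raise StructuralError(
            f"mismatched instruments: {exposed.instrument!r} vs "
            f"{unexposed.instrument!r}")
    beta = exposed.beta_iv - unexposed.beta_iv
    se = float(np.sqrt(exposed.se_iv**2 + unexposed.se_iv**2))
    return CorrectedEstimate(beta_corrected=float(beta), se=se,
                             ci_low=float(beta - Z95 * se),
                             ci_high=float(beta + Z95 * se),
                             instrument=exposed.instrument)


@dataclass
class ProxyMRResult:
    """Full output of one proxy GxE MR run."""

    assoc_exposed: StratumAssociation
    assoc_unexposed: StratumAssociation
    denominator: StratumAssociation
    wald_exposed: WaldEstimate
    wald_unexposed: WaldEstimate
    corrected: CorrectedEstimate
    n_dropped: int = 0

    def frame(self) -> pd.DataFrame:
        rows = []
        for a in (self.assoc_exposed, self.assoc_unexposed, self.denominator):
            rows.append({"kind": "association", "stratum": a.stratum,
                         "instrument": a.instrument, "estimate": a.beta,
                         "se": a.se, "ci_low": a.beta - Z95 * a.se,
                         "ci_high": a.beta + Z95 * a.se, "p": a.p, "n": a.n,
                         "family": a.family, "covariate_set": a.covariate_set})
        for w in (self.wald_exposed, self.wald_unexposed):
            rows.append({"kind": "wald", "stratum": w.stratum,
                         "instrument": w.instrument, "estimate": w.beta_iv,
                         "se": w.se_iv, "ci_low": w.ci_low, "ci_high": w.ci_high,
                         "p": w.p, "n": np.nan, "family": "", "covariate_set": ""})
        c = self.corrected
        rows.append({"kind": "corrected", "stratum": "difference",
                     "instrument": c.instrument, "estimate": c.beta_corrected,
                     "se": c.se, "ci_low": c.ci_low, "ci_high": c.ci_high,
                     "p": c.p, "n": np.nan, "family": "", "covariate_set": ""})
        return pd.DataFrame(rows)


def run_proxy_mr(
    df: pd.DataFrame, instrument, covariates: pd.DataFrame | None = None,
    outcome: str = "left_handed", exposure: str = "cigs_per_day",
    smoking_column: str = "maternal_smoked", instrument_label: str = "instrument",
) -> ProxyMRResult:
    """End-to-end stratified proxy MR on a cohort frame.

    ``instrument`` is a per-row vector (SNP dosage or PRS) aligned with
    ``df``. The Wald denominator regresses the exposure on the instrument
    among smoking mothers and is shared by both strata's ratios.
    """
    inst = pd.Series(np.asarray(instrument, dtype=float), index=df.index,
                     name="instrument")
    work = df.copy()
    work["_instrument"] = inst
    exposed, unexposed, n_dropped = stratify(work, smoking_column)
    if exposed.empty or unexposed.empty:
        raise DegenerateDataError("both smoking strata must be non-empty for proxy MR")

    def cov_for(sub: pd.DataFrame) -> pd.DataFrame | None:
        if covariates is None:
            return None
        return covariates.loc[sub.index].reset_index(drop=True)

    assoc_exp = genetic_association(
        exposed["_instrument"], exposed[outcome], cov_for(exposed),
        family="logistic", stratum="exposed", instrument_label=instrument_label)
    assoc_une = genetic_association(
        unexposed["_instrument"], unexposed[outcome], cov_for(unexposed),
        family="logistic", stratum="unexposed", instrument_label=instrument_label)
    denom = genetic_association(
        exposed["_instrument"], exposed[exposure], cov_for(exposed),
        family="linear", stratum="smokers", instrument_label=instrument_label)

    wald_exp = wald_ratio(assoc_exp.beta, assoc_exp.se, denom.beta, denom.se,
                          stratum="exposed", instrument=instrument_label)
    wald_une = wald_ratio(assoc_une.beta, assoc_une.se, denom.beta, denom.se,
                          stratum="unexposed", instrument=instrument_label)
    corrected = pleiotropy_correct(wald_exp, wald_une)
    return ProxyMRResult(assoc_exposed=assoc_exp, assoc_unexposed=assoc_une,
                         denominator=denom, wald_exposed=wald_exp,
                         wald_unexposed=wald_une, corrected=corrected,
                         n_dropped=n_dropped)


DEFAULT_CONTROLS = {
    "birthweight_kg": "linear",      # positive control
    "sex": "logistic",               # negative controls below
    "multiple_birth": "logistic",
    "breastfed": "logistic",
    "birth_year": "linear",
    "townsend": "linear",
}


def control_checks(
    df: pd.DataFrame, instrument, controls: dict[str, str] | None = None,
    covariates: pd.DataFrame | None = None,
    smoking_column: str = "maternal_smoked", instrument_label: str = "instrument",
) -> pd.DataFrame:
    """Positive (birthweight) and negative (exchangeability) control
    regressions of each control phenotype on the instrument, per stratum."""
    controls = controls or DEFAULT_CONTROLS
    inst = pd.Series(np.asarray(instrument, dtype=float), index=df.index)
    work = df.copy()
    work["_instrument"] = inst
    exposed, unexposed, _ = stratify(work, smoking_column)
    rows = []
    for stratum_name, sub in (("exposed", exposed), ("unexposed", unexposed)):
        cov = covariates.loc[sub.index].reset_index(drop=True) \
            if covariates is not None else None
        for pheno, family in controls.items():
            if pheno not in sub.columns:
                continue
            a = genetic_association(
                sub["_instrument"], sub[pheno], cov, family=family,
                stratum=stratum_name, instrument_label=instrument_label)
            rows.append({"phenotype": pheno, "stratum": stratum_name,
                         "family": family, "beta": a.beta, "se": a.se,
                         "ci_low": a.beta - Z95 * a.se,
                         "ci_high": a.beta + Z95 * a.se, "p": a.p, "n": a.n})
    return pd.DataFrame(rows)
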
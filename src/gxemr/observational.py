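"""Traditional observational stage: logistic regressions of handedness on
early-life predictors, with seasonal month encoding, McFadden pseudo-R² and
the pairwise association matrix (Cramér's V / Pearson / Spearman).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import DegenerateDataError, ParameterError, StructuralError

__all__ = [
    "PredictorSpec",
    "RegressionResult",
    "LogisticFit",
    "AssociationMeasure",
    "encode_month",
    "build_design",
    "fit_logistic",
    "multivariable_fit",
    "univariable_fits",
    "pairwise_association",
]

Z95 = scipy.stats.norm.ppf(0.975)


@dataclass(frozen=True)
class PredictorSpec:
    """How one predictor enters the design matrix.

    role: "binary", "categorical" or "continuous".
    transform: "none", "seasonal-cosine" (birth month) or "z-score".
    Categorical terms are dummy-coded against ``reference_level``.
    """

    name: str
    role: str = "continuous"
    reference_level: str | None = None
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.role not in ("binary", "categorical", "continuous"):
            raise ParameterError(f"unknown predictor role {self.role!r}")
        if self.transform not in ("none", "seasonal-cosine", "z-score"):
            raise ParameterError(f"unknown transform {self.transform!r}")
        if self.role == "categorical" and self.reference_level is None:
            raise ParameterError(
                f"categorical predictor {self.name!r} needs a reference_level")


@dataclass
class RegressionResult:
    """One fitted term: odds ratio (or slope), Wald 95% CI and p-value."""

    term: str
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    model_id: str = ""
    converged: bool = True


@dataclass
class LogisticFit:
    """A fitted logistic model: per-term results plus fit diagnostics."""

    results: list[RegressionResult]
    n_used: int
    pseudo_r2: float
    loglik: float
    loglik_null: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    def result_for(self, term: str) -> RegressionResult:
        for r in self.results:
            if r.term == term:
                return r
        raise KeyError(term)


@dataclass
class AssociationMeasure:
    value: float | None
    measure_type: str
    reason: str | None = None


def encode_month(month) -> np.ndarray | float:
    """Seasonal cosine encoding of birth month.

    ``s(m) = cos(pi * (m - 6.5) / 3)``: a 6-month period with maxima in the
    UK summer (June/July) and winter (December/January) and minima in
    spring and autumn. Scalar in, scalar out.
    """
    arr = np.asarray(month)
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr != np.floor(arr)) \
            or np.any((arr < 1) | (arr > 12)):
        raise ParameterError("month must be an integer in 1..12")
    out = np.cos(np.pi * (arr - 6.5) / 3.0)
    return float(out) if np.isscalar(month) or arr.ndim == 0 else out


def build_design(df: pd.DataFrame, specs: list[PredictorSpec]) -> pd.DataFrame:
    """Encode predictors per their specs into a numeric design frame.

    Rows with missing values are retained as NaN; complete-case filtering is
    the fitting routine's job, so the caller can count exclusions.
    """
    cols: dict[str, pd.Series] = {}
    for spec in specs:
        if spec.name not in df.columns:
            raise StructuralError(f"predictor column {spec.name!r} not in data")
        x = df[spec.name]
        if spec.role == "categorical":
            levels = x.dropna().unique().tolist()
            if spec.reference_level not in levels:
                raise StructuralError(
                    f"reference level {spec.reference_level!r} absent from "
                    f"{spec.name!r} (levels: {sorted(map(str, levels))})")
            for lev in sorted(str(v) for v in levels):
                if lev == str(spec.reference_level):
                    continue
                ind = (x.astype(str) == lev).astype(float)
                ind[x.isna()] = np.nan
                cols[f"{spec.name}[{lev}]"] = ind
            continue
        x = pd.to_numeric(x, errors="coerce")
        if spec.transform == "seasonal-cosine":
            enc = pd.Series(np.nan, index=x.index)
            ok = x.notna()
            enc[ok] = encode_month(x[ok].astype(int).to_numpy())
            cols[f"{spec.name}_cos"] = enc
        elif spec.transform == "z-score":
            mu, sd = x.mean(), x.std(ddof=0)
            if sd == 0:
                raise DegenerateDataError(f"{spec.name!r} is constant; cannot z-score")
            cols[f"{spec.name}_z"] = (x - mu) / sd
        else:
            cols[spec.name] = x.astype(float)
    return pd.DataFrame(cols, index=df.index)


def _collinear_terms(X: np.ndarray, names: list[str]) -> list[str]:
    # columns whose removal restores full rank, found via QR pivoting
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    return [names[i] for i in np.where(diag <= tol)[0]]


def fit_logistic(
    outcome, design: pd.DataFrame, add_intercept: bool = True,
    model_id: str = "",
) -> LogisticFit:
    """Maximum-likelihood logistic fit on complete cases.

    Per-term OR = exp(beta) with 95% Wald CI and two-sided Wald p.
    Separation / non-convergence is flagged on the returned object rather
    than raised; rank deficiency raises naming the collinear terms.
    """
    y = pd.Series(np.asarray(outcome), index=design.index, name="y")
    data = pd.concat([y, design], axis=1)
    data = data.dropna()
    if data.empty:
        raise DegenerateDataError("no complete cases after dropping missing values")
    yv = data["y"].to_numpy(dtype=float)
    if not np.isin(yv, (0.0, 1.0)).all():
        raise ParameterError("outcome must be binary 0/1")
    X = data.drop(columns="y")
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = _collinear_terms(X.to_numpy(), list(X.columns))
        raise StructuralError(f"design matrix is rank-deficient; collinear terms: {bad}")

    flags: list[str] = []
    model = sm.Logit(yv, X)
    with np.errstate(all="ignore"):
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:  # perfect separation raises in statsmodels
            flags.append(f"fit failed: {exc}")
            res = model.fit(method="bfgs", disp=0, maxiter=500)
            converged = False
    if not converged:
        flags.append("non-convergence or separation; estimates unreliable")

    params, bse, pvals = res.params, res.bse, res.pvalues
    n_used = int(len(data))
    results = []
    for term in X.columns:
        if term == "const":
            continue
        b, s = float(params[term]), float(bse[term])
        results.append(RegressionResult(
            term=term, beta=b, se=s, odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - Z95 * s)), ci_high=float(np.exp(b + Z95 * s)),
            p_value=float(pvals[term]), n_used=n_used, model_id=model_id,
            converged=converged))
    llf, llnull = float(res.llf), float(res.llnull)
    pseudo_r2 = 1.0 - llf / llnull if llnull != 0 else 0.0
    return LogisticFit(results=results, n_used=n_used, pseudo_r2=pseudo_r2,
                       loglik=llf, loglik_null=llnull, converged=converged,
                       flags=flags)


def univariable_fits(
    df: pd.DataFrame, outcome: str, specs: list[PredictorSpec],
) -> list[LogisticFit]:
    """One logistic fit per predictor against the outcome."""
    return [fit_logistic(df[outcome], build_design(df, [spec]),
                         model_id=f"univariable:{spec.name}")
            for spec in specs]


def multivariable_fit(
    df: pd.DataFrame, outcome: str, specs: list[PredictorSpec],
    pcs: pd.DataFrame | None = None,
) -> LogisticFit:
    """Joint logistic fit of all predictors (plus optional precomputed
    principal-component covariates) on complete cases, reporting McFadden
    pseudo-R² = 1 − ℓ_model/ℓ_null."""
    design = build_design(df, specs)
    if pcs is not None:
        design = pd.concat([design, pcs.reindex(design.index)], axis=1)
    return fit_logistic(df[outcome], design, model_id="multivariable")


def cramers_v(x, y) -> float:
    """Cramér's V = sqrt(chi² / (n · (min(r, c) − 1))), uncorrected chi²."""
    table = pd.crosstab(pd.Series(x), pd.Series(y))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateDataError("a variable is constant; Cramér's V undefined")
    chi2 = scipy.stats.chi2_contingency(table.to_numpy(), correction=False)[0]
    n = table.to_numpy().sum()
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def pairwise_association(
    x, y, x_role: str = "continuous", y_role: str = "continuous",
) -> AssociationMeasure:
    """Dispatch on variable roles: Cramér's V for two categoricals, Pearson
    for two continuous variables, Spearman's rho for a mixed pair."""
    xs, ys = pd.Series(x), pd.Series(y)
    ok = xs.notna() & ys.notna()
    xs, ys = xs[ok], ys[ok]
    cat = {"binary": True, "categorical": True, "continuous": False}
    try:
        x_cat, y_cat = cat[x_role], cat[y_role]
    except KeyError as exc:
        raise ParameterError(f"unknown variable role {exc}") from None
    for name, s in (("x", xs), ("y", ys)):
        if s.nunique() < 2:
            return AssociationMeasure(None, "undefined",
                                      reason=f"{name} is constant on complete cases")
    if x_cat and y_cat:
        return AssociationMeasure(cramers_v(xs, ys), "cramers_v")
    if not x_cat and not y_cat:
        r = scipy.stats.pearsonr(xs.astype(float), ys.astype(float))[0]
        return AssociationMeasure(float(r), "pearson")
    rho = scipy.stats.spearmanr(xs.astype(float) if not x_cat else xs.astype("category").cat.codes,
                                ys.astype(float) if not y_cat else ys.astype("category").cat.codes)[0]
    return AssociationMeasure(float(rho), "spearman")


def default_predictor_specs() -> list[PredictorSpec]:
    """The early-life predictor set with its standard encodings."""
    return [
        PredictorSpec("sex", "binary"),
        PredictorSpec("multiple_birth", "binary"),
        PredictorSpec("maternal_smoked", "binary"),
        PredictorSpec("breastfed", "binary"),
        PredictorSpec("country", "categorical", reference_level="England"),
        PredictorSpec("birth_year", "continuous"),
        PredictorSpec("birthweight_kg", "continuous"),
        PredictorSpec("birth_month", "continuous", transform="seasonal-cosine"),
        PredictorSpec("townsend", "continuous", transform="z-score"),
    ]
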
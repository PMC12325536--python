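"""Causal-engine tests: stratification, Wald-ratio arithmetic against the
delta-method formula, pleiotropy correction on the published stratum
estimates, and the pleiotropy signature in simulation."""

import numpy as np
import pandas as pd
import pytest

from gxemr.errors import (DegenerateDataError, ParameterError,
                          StructuralError, WeakInstrumentWarning)
from gxemr.proxymr import (WaldEstimate, control_checks, genetic_association,
                           pleiotropy_correct, run_proxy_mr, stratify,
                           wald_ratio)
from gxemr.synthdata import generate_cohort, ukb_preset, weight_for_r2

from oracles import grid_logistic_mle

STRONG = (weight_for_r2(0.33, 0.02, 9.0),)


def se_from_ci(lo, hi):
    return (hi - lo) / (2 * 1.959964)


def wald_from_table(beta, lo, hi, stratum, instrument):
    return WaldEstimate(beta_iv=beta, se_iv=se_from_ci(lo, hi), ci_low=lo,
                        ci_high=hi, stratum=stratum, instrument=instrument)


def test_stratify_partitions_and_counts_missing():
    df = pd.DataFrame({"maternal_smoked": [1, 0, 1, np.nan, 0, 1, 0, 0, 1, 0]})
    exposed, unexposed, dropped = stratify(df)
    assert len(exposed) == 4 and len(unexposed) == 5 and dropped == 1
    assert len(exposed) + len(unexposed) + dropped == len(df)
    all_smoked = pd.DataFrame({"maternal_smoked": [1, 1, 1]})
    _, unexp, _ = stratify(all_smoked)
    assert unexp.empty


def test_stratify_exposed_fraction_under_preset():
    cohort = generate_cohort(ukb_preset(n_pairs=50_000, seed=2))
    exposed, unexposed, _ = stratify(cohort.phenotypes)
    assert len(exposed) / cohort.n == pytest.approx(0.306, abs=0.01)


def test_wald_ratio_formula():
    # beta_gy = 0 limit
    w = wald_ratio(0.0, 0.02, 0.5, 0.001)
    assert w.beta_iv == 0.0
    assert w.se_iv == pytest.approx(0.02 / 0.5)
    # frozen delta-method value for (0.02, 0.01, 0.4, 0.05):
    # sqrt(0.01²/0.4² + 0.02²·0.05²/0.4⁴) = 0.0257694
    w = wald_ratio(0.02, 0.01, 0.4, 0.05)
    assert w.beta_iv == pytest.approx(0.05)
    assert w.se_iv == pytest.approx(0.0257694, abs=1e-6)
    assert w.ci_low < w.beta_iv < w.ci_high


def test_wald_ratio_guards():
    with pytest.raises(ParameterError):
        wald_ratio(0.1, 0.05, 0.0, 0.01)
    with pytest.warns(WeakInstrumentWarning):
        wald_ratio(0.1, 0.05, 0.01, 0.02)


def test_wald_ratio_invariant_to_allele_recoding(rng):
    # recoding dosage -> 2 - dosage flips both association betas;
    # the ratio is unchanged
    n = 30_000
    g = rng.binomial(2, 0.4, size=n).astype(float)
    cigs = 10 + 1.5 * g + rng.normal(0, 6, size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-2.2 + 0.02 * cigs)))).astype(int)
    num = genetic_association(g, y, family="logistic")
    den = genetic_association(g, cigs, family="linear")
    num_f = genetic_association(2 - g, y, family="logistic")
    den_f = genetic_association(2 - g, cigs, family="linear")
    w = wald_ratio(num.beta, num.se, den.beta, den.se)
    w_f = wald_ratio(num_f.beta, num_f.se, den_f.beta, den_f.se)
    assert num_f.beta == pytest.approx(-num.beta, abs=1e-10)
    assert w_f.beta_iv == pytest.approx(w.beta_iv, abs=1e-10)
    assert w_f.se_iv == pytest.approx(w.se_iv, abs=1e-10)


def test_pleiotropy_correct_identical_strata_gives_zero():
    w = wald_from_table(0.1, 0.0, 0.2, "exposed", "snp")
    u = wald_from_table(0.1, 0.0, 0.2, "unexposed", "snp")
    c = pleiotropy_correct(w, u)
    assert c.beta_corrected == 0.0
    assert c.se == pytest.approx(np.sqrt(2) * w.se_iv)


def test_pleiotropy_correct_published_stratum_estimates():
    """Adjusted single-SNP and PRS stratum Wald ratios recombine to the
    published corrected effects (0.0216 and 0.0114)."""
    snp_e = wald_from_table(-0.0135, -0.0650, 0.0381, "exposed", "rs16969968")
    snp_u = wald_from_table(-0.0351, -0.0732, 0.00311, "unexposed", "rs16969968")
    c = pleiotropy_correct(snp_e, snp_u)
    assert c.beta_corrected == pytest.approx(0.0216, abs=5e-5)
    assert c.ci_low == pytest.approx(-0.0426, abs=2e-3)
    assert c.ci_high == pytest.approx(0.0857, abs=2e-3)

    prs_e = wald_from_table(-0.0133, -0.0625, 0.0360, "exposed", "prs")
    prs_u = wald_from_table(-0.0247, -0.0597, 0.0103, "unexposed", "prs")
    c = pleiotropy_correct(prs_e, prs_u)
    assert c.beta_corrected == pytest.approx(0.0114, abs=5e-5)
    assert c.ci_low == pytest.approx(-0.0490, abs=2e-3)
    assert c.ci_high == pytest.approx(0.0719, abs=2e-3)


def test_pleiotropy_correct_mismatched_instruments():
    w = wald_from_table(0.1, 0.0, 0.2, "exposed", "snp")
    u = wald_from_table(0.1, 0.0, 0.2, "unexposed", "prs")
    with pytest.raises(StructuralError):
        pleiotropy_correct(w, u)


def test_genetic_association_matches_grid_oracle():
    y = np.array([0, 1, 0, 1, 1, 0, 0])
    g = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 1.0])
    a = genetic_association(g, y, family="logistic")
    _, b1 = grid_logistic_mle(y, g)
    assert a.beta == pytest.approx(b1, abs=1e-3)


def test_genetic_association_null_on_permuted_outcome(rng):
    n = 5_000
    g = rng.binomial(2, 0.4, size=n).astype(float)
    y = rng.permutation(np.repeat([0, 1], [n - 500, 500]))
    a = genetic_association(g, y, family="logistic")
    assert abs(a.beta) < 3.5 * a.se


def test_pleiotropy_appears_in_both_strata():
    """With a purely pleiotropic variant (no causal path), the
    dosage-handedness association is present in BOTH smoking strata — the
    signature separating pleiotropy from causation."""
    p = ukb_preset(n_pairs=200_000, seed=11, snp_weights=STRONG,
                   causal_beta=0.0, pleiotropy_beta=0.1)
    cohort = generate_cohort(p)
    df = cohort.phenotypes
    g = cohort.offspring_dosage.sum(axis=1)
    for stratum in (0, 1):
        mask = (df.maternal_smoked == stratum).to_numpy()
        a = genetic_association(g[mask], df.left_handed.to_numpy()[mask])
        assert a.beta / a.se > 3.0


def test_run_proxy_mr_needs_both_strata():
    p = ukb_preset(n_pairs=200, seed=1, init_base=0.999)
    cohort = generate_cohort(p)
    if cohort.phenotypes.maternal_smoked.min() == 1:  # all smoked
        with pytest.raises(DegenerateDataError):
            run_proxy_mr(cohort.phenotypes, cohort.offspring_dosage.sum(axis=1))


def test_control_checks_birthweight_sign_pattern():
    """Positive control: negative instrument-birthweight slope only in the
    exposed stratum; genotype-independent covariates stay null."""
    p = ukb_preset(n_pairs=200_000, seed=19, snp_weights=STRONG,
                   bw_theta=-0.03)
    cohort = generate_cohort(p)
    table = control_checks(cohort.phenotypes,
                           cohort.offspring_dosage.sum(axis=1))
    bw = table[table.phenotype == "birthweight_kg"].set_index("stratum")
    assert bw.loc["exposed", "beta"] / bw.loc["exposed", "se"] < -3
    assert abs(bw.loc["unexposed", "beta"] / bw.loc["unexposed", "se"]) < 3
    negatives = table[table.phenotype.isin(["sex", "breastfed", "townsend"])]
    assert (negatives.beta.abs() / negatives.se < 3.5).all()


def test_run_proxy_mr_end_to_end_recovers_causal_effect():
    """Strong instrument, moderate causal effect, no pleiotropy: both the
    exposed-stratum Wald estimate and the corrected estimate sit near the
    generating per-cigarette log-odds."""
    p = ukb_preset(n_pairs=150_000, seed=29, snp_weights=STRONG,
                   causal_beta=0.02)
    cohort = generate_cohort(p)
    res = run_proxy_mr(cohort.phenotypes, cohort.offspring_dosage.sum(axis=1))
    assert res.wald_exposed.beta_iv == pytest.approx(0.02, abs=3 * res.wald_exposed.se_iv)
    assert res.corrected.ci_low < 0.02 < res.corrected.ci_high
    frame = res.frame()
    assert set(frame.kind) == {"association", "wald", "corrected"}
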
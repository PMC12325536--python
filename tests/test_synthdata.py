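"""Generator tests: Hardy-Weinberg structure, Mendelian transmission,
exposure/outcome models and the determinism contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gxemr.errors import ParameterError, SequencingError, StructuralError
from gxemr.synthdata import (SimParams, check_mendelian,
                             draw_parental_genotypes, generate_cohort,
                             simulate_exposure, transmit, ukb_preset,
                             weight_for_r2)
from gxemr.prs import variance_explained


@pytest.mark.parametrize("freq", [0.1, 0.33, 0.5])
def test_hwe_genotype_class_frequencies(rng, freq):
    n = 100_000
    mh, _ = draw_parental_genotypes([freq], n, rng)
    dosage = mh.sum(axis=2)[:, 0]
    expected = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq ** 2])
    observed = np.bincount(dosage, minlength=3) / n
    mc_se = np.sqrt(expected * (1 - expected) / n)
    assert np.all(np.abs(observed - expected) < 3 * mc_se + 1e-12)
    if freq == 0.5:
        assert abs(dosage.mean() - 1.0) < 0.01


def test_hwe_homozygote_fraction_at_ukb_frequency(rng):
    # class-0 fraction (1 - 0.33)^2 = 0.4489, the observed UKB pattern
    mh, _ = draw_parental_genotypes([0.33], 200_000, rng)
    p0 = np.mean(mh.sum(axis=2)[:, 0] == 0)
    assert p0 == pytest.approx(0.449, abs=0.005)


def test_invalid_allele_frequency_rejected(rng):
    for bad in (0.0, 1.0, -0.2, 1.5):
        with pytest.raises(ParameterError):
            draw_parental_genotypes([bad], 10, rng)
    with pytest.raises(ParameterError):
        SimParams(n_pairs=10, allele_freqs=(1.2,), snp_weights=(0.5,))


def test_transmission_forced_heterozygote_and_punnett(rng):
    n = 20_000
    # mother hom-alt, father hom-ref -> offspring always heterozygous
    mh = np.ones((n, 1, 2), dtype=np.int8)
    ph = np.zeros((n, 1, 2), dtype=np.int8)
    off = transmit(mh, ph, rng).sum(axis=2)[:, 0]
    assert np.all(off == 1)
    # both parents heterozygous -> (1/4, 1/2, 1/4)
    het = np.tile(np.array([1, 0], dtype=np.int8), (n, 1, 1))
    off = transmit(het, het, rng).sum(axis=2)[:, 0]
    props = np.bincount(off, minlength=3) / n
    assert np.allclose(props, [0.25, 0.5, 0.25], atol=0.015)


def test_transmission_shape_mismatch(rng):
    with pytest.raises(StructuralError):
        transmit(np.zeros((5, 1, 2)), np.zeros((4, 1, 2)), rng)


def test_mother_offspring_dosage_correlation(rng):
    n = 200_000
    mh, ph = draw_parental_genotypes([0.3], n, rng)
    off = transmit(mh, ph, rng)
    r = np.corrcoef(mh.sum(axis=2)[:, 0], off.sum(axis=2)[:, 0])[0, 1]
    assert r == pytest.approx(0.5, abs=0.01)


def test_spousal_correlation_parameter(rng):
    n = 100_000
    mh, ph = draw_parental_genotypes([0.4], n, rng, spousal_corr=0.3)
    r = np.corrcoef(mh.sum(axis=2)[:, 0], ph.sum(axis=2)[:, 0])[0, 1]
    assert r == pytest.approx(0.3, abs=0.02)


@settings(max_examples=20, deadline=None)
@given(freq=st.floats(0.05, 0.95), seed=st.integers(0, 2**31 - 1),
       n=st.integers(1, 200))
def test_mendelian_consistency_property(freq, seed, n):
    cohort = generate_cohort(SimParams(n_pairs=n, allele_freqs=(freq, 0.5),
                                       snp_weights=(0.5, 0.5), seed=seed))
    assert check_mendelian(cohort)
    assert np.isin(cohort.offspring_dosage, [0, 1, 2]).all()


def test_seed_reproducibility_and_divergence():
    p = ukb_preset(n_pairs=2_000, seed=42)
    a, b = generate_cohort(p), generate_cohort(p)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    assert np.array_equal(a.offspring_dosage, b.offspring_dosage)
    c = generate_cohort(p.replace(seed=43))
    assert not a.phenotypes["left_handed"].equals(c.phenotypes["left_handed"])


def test_empty_cohort_is_valid():
    cohort = generate_cohort(ukb_preset(n_pairs=0))
    assert cohort.n == 0
    assert cohort.offspring_dosage.shape == (0, 1)
    assert list(cohort.to_frame().columns)  # schema intact


def test_cigs_missing_exactly_for_nonsmokers():
    cohort = generate_cohort(ukb_preset(n_pairs=20_000, seed=3))
    df = cohort.phenotypes
    assert df.loc[df.maternal_smoked == 0, "cigs_per_day"].isna().all()
    assert df.loc[df.maternal_smoked == 1, "cigs_per_day"].notna().all()
    assert (df.loc[df.maternal_smoked == 1, "cigs_per_day"] >= 0).all()
    # only cigs_per_day may be missing
    assert not df.drop(columns="cigs_per_day").isna().any().any()


def test_negative_exposure_sd_rejected():
    with pytest.raises(ParameterError):
        SimParams(n_pairs=10, exposure_sd=-1.0)


def test_initiation_independent_of_genotype_by_default():
    cohort = generate_cohort(ukb_preset(n_pairs=100_000, seed=5))
    g = cohort.maternal_dosage[:, 0]
    s = cohort.phenotypes["maternal_smoked"].to_numpy()
    # slope of smoked on dosage under independence: |slope| < 3 * se
    slope = np.cov(g, s)[0, 1] / np.var(g)
    se = np.sqrt(np.var(s) / (len(g) * np.var(g)))
    assert abs(slope) < 3 * se


def test_initiation_depends_on_genotype_when_enabled():
    p = ukb_preset(n_pairs=100_000, seed=5, init_per_allele=0.2)
    cohort = generate_cohort(p)
    g = cohort.maternal_dosage[:, 0]
    s = cohort.phenotypes["maternal_smoked"].to_numpy()
    assert s[g == 2].mean() > s[g == 0].mean() + 0.02


def test_zero_weights_give_flat_exposure():
    p = ukb_preset(n_pairs=100_000, seed=9, snp_weights=(0.0,))
    cohort = generate_cohort(p)
    df = cohort.phenotypes
    smokers = df.maternal_smoked == 1
    g = cohort.maternal_dosage[smokers.to_numpy(), 0]
    cigs = df.loc[smokers, "cigs_per_day"].to_numpy()
    slope = np.cov(g, cigs)[0, 1] / np.var(g)
    assert abs(slope) < 3 * np.std(cigs) / np.sqrt(len(g) * np.var(g))


def test_exposure_variance_decomposition_oracle():
    # weight chosen for 1% of cigs/day variance among smokers -> R^2 ~ 0.01
    w = weight_for_r2(0.33, 0.01, 9.0)
    p = ukb_preset(n_pairs=100_000, seed=13, snp_weights=(w,), init_base=0.6)
    cohort = generate_cohort(p)
    df = cohort.phenotypes
    smokers = (df.maternal_smoked == 1).to_numpy()
    r2 = variance_explained(cohort.maternal_dosage[smokers, 0],
                            df.loc[smokers, "cigs_per_day"])
    assert r2 == pytest.approx(0.01, abs=0.003)


def test_baseline_prevalences_match_preset():
    cohort = generate_cohort(ukb_preset(n_pairs=100_000, seed=17))
    df = cohort.phenotypes
    assert df.left_handed.mean() == pytest.approx(0.0982, abs=0.004)
    assert df.maternal_smoked.mean() == pytest.approx(0.306, abs=0.006)
    assert df.birthweight_kg.mean() == pytest.approx(3.33, abs=0.02)
    assert df.sex.mean() == pytest.approx(1 - 0.545, abs=0.006)


def test_pleiotropy_free_null_has_no_dosage_handedness_association():
    cohort = generate_cohort(ukb_preset(n_pairs=150_000, seed=21))
    df = cohort.phenotypes
    g = cohort.offspring_dosage[:, 0]
    for stratum in (0, 1):
        mask = (df.maternal_smoked == stratum).to_numpy()
        y = df.left_handed.to_numpy()[mask]
        gm = g[mask]
        slope = np.cov(gm, y)[0, 1] / np.var(gm)
        se = np.sqrt(np.var(y) / (mask.sum() * np.var(gm)))
        assert abs(slope) < 3.5 * se


def test_birthweight_slope_negative_only_in_exposed_stratum():
    p = ukb_preset(n_pairs=200_000, seed=23, bw_theta=-0.03,
                   snp_weights=(weight_for_r2(0.33, 0.02, 9.0),))
    cohort = generate_cohort(p)
    df = cohort.phenotypes
    g = cohort.offspring_dosage[:, 0]

    def slope_z(mask):
        y = df.birthweight_kg.to_numpy()[mask]
        gm = g[mask]
        slope = np.cov(gm, y)[0, 1] / np.var(gm)
        return slope / (np.std(y) / np.sqrt(mask.sum() * np.var(gm)))

    assert slope_z((df.maternal_smoked == 1).to_numpy()) < -3
    assert abs(slope_z((df.maternal_smoked == 0).to_numpy())) < 3


def test_outcome_requires_exposure_fields(rng):
    from gxemr.synthdata import simulate_outcomes
    p = ukb_preset(n_pairs=5)
    smoked = np.array([1, 0, 1, 0, 0], dtype=np.int8)
    cigs = np.array([np.nan, np.nan, 10.0, np.nan, np.nan])
    with pytest.raises(SequencingError):
        simulate_outcomes(np.ones((5, 1)), smoked, cigs, np.zeros(5), p, rng)
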
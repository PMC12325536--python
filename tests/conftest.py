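import numpy as np
import pandas as pd
import pytest

from gxemr.prs import SummaryStatRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_correlated_panel(rng, n_ind=400, blocks=((3, 0.95), (2, 0.6), (2, 0.0))):
    """Dosage panel with LD blocks: within a block, each SNP copies the
    block's lead dosage with the given per-allele probability."""
    cols = {}
    positions = []
    snp_idx = 0
    pos = 1000
    for block_size, copy_prob in blocks:
        lead = rng.binomial(2, 0.4, size=n_ind)
        for k in range(block_size):
            noise = rng.binomial(2, 0.4, size=n_ind)
            copy = rng.random(n_ind) < copy_prob
            cols[f"snp{snp_idx}"] = np.where(copy, lead, noise)
            positions.append(pos)
            pos += 5000
            snp_idx += 1
        pos += 50_000
    return pd.DataFrame(cols), positions


def make_stats(panel_cols, positions, rng, chrom="1", p_max=1e-9):
    recs = []
    alleles = [("A", "G"), ("C", "A"), ("G", "T"), ("T", "C")]
    for i, (snp, pos) in enumerate(zip(panel_cols, positions)):
        ea, oa = alleles[i % len(alleles)]
        recs.append(SummaryStatRecord(
            snp_id=snp, chrom=chrom, pos=int(pos), effect_allele=ea,
            other_allele=oa, beta=float(rng.normal(0.5, 0.2)),
            se=0.05, p=float(rng.uniform(1e-12, p_max))))
    return recs


@pytest.fixture
def ld_panel(rng):
    return make_correlated_panel(rng)


@pytest.fixture
def sumstats_12(rng):
    """A 12-variant genome-wide-significant summary-stat set (synthetic
    stand-in for the 12 clumped smoking-heaviness signals)."""
    rows = []
    for i in range(12):
        rows.append({"SNP": f"rs{1000 + i}", "CHR": str(1 + i % 8),
                     "POS": 1_000_000 * (i + 1), "EA": "A", "OA": "G",
                     "BETA": round(float(rng.normal(0.5, 0.15)), 3),
                     "SE": 0.04, "P": 1e-10})
    return pd.DataFrame(rows)
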
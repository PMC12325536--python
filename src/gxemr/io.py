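"""File formats: PLINK `.raw`-dialect dosage files, dosage TSVs, GWAS
summary-statistics TSVs and cohort tables.

Conventions: SNP positions are 1-based, dosage files are whitespace
separated, TSV output is UTF-8 with "NA" as the missing sentinel.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError, StructuralError
from .prs import SummaryStatRecord

log = logging.getLogger("gxemr")

__all__ = [
    "write_raw",
    "read_genotypes",
    "read_sumstats",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "DEFAULT_SUMSTAT_COLUMNS",
]

RAW_META_COLUMNS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]

#: default header names for summary-statistics TSVs
DEFAULT_SUMSTAT_COLUMNS = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "POS",
    "effect_allele": "EA", "other_allele": "OA",
    "beta": "BETA", "se": "SE", "p": "P",
}


def write_raw(path, dosages: pd.DataFrame, counted_alleles: Mapping[str, str],
              sex=None) -> None:
    """Write dosages in the PLINK `.raw` additive dialect: the six metadata
    columns then one ``SNP_ALLELE`` column per variant, space-separated."""
    n = len(dosages)
    missing = [s for s in dosages.columns if s not in counted_alleles]
    if missing:
        raise StructuralError(f"no counted allele recorded for: {missing}")
    out = pd.DataFrame({
        "FID": np.arange(1, n + 1), "IID": np.arange(1, n + 1),
        "PAT": 0, "MAT": 0,
        "SEX": (np.asarray(sex) + 1 if sex is not None else np.zeros(n, dtype=int)),
        "PHENOTYPE": -9,
    })
    for snp in dosages.columns:
        out[f"{snp}_{counted_alleles[snp]}"] = dosages[snp].to_numpy()
    out.to_csv(path, sep=" ", index=False, na_rep="NA")


def _parse_raw_header(columns: list[str]) -> dict[str, str]:
    alleles = {}
    for col in columns[len(RAW_META_COLUMNS):]:
        snp, _, allele = col.rpartition("_")
        if not snp or len(allele) != 1 or allele not in "ACGT":
            raise ParameterError(
                f"malformed .raw dosage column {col!r}: expected SNP_ALLELE")
        alleles[snp] = allele
    return alleles


def read_genotypes(path, dialect: str = "plink-raw") -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a dosage matrix.

    ``plink-raw``: whitespace-separated with FID IID PAT MAT SEX PHENOTYPE
    then SNP_ALLELE columns; the counted allele is parsed from each column
    suffix. ``tsv``: first column is the individual id, the rest are SNP
    columns (no allele metadata). Returns (dosages indexed by IID, counted
    alleles per SNP). Dosages must lie in [0, 2] or be missing.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"genotype file not found: {path}")
    if path.stat().st_size == 0:
        raise ParameterError(f"genotype file is empty: {path}")
    if dialect == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        if list(df.columns[:6]) != RAW_META_COLUMNS:
            raise ParameterError(
                f"{path}: malformed .raw header; expected {RAW_META_COLUMNS} "
                f"got {list(df.columns[:6])}")
        alleles = _parse_raw_header(list(df.columns))
        dosages = df.iloc[:, 6:].copy()
        dosages.columns = list(alleles)
        dosages.index = df["IID"]
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        if df.shape[1] < 2:
            raise ParameterError(f"{path}: dosage TSV needs an id column plus SNPs")
        dosages = df.set_index(df.columns[0])
        alleles = {}
    else:
        raise ConfigError(f"unknown genotype dialect {dialect!r}")
    for col in dosages.columns:
        vals = pd.to_numeric(dosages[col], errors="coerce")
        bad = vals.notna() & ((vals < 0) | (vals > 2))
        nonnum = dosages[col].notna() & vals.isna()
        if nonnum.any():
            line = int(np.where(nonnum)[0][0]) + 2  # +1 header, +1 one-based
            raise ParameterError(f"{path}:{line}: non-numeric dosage in {col!r}")
        if bad.any():
            line = int(np.where(bad)[0][0]) + 2
            raise ParameterError(f"{path}:{line}: dosage outside [0, 2] in {col!r}")
        dosages[col] = vals
    return dosages, alleles


def read_sumstats(
    path, column_map: Mapping[str, str] | None = None,
) -> tuple[list[SummaryStatRecord], pd.DataFrame]:
    """Read GWAS summary statistics; invalid rows are collected in a
    rejects frame (with reasons) rather than aborting the run."""
    colmap = dict(DEFAULT_SUMSTAT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing mandatory columns {missing}")
    records, rejects = [], []
    for i, row in df.iterrows():
        try:
            rec = SummaryStatRecord(
                snp_id=str(row[colmap["snp_id"]]),
                chrom=str(row[colmap["chrom"]]),
                pos=int(row[colmap["pos"]]),
                effect_allele=str(row[colmap["effect_allele"]]).upper(),
                other_allele=str(row[colmap["other_allele"]]).upper(),
                beta=float(row[colmap["beta"]]),
                se=float(row[colmap["se"]]),
                p=float(row[colmap["p"]]))
        except (ParameterError, ValueError, TypeError) as exc:
            rejects.append({"row": int(i) + 2, "snp": str(row.get(colmap["snp_id"], "?")),
                            "reason": str(exc)})
            continue
        records.append(rec)
    rejects_df = pd.DataFrame(rejects, columns=["row", "snp", "reason"])
    if len(rejects_df):
        log.info("read_sumstats: rejected %d of %d rows", len(rejects_df), len(df))
    return records, rejects_df


def write_cohort_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort_tsv(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a cohort table written by the generator (or any TSV with a
    declared column map from file names to canonical names)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if column_map:
        df = df.rename(columns=dict(column_map))
    return df
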
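"""Tab-separated readers and writers.

One dialect everywhere: tab-delimited, '.' decimal, header row. P-value
tables carry one row per SNP; an optional leading ``snp_id`` column names
the SNPs, otherwise S1..Sn are assigned. Correlation matrices are square
tables with phenotype names as both header row and first column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .combine import CombinationResult, validate_correlation
from .simulate import SimulatedDataset

__all__ = [
    "read_pvalue_table",
    "write_pvalue_table",
    "read_corr_matrix",
    "write_corr_matrix",
    "write_results",
    "write_dataset",
    "read_dataset",
]

ID_COLUMNS = ("snp_id", "snp", "id")


def read_pvalue_table(path) -> pd.DataFrame:
    """Read a per-SNP p-value table; index = SNP ids, columns = phenotypes."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty p-value file")
    first = df.columns[0]
    if first.lower() in ID_COLUMNS:
        df = df.set_index(first)
    else:
        df.index = [f"S{i + 1}" for i in range(len(df))]
        df.index.name = "snp_id"
    values = df.to_numpy()
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed number ({exc})") from None
    if not np.isfinite(values).all() or (values < 0).any() or (values > 1).any():
        bad = np.where(~((values >= 0) & (values <= 1)))[0]
        raise ValueError(
            f"{path}: p-values outside [0, 1] in row(s) "
            f"{', '.join(str(df.index[i]) for i in np.unique(bad))}"
        )
    return df.astype(float)


def write_pvalue_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_corr_matrix(path) -> pd.DataFrame:
    """Read a square correlation matrix with name header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_correlation(df.to_numpy(dtype=float))
    return df.astype(float)


def write_corr_matrix(mat, path, names=None) -> None:
    mat = np.asarray(mat, dtype=float)
    if names is None:
        names = [f"pheno_{i + 1}" for i in range(mat.shape[0])]
    pd.DataFrame(mat, index=names, columns=names).to_csv(path, sep="\t")


def write_results(results: list[tuple[str, CombinationResult]], path) -> None:
    """Write combination-test rows: snp_id, method, combined_p, selected_rank."""
    rows = [
        {
            "snp_id": snp,
            "method": res.method,
            "combined_p": res.combined_p,
            "selected_rank": res.selected_index,
        }
        for snp, res in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dataset(data: SimulatedDataset, path) -> None:
    """Export one simulated dataset (columns genotype, pheno_1..pheno_m)."""
    m = data.phenotypes.shape[1]
    df = pd.DataFrame({"genotype": data.genotypes})
    for k in range(m):
        df[f"pheno_{k + 1}"] = data.phenotypes[:, k]
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path) -> SimulatedDataset:
    df = pd.read_csv(path, sep="\t")
    pheno_cols = [c for c in df.columns if c.startswith("pheno_")]
    if "genotype" not in df.columns or not pheno_cols:
        raise ValueError(f"{path}: expected columns genotype, pheno_1..pheno_m")
    return SimulatedDataset(
        df["genotype"].to_numpy(), df[pheno_cols].to_numpy(dtype=float)
    )
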
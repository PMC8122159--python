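"""Tabular I/O: abundance tables and per-gene index/count/frequency TSVs."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .core import CodonCounts, FrequencyVector
from .genetics import GeneticCode, standard_code


def read_abundance_tsv(path: str | Path, value_column: str = "abundance") -> pd.Series:
    """Read a gene_id -> abundance table (TSV, columns gene_id + value)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or value_column not in df.columns:
        raise ValueError(f"{path}: expected columns 'gene_id' and '{value_column}'")
    return df.set_index("gene_id")[value_column].astype(float)


def write_abundance_tsv(series: pd.Series, path: str | Path, value_column: str = "abundance") -> None:
    series.rename(value_column).rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def counts_table(
    all_counts: Iterable[CodonCounts],
    frequencies: Iterable[FrequencyVector] | None = None,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Long-form table: gene_id, codon, amino_acid, count[, frequency]."""
    code = code or standard_code()
    freq_by_gene = (
        {fv.gene_or_set_id: fv.freq for fv in frequencies} if frequencies is not None else None
    )
    rows = []
    for cc in all_counts:
        fmap = freq_by_gene.get(cc.gene_id, {}) if freq_by_gene is not None else None
        for codon in sorted(cc.counts):
            row = {
                "gene_id": cc.gene_id,
                "codon": codon,
                "amino_acid": code.codon_to_aa[codon],
                "count": cc.counts[codon],
            }
            if fmap is not None:
                row["frequency"] = fmap.get(codon)
            rows.append(row)
    return pd.DataFrame(rows)


def write_index_matrix_tsv(values: pd.DataFrame, path: str | Path) -> None:
    values.rename_axis("gene_id").to_csv(path, sep="\t")


def read_index_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
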
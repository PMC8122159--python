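"""Compute the gene x index matrix on the synthetic study genome.

Reads the inputs written by 01_simulate_inputs.py through the package's file
readers, computes all ten indices (ENC, FOP, CAI, CBI, CEC, tAI, nTE,
ChimeraARS, CPS, MTDR), and writes the matrix to results/index_matrix.tsv.
"""

import argparse
from pathlib import Path

from codonuse.core import read_cds_fasta
from codonuse.io import read_abundance_tsv, write_index_matrix_tsv
from codonuse.pipeline import IndexConfig, compute_index_matrix
from codonuse.rates import read_tdr_tsv
from codonuse.trna import read_affinity_tsv, read_trna_pool_tsv

BASE = Path(__file__).resolve().parent.parent / "results"
SYN = BASE / "synthetic"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    genes, report = read_cds_fasta(SYN / "genome.fasta")
    print(f"validated {len(report.accepted)}/{report.n_records} CDS records")
    expr = read_abundance_tsv(SYN / "abundance.tsv")
    pool = read_trna_pool_tsv(
        SYN / "trna_pool.tsv", affinity=read_affinity_tsv(SYN / "trna_affinity.tsv")
    )
    tdr = read_tdr_tsv(SYN / "tdr.tsv")

    config = IndexConfig(expression=expr, trna_pool=pool, mrna=expr, tdr=tdr)
    mat = compute_index_matrix(genes, config)
    write_index_matrix_tsv(mat.values, BASE / "index_matrix.tsv")

    print(f"computed {mat.values.shape[1]} indices for {mat.values.shape[0]} genes")
    if mat.missing_reasons:
        print(f"missing cells: {len(mat.missing_reasons)}")
    for name, why in mat.provenance.items():
        print(f"  {name}: {why}")


if __name__ == "__main__":
    main()
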
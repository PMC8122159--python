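"""Generate the synthetic study inputs.

Writes a 200-gene genome (beta ~ U(0,1) synonymous bias), a matched
protein-abundance table (log-linear in beta, noise sd 0.3), a tRNA pool
adapted to the designated optimal codons, and a per-codon decoding-rate
table, all under results/synthetic/.
"""

import argparse
from pathlib import Path

import pandas as pd

from codonuse.io import write_abundance_tsv
from codonuse.simulate import (
    SyntheticGenomeSpec,
    simulate_expression,
    simulate_genome,
    simulate_tdr_table,
    simulate_trna_pool,
    write_fasta,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=101)
    parser.add_argument("--n-genes", type=int, default=200)
    parser.add_argument("--length-codons", type=int, default=300)
    args = parser.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    gen = simulate_genome(
        SyntheticGenomeSpec(n_genes=args.n_genes, length_codons=args.length_codons, seed=args.seed)
    )
    expr = simulate_expression(gen.beta, noise_sd=0.3, seed=args.seed + 1)
    pool = simulate_trna_pool(gen.optimal_codon_map)
    tdr = simulate_tdr_table(seed=args.seed + 2, optimal_codon_map=gen.optimal_codon_map)

    write_fasta(gen.genes, OUT / "genome.fasta")
    write_abundance_tsv(expr, OUT / "abundance.tsv")
    gen.beta.rename_axis("gene_id").reset_index().to_csv(OUT / "beta.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(pool.tgcn.items()), columns=["anticodon", "tgcn"]
    ).to_csv(OUT / "trna_pool.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(c, a, s) for (c, a), s in sorted(pool.affinity.items())],
        columns=["codon", "anticodon", "s"],
    ).to_csv(OUT / "trna_affinity.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(tdr.tdr.items()), columns=["codon", "rate"]).to_csv(
        OUT / "tdr.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(gen.optimal_codon_map.items()), columns=["amino_acid", "optimal_codon"]
    ).to_csv(OUT / "optimal_codons.tsv", sep="\t", index=False)

    print(f"wrote {args.n_genes} genes ({args.length_codons} codons each) to {OUT}")
    print(f"abundance range: {expr.min():.2f} .. {expr.max():.2f}")


if __name__ == "__main__":
    main()
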
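# codonuse

Synonymous codons are not used equally: selection for translation efficiency
and mutational pressure leave every genome with its own codon-usage bias
(CUB), and the strength of that bias in a gene tracks how highly the gene is
expressed. Dozens of indices quantify this bias from different angles.
`codonuse` implements the main families of gene-level CUB indices on a common
substrate, profiles synonymous codon frequencies across genomes, and compares
indices against protein abundance (PA) the way such comparisons are done in
practice — as Spearman correlations over a gene × index matrix. A seeded
synthetic-genome generator makes the whole pipeline testable end to end
without any downloads.

It is aimed at people analysing coding sequences: pass in-frame CDS FASTA
files (one record per gene, longest isoform pre-selected) plus whatever
auxiliary tables each index needs.

## The indices

For a gene with codon counts $x_i$, family totals $N_a$ and degeneracy $K_a$:

- **RSCU** — $x_i / (N_a/K_a)$: observed over uniform-usage expectation.
- **ENC** (effective number of codons) — per-family homozygosity
  $\hat F = \sum_i p_i^2$ averaged within each degeneracy class $d$, then
  $\mathrm{ENC} = 2 + 9/\hat F_2 + 1/\hat F_3 + 5/\hat F_4 + 3/\hat F_6$,
  ranging 20 (one codon per amino acid) to 61 (uniform usage).
- **FOP** — fraction of codons that are family-optimal in a reference set of
  highly expressed genes (top 20% by PA by default).
- **CAI** — geometric mean of relative-adaptiveness weights
  $w_i = x_i/\max(\text{family } x)$ computed on the reference set.
- **CBI** — $(N_\mathrm{pfr} - N_\mathrm{rand})/(N_\mathrm{tot} - N_\mathrm{rand})$,
  the preferred-codon count rescaled against the uniform-usage expectation.
- **CEC** — Pearson correlation between the gene's per-codon enrichment
  (family frequency × $K_a$) and the reference set's relative codon
  frequencies.
- **tAI** — geometric mean of tRNA-supply weights
  $W_i = \sum_j (1-s_{ij})\,\mathrm{tGCN}_j$ (anticodon copy numbers
  discounted by wobble penalties), max-normalized.
- **nTE** — supply/demand: tAI weights divided by mRNA-weighted codon usage,
  renormalized, geometric-mean aggregated.
- **ChimeraARS** — mean, over start positions, of the longest substring
  starting there that occurs anywhere in a reference sequence set
  (nucleotide or codon alphabet).
- **CPS** — per-pair log-ratio
  $\ln\!\big(F(AB) \big/ \tfrac{F(A)F(B)}{F(X)F(Y)} F(XY)\big)$ of observed
  to expected codon-pair frequency, amino-acid corrected; gene score is the
  mean over its pairs.
- **MTDR** — geometric mean of per-codon typical decoding rates from an
  external table.

## Worked example

```python
import codonuse as cu

gen  = cu.simulate_genome(cu.SyntheticGenomeSpec(n_genes=200, length_codons=300, seed=101))
expr = cu.simulate_expression(gen.beta, noise_sd=0.3, seed=102)
pool = cu.simulate_trna_pool(gen.optimal_codon_map)
tdr  = cu.simulate_tdr_table(seed=103, optimal_codon_map=gen.optimal_codon_map)

mat = cu.compute_index_matrix(
    gen.genes,
    cu.IndexConfig(expression=expr, trna_pool=pool, mrna=expr, tdr=tdr),
)
report = cu.correlate_with_expression(mat, expr)
print(report.pairs[["name_a", "rho"]])
```

On this genome (gene-level bias β drawn uniformly, abundance log-linear in β)
the run prints, among others:

```
    cai  rho = +0.930
    fop  rho = +0.930
    tai  rho = +0.929
    enc  rho = -0.926
    nte  rho = +0.156
    cps  rho = -0.260
```

CAI, FOP, CBI, CEC, tAI, ChimeraARS and MTDR all track abundance strongly
and positively; ENC tracks it negatively because a *low* effective number of
codons means *strong* bias. nTE and CPS are weak or inverted on this
synthetic genome — expected behaviour, not a defect: the generator models
per-codon bias only, so supply/demand ratios and codon-pair preferences
carry almost no expression signal (see `docs/methods.md`). The same analysis
is packaged as numbered drivers:

```
python analysis/01_simulate_inputs.py     # genome + abundance + tRNA + rates
python analysis/02_codon_frequencies.py   # cross-genome frequency matrix
python analysis/03_index_matrix.py        # gene x index matrix
python analysis/04_index_comparison.py    # correlation reports
```

with tables written under `results/`.

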
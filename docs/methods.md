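# Methods

## Substrate

Every index operates on `CodonCounts`: a CDS is read in frame 0 as
consecutive, non-overlapping triplets; codons containing ambiguous IUPAC
bases are excluded from counts and reported per gene (no fractional
assignment exists that would not be arbitrary); stop codons are excluded from
all index arithmetic (an `include_stops` flag exists for frequency tables
only). Validation is strict by default — a record whose length is not a
multiple of 3, or that contains an internal stop, is rejected with its id —
because such records usually indicate annotation errors rather than data to
be salvaged. A lenient policy trims trailing partial codons and keeps
internal-stop records (their stops are skipped at counting), logging both.
Genetic codes come from the NCBI translation tables via Biopython; the
standard table (id 1) is the default and variant tables (mitochondria,
plastids) can be selected per genome. Reading frames other than 0, ORF
discovery and isoform selection are out of scope: callers supply one
in-frame CDS per gene.

## Index definitions and numerical choices

**ENC.** Per-family homozygosity uses the plug-in estimator
F = sum p_i^2 exactly; the bias-corrected form (nF−1)/(n−1) is available via
`corrected=True` but is not the default, because the plug-in form is the one
the index's common presentation writes down. Families observed fewer than 2
times are excluded from their class average — an F from n=1 is degenerate at
1 and would fabricate bias. The class constants (2 + 9/F2 + 1/F3 + 5/F4 +
3/F6) are derived from the genetic code's degeneracy census rather than
hard-coded, so variant codes get the analogous formula. When a degeneracy
class is absent: a missing 3-fold class is imputed as (F2+F4)/2 (Wright's
convention); any other missing class drops its term and the partial sum is
rescaled by max_attainable_full / max_attainable_partial; `policy="strict"`
raises instead. Values are capped at the code's maximum (61); with the
plug-in estimator the cap can only bind through the missing-class rescaling.
No short-gene correction is applied.

**CAI.** Weights are family-max-normalized counts in the reference set.
Zero-count codons receive a pseudo-count of 0.5 occurrences before division
(prevents log 0; configurable). Methionine, tryptophan and stops are
excluded from the geometric mean (the standard Sharp–Li convention — they
offer no synonymous choice); configurable. A family entirely absent from the
reference has undefined weights, reported rather than guessed.

**Reference sets.** Top ceil(fraction·N) genes by abundance, fraction 0.2 by
default, over the genes present in both the genome and the abundance table.
Ties at the cutoff are broken by (abundance desc, gene id asc) so selection
is deterministic regardless of input order.

**FOP / CBI.** The preferred (optimal) codon of each amino acid is its
maximum-occurrence codon in the reference set; ties resolve to the
lexicographically smallest codon by default, or `ties="all"` keeps every
tied codon (this changes the FOP numerator and CBI's per-amino-acid
preferred count). CBI excludes single-codon amino acids from all three of
its terms, since they contribute no choice; FOP follows its plain printed
definition (optimal / total counted codons).

**CEC.** Implemented from its textual description: the gene's per-codon
enrichment (within-family frequency divided by the uniform expectation 1/Ka)
is correlated — Pearson by default, matching the index's description as a
linear correlation coefficient; Spearman optional — against the reference
set's relative codon frequencies, over codons defined in both. The original
publication's exact normalization may differ in detail; this reading is the
documented interpretation. At least 3 shared families and nonzero variance
on both vectors are required.

**tAI.** Raw weight W_i = sum over decoding anticodons of (1−s_ij)·tGCN_j,
then division by the global maximum (required for the documented 0–1 range;
the raw sum alone is unbounded). The packaged default affinity table
contains Watson–Crick pairs at s=0 plus the standard third-position wobble
pairs at the original tAI publication's penalty constants (G:U 0.41, I:C
0.28, I:A 0.9999, U:G 0.68), restricted to anticodons whose Watson–Crick
codon is synonymous with the decoded codon — this exclusion removes
biologically spurious cross-family pairs (an Ile anticodon reading ATG, a
stop-cognate anticodon) without per-case special-casing. Whether a given
organism needs bacterial or eukaryotic wobble constants is the caller's
call: the table is a replaceable TSV input. Codons no tRNA can decode
receive the geometric mean of the defined normalized weights (the original
convention), reported; a strict mode raises.

**nTE.** Supply is the max-normalized tAI weight; demand is codon usage
weighted by mRNA copies over the transcriptome (U_i = sum_g n_ig·m_g),
max-normalized; per-codon nTE = supply/demand is max-normalized once more
and aggregated as a geometric mean. Genes whose abundance is missing are
dropped from the demand sum and reported; a `unit_copies` flag uses pooled
counts when no mRNA table exists, recorded in the demand provenance. A gene
codon with zero demand makes that gene's nTE undefined (reported), never
silently imputed.

**ChimeraARS.** Defined per position: the length of the longest substring
starting at that position that occurs anywhere in the reference, averaged
over positions; units are tokens of the chosen alphabet (nucleotides, or
codons — lengths then count triplets). The index structure is a suffix
automaton over the reference sequences separated by unique sentinels
(matches cannot span sequences); its answers are contract-checked against a
naive quadratic scan in the tests, which is the defining specification. When
the target is itself part of the reference it is excluded by id before
scoring — otherwise the score degenerates to the trivial suffix identity
(L+1)/2.

**CPS.** Pair counts are taken within genes only, over consecutive in-frame
codon pairs; pairs containing a stop or ambiguous codon are skipped. All six
frequency families (codon pair, codon, amino-acid pair, amino acid) are
computed from the same pair counts, i.e. codon and amino-acid frequencies
are the pair marginals — this keeps the families mutually consistent so that
a corpus at exact independence yields CPS = 0 identically. Pairs absent from
the corpus have undefined CPS and are skipped in gene means (count
reported); an optional pseudo-count smooths every sense-codon pair before
normalization. The corpus is an explicit parameter; the pipeline default is
the full genome.

**MTDR.** Geometric mean of per-codon decoding rates over the gene, stops
excluded. The rate table is an input (these rates are estimated from
ribosome profiling elsewhere; fitting them is out of scope) and is treated
as unitless — MTDR scales linearly with the table.

**Correlations.** Spearman with average-rank ties via scipy, pairwise-
complete deletion per pair (n reported per pair), p-values from the
large-sample approximation, no multiple-testing correction (a
Benjamini–Hochberg pass can be applied downstream if wanted). The index
matrix keeps missing cells explicit with a reason string per cell; nothing
is imputed.

## The synthetic generator

`simulate_genome` draws, per gene, amino acids iid from a composition
(uniform over the code's amino acids by default) and then chooses each
codon from its family by a convex mixture: with bias strength β, the
designated optimal codon has probability β + (1−β)/Ka and every sibling
(1−β)/Ka. The mixture makes the endpoints analytic — β=0 is exactly uniform
usage and β=1 forces FOP=1 and ENC=20 — which is why it is preferred over a
Dirichlet draw. Genes start with ATG, end with a single stop, contain no
internal stop, and carry at least two amino acids from each degeneracy class
so class-based statistics are always computable (minimum gene length 9
codons plus start). The default optimal-codon map is the alphabetically
first codon of each family — an arbitrary but fixed convention, replaceable
per run.

`simulate_expression` produces abundance exp(a + b·β + ε) with a=1, b=3,
ε ~ N(0, noise_sd); b=3 gives roughly a 20-fold dynamic range across β, a
deliberately modest stand-in for real protein-abundance ranges, and
noise_sd=0.3 leaves the bias–abundance rank correlation strong but not
degenerate. `simulate_trna_pool` gives the Watson–Crick anticodon of every
sense codon `low_copy` (default 1) gene copies, raised to `high_copy`
(default 10) for optimal codons; by default its affinity map is
Watson–Crick-only so that the optimal codons are exactly the weight-maximal
ones (β=1 genes then have tAI exactly 1); the packaged wobble table can be
used instead. `simulate_tdr_table` draws log-normal rates whose median is
`fast_factor` (default 3) times higher for optimal codons — the
supply-matched decoding-speed advantage observed in real data, and the
mechanism through which MTDR acquires an expression signal here. All
generators are pure functions of (spec, seed); identical seeds give
byte-identical FASTA output.

What the generator deliberately does **not** model: GC-content variation,
codon-pair-level selection, length–bias coupling, amino-acid composition
differences between highly and lowly expressed genes, and mutational
heterogeneity along genes. Passing end-to-end tests therefore demonstrates
that the indices recover a *synonymous, per-codon* bias signal coupled to
expression — not that they would rank a real genome identically, where those
confounders matter.

Two structural consequences are worth knowing. First, because pair structure
is absent, gene-level CPS on synthetic genomes reflects only the mixing of
gene-level bias: rare codons co-occur in low-bias genes, making rare–rare
pairs relatively the most overrepresented (per family, ln E[r²]/E[r]² =
ln 4/3 at β ~ U(0,1)), so CPS is a U-shaped, slightly rare-favouring
function of bias and correlates weakly *negatively* with abundance here —
in real genomes the positive CPS–expression relation comes from genuine
pair-level selection. Second, nTE divides a fixed 10× supply ratio by an
expression-weighted demand ratio that grows with family size (≈6× for
two-fold up to ≈16× for six-fold families), so its per-codon values have
mixed signs across degeneracy classes and its abundance correlation is weak
and seed-dependent (−0.25 to +0.86 across seeds at the default conditions) —
consistent with nTE's reputation as the outlier among these indices.

## Problem sizes

The shipped analysis uses 200 genes of 300 codons (β ~ U(0,1), noise 0.3),
40-gene genomes for the cross-genome frequency profile, and 100 seeded gene
pairs for the bias-recovery comparison; these sizes put every binomial
tolerance used in the tests well below the effects being checked while the
full suite stays fast on a single CPU.

## Known limitations

- CEC follows the summarized definition, not a line-by-line port of the
  original implementation.
- The packaged wobble penalties are the original tAI constants; organisms
  with unusual decoding (lysidine-modified anticodons, selenocysteine) need
  a custom affinity table.
- ENC's missing-class handling is a documented convention, not a fitted
  correction; genes short enough to lack whole degeneracy classes get more
  of their ENC from convention than from data.
- The abundance-vs-index comparison assumes one abundance value per gene;
  the multi-tissue helper is a plain arithmetic mean over columns.
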
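"""Reference-set indices: CAI, FOP, CBI and the codon-enrichment correlation.

All four compare a gene's codon usage against a reference set of highly
expressed genes — by convention the top 20% of genes by protein abundance.
CAI weights each codon by its relative adaptiveness in the reference set and
scores a gene as the geometric mean of its codon weights; FOP is the fraction
of codons that are family-optimal in the reference; CBI rescales the
preferred-codon count against the uniform-usage expectation; CEC correlates
the gene's per-family enrichment vector with the reference's relative codon
frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core import CodonCounts, codon_frequency, pool_counts
from .genetics import GeneticCode, standard_code


class ReferenceIndexError(ValueError):
    pass


@dataclass
class ReferenceSet:
    gene_ids: list[str]
    pooled_counts: CodonCounts
    selection_rule: str


@dataclass
class CodonWeights:
    """Per-codon relative adaptiveness in (0, 1], family-max (or global-max)
    normalized. Codons whose weight cannot be defined are reported, not
    silently given a value."""

    weights: dict[str, float]
    excluded_codons: frozenset[str] = frozenset()
    undefined_families: tuple[str, ...] = ()
    substituted_codons: tuple[str, ...] = ()


@dataclass
class PreferredCodonSet:
    """Per-amino-acid preferred (optimal) codons from a reference set."""

    preferred: dict[str, tuple[str, ...]]
    per_aa_count: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.per_aa_count = {aa: len(cs) for aa, cs in self.preferred.items()}

    def all_preferred(self) -> frozenset[str]:
        return frozenset(c for cs in self.preferred.values() for c in cs)


def select_reference_set(
    expression: Mapping[str, float],
    genome: Sequence[CodonCounts],
    fraction: float = 0.2,
) -> ReferenceSet:
    """Top ``ceil(fraction * N)`` genes by abundance, with pooled counts.

    N is the number of genome genes with an abundance value. Ties at the
    cutoff are broken deterministically: abundance descending, then gene id
    ascending.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    by_id = {cc.gene_id: cc for cc in genome}
    covered = [g for g in by_id if g in expression]
    if not covered:
        raise ReferenceIndexError("no overlap between expression table and genome")
    ranked = sorted(covered, key=lambda g: (-float(expression[g]), g))
    k = math.ceil(fraction * len(covered))
    chosen = ranked[:k]
    return ReferenceSet(
        gene_ids=chosen,
        pooled_counts=pool_counts([by_id[g] for g in chosen], set_id="reference"),
        selection_rule=f"top {fraction:g} by abundance ({k}/{len(covered)} genes)",
    )


def cai_weights(
    ref: ReferenceSet,
    code: GeneticCode | None = None,
    pseudo: float = 0.5,
    exclude_single_and_stops: bool = True,
) -> CodonWeights:
    """Relative adaptiveness w_i = x_i / max(family counts) in the reference.

    Zero-count codons receive ``pseudo`` occurrences before division so that
    log weights stay finite. Single-codon amino acids (Met, Trp under the
    standard code) and stops go to ``excluded_codons`` per the Sharp-Li
    convention; families entirely absent from the reference are undefined.
    """
    code = code or standard_code()
    pooled = ref.pooled_counts
    if pooled.n_codons == 0:
        raise ReferenceIndexError("reference set has empty pooled counts")
    weights: dict[str, float] = {}
    excluded: set[str] = set(code.stop_codons)
    undefined: list[str] = []
    for aa, family in code.families.items():
        if len(family) == 1 and exclude_single_and_stops:
            excluded.update(family)
            continue
        xs = {c: pooled.get(c) for c in family}
        mx = max(xs.values())
        if mx == 0:
            undefined.append(aa)
            continue
        for c, x in xs.items():
            weights[c] = (x if x > 0 else pseudo) / mx
    return CodonWeights(
        weights=weights,
        excluded_codons=frozenset(excluded),
        undefined_families=tuple(undefined),
    )


def geometric_mean_index(
    counts: CodonCounts,
    weights: Mapping[str, float],
    excluded: frozenset[str] = frozenset(),
) -> float:
    """exp(mean log weight) over the gene's scorable codons.

    Shared kernel of CAI, tAI, nTE and MTDR: codons in ``excluded`` or with
    no defined weight are skipped; at least one scorable codon is required.
    """
    log_sum = 0.0
    n = 0
    for codon, x in counts.counts.items():
        if codon in excluded:
            continue
        w = weights.get(codon)
        if w is None:
            continue
        if w <= 0:
            raise ValueError(f"non-positive weight {w} for codon {codon}")
        log_sum += x * math.log(w)
        n += x
    if n == 0:
        raise ReferenceIndexError(f"{counts.gene_id!r}: no scorable codons")
    return math.exp(log_sum / n)


def cai(counts: CodonCounts, weights: CodonWeights) -> float:
    """Codon adaptation index: geometric mean of reference weights, in (0, 1]."""
    return geometric_mean_index(counts, weights.weights, weights.excluded_codons)


def preferred_codons(
    ref: ReferenceSet,
    code: GeneticCode | None = None,
    ties: Literal["lexicographic", "all"] = "lexicographic",
) -> PreferredCodonSet:
    """Maximum-occurrence codon per amino acid in the reference set.

    Families absent from the reference are omitted. Ties at the maximum are
    resolved to the lexicographically smallest codon by default; ``ties="all"``
    keeps every tied codon (affects the FOP numerator and CBI's Oa_prf).
    """
    code = code or standard_code()
    pooled = ref.pooled_counts
    preferred: dict[str, tuple[str, ...]] = {}
    for aa, family in code.families.items():
        xs = {c: pooled.get(c) for c in family}
        mx = max(xs.values())
        if mx == 0:
            continue
        best = tuple(sorted(c for c, x in xs.items() if x == mx))
        preferred[aa] = best if ties == "all" else best[:1]
    return PreferredCodonSet(preferred=preferred)


def fop(counts: CodonCounts, preferred: PreferredCodonSet) -> float:
    """Frequency of optimal codons: optimal / total counted codons, in [0, 1]."""
    if counts.n_codons == 0:
        raise ReferenceIndexError(f"{counts.gene_id!r}: empty gene")
    opt = preferred.all_preferred()
    n_opt = sum(x for c, x in counts.counts.items() if c in opt)
    return n_opt / counts.n_codons


def cbi(
    counts: CodonCounts,
    preferred: PreferredCodonSet,
    code: GeneticCode | None = None,
) -> float:
    """Codon bias index: (Npfr - Nrand) / (Ntot - Nrand), in [-1, 1].

    Nrand is the preferred-codon count expected under uniform synonymous
    usage, sum_a Na * Oa_prf / Ka. Single-codon amino acids contribute no
    choice and are excluded from all three terms.
    """
    code = code or standard_code()
    opt = preferred.all_preferred()
    n_pfr = 0.0
    n_rand = 0.0
    n_tot = 0
    for aa, family in code.families.items():
        ka = len(family)
        if ka == 1:
            continue
        na = counts.per_aa_totals.get(aa, 0)
        if na == 0:
            continue
        oa = len([c for c in preferred.preferred.get(aa, ()) if c in opt])
        if oa == 0:
            continue
        n_tot += na
        n_rand += na * oa / ka
        n_pfr += sum(counts.get(c) for c in preferred.preferred[aa])
    if n_tot - n_rand <= 0:
        raise ReferenceIndexError(
            f"{counts.gene_id!r}: degenerate CBI denominator (Ntot={n_tot}, Nrand={n_rand})"
        )
    return (n_pfr - n_rand) / (n_tot - n_rand)


def cec_vectors(
    counts: CodonCounts,
    ref: ReferenceSet,
    code: GeneticCode | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """The two vectors behind CEC, over codons defined in both inputs.

    Returns (codons, target enrichment = family frequency * Ka, reference
    relative codon frequency).
    """
    code = code or standard_code()
    pooled = ref.pooled_counts
    if pooled.n_codons == 0:
        raise ReferenceIndexError("reference set has empty pooled counts")
    target_freq = codon_frequency(counts, code)
    codons: list[str] = []
    xs: list[float] = []
    ys: list[float] = []
    for codon in sorted(target_freq.freq):
        aa = code.codon_to_aa[codon]
        codons.append(codon)
        xs.append(target_freq.freq[codon] * len(code.families[aa]))
        ys.append(pooled.get(codon) / pooled.n_codons)
    return codons, np.asarray(xs), np.asarray(ys)


def cec(
    counts: CodonCounts,
    ref: ReferenceSet,
    code: GeneticCode | None = None,
    method: Literal["pearson", "spearman"] = "pearson",
) -> float:
    """Codon-enrichment correlation of a gene against a reference set.

    The gene's per-codon enrichment is its within-family frequency divided by
    the uniform expectation 1/Ka; the reference vector is each codon's
    relative frequency among all reference codons. The linear (Pearson)
    correlation over codons defined in both is returned; Spearman optional.
    """
    code = code or standard_code()
    codons, x, y = cec_vectors(counts, ref, code)
    fams = {code.codon_to_aa[c] for c in codons}
    if len(fams) < 3:
        raise ReferenceIndexError(
            f"{counts.gene_id!r}: only {len(fams)} shared families, need >= 3"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ReferenceIndexError(f"{counts.gene_id!r}: zero-variance enrichment vector")
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    return float(sps.pearsonr(x, y).statistic)
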
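"""Multi-codon pattern indices: ChimeraARS and the codon pair score (CPS).

ChimeraARS measures how much a coding region reuses substrings found
elsewhere in a reference set: for every start position in the target it takes
the length of the longest substring starting there that occurs anywhere in
the reference, and averages those lengths. Works on a nucleotide alphabet or
a codon-token alphabet (lengths then count codons).

CPS quantifies over/under-representation of a codon pair relative to the
independence expectation, corrected for amino-acid pair usage:

    CPS(AB) = ln( F(AB) / ( F(A) F(B) / (F(X) F(Y)) * F(XY) ) )

with codon-pair, codon, amino-acid-pair and amino-acid frequencies all taken
from the same corpus. A gene's CPS is the arithmetic mean over its
consecutive in-frame codon pairs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Literal, Sequence

from .core import CodingSequence, normalize_seq
from .genetics import GeneticCode, STOP, standard_code


class PatternIndexError(ValueError):
    pass


Alphabet = Literal["nucleotide", "codon"]


class _SuffixAutomaton:
    """Suffix automaton over a token sequence; recognizes exactly its substrings.

    Multiple sequences are indexed by appending each with a unique sentinel
    token, so no match can span two sequences.
    """

    __slots__ = ("next", "link", "length", "last")

    def __init__(self) -> None:
        self.next: list[dict[Hashable, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        self.last = 0

    def extend(self, ch: Hashable) -> None:
        cur = len(self.next)
        self.next.append({})
        self.length.append(self.length[self.last] + 1)
        self.link.append(-1)
        p = self.last
        while p != -1 and ch not in self.next[p]:
            self.next[p][ch] = cur
            p = self.link[p]
        if p == -1:
            self.link[cur] = 0
        else:
            q = self.next[p][ch]
            if self.length[p] + 1 == self.length[q]:
                self.link[cur] = q
            else:
                clone = len(self.next)
                self.next.append(dict(self.next[q]))
                self.length.append(self.length[p] + 1)
                self.link.append(self.link[q])
                while p != -1 and self.next[p].get(ch) == q:
                    self.next[p][ch] = clone
                    p = self.link[p]
                self.link[q] = clone
                self.link[cur] = clone
        self.last = cur

    def longest_prefix(self, tokens: Sequence[Hashable], start: int) -> int:
        """Length of the longest substring of the index starting at
        tokens[start]."""
        state = 0
        length = 0
        for i in range(start, len(tokens)):
            nxt = self.next[state].get(tokens[i])
            if nxt is None:
                break
            state = nxt
            length += 1
        return length


def _tokenize(seq: str, alphabet: Alphabet) -> tuple[str, ...]:
    seq = normalize_seq(seq)
    if alphabet == "nucleotide":
        return tuple(seq)
    if len(seq) % 3 != 0:
        raise PatternIndexError(f"codon alphabet needs length divisible by 3, got {len(seq)}")
    return tuple(seq[i : i + 3] for i in range(0, len(seq), 3))


@dataclass
class SubstringReference:
    """Queryable index over a reference sequence set.

    Built once per (reference, alphabet); answers longest-match-from-position
    queries identically to a naive scan of the raw sequences.
    """

    sequences: list[tuple[str, str]]
    alphabet: Alphabet = "nucleotide"
    _sa: _SuffixAutomaton = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise PatternIndexError("empty reference")
        self._sa = _SuffixAutomaton()
        for k, (_, seq) in enumerate(self.sequences):
            for tok in _tokenize(seq, self.alphabet):
                self._sa.extend(tok)
            self._sa.extend(("$", k))  # unique sentinel: matches cannot span sequences
            self._sa.last = 0

    @classmethod
    def from_cds(
        cls, genes: Iterable[CodingSequence], alphabet: Alphabet = "nucleotide"
    ) -> "SubstringReference":
        return cls([(g.gene_id, g.seq) for g in genes], alphabet=alphabet)

    def ids(self) -> frozenset[str]:
        return frozenset(gid for gid, _ in self.sequences)

    def without(self, gene_id: str) -> "SubstringReference":
        remaining = [(g, s) for g, s in self.sequences if g != gene_id]
        if not remaining:
            raise PatternIndexError(f"reference empty after excluding {gene_id!r}")
        return SubstringReference(remaining, alphabet=self.alphabet)

    def match_lengths(self, target: str) -> list[int]:
        """Per-start-position longest-match lengths of ``target``."""
        tokens = _tokenize(target, self.alphabet)
        return [self._sa.longest_prefix(tokens, p) for p in range(len(tokens))]


def naive_match_lengths(
    target: str, sequences: Sequence[tuple[str, str]], alphabet: Alphabet
) -> list[int]:
    """Quadratic reference scan used as the correctness oracle for the index."""
    tokens = _tokenize(target, alphabet)
    ref_tokens = [_tokenize(s, alphabet) for _, s in sequences]
    out = []
    for p in range(len(tokens)):
        best = 0
        for rt in ref_tokens:
            max_len = min(len(tokens) - p, len(rt))
            for ln in range(best + 1, max_len + 1):
                needle = tokens[p : p + ln]
                if any(rt[i : i + ln] == needle for i in range(len(rt) - ln + 1)):
                    best = ln
                else:
                    break
        out.append(best)
    return out


def chimera_ars(
    target: CodingSequence,
    ref: SubstringReference,
    exclude_self: bool = True,
) -> float:
    """Average repetitive substring score of ``target`` against ``ref``.

    Mean over start positions of the longest substring starting there that
    occurs in the reference; units are tokens of the reference's alphabet.
    When the target's id is present in the reference and ``exclude_self``,
    the reference is re-indexed without it (otherwise the score degenerates
    to the trivial suffix identity).
    """
    if not target.seq:
        raise PatternIndexError(f"{target.gene_id!r}: empty target")
    if exclude_self and target.gene_id in ref.ids():
        ref = ref.without(target.gene_id)
    lengths = ref.match_lengths(target.seq)
    return sum(lengths) / len(lengths)


@dataclass
class CodonPairTable:
    """Corpus frequencies for CPS: codon pairs, codons, amino-acid pairs,
    amino acids. Each family sums to 1 over its support."""

    pair_freq: dict[tuple[str, str], float]
    codon_freq: dict[str, float]
    aa_pair_freq: dict[tuple[str, str], float]
    aa_freq: dict[str, float]
    provenance: str = ""


def build_codon_pair_table(
    corpus: Iterable[CodingSequence],
    code: GeneticCode | None = None,
    pseudo_count: float = 0.0,
) -> CodonPairTable:
    """Count consecutive in-frame codon pairs within genes (never across gene
    boundaries); pairs containing a stop or ambiguous codon are excluded.

    ``pseudo_count`` > 0 adds that amount to every sense-codon pair before
    normalization (smoothing for corpora with unobserved pairs); amino-acid
    and single-codon frequencies are recomputed from the smoothed pair counts
    so the six frequency families stay mutually consistent.
    """
    code = code or standard_code()
    pair_counts: Counter[tuple[str, str]] = Counter()
    n_genes = 0
    for gene in corpus:
        n_genes += 1
        codons = [
            c
            for c in gene.codons()
            if not (set(c) - set("ACGT")) and code.codon_to_aa[c] != STOP
        ]
        for a, b in zip(codons, codons[1:]):
            pair_counts[(a, b)] += 1
    if n_genes == 0:
        raise PatternIndexError("empty corpus")
    if pseudo_count > 0:
        for a in code.sense_codons:
            for b in code.sense_codons:
                pair_counts[(a, b)] += pseudo_count
    total_pairs = sum(pair_counts.values())
    if total_pairs == 0:
        raise PatternIndexError("corpus contains no scorable codon pairs")

    codon_counts: Counter[str] = Counter()
    aa_pair_counts: Counter[tuple[str, str]] = Counter()
    aa_counts: Counter[str] = Counter()
    for (a, b), n in pair_counts.items():
        codon_counts[a] += n
        codon_counts[b] += n
        xa, xb = code.codon_to_aa[a], code.codon_to_aa[b]
        aa_pair_counts[(xa, xb)] += n
        aa_counts[xa] += n
        aa_counts[xb] += n

    total_codons = sum(codon_counts.values())
    return CodonPairTable(
        pair_freq={p: n / total_pairs for p, n in pair_counts.items()},
        codon_freq={c: n / total_codons for c, n in codon_counts.items()},
        aa_pair_freq={p: n / total_pairs for p, n in aa_pair_counts.items()},
        aa_freq={a: n / total_codons for a, n in aa_counts.items()},
        provenance=f"{n_genes} genes, {total_pairs:g} pairs, pseudo={pseudo_count:g}",
    )


def cps_pair(
    table: CodonPairTable,
    pair: tuple[str, str],
    code: GeneticCode | None = None,
) -> float:
    """CPS of one codon pair; None-equivalent cases raise (undefined)."""
    code = code or standard_code()
    a, b = pair
    xa, xb = code.codon_to_aa[a], code.codon_to_aa[b]
    fab = table.pair_freq.get(pair, 0.0)
    fa = table.codon_freq.get(a, 0.0)
    fb = table.codon_freq.get(b, 0.0)
    fxy = table.aa_pair_freq.get((xa, xb), 0.0)
    fx = table.aa_freq.get(xa, 0.0)
    fy = table.aa_freq.get(xb, 0.0)
    if min(fab, fa, fb, fxy, fx, fy) <= 0:
        raise PatternIndexError(f"undefined CPS for pair {pair}: zero frequency term")
    return math.log(fab / (fa * fb / (fx * fy) * fxy))


def cps_gene(
    gene: CodingSequence,
    table: CodonPairTable,
    code: GeneticCode | None = None,
) -> float:
    """Gene CPS: arithmetic mean over its scorable consecutive codon pairs.

    Pairs with undefined CPS (absent from the corpus) are skipped; at least
    one scorable pair is required.
    """
    value, _ = cps_gene_detail(gene, table, code)
    return value


def cps_gene_detail(
    gene: CodingSequence,
    table: CodonPairTable,
    code: GeneticCode | None = None,
) -> tuple[float, int]:
    """(gene CPS, number of skipped pairs)."""
    code = code or standard_code()
    codons = [
        c
        for c in gene.codons()
        if not (set(c) - set("ACGT")) and code.codon_to_aa[c] != STOP
    ]
    total = 0.0
    n = 0
    skipped = 0
    for pair in zip(codons, codons[1:]):
        try:
            total += cps_pair(table, pair, code)
            n += 1
        except PatternIndexError:
            skipped += 1
    if n == 0:
        raise PatternIndexError(f"{gene.gene_id!r}: no scorable codon pairs")
    return total / n, skipped
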
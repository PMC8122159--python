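"""tRNA-adaptation indices: tAI and the normalized translation efficiency nTE.

A codon's raw tAI weight sums, over every anticodon that can decode it,
(1 - s_ij) * tGCN_j — pairing efficiency times tRNA gene copy number. Weights
are normalized by the global maximum so the gene score (a geometric mean)
lives in (0, 1]. nTE divides each codon's supply (normalized tAI weight) by
its demand (codon usage weighted by mRNA copy number across the transcriptome),
renormalizes, and takes the geometric mean over the gene.

The default codon-anticodon affinity table is packaged (``data/``): Watson-
Crick pairs at s = 0 plus the standard third-position wobble pairs at the
published tAI penalty constants, restricted to anticodons whose Watson-Crick
codon is synonymous with the decoded codon. It is an input, not a constant:
pass any affinity table to model other organisms or wobble assumptions.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

from .core import CodonCounts
from .genetics import GeneticCode, reverse_complement, standard_code
from .reference import CodonWeights, geometric_mean_index


class TRNAIndexError(ValueError):
    pass


@dataclass
class TRNAPool:
    """Anticodon gene copy numbers plus codon-anticodon affinities.

    ``tgcn``: anticodon (5'->3' DNA alphabet) -> gene copy number.
    ``affinity``: (codon, anticodon) -> s in [0, 1]; 1 - s is the pairing
    efficiency. Pairs absent from the map are not decodable.
    """

    tgcn: dict[str, int]
    affinity: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for pair, s in self.affinity.items():
            if not 0.0 <= s <= 1.0:
                raise TRNAIndexError(f"affinity s={s} out of [0,1] for {pair}")
        if not any(v > 0 for v in self.tgcn.values()):
            raise TRNAIndexError("tRNA pool has no anticodon with positive copy number")


@dataclass
class DemandVector:
    """Transcriptome-wide codon demand U_i = sum_g n_ig * m_g."""

    demand: dict[str, float]
    source: str
    dropped_genes: tuple[str, ...] = ()


#: Wobble penalties of the original tAI parameterization, keyed by
#: (anticodon wobble base at position 34, codon third base).
WOBBLE_PENALTIES: dict[tuple[str, str], float] = {
    ("G", "T"): 0.41,   # G:U
    ("A", "C"): 0.28,   # A34 read as inosine, I:C
    ("A", "A"): 0.9999, # I:A
    ("T", "G"): 0.68,   # U:G
}


def build_standard_affinity(code: GeneticCode | None = None) -> dict[tuple[str, str], float]:
    """Watson-Crick plus standard wobble pairs with published tAI penalties.

    Wobble pairs are only included when the anticodon's Watson-Crick codon is
    synonymous with the decoded codon, which excludes cross-family misreading
    (e.g. an Ile anticodon decoding ATG).
    """
    code = code or standard_code()
    pairs: dict[tuple[str, str], float] = {}
    for codon in code.sense_codons:
        wc_anticodon = reverse_complement(codon)
        pairs[(codon, wc_anticodon)] = 0.0
        for (wobble34, third), s in WOBBLE_PENALTIES.items():
            if codon[2] != third:
                continue
            anticodon = wobble34 + wc_anticodon[1:]
            if anticodon == wc_anticodon:
                continue
            partner_codon = reverse_complement(anticodon)
            if partner_codon in code.stop_codons:
                continue
            if code.codon_to_aa[partner_codon] != code.codon_to_aa[codon]:
                continue
            pairs[(codon, anticodon)] = s
    return pairs


def default_affinity_table() -> dict[tuple[str, str], float]:
    """Load the packaged default affinity TSV (codon, anticodon, s)."""
    path = resources.files("codonuse") / "data" / "tai_affinity_standard.tsv"
    with path.open() as fh:
        return _parse_affinity(fh)


def _parse_affinity(fh: Iterable[str]) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    reader = csv.DictReader((ln for ln in fh if not ln.startswith("#")), delimiter="\t")
    for row in reader:
        out[(row["codon"], row["anticodon"])] = float(row["s"])
    return out


def read_affinity_tsv(path: str | Path) -> dict[tuple[str, str], float]:
    with open(path) as fh:
        return _parse_affinity(fh)


def read_trna_pool_tsv(
    path: str | Path,
    affinity: Mapping[tuple[str, str], float] | None = None,
) -> TRNAPool:
    """Read anticodon copy numbers (columns anticodon, tgcn); affinity
    defaults to the packaged table."""
    tgcn: dict[str, int] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            tgcn[row["anticodon"].upper().replace("U", "T")] = int(row["tgcn"])
    aff = dict(affinity) if affinity is not None else default_affinity_table()
    return TRNAPool(tgcn=tgcn, affinity=aff)


ZeroPolicy = Literal["geometric_mean", "strict"]


def tai_weights(
    pool: TRNAPool,
    code: GeneticCode | None = None,
    zero_policy: ZeroPolicy = "geometric_mean",
) -> CodonWeights:
    """Normalized tAI weights: raw W_i = sum_j (1 - s_ij) tGCN_j, then
    divided by the maximum raw weight.

    Codons with no decoding tRNA get the geometric mean of the nonzero
    normalized weights (the original tAI convention) and are reported in
    ``substituted_codons``; ``zero_policy="strict"`` raises instead.
    """
    code = code or standard_code()
    raw: dict[str, float] = {}
    for codon in code.sense_codons:
        w = 0.0
        for (c, anticodon), s in pool.affinity.items():
            if c == codon:
                w += (1.0 - s) * pool.tgcn.get(anticodon, 0)
        raw[codon] = w
    mx = max(raw.values())
    if mx <= 0:
        raise TRNAIndexError("all raw tAI weights are zero")
    weights = {c: w / mx for c, w in raw.items() if w > 0}
    zeros = tuple(sorted(c for c, w in raw.items() if w == 0))
    if zeros:
        if zero_policy == "strict":
            raise TRNAIndexError(f"codons with no decoding tRNA: {zeros}")
        gm = math.exp(sum(math.log(w) for w in weights.values()) / len(weights))
        for c in zeros:
            weights[c] = gm
    return CodonWeights(
        weights=weights,
        excluded_codons=frozenset(code.stop_codons),
        substituted_codons=zeros,
    )


def tai(counts: CodonCounts, weights: CodonWeights) -> float:
    """tRNA adaptation index: geometric mean of normalized weights, (0, 1]."""
    return geometric_mean_index(counts, weights.weights, weights.excluded_codons)


def codon_demand(
    genome: Iterable[CodonCounts],
    mrna: Mapping[str, float] | None = None,
    unit_copies: bool = False,
) -> DemandVector:
    """Codon demand U_i = sum over genes of (count of codon i) * mRNA copies.

    Genes missing from the abundance table are dropped and reported. With
    ``unit_copies`` every gene counts once (demand = pooled genome counts),
    for use when no mRNA table exists.
    """
    demand: dict[str, float] = {}
    dropped: list[str] = []
    n_used = 0
    for cc in genome:
        if unit_copies:
            m = 1.0
        elif mrna is None or cc.gene_id not in mrna:
            dropped.append(cc.gene_id)
            continue
        else:
            m = float(mrna[cc.gene_id])
        n_used += 1
        for codon, x in cc.counts.items():
            demand[codon] = demand.get(codon, 0.0) + x * m
    if n_used == 0:
        raise TRNAIndexError("no genes overlap the mRNA abundance table")
    source = "unit copies (pooled counts)" if unit_copies else f"mRNA table ({n_used} genes)"
    return DemandVector(demand=demand, source=source, dropped_genes=tuple(dropped))


def nte_weights(weights: CodonWeights, demand: DemandVector) -> CodonWeights:
    """Per-codon normalized translation efficiency values.

    Supply cTE = max-normalized tAI weights; demand cU = max-normalized usage;
    nTE_i = cTE_i / cU_i, max-normalized once more. Codons with zero or
    missing demand have undefined nTE.
    """
    max_w = max(weights.weights.values())
    max_u = max((u for u in demand.demand.values() if u > 0), default=0.0)
    if max_u <= 0:
        raise TRNAIndexError("demand vector has no positive entry")
    ratio: dict[str, float] = {}
    for codon, w in weights.weights.items():
        u = demand.demand.get(codon, 0.0)
        if u <= 0:
            continue
        ratio[codon] = (w / max_w) / (u / max_u)
    if not ratio:
        raise TRNAIndexError("no codon has both a tAI weight and positive demand")
    mx = max(ratio.values())
    return CodonWeights(
        weights={c: v / mx for c, v in ratio.items()},
        excluded_codons=weights.excluded_codons,
    )


def nte(
    counts: CodonCounts,
    weights: CodonWeights,
    demand: DemandVector,
) -> float:
    """Gene-level nTE: geometric mean of per-codon nTE values, in (0, 1].

    Raises if the gene uses a codon whose nTE is undefined (zero demand).
    """
    per_codon = nte_weights(weights, demand)
    missing = [
        c
        for c in counts.counts
        if c not in per_codon.weights and c not in per_codon.excluded_codons
    ]
    if missing:
        raise TRNAIndexError(
            f"{counts.gene_id!r}: codons with undefined nTE (zero demand): {sorted(missing)}"
        )
    return geometric_mean_index(counts, per_codon.weights, per_codon.excluded_codons)
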
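"""Seeded generators for synthetic genomes, expression, tRNA pools and
decoding-rate tables.

The bias model is a per-family convex mixture: with bias strength beta in
[0, 1], a codon for amino acid a is the designated optimal codon with
probability beta + (1 - beta)/Ka and each sibling with probability
(1 - beta)/Ka. beta = 0 is exactly uniform synonymous usage; beta = 1 puts
all mass on the optimal codon, so genes then have FOP = 1 and ENC = 20 by
construction. Expression is log-linear in beta plus Gaussian noise, the
monotone bias-expression coupling the index-comparison analysis assumes.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CodingSequence
from .genetics import GeneticCode, reverse_complement, standard_code
from .rates import DecodingRateTable
from .trna import TRNAPool, default_affinity_table


class SimulationError(ValueError):
    pass


def default_optimal_codons(code: GeneticCode | None = None) -> dict[str, str]:
    """Deterministic designated-optimal map: the alphabetically first codon
    of every family."""
    code = code or standard_code()
    return {aa: family[0] for aa, family in code.families.items()}


@dataclass
class SyntheticGenomeSpec:
    """Parameters of a synthetic genome.

    ``length_codons`` counts codons per gene including the ATG start and
    excluding the stop. ``bias`` may be a scalar (shared beta), a sequence of
    per-gene betas, or None to draw beta ~ Uniform(0, 1) per gene.
    """

    n_genes: int = 200
    length_codons: int | tuple[int, int] = 300
    bias: float | Sequence[float] | None = None
    optimal_codon_map: dict[str, str] | None = None
    amino_acid_composition: dict[str, float] | None = None
    seed: int = 0
    code: GeneticCode = field(default_factory=standard_code)


@dataclass
class SyntheticGenome:
    """A simulated genome with its generating parameters exposed."""

    genes: list[CodingSequence]
    beta: pd.Series
    optimal_codon_map: dict[str, str]
    spec: SyntheticGenomeSpec


def _gene_lengths(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.length_codons, int):
        return np.full(spec.n_genes, spec.length_codons)
    lo, hi = spec.length_codons
    return rng.integers(lo, hi + 1, size=spec.n_genes)


def _betas(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.bias is None:
        return rng.uniform(0.0, 1.0, size=spec.n_genes)
    arr = np.atleast_1d(np.asarray(spec.bias, dtype=float))
    if arr.size == 1:
        arr = np.full(spec.n_genes, float(arr[0]))
    if arr.size != spec.n_genes:
        raise SimulationError(f"bias length {arr.size} != n_genes {spec.n_genes}")
    if np.any((arr < 0) | (arr > 1)):
        raise SimulationError("bias values must lie in [0, 1]")
    return arr


def simulate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Generate in-frame CDSs: ATG start, beta-mixture codon choice per amino
    acid, one stop appended, no internal stops.

    Every gene carries at least two amino acids from each degeneracy class
    (2-, 3-, 4-, 6-fold) so class-based statistics are computable; the rest of
    the amino-acid sequence is drawn iid from the composition (uniform over
    the code's amino acids by default).
    """
    code = spec.code
    rng = np.random.default_rng(spec.seed)
    optimal = dict(spec.optimal_codon_map or default_optimal_codons(code))
    for aa, codon in optimal.items():
        if codon not in code.families[aa]:
            raise SimulationError(f"optimal codon {codon} does not encode {aa}")

    classes = code.degeneracy_classes()
    anchor_classes = [d for d in (2, 3, 4, 6) if d in classes]
    aas = sorted(code.families)
    if spec.amino_acid_composition:
        probs = np.array([spec.amino_acid_composition.get(a, 0.0) for a in aas], dtype=float)
        if probs.sum() <= 0:
            raise SimulationError("amino_acid_composition has no mass")
        probs = probs / probs.sum()
    else:
        probs = np.full(len(aas), 1.0 / len(aas))

    lengths = _gene_lengths(spec, rng)
    min_len = 1 + 2 * len(anchor_classes)
    if np.any(lengths < min_len):
        raise SimulationError(
            f"length_codons must be >= {min_len} to carry all degeneracy classes"
        )
    betas = _betas(spec, rng)
    stop = sorted(code.stop_codons)[0]

    genes: list[CodingSequence] = []
    width = len(str(spec.n_genes - 1))
    for g in range(spec.n_genes):
        beta = betas[g]
        body_len = int(lengths[g]) - 1  # minus the ATG start
        # two anchors per degeneracy class guarantee usable families
        anchors = [str(rng.choice(classes[d])) for d in anchor_classes for _ in range(2)]
        drawn = list(rng.choice(aas, size=body_len - len(anchors), p=probs))
        body_aas = anchors + drawn
        perm = rng.permutation(len(body_aas))
        body_aas = [body_aas[i] for i in perm]
        codons = ["ATG"]
        for aa in body_aas:
            family = code.families[aa]
            ka = len(family)
            p = np.full(ka, (1.0 - beta) / ka)
            p[family.index(optimal[aa])] += beta
            codons.append(str(family[int(rng.choice(ka, p=p))]))
        codons.append(stop)
        genes.append(CodingSequence(gene_id=f"g{g:0{width}d}", seq="".join(codons)))
    beta_series = pd.Series(betas, index=[g.gene_id for g in genes], name="beta")
    return SyntheticGenome(genes=genes, beta=beta_series, optimal_codon_map=optimal, spec=spec)


def simulate_expression(
    beta: pd.Series | Mapping[str, float],
    noise_sd: float = 0.3,
    seed: int = 0,
    intercept: float = 1.0,
    slope: float = 3.0,
) -> pd.Series:
    """Abundance = exp(intercept + slope * beta + eps), eps ~ N(0, noise_sd).

    slope > 0 couples expression monotonically to codon bias; noise_sd = 0
    makes the abundance rank order equal the beta rank order exactly.
    """
    if slope < 0:
        raise SimulationError("slope must be non-negative")
    beta = pd.Series(dict(beta)) if not isinstance(beta, pd.Series) else beta
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=len(beta)) if noise_sd > 0 else np.zeros(len(beta))
    return pd.Series(
        np.exp(intercept + slope * beta.to_numpy(dtype=float) + eps),
        index=beta.index,
        name="abundance",
    )


def simulate_trna_pool(
    optimal_codon_map: Mapping[str, str],
    high_copy: int = 10,
    low_copy: int = 1,
    code: GeneticCode | None = None,
    wobble: bool = False,
) -> TRNAPool:
    """tRNA pool adapted to the designated optimal codons.

    The Watson-Crick anticodon of every sense codon gets ``low_copy`` gene
    copies, raised to ``high_copy`` for optimal codons. By default affinities
    are Watson-Crick only (every codon decoded solely by its cognate
    anticodon), which makes the optimal codons exactly the weight-maximal
    ones; ``wobble=True`` uses the packaged wobble affinity table instead.
    """
    if high_copy <= 0:
        raise SimulationError("high_copy must be positive")
    code = code or standard_code()
    optimal = set(optimal_codon_map.values())
    tgcn: dict[str, int] = {}
    for codon in code.sense_codons:
        anticodon = reverse_complement(codon)
        copies = high_copy if codon in optimal else low_copy
        tgcn[anticodon] = max(tgcn.get(anticodon, 0), copies)
    if wobble:
        affinity = default_affinity_table()
    else:
        affinity = {(c, reverse_complement(c)): 0.0 for c in code.sense_codons}
    return TRNAPool(tgcn=tgcn, affinity=affinity)


def simulate_tdr_table(
    seed: int = 0,
    optimal_codon_map: Mapping[str, str] | None = None,
    base_rate: float = 5.0,
    fast_factor: float = 3.0,
    sigma: float = 0.2,
    code: GeneticCode | None = None,
) -> DecodingRateTable:
    """Log-normal per-codon decoding rates, all positive.

    When an optimal-codon map is given, optimal codons get ``fast_factor``
    times the base median rate — the supply-matched decoding-speed advantage
    the comparison analysis assumes.
    """
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    optimal = set(optimal_codon_map.values()) if optimal_codon_map else set()
    tdr = {}
    for codon in code.sense_codons:
        median = base_rate * (fast_factor if codon in optimal else 1.0)
        tdr[codon] = float(median * math.exp(rng.normal(0.0, sigma)))
    return DecodingRateTable(tdr=tdr, source=f"simulated (seed={seed})")


def write_fasta(genes: Sequence[CodingSequence], path: str | Path) -> None:
    """Write genes as a plain FASTA (deterministic byte content)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.seq), 60):
                fh.write(g.seq[i : i + 60] + "\n")
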
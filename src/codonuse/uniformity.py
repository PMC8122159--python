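"""Uniformity-based indices: RSCU and the effective number of codons (ENC).

ENC follows Wright's construction: per-family codon homozygosity
F = sum_i p_i^2 (plug-in estimator), averaged within each degeneracy class d,
then

    ENC = n_single + sum_d A_d / F_d

where A_d is the number of amino acids of degeneracy d and n_single the
number of single-codon amino acids. For the standard code this is the
familiar 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, bounded between 20 (one codon per
amino acid) and 61 (all synonymous codons equiprobable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .core import CodonCounts
from .genetics import GeneticCode, standard_code


class EncUndefinedError(ValueError):
    """ENC cannot be computed (no degeneracy class has usable families)."""


MissingClassPolicy = Literal["wright", "strict"]


@dataclass
class DegeneracyClassStats:
    """Intermediate homozygosity statistics behind an ENC value.

    ``per_aa_F`` maps amino acid -> (F-hat, n); ``per_class_F`` maps
    degeneracy d -> mean F-hat over contributing families; ``A_d`` counts
    contributing families per class.
    """

    per_aa_F: dict[str, tuple[float, int]]
    per_class_F: dict[int, float]
    A_d: dict[int, int]
    missing_classes: tuple[int, ...] = ()
    imputed_f3: bool = False
    excluded_families: list[str] = field(default_factory=list)


def rscu(counts: CodonCounts, code: GeneticCode | None = None) -> dict[str, float]:
    """Relative synonymous codon usage: observed count / uniform expectation.

    RSCU(c) = x_c / (Na / Ka). Equal usage within every family gives RSCU = 1
    for every codon; a single-codon amino acid always has RSCU = 1. Codons of
    unobserved amino acids are omitted (undefined, not zero).
    """
    code = code or standard_code()
    if counts.n_codons == 0:
        raise ValueError(f"{counts.gene_id!r}: empty codon counts")
    out: dict[str, float] = {}
    for aa, family in code.families.items():
        na = counts.per_aa_totals.get(aa, 0)
        if na == 0:
            continue
        expected = na / len(family)
        for codon in family:
            out[codon] = counts.get(codon) / expected
    return out


def _family_homozygosity(xs: list[int], corrected: bool) -> float | None:
    """F-hat of one synonymous family from its codon counts."""
    n = sum(xs)
    if n == 0:
        return None
    f = sum((x / n) ** 2 for x in xs)
    if corrected:
        if n < 2:
            return None
        f = (n * f - 1) / (n - 1)
    return f


def degeneracy_stats(
    counts: CodonCounts,
    code: GeneticCode | None = None,
    min_count: int = 2,
    corrected: bool = False,
) -> DegeneracyClassStats:
    """Per-family and per-class homozygosity statistics.

    Families observed fewer than ``min_count`` times are excluded from their
    class average (an F-hat from n=1 is degenerate at 1 and would inflate
    apparent bias).
    """
    code = code or standard_code()
    per_aa: dict[str, tuple[float, int]] = {}
    excluded: list[str] = []
    by_class: dict[int, list[float]] = {}
    for aa, family in code.families.items():
        d = len(family)
        if d == 1:
            continue
        n = counts.per_aa_totals.get(aa, 0)
        if n == 0:
            continue
        if n < min_count:
            excluded.append(aa)
            continue
        f = _family_homozygosity([counts.get(c) for c in family], corrected)
        if f is None:
            excluded.append(aa)
            continue
        per_aa[aa] = (f, n)
        by_class.setdefault(d, []).append(f)
    per_class = {d: sum(fs) / len(fs) for d, fs in by_class.items()}
    a_d = {d: len(fs) for d, fs in by_class.items()}
    all_classes = sorted(d for d in code.degeneracy_classes() if d > 1)
    missing = tuple(d for d in all_classes if d not in per_class)
    return DegeneracyClassStats(
        per_aa_F=per_aa,
        per_class_F=per_class,
        A_d=a_d,
        missing_classes=missing,
        excluded_families=excluded,
    )


def _class_census(code: GeneticCode) -> tuple[int, dict[int, int]]:
    """(number of single-codon amino acids, class -> number of amino acids)."""
    classes = code.degeneracy_classes()
    n_single = len(classes.get(1, ()))
    return n_single, {d: len(aas) for d, aas in classes.items() if d > 1}


def enc_detail(
    counts: CodonCounts,
    code: GeneticCode | None = None,
    policy: MissingClassPolicy = "wright",
    min_count: int = 2,
    corrected: bool = False,
) -> tuple[float, DegeneracyClassStats]:
    """ENC together with its intermediate class statistics.

    Missing-class handling (default, logged in the stats object): an absent
    3-fold class is imputed as (F2 + F4)/2 when both neighbours exist; any
    other absent class drops its term and the result is rescaled by the full
    range maximum over the attainable partial maximum. ``policy="strict"``
    raises instead. The result is capped at the code's maximum (61 for the
    standard code).
    """
    code = code or standard_code()
    stats = degeneracy_stats(counts, code, min_count=min_count, corrected=corrected)
    n_single, census = _class_census(code)
    per_class = dict(stats.per_class_F)

    if stats.missing_classes:
        if policy == "strict":
            raise EncUndefinedError(
                f"{counts.gene_id!r}: degeneracy classes {stats.missing_classes} absent"
            )
        if 3 in stats.missing_classes and 2 in per_class and 4 in per_class:
            per_class[3] = (per_class[2] + per_class[4]) / 2
            stats.imputed_f3 = True
    if not per_class:
        raise EncUndefinedError(f"{counts.gene_id!r}: no degeneracy class has usable families")

    present = sorted(per_class)
    enc_partial = n_single + sum(census[d] / per_class[d] for d in present)
    max_full = n_single + sum(census[d] * d for d in census)
    max_partial = n_single + sum(census[d] * d for d in present)
    value = enc_partial * (max_full / max_partial)
    value = min(value, max_full)
    return value, stats


def enc(
    counts: CodonCounts,
    code: GeneticCode | None = None,
    policy: MissingClassPolicy = "wright",
    min_count: int = 2,
    corrected: bool = False,
) -> float:
    """Effective number of codons of one gene. See :func:`enc_detail`."""
    value, _ = enc_detail(counts, code, policy=policy, min_count=min_count, corrected=corrected)
    return value
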
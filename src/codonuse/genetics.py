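"""Genetic-code model.

Wraps Biopython's NCBI translation tables into a small object that exposes
the quantities codon-usage indices need: the codon -> amino-acid map, the
synonymous families, the per-amino-acid degeneracy Ka and the stop set.

Under the standard code (table 1) the degeneracy census is: 9 amino acids
two-fold, 1 three-fold (Ile), 5 four-fold, 3 six-fold (Leu/Ser/Arg), and
2 single-codon (Met, Trp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

BASES = "ACGT"
#: All 64 codons in lexicographic order.
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
STOP = "*"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GeneticCodeError(ValueError):
    pass


@dataclass(frozen=True)
class GeneticCode:
    """A translation table with derived degeneracy structure.

    Attributes
    ----------
    table_id:
        NCBI translation-table identifier (1 = standard).
    codon_to_aa:
        Map over all 64 codons; stops map to ``"*"``.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str] = field(init=False)
    families: dict[str, tuple[str, ...]] = field(init=False)
    degeneracy: dict[str, int] = field(init=False)
    sense_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(CODONS):
            missing = set(CODONS) - set(self.codon_to_aa)
            raise GeneticCodeError(f"codon map must cover all 64 codons (missing {sorted(missing)[:3]}...)")
        stops = frozenset(c for c, a in self.codon_to_aa.items() if a == STOP)
        fams: dict[str, list[str]] = {}
        for codon in CODONS:
            aa = self.codon_to_aa[codon]
            if aa != STOP:
                fams.setdefault(aa, []).append(codon)
        object.__setattr__(self, "stop_codons", stops)
        object.__setattr__(self, "families", {a: tuple(sorted(cs)) for a, cs in fams.items()})
        object.__setattr__(self, "degeneracy", {a: len(cs) for a, cs in self.families.items()})
        object.__setattr__(
            self, "sense_codons", tuple(c for c in CODONS if c not in stops)
        )

    @classmethod
    def from_table_id(cls, table_id: int = 1) -> "GeneticCode":
        """Load an NCBI translation table (1 = standard) by id."""
        try:
            table = CodonTable.unambiguous_dna_by_id[table_id]
        except KeyError as exc:
            raise GeneticCodeError(f"unknown NCBI translation table id {table_id}") from exc
        mapping = {c: STOP for c in table.stop_codons}
        mapping.update(table.forward_table)
        return cls(table_id=table_id, codon_to_aa=dict(mapping))

    def aa(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def family_of(self, codon: str) -> tuple[str, ...]:
        """Synonymous codons of ``codon`` (including itself)."""
        return self.families[self.codon_to_aa[codon]]

    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Amino acids grouped by degeneracy Ka, single-codon class included."""
        out: dict[int, list[str]] = {}
        for aa, d in self.degeneracy.items():
            out.setdefault(d, []).append(aa)
        return {d: tuple(sorted(aas)) for d, aas in sorted(out.items())}


_STANDARD: GeneticCode | None = None


def standard_code() -> GeneticCode:
    """The standard genetic code (cached)."""
    global _STANDARD
    if _STANDARD is None:
        _STANDARD = GeneticCode.from_table_id(1)
    return _STANDARD
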
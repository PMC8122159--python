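"""CDS validation, codon counting and synonymous codon frequencies.

Every index in the package consumes :class:`CodonCounts` — a per-gene vector
of counts over the 64 codons obtained by reading the CDS in frame 0 as
consecutive non-overlapping triplets. Codons containing ambiguous bases are
excluded from counts and tracked; stop codons are excluded from index math.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

from .genetics import GeneticCode, STOP, standard_code

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

Policy = Literal["strict", "lenient"]


class CDSValidationError(ValueError):
    """A record failed validation under the strict policy."""


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding sequence (normalized to uppercase DNA)."""

    gene_id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq) - len(self.seq) % 3, 3)]


@dataclass
class ValidationReport:
    """Per-file account of what validation accepted, trimmed or rejected."""

    n_records: int = 0
    accepted: list[str] = field(default_factory=list)
    trimmed: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class CodonCounts:
    """Codon counts of one gene (or a pooled gene set).

    ``counts`` holds only observed codons; ``per_aa_totals`` the family totals
    Na; ``n_codons`` the total counted (non-excluded) codons.
    """

    gene_id: str
    counts: dict[str, int]
    n_codons: int
    per_aa_totals: dict[str, int]
    ambiguous_codons: list[str] = field(default_factory=list)
    stops_excluded: int = 0

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)


@dataclass
class FrequencyVector:
    """Within-family synonymous frequencies: freq(c) = count(c) / Na(aa(c)).

    Codons of amino acids absent from the input are undefined (listed in
    ``undefined_codons``), not zero.
    """

    gene_or_set_id: str
    freq: dict[str, float]
    undefined_codons: frozenset[str] = frozenset()


def normalize_seq(raw: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return raw.upper().replace("U", "T")


def _validate(
    gene_id: str,
    seq: str,
    code: GeneticCode,
    policy: Policy,
    report: ValidationReport,
) -> CodingSequence | None:
    bad = set(seq) - IUPAC_DNA
    if bad:
        msg = f"record {gene_id!r}: non-nucleotide characters {sorted(bad)}"
        if policy == "strict":
            raise CDSValidationError(msg)
        report.rejected.append((gene_id, msg))
        return None
    if len(seq) % 3 != 0:
        msg = f"record {gene_id!r}: length {len(seq)} not divisible by 3"
        if policy == "strict":
            raise CDSValidationError(msg)
        seq = seq[: len(seq) - len(seq) % 3]
        report.trimmed.append(gene_id)
        report.warnings.append(msg + " (trimmed)")
    if not seq:
        msg = f"record {gene_id!r}: empty sequence"
        if policy == "strict":
            raise CDSValidationError(msg)
        report.rejected.append((gene_id, msg))
        return None
    # internal stops: scan all codons but the last
    for i in range(0, len(seq) - 3, 3):
        codon = seq[i : i + 3]
        if codon in code.stop_codons:
            msg = f"record {gene_id!r}: internal stop {codon} at codon {i // 3}"
            if policy == "strict":
                raise CDSValidationError(msg)
            report.warnings.append(msg)
            break
    report.accepted.append(gene_id)
    return CodingSequence(gene_id=gene_id, seq=seq)


def read_cds_fasta(
    path: str | Path,
    policy: Policy = "strict",
    code: GeneticCode | None = None,
) -> tuple[list[CodingSequence], ValidationReport]:
    """Read and validate a multi-record nucleotide FASTA of CDSs.

    Strict policy raises :class:`CDSValidationError` naming the offending
    record; lenient trims trailing partial codons and keeps records with
    internal stops (which :func:`count_codons` then excludes from counts).
    """
    code = code or standard_code()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ValidationReport()
    out: list[CodingSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        report.n_records += 1
        cds = _validate(rec.id, normalize_seq(str(rec.seq)), code, policy, report)
        if cds is not None:
            out.append(cds)
    if report.n_records == 0:
        raise CDSValidationError(f"{path}: no FASTA records found")
    return out, report


def count_codons(
    cds: CodingSequence,
    code: GeneticCode | None = None,
    include_stops: bool = False,
) -> CodonCounts:
    """Count in-frame codons of a validated CDS.

    Ambiguous codons are excluded and listed; stop codons are excluded
    unless ``include_stops`` (frequency tables only — index math never
    includes stops).
    """
    code = code or standard_code()
    seq = normalize_seq(cds.seq)
    counts: dict[str, int] = {}
    per_aa: dict[str, int] = {}
    ambiguous: list[str] = []
    stops = 0
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if set(codon) - set("ACGT"):
            ambiguous.append(codon)
            continue
        aa = code.codon_to_aa[codon]
        if aa == STOP and not include_stops:
            stops += 1
            continue
        counts[codon] = counts.get(codon, 0) + 1
        per_aa[aa] = per_aa.get(aa, 0) + 1
    return CodonCounts(
        gene_id=cds.gene_id,
        counts=counts,
        n_codons=sum(counts.values()),
        per_aa_totals=per_aa,
        ambiguous_codons=ambiguous,
        stops_excluded=stops,
    )


def counts_from_codons(
    gene_id: str,
    codons: Iterable[str],
    code: GeneticCode | None = None,
) -> CodonCounts:
    """Build :class:`CodonCounts` directly from a codon list (no stops/ambiguity)."""
    code = code or standard_code()
    return count_codons(CodingSequence(gene_id, "".join(codons)), code)


def pool_counts(all_counts: Iterable[CodonCounts], set_id: str = "pooled") -> CodonCounts:
    """Aggregate per-gene counts over a gene set (reference sets, genomes)."""
    counts: dict[str, int] = {}
    per_aa: dict[str, int] = {}
    ambiguous: list[str] = []
    stops = 0
    for cc in all_counts:
        for codon, x in cc.counts.items():
            counts[codon] = counts.get(codon, 0) + x
        for aa, n in cc.per_aa_totals.items():
            per_aa[aa] = per_aa.get(aa, 0) + n
        ambiguous.extend(cc.ambiguous_codons)
        stops += cc.stops_excluded
    return CodonCounts(
        gene_id=set_id,
        counts=counts,
        n_codons=sum(counts.values()),
        per_aa_totals=per_aa,
        ambiguous_codons=ambiguous,
        stops_excluded=stops,
    )


def codon_frequency(counts: CodonCounts, code: GeneticCode | None = None) -> FrequencyVector:
    """Synonymous codon frequency: count(c) / Na(aa(c)).

    For each amino acid observed at least once, family frequencies sum to 1;
    a single-codon amino acid present in the input has frequency exactly 1.
    Families never observed are undefined, not zero.
    """
    code = code or standard_code()
    if counts.n_codons == 0:
        raise ValueError(f"{counts.gene_id!r}: empty codon counts")
    freq: dict[str, float] = {}
    undefined: set[str] = set()
    for aa, family in code.families.items():
        na = counts.per_aa_totals.get(aa, 0)
        if na == 0:
            undefined.update(family)
            continue
        for codon in family:
            freq[codon] = counts.get(codon) / na
    return FrequencyVector(
        gene_or_set_id=counts.gene_id, freq=freq, undefined_codons=frozenset(undefined)
    )
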
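"""Experiment-derived index: mean typical decoding rate (MTDR).

MTDR is the geometric mean of per-codon typical decoding rates (TDR) over a
gene. The TDR table is an input — typically estimated elsewhere from
ribosome-profiling data — and is treated as unitless relative rates; MTDR
scales linearly with the table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .core import CodonCounts
from .genetics import GeneticCode, standard_code
from .reference import geometric_mean_index


class RateIndexError(ValueError):
    pass


@dataclass
class DecodingRateTable:
    """Per-codon positive decoding rates (log-safe by construction)."""

    tdr: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        bad = {c: r for c, r in self.tdr.items() if not r > 0}
        if bad:
            raise RateIndexError(f"non-positive decoding rates: {bad}")


def read_tdr_tsv(path: str | Path, source: str | None = None) -> DecodingRateTable:
    """Read a TSV with columns codon, rate."""
    tdr: dict[str, float] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            tdr[row["codon"].upper().replace("U", "T")] = float(row["rate"])
    return DecodingRateTable(tdr=tdr, source=source or str(path))


MissingRatePolicy = Literal["error", "exclude"]


def mtdr(
    counts: CodonCounts,
    rates: DecodingRateTable,
    code: GeneticCode | None = None,
    missing_policy: MissingRatePolicy = "error",
) -> float:
    """Geometric mean of decoding rates over a gene's codons (stops excluded).

    Codons absent from the rate table raise by default; ``"exclude"`` skips
    them (the gene must retain at least one rated codon).
    """
    code = code or standard_code()
    if missing_policy == "error":
        missing = sorted(
            c for c in counts.counts if c not in rates.tdr and c not in code.stop_codons
        )
        if missing:
            raise RateIndexError(
                f"{counts.gene_id!r}: codons missing from the rate table: {missing}"
            )
    return geometric_mean_index(counts, rates.tdr, frozenset(code.stop_codons))
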
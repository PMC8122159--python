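"""Index-comparison pipeline: gene x index matrix, Spearman correlations with
protein abundance, inter-index correlation structure, and cross-genome
synonymous frequency profiles.

The ten indices covered: ENC, FOP, CAI, CBI, CEC, tAI, nTE, ChimeraARS, CPS,
MTDR. Each needs different auxiliary inputs (an expression table for the
reference-set indices, a tRNA pool for tAI/nTE, a decoding-rate table for
MTDR); requesting an index without its input is a configuration error, and a
gene whose value is undefined gets an explicit missing marker with a reason,
never an imputed number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import rates, reference, trna, uniformity
from .core import CodingSequence, CodonCounts, codon_frequency, count_codons, pool_counts
from .genetics import CODONS, GeneticCode, standard_code
from .pairs import SubstringReference, build_codon_pair_table, chimera_ars, cps_gene
from .rates import DecodingRateTable
from .trna import TRNAPool

ALL_INDICES = ("enc", "fop", "cai", "cbi", "cec", "tai", "nte", "chimera_ars", "cps", "mtdr")


class ConfigurationError(ValueError):
    pass


@dataclass
class IndexConfig:
    """Per-index parameters and auxiliary tables for a pipeline run."""

    indices: Sequence[str] = ALL_INDICES
    code: GeneticCode = field(default_factory=standard_code)
    expression: Mapping[str, float] | pd.Series | None = None
    reference_fraction: float = 0.2
    cai_pseudo: float = 0.5
    preferred_ties: Literal["lexicographic", "all"] = "lexicographic"
    trna_pool: TRNAPool | None = None
    mrna: Mapping[str, float] | pd.Series | None = None
    demand_unit_copies: bool = False
    tdr: DecodingRateTable | None = None
    chimera_alphabet: Literal["nucleotide", "codon"] = "nucleotide"
    chimera_reference: Literal["reference_set", "genome"] = "reference_set"
    cps_pseudo: float = 0.0


@dataclass
class IndexMatrix:
    """Gene x index values with explicit missingness and provenance."""

    values: pd.DataFrame
    missing_reasons: dict[tuple[str, str], str]
    provenance: dict[str, str]


@dataclass
class CorrelationReport:
    """Pairwise Spearman correlations (pairwise-complete observations)."""

    pairs: pd.DataFrame  # columns: name_a, name_b, rho, n_genes, p_value
    matrix: pd.DataFrame | None = None
    method: str = "spearman (average ranks, pairwise-complete)"


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """(rho, p, n) over pairwise-complete entries, average-rank ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise ConfigurationError(f"need >= 3 pairwise-complete observations, got {n}")
    res = sps.spearmanr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue), n


def _check_inputs(config: IndexConfig) -> None:
    requested = set(config.indices)
    unknown = requested - set(ALL_INDICES)
    if unknown:
        raise ConfigurationError(f"unknown indices {sorted(unknown)}; known: {ALL_INDICES}")
    needs_expr = requested & {"fop", "cai", "cbi", "cec"}
    if config.chimera_reference == "reference_set" and "chimera_ars" in requested:
        needs_expr.add("chimera_ars")
    if needs_expr and config.expression is None:
        raise ConfigurationError(
            f"indices {sorted(needs_expr)} require an expression (abundance) table"
        )
    if requested & {"tai", "nte"} and config.trna_pool is None:
        raise ConfigurationError("indices ['tai', 'nte'] require a tRNA pool (trna_pool)")
    if "nte" in requested and config.mrna is None and not config.demand_unit_copies:
        raise ConfigurationError(
            "index 'nte' requires an mRNA abundance table (mrna) or demand_unit_copies=True"
        )
    if "mtdr" in requested and config.tdr is None:
        raise ConfigurationError("index 'mtdr' requires a decoding-rate table (tdr)")


def compute_index_matrix(genome: Sequence[CodingSequence], config: IndexConfig) -> IndexMatrix:
    """Compute one value per gene per requested index.

    Shared inputs (reference set, weights, pair table, substring reference,
    demand) are built once; per-gene failures are recorded as missing cells
    with their reason.
    """
    _check_inputs(config)
    code = config.code
    counts = {g.gene_id: count_codons(g, code) for g in genome}
    gene_ids = [g.gene_id for g in genome]
    requested = [i for i in ALL_INDICES if i in set(config.indices)]

    provenance: dict[str, str] = {}
    scorers: dict[str, Callable[[CodingSequence, CodonCounts], float]] = {}

    if "enc" in requested:
        provenance["enc"] = "plug-in homozygosity, min family count 2, Wright missing-class policy"
        scorers["enc"] = lambda g, cc: uniformity.enc(cc, code)

    needs_ref = {"fop", "cai", "cbi", "cec"} & set(requested)
    if config.chimera_reference == "reference_set" and "chimera_ars" in requested:
        needs_ref.add("chimera_ars")
    ref = None
    if needs_ref:
        expr = dict(pd.Series(config.expression).items())
        ref = reference.select_reference_set(
            expr, list(counts.values()), fraction=config.reference_fraction
        )
    if "fop" in requested or "cbi" in requested:
        pref = reference.preferred_codons(ref, code, ties=config.preferred_ties)
        if "fop" in requested:
            provenance["fop"] = f"preferred codons from {ref.selection_rule}, ties={config.preferred_ties}"
            scorers["fop"] = lambda g, cc: reference.fop(cc, pref)
        if "cbi" in requested:
            provenance["cbi"] = f"preferred codons from {ref.selection_rule}"
            scorers["cbi"] = lambda g, cc: reference.cbi(cc, pref, code)
    if "cai" in requested:
        w = reference.cai_weights(ref, code, pseudo=config.cai_pseudo)
        provenance["cai"] = f"weights from {ref.selection_rule}, pseudo={config.cai_pseudo}"
        scorers["cai"] = lambda g, cc: reference.cai(cc, w)
    if "cec" in requested:
        provenance["cec"] = f"Pearson enrichment correlation vs {ref.selection_rule}"
        scorers["cec"] = lambda g, cc: reference.cec(cc, ref, code)

    if "tai" in requested or "nte" in requested:
        tw = trna.tai_weights(config.trna_pool, code)
        if "tai" in requested:
            provenance["tai"] = "max-normalized supply weights from tRNA pool"
            scorers["tai"] = lambda g, cc: trna.tai(cc, tw)
        if "nte" in requested:
            demand = trna.codon_demand(
                list(counts.values()),
                mrna=dict(pd.Series(config.mrna).items()) if config.mrna is not None else None,
                unit_copies=config.demand_unit_copies,
            )
            ntw = trna.nte_weights(tw, demand)
            provenance["nte"] = f"supply/demand, demand from {demand.source}"
            scorers["nte"] = lambda g, cc: reference.geometric_mean_index(
                cc, ntw.weights, ntw.excluded_codons
            )

    if "chimera_ars" in requested:
        ref_genes = (
            [g for g in genome if g.gene_id in set(ref.gene_ids)]
            if config.chimera_reference == "reference_set"
            else list(genome)
        )
        sref = SubstringReference.from_cds(ref_genes, alphabet=config.chimera_alphabet)
        provenance["chimera_ars"] = (
            f"{config.chimera_reference} reference ({len(ref_genes)} genes), "
            f"alphabet={config.chimera_alphabet}, self-excluded by id"
        )
        scorers["chimera_ars"] = lambda g, cc: chimera_ars(g, sref, exclude_self=True)

    if "cps" in requested:
        table = build_codon_pair_table(genome, code, pseudo_count=config.cps_pseudo)
        provenance["cps"] = f"corpus = full genome ({table.provenance})"
        scorers["cps"] = lambda g, cc: cps_gene(g, table, code)

    if "mtdr" in requested:
        provenance["mtdr"] = f"rate table: {config.tdr.source or 'unnamed'}"
        scorers["mtdr"] = lambda g, cc: rates.mtdr(cc, config.tdr, code)

    values = pd.DataFrame(np.nan, index=gene_ids, columns=requested, dtype=float)
    missing: dict[tuple[str, str], str] = {}
    for g in genome:
        cc = counts[g.gene_id]
        for name in requested:
            try:
                values.loc[g.gene_id, name] = scorers[name](g, cc)
            except ValueError as exc:
                missing[(g.gene_id, name)] = str(exc)
    return IndexMatrix(values=values, missing_reasons=missing, provenance=provenance)


def correlate_with_expression(
    matrix: IndexMatrix, expression: Mapping[str, float] | pd.Series
) -> CorrelationReport:
    """Spearman rho of every index against abundance, pairwise-complete.

    Signs are reported raw: ENC is expected to correlate negatively (low ENC
    = strong bias) while all other indices score adaptation upward.
    """
    expr = pd.Series(expression, dtype=float)
    common = matrix.values.index.intersection(expr.index)
    rows = []
    for name in matrix.values.columns:
        x = matrix.values.loc[common, name].to_numpy()
        y = expr.loc[common].to_numpy()
        rho, p, n = spearman(x, y)
        rows.append({"name_a": name, "name_b": "abundance", "rho": rho, "n_genes": n, "p_value": p})
    return CorrelationReport(pairs=pd.DataFrame(rows))


def index_correlation_matrix(matrix: IndexMatrix) -> tuple[CorrelationReport, dict[str, tuple]]:
    """Full symmetric inter-index Spearman matrix plus the extreme pairs.

    Returns the report and ``{"highest": (a, b, rho), "lowest": (a, b, rho)}``
    over off-diagonal pairs (for dot-plot follow-ups).
    """
    names = list(matrix.values.columns)
    if len(names) < 2:
        raise ConfigurationError("need >= 2 indices for an inter-index matrix")
    mat = pd.DataFrame(1.0, index=names, columns=names)
    rows = []
    extremes: dict[str, tuple] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rho, p, n = spearman(
                matrix.values[a].to_numpy(), matrix.values[b].to_numpy()
            )
            mat.loc[a, b] = mat.loc[b, a] = rho
            rows.append({"name_a": a, "name_b": b, "rho": rho, "n_genes": n, "p_value": p})
    pairs = pd.DataFrame(rows)
    hi = pairs.loc[pairs["rho"].idxmax()]
    lo = pairs.loc[pairs["rho"].idxmin()]
    extremes["highest"] = (hi["name_a"], hi["name_b"], float(hi["rho"]))
    extremes["lowest"] = (lo["name_a"], lo["name_b"], float(lo["rho"]))
    return CorrelationReport(pairs=pairs, matrix=mat), extremes


def cross_genome_frequency_matrix(
    genomes: Mapping[str, Sequence[CodingSequence]],
    codes: GeneticCode | Mapping[str, GeneticCode] | None = None,
) -> pd.DataFrame:
    """Pooled within-family codon frequencies, one row per genome, 64 columns.

    Codons of amino acids absent from a genome (and stop codons) are NaN.
    Each observed family's frequencies sum to 1 within a row — the
    cross-genome profile underlying the frequency heatmap.
    """
    rows = {}
    for name, genes in genomes.items():
        if not genes:
            raise ConfigurationError(f"genome {name!r} is empty")
        if codes is None:
            code = standard_code()
        elif isinstance(codes, GeneticCode):
            code = codes
        else:
            code = codes[name]
        pooled = pool_counts([count_codons(g, code) for g in genes], set_id=name)
        fv = codon_frequency(pooled, code)
        rows[name] = {c: fv.freq.get(c, np.nan) for c in CODONS}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CODONS))


def average_abundance_columns(table: pd.DataFrame) -> pd.Series:
    """Arithmetic mean across per-tissue abundance columns (multi-tissue
    panels are averaged into one abundance value per gene)."""
    return table.mean(axis=1).rename("abundance")
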
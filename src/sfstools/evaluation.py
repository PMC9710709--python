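"""Precision/recall of specific strings against a simulated truth set.

Recall is the fraction of de novo variants overlapped by at least one
retained (abundance-filtered) specific-string emission; precision is the
fraction of retained emissions that overlap a de novo variant. Overlap
is decided by lifting each emission's read interval to haplotype
coordinates and intersecting it with the truth placements
(breakpoint-inclusive; see :func:`sfstools.simulate.placement_overlaps`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sfstools.alphabet import canonical
from sfstools.search import SfsEmission, SfsTable

logger = logging.getLogger(__name__)

VARIANT_KINDS = ("snp", "insertion", "deletion", "inversion")


@dataclass(frozen=True)
class _TruthRow:
    variant_id: int
    kind: str
    haplotype_id: str
    hap_begin: int
    hap_end: int


@dataclass(frozen=True)
class _ReadRow:
    read_id: str
    haplotype_id: str
    hap_begin: int
    hap_end: int
    strand: str


@dataclass
class EvalReport:
    n_sfs_total: int
    n_sfs_after_tau: int
    n_sfs_covering: int
    n_variants_total: int
    n_variants_covered: int
    precision: float            # NaN when no emission survives the filter
    recall: float
    precision_distinct: float   # per distinct canonical sequence
    tau: int
    by_kind: dict[str, dict[str, int | float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_sfs_total": self.n_sfs_total,
            "n_sfs_after_tau": self.n_sfs_after_tau,
            "n_sfs_covering": self.n_sfs_covering,
            "n_variants_total": self.n_variants_total,
            "n_variants_covered": self.n_variants_covered,
            "precision": self.precision,
            "recall": self.recall,
            "precision_distinct": self.precision_distinct,
            "tau": self.tau,
            "by_kind": self.by_kind,
        }


def _lift(read: _ReadRow, begin: int, end: int) -> tuple[int, int]:
    if read.strand == "+":
        hb, he = read.hap_begin + begin, read.hap_begin + end
    else:
        hb, he = read.hap_end - end, read.hap_end - begin
    hb = max(read.hap_begin, min(hb, read.hap_end))
    he = max(read.hap_begin, min(he, read.hap_end))
    return hb, he


def _overlaps(row: _TruthRow, hb: int, he: int) -> bool:
    if row.kind == "deletion":
        return hb < row.hap_begin < he
    return hb < row.hap_end and row.hap_begin < he


def _evaluate(emissions: list[SfsEmission], truth: list[_TruthRow],
              reads: dict[str, _ReadRow], tau: int) -> EvalReport:
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    counts: dict[str, int] = {}
    for em in emissions:
        key = canonical(em.sequence)
        counts[key] = counts.get(key, 0) + 1
    retained = [em for em in emissions if counts[canonical(em.sequence)] >= tau]

    by_hap: dict[str, list[_TruthRow]] = {}
    for row in truth:
        by_hap.setdefault(row.haplotype_id, []).append(row)

    covered: set[int] = set()
    n_covering = 0
    covering_distinct: set[str] = set()
    retained_distinct: set[str] = set()
    for em in retained:
        read = reads.get(em.target_id)
        if read is None:
            raise ValueError(f"emission references unknown read {em.target_id!r}")
        hb, he = _lift(read, em.begin, em.end)
        hits = [row for row in by_hap.get(read.haplotype_id, ())
                if _overlaps(row, hb, he)]
        key = canonical(em.sequence)
        retained_distinct.add(key)
        if hits:
            n_covering += 1
            covering_distinct.add(key)
            covered.update(row.variant_id for row in hits)

    n_variants = len({row.variant_id for row in truth})
    if retained:
        precision = n_covering / len(retained)
        precision_distinct = len(covering_distinct) / len(retained_distinct)
    else:
        logger.warning("no emissions survive tau=%d; precision undefined", tau)
        precision = math.nan
        precision_distinct = math.nan
    recall = (len(covered) / n_variants) if n_variants else 0.0

    by_kind: dict[str, dict[str, int | float]] = {}
    for kind in VARIANT_KINDS:
        ids = {row.variant_id for row in truth if row.kind == kind}
        if not ids:
            continue
        hit = len(ids & covered)
        by_kind[kind] = {"total": len(ids), "covered": hit,
                         "recall": hit / len(ids)}
    return EvalReport(
        n_sfs_total=len(emissions),
        n_sfs_after_tau=len(retained),
        n_sfs_covering=n_covering,
        n_variants_total=n_variants,
        n_variants_covered=len(covered),
        precision=precision,
        recall=recall,
        precision_distinct=precision_distinct,
        tau=tau,
        by_kind=by_kind,
    )


def evaluate_simulation(emissions: list[SfsEmission], trio, tau: int = 1
                        ) -> EvalReport:
    """Evaluate emissions from a search over simulated child reads
    against the trio's de novo truth set."""
    truth = [_TruthRow(p.variant.vid, p.variant.kind, hap_id,
                       p.hap_begin, p.hap_end)
             for hap_id, hap in trio.haplotypes.items()
             for p in hap.placements if p.variant.origin == "de_novo"]
    reads = {r.read_id: _ReadRow(r.read_id, r.haplotype_id, r.hap_begin,
                                 r.hap_end, r.strand)
             for sample_reads in trio.reads.values() for r in sample_reads}
    return _evaluate(emissions, truth, reads, tau)


def evaluate_tables(emissions: list[SfsEmission], truth_df: pd.DataFrame,
                    reads_df: pd.DataFrame, tau: int = 1) -> EvalReport:
    """Same evaluation, driven from the TSV exports (CLI entry point).

    ``truth_df`` must hold columns variant_id/kind/origin/haplotype_id/
    hap_begin/hap_end and ``reads_df`` read_id/haplotype_id/hap_begin/
    hap_end/strand.
    """
    denovo = truth_df[truth_df["origin"] == "de_novo"]
    truth = [_TruthRow(int(r.variant_id), str(r.kind), str(r.haplotype_id),
                       int(r.hap_begin), int(r.hap_end))
             for r in denovo.itertuples()]
    reads = {str(r.read_id): _ReadRow(str(r.read_id), str(r.haplotype_id),
                                      int(r.hap_begin), int(r.hap_end),
                                      str(r.strand))
             for r in reads_df.itertuples()}
    return _evaluate(emissions, truth, reads, tau)


def benchmark_trio(
    genome_length: int = 50_000,
    coverage: float = 30.0,
    n_inherited: int = 10,
    n_denovo: int = 20,
    sv_size_range: tuple[int, int] = (50, 500),
    tau: int = 5,
    error_rate: float = 0.0,
    mode: str = "exact",
    seed: int = 1,
    threads: int = 1,
    recombination: bool = False,
):
    """End-to-end simulated-trio benchmark.

    Simulates a trio, indexes the combined parent reads (both strands),
    searches the child reads for child-specific strings, filters at
    ``tau`` and evaluates precision/recall against the de novo truth
    set. All randomness derives from ``seed`` through named substreams.
    Returns ``(report, trio, table)`` with the unfiltered count table.
    """
    from sfstools import fmd_index, simulate
    from sfstools.search import search_collection

    seeds = np.random.SeedSequence(seed).spawn(4)
    genome = simulate.generate_genome(genome_length, seeds[0])
    trio = simulate.make_trio(genome, n_inherited=n_inherited,
                              n_denovo=n_denovo, sv_size_range=sv_size_range,
                              recombination=recombination, seed=seeds[1])
    parent_haps = {h: trio.haplotypes[h].sequence
                   for h in simulate.PARENT_HAPLOTYPES}
    child_haps = {h: trio.haplotypes[h].sequence
                  for h in simulate.CHILD_HAPLOTYPES}
    parent_reads = simulate.simulate_reads(parent_haps, coverage,
                                           error_rate=error_rate,
                                           seed=seeds[2])
    child_reads = simulate.simulate_reads(child_haps, coverage,
                                          error_rate=error_rate,
                                          seed=seeds[3])
    trio.reads = {
        "father": [r for r in parent_reads if r.haplotype_id.startswith("father")],
        "mother": [r for r in parent_reads if r.haplotype_id.startswith("mother")],
        "child": child_reads,
    }
    index = fmd_index.build_index([r.sequence for r in parent_reads],
                                  strand_mode="both")
    table, emissions = search_collection(
        [(r.read_id, r.sequence) for r in child_reads], index, mode=mode,
        threads=threads, collect_emissions=True)
    report = evaluate_simulation(emissions, trio, tau=tau)
    return report, trio, table


def summarize_table(table: SfsTable) -> dict:
    """Descriptive statistics of a specific-string table."""
    if not table.counts:
        return {"n_sequences": 0, "total_count": 0,
                "length_quantiles": {}, "count_quantiles": {}}
    lengths = np.array([len(s) for s in table.counts], dtype=float)
    counts = np.array(list(table.counts.values()), dtype=float)

    def quantiles(x: np.ndarray) -> dict[str, float]:
        qs = np.quantile(x, [0.0, 0.25, 0.5, 0.75, 1.0])
        return {"min": qs[0], "q25": qs[1], "median": qs[2],
                "q75": qs[3], "max": qs[4]}

    return {
        "n_sequences": len(table.counts),
        "total_count": int(counts.sum()),
        "length_quantiles": quantiles(lengths),
        "count_quantiles": quantiles(counts),
    }
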
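"""High-quality filtering chain, endogenous-DNA statistics and sex call.

The chain mirrors standard ancient-DNA practice on low-coverage shotgun data:
mapping-quality filtering, clonal-duplicate removal by 5' coordinate,
subtraction of reads that also align to a contaminant (human-like) genome
irrespective of their target mapping quality, and restriction to uniquely
aligned reads. The filter order is fixed (mapq -> dedup -> contaminant
subtraction -> uniqueness) because duplicate removal before or after the
mapping-quality filter changes the counts; the order can be permuted
explicitly where that sensitivity is under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .multimap import KmerIndex, align_read, assign_mapq, build_index
from .sequence_io import AlignmentHit, GenomeDB, Read
from .util import DataError, format_pct

DEFAULT_ORDER = ("mapq", "dedup", "contaminant", "unique")


@dataclass
class FilterChainReport:
    raw_reads: int
    aligned_raw: int
    aligned_raw_pct: float
    after_mapq: int
    after_dedup: int
    after_contaminant_subtraction: int
    after_unique: int
    high_quality_pct: float
    genome_retrieval_pct: float
    removed: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SexCall:
    x_coverage: float
    autosome_coverage: float
    ratio: float
    call: str  # XX / XY / indeterminate


def filter_mapq(hits: Iterable[AlignmentHit], threshold: int = 30) -> list[AlignmentHit]:
    out = []
    for h in hits:
        if h.mapq is None:
            raise DataError(f"hit for read {h.read_id} has no mapq assigned")
        if h.mapq >= threshold:
            out.append(h)
    return out


def remove_duplicates(
    hits: Iterable[AlignmentHit], reads: dict[str, Read]
) -> list[AlignmentHit]:
    """Keep one hit per (contig, strand, 5' start): highest base-quality sum,
    ties broken by lexicographically smallest read id."""
    best: dict[tuple, tuple] = {}
    for h in hits:
        key = (h.contig, h.strand, h.five_prime_start)
        qual_sum = sum(reads[h.read_id].qualities)
        rank = (-qual_sum, h.read_id)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, h)
    out = [entry[1] for entry in best.values()]
    out.sort(key=lambda h: (h.contig, h.start, h.strand, h.read_id))
    return out


def subtract_contaminant(
    hits_target: Iterable[AlignmentHit],
    reads: dict[str, Read],
    contaminant_index: KmerIndex,
    max_mismatch: int = 3,
) -> list[AlignmentHit]:
    """Drop every read with any contaminant-genome alignment at <= max_mismatch,
    regardless of its target mapping quality."""
    hits_target = list(hits_target)
    contaminated: dict[str, bool] = {}
    for h in hits_target:
        if h.read_id not in contaminated:
            c_hits = align_read(reads[h.read_id], contaminant_index, max_mismatch)
            contaminated[h.read_id] = bool(c_hits)
    return [h for h in hits_target if not contaminated[h.read_id]]


def keep_unique(
    hits: Iterable[AlignmentHit],
    full_hits_by_read: dict[str, list[AlignmentHit]],
) -> list[AlignmentHit]:
    """Keep reads whose best target-genome placement is their only placement
    at the best mismatch count, with no alternative within 2 mismatches — the
    analogue of a unique-alignment tag with zero suboptimal hits."""
    out = []
    for h in hits:
        all_hits = full_hits_by_read.get(h.read_id, [])
        best = min(a.mismatches for a in all_hits) if all_hits else h.mismatches
        n_best = sum(1 for a in all_hits if a.mismatches == best)
        n_close = sum(1 for a in all_hits if best < a.mismatches <= best + 2)
        if n_best == 1 and n_close == 0:
            out.append(h)
    return out


def coverage_fraction(
    hits: Iterable[AlignmentHit], genomes: GenomeDB, genome: str,
    exclude_mito: bool = True,
) -> float:
    """Fraction of the (nuclear) genome covered by >= 1 surviving read."""
    contigs = {
        c.name: len(c)
        for c in genomes.contigs(genome)
        if not (exclude_mito and c.contig_class == "mito")
    }
    total = sum(contigs.values())
    if total == 0:
        raise DataError(f"genome {genome!r} has no eligible contigs")
    covered = 0
    deltas: dict[str, np.ndarray] = {
        name: np.zeros(length + 1, dtype=np.int32) for name, length in contigs.items()
    }
    for h in hits:
        if h.contig in deltas:
            deltas[h.contig][h.start] += 1
            deltas[h.contig][h.end] -= 1
    for arr in deltas.values():
        covered += int(np.count_nonzero(np.cumsum(arr[:-1]) > 0))
    return covered / total


def summarize_chain(
    raw_reads: int,
    aligned_raw: int,
    after_mapq: int,
    after_dedup: int,
    after_contaminant: int,
    after_unique: int,
    surviving_hits: Sequence[AlignmentHit],
    genomes: Optional[GenomeDB] = None,
    genome: Optional[str] = None,
) -> FilterChainReport:
    """Assemble the per-stage report; percentages round half-up to 1 decimal."""
    if raw_reads == 0:
        raise DataError("raw read count is zero")
    retrieval = 0.0
    if genomes is not None and genome is not None:
        retrieval = format_pct(
            coverage_fraction(surviving_hits, genomes, genome), 1.0
        )
    return FilterChainReport(
        raw_reads=raw_reads,
        aligned_raw=aligned_raw,
        aligned_raw_pct=format_pct(aligned_raw, raw_reads),
        after_mapq=after_mapq,
        after_dedup=after_dedup,
        after_contaminant_subtraction=after_contaminant,
        after_unique=after_unique,
        high_quality_pct=format_pct(after_unique, raw_reads),
        genome_retrieval_pct=retrieval,
        removed={
            "unaligned": raw_reads - aligned_raw,
            "mapq": aligned_raw - after_mapq,
            "dedup": after_mapq - after_dedup,
            "contaminant": after_dedup - after_contaminant,
            "non_unique": after_contaminant - after_unique,
        },
    )


def call_sex(
    hits: Iterable[AlignmentHit],
    genomes: GenomeDB,
    genome: str,
    xx_threshold: float = 0.8,
    xy_threshold: float = 0.6,
) -> SexCall:
    """Sex from the ratio of mean X-chromosome depth to mean autosome depth.

    A female (XX) carries X at the autosomal copy number (ratio ~ 1), a male
    half of it (~ 0.5); the band between the thresholds is a refusal zone.
    """
    x_len = sum(len(c) for c in genomes.contigs_of_class(genome, "X"))
    auto_len = sum(len(c) for c in genomes.contigs_of_class(genome, "autosome"))
    if x_len == 0 or auto_len == 0:
        raise DataError("genome must have both X and autosome contigs")
    x_names = {c.name for c in genomes.contigs_of_class(genome, "X")}
    auto_names = {c.name for c in genomes.contigs_of_class(genome, "autosome")}
    x_bases = sum(h.length for h in hits if h.contig in x_names)
    auto_bases = sum(h.length for h in hits if h.contig in auto_names)
    auto_cov = auto_bases / auto_len
    if auto_cov == 0:
        raise DataError("zero autosome coverage")
    x_cov = x_bases / x_len
    ratio = x_cov / auto_cov
    if ratio >= xx_threshold:
        call = "XX"
    elif ratio <= xy_threshold:
        call = "XY"
    else:
        call = "indeterminate"
    return SexCall(x_cov, auto_cov, ratio, call)


def nuclear_view(genomes: GenomeDB, genome: str) -> GenomeDB:
    """A single-genome GenomeDB without the mitochondrial contig(s)."""
    view = GenomeDB()
    view.add_genome(
        genome, [c for c in genomes.contigs(genome) if c.contig_class != "mito"]
    )
    return view


def run_filter_chain(
    reads: Sequence[Read],
    genomes: GenomeDB,
    target: str,
    contaminant: str,
    mapq_threshold: int = 30,
    max_mismatch: int = 3,
    seed_len: int = 7,
    order: Sequence[str] = DEFAULT_ORDER,
) -> tuple[list[AlignmentHit], FilterChainReport, dict[str, list[AlignmentHit]]]:
    """Align reads to the nuclear target genome and run the filter chain.

    Returns the surviving hits, the stage report, and the full per-read hit
    lists (needed by downstream uniqueness-aware consumers).
    """
    if set(order) != set(DEFAULT_ORDER):
        raise DataError(f"order must permute {DEFAULT_ORDER}")
    target_db = nuclear_view(genomes, target)
    target_index = build_index(target_db, seed_len=seed_len)
    contaminant_index = build_index(
        _single_genome_view(genomes, contaminant), seed_len=seed_len
    )
    read_map = {r.id: r for r in reads}

    full_hits: dict[str, list[AlignmentHit]] = {}
    primary: list[AlignmentHit] = []
    for read in reads:
        hits = align_read(read, target_index, max_mismatch)
        if not hits:
            continue
        hits = assign_mapq(hits)
        full_hits[read.id] = hits
        primary.append(max(hits, key=lambda h: (h.mapq, -h.mismatches)))

    aligned_raw = len(primary)
    counts: dict[str, int] = {}
    current = primary
    for stage in order:
        if stage == "mapq":
            current = filter_mapq(current, mapq_threshold)
        elif stage == "dedup":
            current = remove_duplicates(current, read_map)
        elif stage == "contaminant":
            current = subtract_contaminant(
                current, read_map, contaminant_index, max_mismatch
            )
        elif stage == "unique":
            current = keep_unique(current, full_hits)
        counts[stage] = len(current)

    report = summarize_chain(
        raw_reads=len(reads),
        aligned_raw=aligned_raw,
        after_mapq=counts["mapq"],
        after_dedup=counts["dedup"],
        after_contaminant=counts["contaminant"],
        after_unique=counts["unique"],
        surviving_hits=current,
        genomes=genomes,
        genome=target,
    )
    return current, report, full_hits


def _single_genome_view(genomes: GenomeDB, genome: str) -> GenomeDB:
    view = GenomeDB()
    view.add_genome(genome, genomes.contigs(genome))
    return view
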
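"""Desk-scale ungapped multi-genome aligner and FastQ-Screen-style classifier.

The aligner is an exhaustive seeded end-to-end (ungapped) search: a read is
partitioned into non-overlapping seeds, each seed's exact occurrences are
looked up in a k-mer index, and every implied end-to-end placement is scored
by full-length mismatch count on both strands. By the pigeonhole principle a
read with at most m mismatches must contain at least one exact seed whenever
it carries >= m+1 non-overlapping seeds, so with 30 bp minimum reads and
m <= 3 a seed length of 7 guarantees completeness; longer seeds trade
completeness for speed.

Screening classifies every read, per mismatch tolerance, into the four
multi-genome categories (unique/multiple hits x one/multiple genomes) plus
no-hit, and the species call picks the genome with the highest
unique-to-one-genome fraction at zero mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_io import AlignmentHit, GenomeDB, Read
from .util import ConfigError, DataError, encode_dna, reverse_complement


class ScreenCategory(str, Enum):
    UNIQUE_ONE_GENOME = "unique_one_genome"
    MULTI_ONE_GENOME = "multi_one_genome"
    UNIQUE_MULTI_GENOME = "unique_multi_genome"
    MULTI_MULTI_GENOME = "multi_multi_genome"
    NO_HIT = "no_hit"


class KmerIndex:
    """Exact k-mer index over every contig of every genome.

    Both strands are served by reverse-complementing the query read, so only
    the forward strand is indexed.
    """

    def __init__(self, genomes: GenomeDB, seed_len: int = 12):
        if seed_len < 4:
            raise ConfigError("seed_len must be >= 4")
        self.seed_len = seed_len
        self.genomes = genomes
        self.genome_names: list[str] = list(genomes.names)
        self.contig_names: list[list[str]] = []
        self.contig_codes: list[list[np.ndarray]] = []
        self._postings: dict[str, list[tuple[int, int, int]]] = {}

        for g_idx, genome in enumerate(self.genome_names):
            names, codes = [], []
            for c_idx, contig in enumerate(genomes.contigs(genome)):
                if len(contig) < seed_len:
                    raise ConfigError(
                        f"contig {contig.name} shorter than seed_len {seed_len}"
                    )
                names.append(contig.name)
                codes.append(encode_dna(contig.sequence))
                seq = contig.sequence
                add = self._postings.setdefault
                for pos in range(len(seq) - seed_len + 1):
                    kmer = seq[pos : pos + seed_len]
                    if "N" in kmer:
                        continue
                    add(kmer, []).append((g_idx, c_idx, pos))
            self.contig_names.append(names)
            self.contig_codes.append(codes)

    def lookup(self, kmer: str) -> list[tuple[int, int, int]]:
        return self._postings.get(kmer, [])


def build_index(genomes: GenomeDB, seed_len: int = 12) -> KmerIndex:
    return KmerIndex(genomes, seed_len=seed_len)


def align_read(
    read: Read,
    index: KmerIndex,
    max_mismatch: int,
) -> list[AlignmentHit]:
    """All end-to-end placements of a read with <= max_mismatch mismatches.

    N in the read or the reference always counts as a mismatch. Completeness
    holds whenever the read holds >= max_mismatch+1 non-overlapping seeds.
    """
    k = index.seed_len
    length = len(read)
    if length == 0:
        return []
    if length < (max_mismatch + 1) * k:
        # too short to hold max_mismatch+1 seeds: pigeonhole no longer
        # guarantees an exact seed, so fall back to a full scan
        return _scan_align(read, index, max_mismatch)
    hits: list[AlignmentHit] = []
    offsets = range(0, length - k + 1, k)
    arange = np.arange(length)

    for strand, seq in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
        candidates: dict[tuple[int, int], set[int]] = {}
        for off in offsets:
            for g_idx, c_idx, pos in index.lookup(seq[off : off + k]):
                start = pos - off
                if start < 0:
                    continue
                if start + length > len(index.contig_codes[g_idx][c_idx]):
                    continue
                candidates.setdefault((g_idx, c_idx), set()).add(start)
        if not candidates:
            continue
        query = encode_dna(seq)
        for (g_idx, c_idx), starts in candidates.items():
            codes = index.contig_codes[g_idx][c_idx]
            starts_arr = np.fromiter(starts, dtype=np.int64)
            windows = codes[starts_arr[:, None] + arange]
            mism = (
                (windows != query) | (windows == 4) | (query == 4)
            ).sum(axis=1)
            for start, mm in zip(starts_arr, mism):
                if mm <= max_mismatch:
                    hits.append(
                        AlignmentHit(
                            read_id=read.id,
                            genome=index.genome_names[g_idx],
                            contig=index.contig_names[g_idx][c_idx],
                            start=int(start),
                            strand=strand,
                            mismatches=int(mm),
                            length=length,
                        )
                    )
    hits.sort(key=lambda h: (h.genome, h.contig, h.start, h.strand))
    return hits


def _scan_align(
    read: Read, index: KmerIndex, max_mismatch: int
) -> list[AlignmentHit]:
    """Exhaustive sliding-window alignment (completeness fallback)."""
    length = len(read)
    hits: list[AlignmentHit] = []
    for strand, seq in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
        query = encode_dna(seq)
        for g_idx, genome in enumerate(index.genome_names):
            for c_idx, codes in enumerate(index.contig_codes[g_idx]):
                if len(codes) < length:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(codes, length)
                mism = ((windows != query) | (windows == 4) | (query == 4)).sum(axis=1)
                for start in np.nonzero(mism <= max_mismatch)[0]:
                    hits.append(
                        AlignmentHit(
                            read_id=read.id,
                            genome=genome,
                            contig=index.contig_names[g_idx][c_idx],
                            start=int(start),
                            strand=strand,
                            mismatches=int(mism[start]),
                            length=length,
                        )
                    )
    hits.sort(key=lambda h: (h.genome, h.contig, h.start, h.strand))
    return hits


def assign_mapq(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Mapping-quality surrogate for one read's hits within one genome.

    Unique best placement with no alternative within 2 mismatches -> 37;
    best placement tied with another location -> 0 (for every hit);
    unique best with a close alternative -> 25. Non-best hits always get 0.
    """
    if not hits:
        return []
    genomes = {h.genome for h in hits}
    if len(genomes) != 1:
        raise DataError("assign_mapq expects hits from a single genome")
    reads = {h.read_id for h in hits}
    if len(reads) != 1:
        raise DataError("assign_mapq expects hits from a single read")
    best = min(h.mismatches for h in hits)
    n_best = sum(1 for h in hits if h.mismatches == best)
    out = []
    for h in hits:
        if h.mismatches != best or n_best > 1:
            mapq = 0
        elif any(
            o is not h and o.mismatches <= best + 2 for o in hits
        ):
            mapq = 25
        else:
            mapq = 37
        out.append(
            AlignmentHit(
                h.read_id, h.genome, h.contig, h.start, h.strand,
                h.mismatches, h.length, mapq,
            )
        )
    return out


@dataclass
class ScreenReport:
    """Per-genome, per-tolerance read-classification fractions.

    Reads hitting several genomes are counted once per genome in the
    multi-genome categories, so per-genome fractions can sum past 1; at the
    read level every read has exactly one category per tolerance.
    """

    n_reads: int
    genomes: list[str]
    tolerances: list[int]
    counts: dict[int, dict[str, dict[ScreenCategory, int]]]
    no_hit: dict[int, int]
    read_categories: dict[int, dict[str, ScreenCategory]] = field(repr=False, default_factory=dict)

    def fraction(self, tolerance: int, genome: str, category: ScreenCategory) -> float:
        return self.counts[tolerance][genome][category] / self.n_reads

    def unique_fractions(self, tolerance: int = 0) -> dict[str, float]:
        return {
            g: self.fraction(tolerance, g, ScreenCategory.UNIQUE_ONE_GENOME)
            for g in self.genomes
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.tolerances:
            for g in self.genomes:
                row = {"tolerance": m, "genome": g}
                for cat in ScreenCategory:
                    if cat is ScreenCategory.NO_HIT:
                        continue
                    row[cat.value] = self.fraction(m, g, cat)
                rows.append(row)
        frame = pd.DataFrame(rows)
        frame["no_hit"] = [self.no_hit[m] / self.n_reads for m in frame["tolerance"]]
        return frame

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "genomes": self.genomes,
            "tolerances": self.tolerances,
            "fractions": {
                str(m): {
                    g: {
                        cat.value: self.fraction(m, g, cat)
                        for cat in ScreenCategory
                        if cat is not ScreenCategory.NO_HIT
                    }
                    for g in self.genomes
                }
                for m in self.tolerances
            },
            "no_hit": {str(m): self.no_hit[m] / self.n_reads for m in self.tolerances},
        }


def classify_read(
    per_genome_hit_counts: dict[str, int]
) -> tuple[ScreenCategory, list[str]]:
    """Category of one read from its per-genome hit counts at one tolerance."""
    with_hits = [g for g, n in per_genome_hit_counts.items() if n > 0]
    if not with_hits:
        return ScreenCategory.NO_HIT, []
    max_hits = max(per_genome_hit_counts[g] for g in with_hits)
    if len(with_hits) == 1:
        cat = (
            ScreenCategory.UNIQUE_ONE_GENOME
            if max_hits == 1
            else ScreenCategory.MULTI_ONE_GENOME
        )
    else:
        cat = (
            ScreenCategory.UNIQUE_MULTI_GENOME
            if max_hits == 1
            else ScreenCategory.MULTI_MULTI_GENOME
        )
    return cat, with_hits


def screen(
    reads: Iterable[Read],
    genomes: GenomeDB,
    tolerances: Sequence[int] = (0, 1, 2, 3),
    seed_len: int = 7,
    index: Optional[KmerIndex] = None,
    keep_read_categories: bool = False,
) -> ScreenReport:
    """Align every read once at the loosest tolerance, then classify at each."""
    tolerances = sorted(set(tolerances))
    if index is None:
        index = build_index(genomes, seed_len=seed_len)
    genome_names = index.genome_names
    counts = {
        m: {g: {cat: 0 for cat in ScreenCategory} for g in genome_names}
        for m in tolerances
    }
    no_hit = {m: 0 for m in tolerances}
    read_categories: dict[int, dict[str, ScreenCategory]] = {m: {} for m in tolerances}

    n_reads = 0
    max_m = tolerances[-1]
    for read in reads:
        n_reads += 1
        hits = align_read(read, index, max_m)
        for m in tolerances:
            per_genome = {g: 0 for g in genome_names}
            for h in hits:
                if h.mismatches <= m:
                    per_genome[h.genome] += 1
            cat, with_hits = classify_read(per_genome)
            if cat is ScreenCategory.NO_HIT:
                no_hit[m] += 1
            else:
                for g in with_hits:
                    counts[m][g][cat] += 1
            if keep_read_categories:
                read_categories[m][read.id] = cat
    if n_reads == 0:
        raise DataError("screen requires at least one read")
    return ScreenReport(
        n_reads=n_reads,
        genomes=genome_names,
        tolerances=list(tolerances),
        counts=counts,
        no_hit=no_hit,
        read_categories=read_categories if keep_read_categories else {},
    )


@dataclass
class SpeciesCall:
    species: str              # genome name or "ambiguous"
    margin: float             # percentage-point gap to the runner-up
    unique_fractions: dict[str, float]

    @property
    def is_ambiguous(self) -> bool:
        return self.species == "ambiguous"


def call_species(report: ScreenReport, margin_threshold: float = 2.0) -> SpeciesCall:
    """Call the source species as the genome maximising the unique fraction
    at zero mismatches; refuse when the margin to the runner-up is below the
    threshold (percentage points)."""
    if not report.genomes:
        raise DataError("empty screen report")
    fractions = report.unique_fractions(tolerance=0)
    ranked = sorted(fractions.items(), key=lambda kv: (-kv[1], kv[0]))
    best, best_frac = ranked[0]
    runner_frac = ranked[1][1] if len(ranked) > 1 else 0.0
    margin = 100.0 * (best_frac - runner_frac)
    if len(ranked) > 1 and margin < margin_threshold:
        return SpeciesCall("ambiguous", margin, fractions)
    return SpeciesCall(best, margin, fractions)
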
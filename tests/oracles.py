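"""Independent reference implementations used only to check the package."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from vellum.sequence_io import AlignmentHit, GenomeDB, Read
from vellum.util import encode_dna, reverse_complement


def brute_force_align(
    read: Read, genomes: GenomeDB, max_mismatch: int
) -> list[AlignmentHit]:
    """Scan every position of every contig on both strands."""
    hits = []
    for genome in genomes.names:
        for contig in genomes.contigs(genome):
            codes = encode_dna(contig.sequence)
            for strand, seq in (
                ("+", read.sequence),
                ("-", reverse_complement(read.sequence)),
            ):
                query = encode_dna(seq)
                length = len(query)
                if len(codes) < length:
                    continue
                windows = sliding_window_view(codes, length)
                mism = (
                    (windows != query) | (windows == 4) | (query == 4)
                ).sum(axis=1)
                for start in np.nonzero(mism <= max_mismatch)[0]:
                    hits.append(
                        AlignmentHit(
                            read.id, genome, contig.name, int(start), strand,
                            int(mism[start]), length,
                        )
                    )
    hits.sort(key=lambda h: (h.genome, h.contig, h.start, h.strand))
    return hits


def hit_key(hit: AlignmentHit) -> tuple:
    return (hit.genome, hit.contig, hit.start, hit.strand, hit.mismatches)


def nj_three_taxon_branches(dab: float, dac: float, dbc: float) -> tuple[float, float, float]:
    """Closed form for the star tree on three taxa: v_x = (d_xy + d_xz - d_yz)/2."""
    return (
        (dab + dac - dbc) / 2.0,
        (dab + dbc - dac) / 2.0,
        (dac + dbc - dab) / 2.0,
    )


def spaced_positions(
    rng: np.random.Generator, length: int, n: int, min_gap: int, margin: int = 30
) -> np.ndarray:
    """n sorted positions with pairwise gaps >= min_gap, away from the ends."""
    slack = length - 2 * margin - (n - 1) * min_gap
    base = np.sort(rng.choice(slack, size=n, replace=False))
    return base + margin + np.arange(n) * min_gap
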
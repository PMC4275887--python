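"""Adapter trimming and length filtering.

The trimmer reproduces a deliberately conservative configuration: any
read-suffix / adapter-prefix overlap of at least ``min_overlap`` bases (down
to a single base) is removed. A 1 bp minimum overlap causes frequent spurious
trims of reads that merely end in the adapter's first base; that is the
intended behaviour, chosen to guard against adapter poisoning of downstream
alignment rather than to maximise retained sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable

from .sequence_io import Read
from .util import DataError


@dataclass
class TrimReport:
    reads_in: int = 0
    reads_trimmed: int = 0
    reads_discarded_short: int = 0
    reads_out: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def trim_adapter(
    read: Read,
    adapter: str,
    min_overlap: int = 1,
    max_error_rate: float = 0.1,
) -> Read:
    """Remove the longest admissible 3' adapter overlap from a read.

    An overlap of length k (read suffix vs adapter prefix) is admissible when
    k >= min_overlap and its mismatch count is <= floor(k * max_error_rate).
    The longest admissible overlap wins; with none, the read is unchanged.
    """
    if not adapter:
        raise DataError("adapter must be nonempty")
    if len(read) == 0:
        return read
    seq = read.sequence
    max_k = min(len(seq), len(adapter))
    for k in range(max_k, min_overlap - 1, -1):
        allowed = math.floor(k * max_error_rate)
        mismatches = sum(
            1 for a, b in zip(seq[len(seq) - k :], adapter[:k]) if a != b
        )
        if mismatches <= allowed:
            return Read(read.id, seq[: len(seq) - k], read.qualities[: len(seq) - k])
    return read


def length_filter(
    reads: Iterable[Read], min_len: int = 30, reads_trimmed: int = 0
) -> tuple[list[Read], TrimReport]:
    """Keep reads of length >= min_len; counts are conserved in the report."""
    reads = list(reads)
    kept = [r for r in reads if len(r) >= min_len]
    report = TrimReport(
        reads_in=len(reads),
        reads_trimmed=reads_trimmed,
        reads_discarded_short=len(reads) - len(kept),
        reads_out=len(kept),
    )
    return kept, report


def prepare_reads(
    reads: Iterable[Read],
    adapter: str,
    min_overlap: int = 1,
    max_error_rate: float = 0.1,
    min_len: int = 30,
) -> tuple[list[Read], TrimReport]:
    """Trim adapters then length-filter; the standard read preparation step."""
    trimmed = []
    n_trimmed = 0
    for read in reads:
        out = trim_adapter(read, adapter, min_overlap, max_error_rate)
        if len(out) < len(read):
            n_trimmed += 1
        trimmed.append(out)
    return length_filter(trimmed, min_len=min_len, reads_trimmed=n_trimmed)
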
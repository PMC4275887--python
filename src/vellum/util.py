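"""Shared helpers: seeding, DNA encoding, percentage formatting."""

from __future__ import annotations

import hashlib
import math
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# numeric DNA encoding; 4 (N / anything else) never matches anything
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid configuration value."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode_dna(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_dna(codes: np.ndarray) -> str:
    return _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")


def derive_seed(master: int, name: str) -> int:
    """Derive a stable per-stream seed (< 2**31) from a master seed and a name."""
    digest = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def format_pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to `decimals` places (the convention used in
    all nuclear-read summary tables; the mitochondrial contamination statistic
    uses its own floor/ceil convention instead)."""
    if denominator == 0:
        raise DataError("percentage with zero denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(exp, rounding=ROUND_HALF_UP))


def floor_pct(numerator: float, denominator: float) -> int:
    if denominator == 0:
        raise DataError("percentage with zero denominator")
    return math.floor(100.0 * numerator / denominator)


def ceil_pct(numerator: float, denominator: float) -> int:
    if denominator == 0:
        raise DataError("percentage with zero denominator")
    return math.ceil(100.0 * numerator / denominator)
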
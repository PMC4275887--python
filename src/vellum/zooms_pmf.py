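"""Collagen peptide-mass-fingerprint (ZooMS) species identification.

Tryptic peptides are predicted from collagen sequences (cleave after K or R
unless followed by P), monoisotopic [M+H]+ masses computed with optional
proline hydroxylation (the characteristic collagen modification, +15.994915
Da each), and a MALDI peak list is matched against per-species marker tables
within a mass tolerance. The species score is the fraction of a species'
diagnostic markers matched by some peak.

All masses are singly protonated monoisotopic values, the MALDI-TOF
convention; tolerances may be absolute (Da) or relative (ppm).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .util import ConfigError, DataError

WATER = 18.010565
PROTON = 1.007276
HYDROXYLATION = 15.994915

# monoisotopic residue masses
RESIDUE_MASS = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

_CLEAVE_RE = re.compile(r"(?<=[KR])(?!P)")


def digest(protein: str, missed_cleavages: int = 0) -> list[str]:
    """Tryptic digest: cleave after K or R except before P.

    Peptides are returned in sequence order; their concatenation equals the
    input. With missed cleavages, joined runs of up to mc+1 adjacent peptides
    are appended after the fully cleaved set.
    """
    protein = protein.strip().upper()
    if not protein:
        raise DataError("empty protein sequence")
    bad = set(protein) - set(RESIDUE_MASS)
    if bad:
        raise DataError(f"invalid residues {sorted(bad)}")
    if not 0 <= missed_cleavages <= 2:
        raise ConfigError("missed_cleavages must be 0-2")
    peptides = [p for p in _CLEAVE_RE.split(protein) if p]
    if missed_cleavages == 0:
        return peptides
    out = list(peptides)
    for span in range(2, missed_cleavages + 2):
        for i in range(len(peptides) - span + 1):
            out.append("".join(peptides[i : i + span]))
    return out


def peptide_mass(peptide: str, n_hydroxylations: int = 0) -> float:
    """Monoisotopic [M+H]+ mass of a peptide with optional hydroxyprolines."""
    if not peptide:
        raise DataError("empty peptide")
    bad = set(peptide.upper()) - set(RESIDUE_MASS)
    if bad:
        raise DataError(f"invalid residues {sorted(bad)}")
    n_pro = peptide.upper().count("P")
    if n_hydroxylations < 0 or n_hydroxylations > n_pro:
        raise DataError(
            f"{n_hydroxylations} hydroxylations but only {n_pro} prolines"
        )
    mass = sum(RESIDUE_MASS[r] for r in peptide.upper())
    return mass + WATER + PROTON + HYDROXYLATION * n_hydroxylations


@dataclass(frozen=True)
class Marker:
    species: str
    marker_id: str
    diagnostic: bool = True
    peptide: Optional[str] = None
    mass: Optional[float] = None
    max_hydroxylations: int = 0

    def masses(self) -> list[float]:
        if self.peptide:
            return [
                peptide_mass(self.peptide, h)
                for h in range(self.max_hydroxylations + 1)
            ]
        if self.mass is not None:
            return [self.mass]
        raise DataError(f"marker {self.marker_id}: neither peptide nor mass given")


@dataclass
class PeakList:
    masses: list[float]
    intensities: Optional[list[float]] = None

    def __post_init__(self):
        if any(m <= 0 for m in self.masses):
            raise DataError("peak masses must be positive")
        order = sorted(range(len(self.masses)), key=lambda i: self.masses[i])
        self.masses = [self.masses[i] for i in order]
        if self.intensities is not None:
            self.intensities = [self.intensities[i] for i in order]


@dataclass
class SpeciesScore:
    species: str
    score: float                      # matched diagnostic / total diagnostic
    matched: list[str] = field(default_factory=list)
    matched_masses: list[float] = field(default_factory=list)


def read_peak_list(path: Union[str, Path]) -> PeakList:
    """Two-column TSV (m/z, optional intensity), '#' comments allowed."""
    masses, intensities = [], []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("m/z"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                masses.append(float(parts[0]))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad m/z value") from exc
            intensities.append(float(parts[1]) if len(parts) > 1 else 1.0)
    return PeakList(masses, intensities)


def read_mzml_peaks(path: Union[str, Path]) -> PeakList:
    """Read the m/z arrays of an mzML file (summed over spectra)."""
    from pyteomics import mzml  # deferred: only needed for this format

    masses: list[float] = []
    with mzml.read(str(path)) as reader:
        for spectrum in reader:
            masses.extend(float(m) for m in spectrum["m/z array"])
    if not masses:
        raise DataError(f"{path}: no peaks found")
    return PeakList(masses)


def read_marker_table(path: Union[str, Path]) -> list[Marker]:
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"species", "marker_id", "diagnostic"}
    if not required <= set(table.columns):
        raise DataError(f"{path}: marker table needs columns {sorted(required)}")
    markers = []
    for row in table.itertuples():
        peptide = getattr(row, "peptide", None)
        if isinstance(peptide, float):  # NaN from pandas
            peptide = None
        mass = getattr(row, "mass", None)
        if mass is not None and pd.isna(mass):
            mass = None
        markers.append(
            Marker(
                species=row.species,
                marker_id=row.marker_id,
                diagnostic=bool(row.diagnostic),
                peptide=peptide,
                mass=float(mass) if mass is not None else None,
                max_hydroxylations=int(getattr(row, "max_hydroxylations", 0) or 0),
            )
        )
    if not markers:
        raise DataError(f"{path}: empty marker table")
    return markers


def load_demo_markers() -> list[Marker]:
    """Bundled synthetic demonstration marker table (collagen-like peptides
    invented for testing; not published marker masses)."""
    with resources.as_file(
        resources.files("vellum").joinpath("data/markers_demo.tsv")
    ) as path:
        return read_marker_table(path)


def match_peaks(
    peaks: PeakList,
    markers: Sequence[Marker],
    tolerance: float = 0.2,
    unit: str = "Da",
) -> dict[str, SpeciesScore]:
    """Score each species by the fraction of its diagnostic markers matched.

    A marker is matched when any peak lies within +/- tolerance of any of its
    masses; one peak may satisfy several markers. Matching is monotone in the
    tolerance.
    """
    if tolerance <= 0:
        raise ConfigError("tolerance must be positive")
    if unit not in ("Da", "ppm"):
        raise ConfigError("unit must be 'Da' or 'ppm'")
    if not markers:
        raise DataError("empty marker table")

    scores: dict[str, SpeciesScore] = {}
    by_species: dict[str, list[Marker]] = {}
    for marker in markers:
        by_species.setdefault(marker.species, []).append(marker)

    for species, species_markers in by_species.items():
        diagnostic = [m for m in species_markers if m.diagnostic]
        matched_ids: list[str] = []
        matched_masses: list[float] = []
        for marker in diagnostic:
            hit_mass = None
            for mass in marker.masses():
                tol = tolerance if unit == "Da" else mass * tolerance * 1e-6
                if any(abs(peak - mass) <= tol for peak in peaks.masses):
                    hit_mass = mass
                    break
            if hit_mass is not None:
                matched_ids.append(marker.marker_id)
                matched_masses.append(hit_mass)
        score = len(matched_ids) / len(diagnostic) if diagnostic else 0.0
        scores[species] = SpeciesScore(species, score, matched_ids, matched_masses)
    return scores


@dataclass
class PmfCall:
    species: str  # or "ambiguous"
    margin: float
    scores: dict[str, float]


def call_species_pmf(
    scores: dict[str, SpeciesScore], margin_threshold: float = 0.2
) -> PmfCall:
    """Argmax species score; ambiguous when the top two are within the margin."""
    if len(scores) < 2:
        raise DataError("need scores for at least two species")
    flat = {s: sc.score for s, sc in scores.items()}
    ranked = sorted(flat.items(), key=lambda kv: (-kv[1], kv[0]))
    margin = ranked[0][1] - ranked[1][1]
    if margin < margin_threshold:
        return PmfCall("ambiguous", margin, flat)
    return PmfCall(ranked[0][0], margin, flat)


def synthetic_spectrum(
    markers: Sequence[Marker],
    species: str,
    noise_masses: Iterable[float] = (),
) -> PeakList:
    """Peak list containing every marker mass of one species plus noise peaks
    — a matched synthetic spectrum for end-to-end agreement checks."""
    masses: list[float] = []
    for marker in markers:
        if marker.species == species:
            masses.extend(marker.masses())
    masses.extend(noise_masses)
    if not masses:
        raise DataError(f"no markers for species {species!r}")
    return PeakList(masses)
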
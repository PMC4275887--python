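"""Pseudo-haploid genotyping at panel sites and breed allele-sharing.

Low-coverage samples are genotyped by drawing one sequencing read per SNP
site (base quality >= 15, mapping quality >= 30) and doubling the observed
allele to a homozygous pseudo-diploid call. Transition SNPs (C/T, G/A) are
excluded a priori because post-mortem deamination mimics them; merging with
the reference panel removes strand-ambiguous A/T and C/G SNPs and flips
opposite-strand calls, so only A/C and G/T allele pairs can survive.

Affinity to reference individuals is mean identity-by-state sharing
s = sum(IBS) / (2 L) over the loci both genotypes cover, averaged per breed
and optionally interpolated over geography by inverse-distance weighting.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_io import (
    MISSING_GENOTYPE,
    AlignmentHit,
    PanelSite,
    Read,
    SnpPanel,
)
from .util import DataError, reverse_complement

TRANSITION_PAIRS = (frozenset("CT"), frozenset("GA"))
AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PseudoDiploidGenotypes:
    calls: pd.Series                  # site_id -> "AA" style call or ".."
    # allele pair of the site the call was made against; None means the calls
    # were made directly against the target panel (same orientation)
    site_alleles: Optional[dict[str, frozenset]] = None
    excluded_transition: int = 0      # C/T and G/A panel sites dropped a priori
    excluded_no_coverage: int = 0
    excluded_off_panel: int = 0       # sampled base matching neither allele
    excluded_ambiguous: int = 0       # A/T, C/G sites dropped at merge
    excluded_irreconcilable: int = 0  # calls no strand flip can reconcile

    @property
    def n_called(self) -> int:
        return int((self.calls != MISSING_GENOTYPE).sum())


def _site_rng(seed: int, site_id: str) -> np.random.Generator:
    # keyed per site so calls do not depend on site processing order
    return np.random.default_rng([seed % (2**31), zlib.crc32(site_id.encode())])


def call_pseudo_haploid(
    hits: Iterable[AlignmentHit],
    reads: dict[str, Read],
    sites: Sequence[PanelSite],
    min_bq: int = 15,
    min_mapq: int = 30,
    seed: int = 0,
) -> PseudoDiploidGenotypes:
    """One random eligible read base per site, doubled to a homozygous call.

    Eligible bases come from hits with mapq >= min_mapq whose base at the
    site has quality >= min_bq. Transition-pair sites are excluded outright;
    a sampled base matching neither panel allele gives a missing call.
    """
    hits = list(hits)
    by_contig: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h)
    for lst in by_contig.values():
        lst.sort(key=lambda h: h.start)
    starts = {c: np.array([h.start for h in lst]) for c, lst in by_contig.items()}

    result: dict[str, str] = {}
    excluded_transition = no_cov = off_panel = 0
    for site in sites:
        if site.alleles in TRANSITION_PAIRS:
            excluded_transition += 1
            continue
        eligible: list[str] = []
        contig_hits = by_contig.get(site.contig, [])
        if contig_hits:
            arr = starts[site.contig]
            lo = int(np.searchsorted(arr, site.pos - max(h.length for h in contig_hits)))
            for h in contig_hits[lo:]:
                if h.start > site.pos:
                    break
                if not (h.start <= site.pos < h.end):
                    continue
                if (h.mapq or 0) < min_mapq:
                    continue
                offset = site.pos - h.start
                if h.strand == "+":
                    base = reads[h.read_id].sequence[offset]
                    bq = reads[h.read_id].qualities[offset]
                else:
                    oriented = reverse_complement(reads[h.read_id].sequence)
                    base = oriented[offset]
                    bq = reads[h.read_id].qualities[h.length - 1 - offset]
                if bq >= min_bq and base in "ACGT":
                    eligible.append(base)
        if not eligible:
            no_cov += 1
            result[site.site_id] = MISSING_GENOTYPE
            continue
        rng = _site_rng(seed, site.site_id)
        base = eligible[int(rng.integers(len(eligible)))]
        if base in site.alleles:
            result[site.site_id] = base + base
        else:
            off_panel += 1
            result[site.site_id] = MISSING_GENOTYPE

    return PseudoDiploidGenotypes(
        calls=pd.Series(result, dtype=object),
        excluded_transition=excluded_transition,
        excluded_no_coverage=no_cov,
        excluded_off_panel=off_panel,
    )


def merge_with_panel(
    calls: PseudoDiploidGenotypes, panel: SnpPanel
) -> PseudoDiploidGenotypes:
    """Orient calls to the panel strand and drop strand-ambiguous SNPs.

    When the calls carry their own site allele pairs (e.g. imported from
    another panel), a call is kept as-is if its pair equals the panel's,
    complemented if its pair is the reverse complement of the panel's, and
    removed otherwise. Calls made directly against this panel reconcile at
    the base level (complement the base when only its complement is a panel
    allele). A/T and C/G panel sites are removed first — a strand flip is
    undetectable there. After this and the a-priori transition filter only
    A/C and G/T pairs survive.
    """
    merged: dict[str, str] = {}
    ambiguous = irreconcilable = 0
    site_by_id = {s.site_id: s for s in panel.sites}
    for site_id, call in calls.calls.items():
        site = site_by_id.get(site_id)
        if site is None:
            continue
        if site.alleles in AMBIGUOUS_PAIRS:
            ambiguous += 1
            continue
        if site.alleles in TRANSITION_PAIRS:
            continue
        if call == MISSING_GENOTYPE:
            merged[site_id] = call
            continue
        base = call[0]
        call_pair = (calls.site_alleles or {}).get(site_id)
        if call_pair is not None:
            revcomp_pair = frozenset(_COMP[a] for a in site.alleles)
            if call_pair == site.alleles and base in site.alleles:
                merged[site_id] = call
            elif call_pair == revcomp_pair and _COMP[base] in site.alleles:
                merged[site_id] = _COMP[base] + _COMP[base]
            else:
                irreconcilable += 1
        elif base in site.alleles:
            merged[site_id] = call
        elif _COMP[base] in site.alleles:
            merged[site_id] = _COMP[base] + _COMP[base]
        else:
            irreconcilable += 1

    surviving_pairs = {
        site_by_id[sid].alleles for sid in merged
    }
    assert surviving_pairs <= {frozenset("AC"), frozenset("GT")}, (
        "allele pairs other than A/C and G/T survived the merge filters"
    )
    return PseudoDiploidGenotypes(
        calls=pd.Series(merged, dtype=object),
        excluded_transition=calls.excluded_transition,
        excluded_no_coverage=calls.excluded_no_coverage,
        excluded_off_panel=calls.excluded_off_panel,
        excluded_ambiguous=ambiguous,
        excluded_irreconcilable=irreconcilable,
    )


def ibs(genotype_a: str, genotype_b: str) -> int:
    """Identity-by-state count (0-2) between two diploid genotypes."""
    a = sorted(genotype_a)
    b = list(sorted(genotype_b))
    shared = 0
    for allele in a:
        if allele in b:
            b.remove(allele)
            shared += 1
    return shared


def allele_sharing(
    sample: pd.Series, reference: pd.Series
) -> Optional[tuple[float, int]]:
    """Mean IBS sharing s = sum(IBS) / (2 n) over jointly non-missing loci.

    Returns (s, n_overlap), or None when the genotypes share no usable locus
    (pairwise deletion: each comparison uses its own overlap).
    """
    common = sample.index.intersection(reference.index)
    total = 0
    n = 0
    for site_id in common:
        g1, g2 = sample[site_id], reference[site_id]
        if MISSING_GENOTYPE in (g1, g2) or "N" in g1 or "N" in g2:
            continue
        total += ibs(g1, g2)
        n += 1
    if n == 0:
        return None
    return total / (2 * n), n


@dataclass
class SharingResult:
    per_individual: pd.DataFrame   # columns: breed, sharing, n_overlap
    per_breed: pd.DataFrame        # index breed; columns: sharing, lon, lat (ranked)
    grid: Optional[pd.DataFrame] = None


def breed_summary(
    per_individual_sharing: dict[str, tuple[float, int]],
    breeds: pd.Series,
    coords: pd.DataFrame,
) -> SharingResult:
    """Average individual sharing within breeds; breeds with no usable
    individual are omitted. The per-breed table is ranked by sharing."""
    rows = []
    for ind, (s, n) in per_individual_sharing.items():
        rows.append({"individual": ind, "breed": breeds[ind], "sharing": s, "n_overlap": n})
    per_ind = pd.DataFrame(rows).set_index("individual")
    per_breed = (
        per_ind.groupby("breed")["sharing"].mean().to_frame("sharing")
    )
    per_breed = per_breed.join(coords, how="left").sort_values(
        "sharing", ascending=False
    )
    return SharingResult(per_individual=per_ind, per_breed=per_breed)


def sharing_against_panel(
    sample_calls: PseudoDiploidGenotypes, panel: SnpPanel
) -> SharingResult:
    """Sharing of one pseudo-diploid sample against every panel individual,
    summarised per breed."""
    per_ind: dict[str, tuple[float, int]] = {}
    for ind in panel.individuals:
        res = allele_sharing(sample_calls.calls, panel.genotypes[ind])
        if res is None:
            continue
        per_ind[ind] = res
    if not per_ind:
        raise DataError("no panel individual overlaps the sample calls")
    return breed_summary(per_ind, panel.breeds, panel.coords)


def interpolate_grid(
    breed_means: pd.DataFrame,
    power: float = 2.0,
    resolution: int = 25,
    pad: float = 1.0,
) -> pd.DataFrame:
    """Inverse-distance-weighted sharing surface over the breeds' bounding box.

    Exact at breed coordinates; values bounded by the input min/max. The grid
    is emitted as long-form (lon, lat, sharing) data, not a rendered map.
    """
    pts = breed_means.dropna(subset=["lon", "lat", "sharing"])
    if len(pts) < 3:
        raise DataError("interpolation needs >= 3 breeds with coordinates")
    lon = np.linspace(pts.lon.min() - pad, pts.lon.max() + pad, resolution)
    lat = np.linspace(pts.lat.min() - pad, pts.lat.max() + pad, resolution)
    gx, gy = np.meshgrid(lon, lat)
    px = pts.lon.to_numpy()
    py = pts.lat.to_numpy()
    pv = pts.sharing.to_numpy()
    d2 = (gx[..., None] - px) ** 2 + (gy[..., None] - py) ** 2
    dist = np.sqrt(d2)
    values = np.empty(gx.shape)
    exact = dist.min(axis=-1) < 1e-12
    with np.errstate(divide="ignore"):
        w = 1.0 / dist**power
    w[~np.isfinite(w)] = 0.0
    values = (w * pv).sum(axis=-1) / np.where(w.sum(axis=-1) == 0, 1, w.sum(axis=-1))
    nearest = dist.argmin(axis=-1)
    values[exact] = pv[nearest[exact]]
    return pd.DataFrame(
        {"lon": gx.ravel(), "lat": gy.ravel(), "sharing": values.ravel()}
    )
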
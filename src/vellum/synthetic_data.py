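"""Synthetic inputs for the parchment pipeline, with full truth records.

The generator emulates the study conditions end to end: several toy genomes
with controlled homology standing in for the sheep/cow/goat/human references,
short single-end reads (49 bp) with cytosine-deamination damage and adapter
read-through, mitochondrial read sets drawn from a target and a contaminant
haplotype, and a multi-breed SNP panel with Balding-Nichols differentiation
and per-breed geographic coordinates.

Every operation is deterministic under a fixed seed; independent random
streams are derived per concern (fragments, damage, errors) so that, e.g.,
switching damage off does not perturb fragment sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_io import Contig, GenomeDB, PanelSite, Read, SnpPanel, MISSING_GENOTYPE
from .util import ConfigError, DataError, derive_seed, reverse_complement

BASES = "ACGT"
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
DEFAULT_SPECIES = ("sheep_like", "cow_like", "goat_like", "human_like")

# unordered allele pairs with transition pairs (A/G, C/T) twice as likely,
# roughly the transition bias of real SNP ascertainment
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]
_ALLELE_PAIR_P = np.array([2, 2, 1, 1, 1, 1], dtype=float)
_ALLELE_PAIR_P /= _ALLELE_PAIR_P.sum()

MITO_REPEAT_LEN = 75  # tandem control-region-like motif planted twice


@dataclass
class TruthRecord:
    """Ground truth emitted alongside simulated data."""

    read_sources: dict[str, str] = field(default_factory=dict)
    origins: dict[str, tuple] = field(default_factory=dict)  # (genome, contig, pos, strand, frag_len)
    damage_positions: dict[str, tuple[int, ...]] = field(default_factory=dict)
    diagnostic_sites: list[int] = field(default_factory=list)
    variant_positions: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    repeat_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    mito_repeat: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def source_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for src in self.read_sources.values():
            counts[src] = counts.get(src, 0) + 1
        return counts


@dataclass
class SimGenomeConfig:
    seed: int
    n_species: int = 4
    contig_spec: Sequence[tuple[str, int, str]] = (
        ("chr1", 40_000, "autosome"),
        ("chrX", 8_000, "X"),
        ("chrM", 16_500, "mito"),
    )
    divergence: Sequence[float] = (0.04, 0.08, 0.10, 0.16)
    shared_repeat: Optional[tuple[int, int]] = (100, 5)
    gc: float = 0.42
    species_names: Optional[Sequence[str]] = None

    def __post_init__(self):
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if np.isscalar(self.divergence):
            self.divergence = (float(self.divergence),) * self.n_species
        if len(self.divergence) != self.n_species:
            raise ConfigError("divergence must give one value per species")
        for d in self.divergence:
            if not 0.0 <= d <= 0.5:
                raise ConfigError(f"divergence {d} outside [0, 0.5]")
        for name, length, cls in self.contig_spec:
            if length <= 0:
                raise ConfigError(f"contig {name}: length must be > 0")
            if cls not in ("autosome", "X", "mito"):
                raise ConfigError(f"contig {name}: unknown class {cls!r}")
        if not 0.0 < self.gc < 1.0:
            raise ConfigError("gc must be in (0, 1)")
        if self.species_names is None:
            if self.n_species <= len(DEFAULT_SPECIES):
                self.species_names = DEFAULT_SPECIES[: self.n_species]
            else:
                self.species_names = tuple(
                    f"species{i}" for i in range(self.n_species)
                )
        if len(self.species_names) != self.n_species:
            raise ConfigError("species_names length must equal n_species")


@dataclass
class SimReadConfig:
    seed: int
    n_reads: int = 10_000
    read_length: int = 49
    fragment_mean: float = 55.0
    fragment_sd: float = 20.0
    delta5: float = 0.0        # 5' terminal C->T deamination probability
    lam: float = 0.3           # per-position geometric decay moving inward
    seq_error: float = 0.0
    adapter: str = DEFAULT_ADAPTER
    mix: dict[str, float] = field(default_factory=lambda: {"target": 1.0})
    target_genome: str = "sheep_like"
    individual_divergence: float = 0.001  # second same-species individual
    duplicate_fraction: float = 0.0

    def __post_init__(self):
        if self.n_reads < 0:
            raise ConfigError("n_reads must be >= 0")
        if self.read_length < 1:
            raise ConfigError("read_length must be >= 1")
        for name, value in (
            ("delta5", self.delta5),
            ("lam", self.lam),
            ("seq_error", self.seq_error),
            ("duplicate_fraction", self.duplicate_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        total = sum(self.mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mix proportions sum to {total}, expected 1")


@dataclass
class SimPanelConfig:
    seed: int
    n_breeds: int = 8
    n_sites: int = 5_000
    fst: float = 0.15
    n_per_breed: int = 12
    coords: Optional[Sequence[tuple[float, float]]] = None
    target_breed: Optional[str] = None
    ancestral_freq: Optional[float] = None  # fixed shared frequency (default U(0.05, 0.95))

    def __post_init__(self):
        if not 0.0 < self.fst < 1.0:
            raise ConfigError("fst must be in (0, 1)")
        if self.ancestral_freq is not None and not 0.0 <= self.ancestral_freq <= 1.0:
            raise ConfigError("ancestral_freq must be in [0, 1]")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.n_breeds < 1:
            raise ConfigError("n_breeds must be >= 1")
        if self.coords is None:
            # spread breeds over a Europe-sized box
            self.coords = tuple(
                (-10.0 + 3.5 * i, 45.0 + 1.5 * (i % 3)) for i in range(self.n_breeds)
            )
        if len(set(self.coords)) != self.n_breeds:
            raise ConfigError("breed coordinates must be unique")
        if self.target_breed is None:
            self.target_breed = "breed0"

    @property
    def breed_names(self) -> list[str]:
        return [f"breed{i}" for i in range(self.n_breeds)]


# ---------------------------------------------------------------------------
# Genomes


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=length, p=probs).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return codes.tobytes().translate(bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")).decode()


def simulate_genomes(cfg: SimGenomeConfig) -> tuple[GenomeDB, TruthRecord]:
    """Generate ``n_species`` genomes sharing one contig structure.

    Each species is an independently substituted copy of a common ancestral
    sequence, so the expected pairwise divergence of species i and j is
    approximately ``1 - (1 - d_i)(1 - d_j)`` (ignoring coincident hits).
    Shared repeats are written verbatim at the same coordinates in every
    genome; every mito contig additionally carries a 75 bp tandem motif x2
    emulating the hard-to-align control-region repeat.
    """
    rng = np.random.default_rng(derive_seed(cfg.seed, "genomes"))
    truth = TruthRecord()

    ancestral = {
        name: _random_sequence(rng, length, cfg.gc)
        for name, length, _cls in cfg.contig_spec
    }

    repeat = None
    repeat_slots: dict[str, list[int]] = {}
    if cfg.shared_repeat is not None:
        rep_len, copies = cfg.shared_repeat
        repeat = _random_sequence(rng, rep_len, cfg.gc)
        # place copies in the longest contig at evenly spaced, non-overlapping slots
        host = max(cfg.contig_spec, key=lambda spec: spec[1])
        host_name, host_len, _ = host
        stride = host_len // (copies + 1)
        if stride <= rep_len:
            raise ConfigError("shared_repeat copies do not fit in the largest contig")
        repeat_slots[host_name] = [stride * (i + 1) for i in range(copies)]

    mito_motifs: dict[str, np.ndarray] = {}
    for name, length, cls in cfg.contig_spec:
        if cls == "mito":
            if length < 2 * MITO_REPEAT_LEN + 10:
                raise ConfigError(f"mito contig {name} too short for tandem motif")
            mito_motifs[name] = _random_sequence(rng, MITO_REPEAT_LEN, cfg.gc)

    db = GenomeDB()
    for species, div in zip(cfg.species_names, cfg.divergence):
        contigs = []
        for name, length, cls in cfg.contig_spec:
            seq = ancestral[name].copy()
            n_sub = rng.binomial(length, div)
            pos = rng.choice(length, size=n_sub, replace=False) if n_sub else np.array([], dtype=int)
            if n_sub:
                shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
                seq[pos] = (seq[pos] + shift) % 4
            truth.variant_positions[(species, name)] = np.sort(pos)
            # shared repeats overwrite divergence so they are verbatim everywhere
            if repeat is not None and name in repeat_slots:
                for start in repeat_slots[name]:
                    seq[start : start + len(repeat)] = repeat
                truth.repeat_positions.setdefault(species, []).extend(
                    (name, start) for start in repeat_slots[name]
                )
            if cls == "mito":
                motif = mito_motifs[name]
                start = length - 2 * MITO_REPEAT_LEN - 5
                seq[start : start + MITO_REPEAT_LEN] = motif
                seq[start + MITO_REPEAT_LEN : start + 2 * MITO_REPEAT_LEN] = motif
                truth.mito_repeat[species] = (name, start, start + 2 * MITO_REPEAT_LEN)
            contigs.append(Contig(name, _codes_to_str(seq), cls))
        db.add_genome(species, contigs)
    return db, truth


def second_individual(
    db: GenomeDB, genome: str, seed: int, divergence: float = 0.001
) -> list[Contig]:
    """Derive a second same-species individual by sparse substitution."""
    rng = np.random.default_rng(derive_seed(seed, f"individual2:{genome}"))
    contigs = []
    for contig in db.contigs(genome):
        seq = np.frombuffer(contig.sequence.encode(), dtype=np.uint8).copy()
        codes = np.zeros(len(seq), dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            codes[seq == b] = i
        n_sub = rng.binomial(len(codes), divergence)
        if n_sub:
            pos = rng.choice(len(codes), size=n_sub, replace=False)
            shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
            codes[pos] = (codes[pos] + shift) % 4
        contigs.append(Contig(contig.name, _codes_to_str(codes), contig.contig_class))
    return contigs


# ---------------------------------------------------------------------------
# Reads


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _apply_damage(
    fragment: list[str], delta5: float, lam: float, rng: np.random.Generator
) -> list[int]:
    """Double-stranded deamination: 5' C->T and mirrored 3' G->A.

    Uniform draws are consumed for every position regardless of delta5 so
    that changing the damage rate never shifts the random stream.
    """
    n = len(fragment)
    u5 = rng.random(n)
    u3 = rng.random(n)
    changed = []
    for k in range(n):
        p5 = delta5 * (1.0 - lam) ** k
        if fragment[k] == "C" and u5[k] < p5:
            fragment[k] = "T"
            changed.append(k)
        p3 = delta5 * (1.0 - lam) ** (n - 1 - k)
        if fragment[k] == "G" and u3[k] < p3:
            fragment[k] = "A"
            changed.append(k)
    return changed


def _apply_errors(
    fragment: list[str], seq_error: float, rng: np.random.Generator
) -> None:
    n = len(fragment)
    u = rng.random(n)
    if seq_error == 0.0:
        return
    hit = np.nonzero(u < seq_error)[0]
    if len(hit) == 0:
        return
    offsets = rng.integers(1, 4, size=len(hit))
    for idx, off in zip(hit, offsets):
        base = fragment[idx]
        if base in BASES:
            fragment[idx] = BASES[(BASES.index(base) + off) % 4]


def _simulate_from_sources(
    sources: dict[str, list[Contig]],
    probs: dict[str, float],
    cfg: SimReadConfig,
    id_prefix: str = "r",
) -> tuple[list[Read], TruthRecord]:
    for name, contigs in sources.items():
        if not contigs or all(len(c) == 0 for c in contigs):
            raise DataError(f"source {name!r} has no sequence")

    rng_frag = np.random.default_rng(derive_seed(cfg.seed, "fragments"))
    rng_damage = np.random.default_rng(derive_seed(cfg.seed, "damage"))
    rng_error = np.random.default_rng(derive_seed(cfg.seed, "errors"))

    labels = list(sources)
    p = np.array([probs[s] for s in labels])
    # per-source cumulative contig weights for length-proportional sampling
    weights = {
        s: np.cumsum([len(c) for c in contigs]) / sum(len(c) for c in contigs)
        for s, contigs in sources.items()
    }
    mu, sigma = _lognormal_params(cfg.fragment_mean, cfg.fragment_sd)

    src_idx = rng_frag.choice(len(labels), size=cfg.n_reads, p=p)
    flen_raw = rng_frag.lognormal(mu, sigma, size=cfg.n_reads)
    flens = np.clip(np.rint(flen_raw).astype(int), 18, 150)
    strands = rng_frag.random(cfg.n_reads) < 0.5
    u_contig = rng_frag.random(cfg.n_reads)
    u_pos = rng_frag.random(cfg.n_reads)
    dup_u = rng_frag.random(cfg.n_reads)

    reads: list[Read] = []
    truth = TruthRecord()
    prev_origin = None
    for i in range(cfg.n_reads):
        label = labels[src_idx[i]]
        contigs = sources[label]
        ci = int(np.searchsorted(weights[label], u_contig[i], side="right"))
        ci = min(ci, len(contigs) - 1)
        contig = contigs[ci]
        flen = min(int(flens[i]), len(contig))
        if (
            cfg.duplicate_fraction > 0.0
            and prev_origin is not None
            and dup_u[i] < cfg.duplicate_fraction
        ):
            label, contig, pos, strand, flen = prev_origin
        else:
            pos = int(u_pos[i] * (len(contig) - flen + 1))
            strand = "-" if strands[i] else "+"
            prev_origin = (label, contig, pos, strand, flen)

        frag = contig.sequence[pos : pos + flen]
        if strand == "-":
            frag = reverse_complement(frag)
        frag_list = list(frag)
        damaged = _apply_damage(frag_list, cfg.delta5, cfg.lam, rng_damage)
        _apply_errors(frag_list, cfg.seq_error, rng_error)

        seq = "".join(frag_list)
        if flen < cfg.read_length:
            tail = cfg.adapter[: cfg.read_length - flen]
            if len(tail) < cfg.read_length - flen:
                tail += "A" * (cfg.read_length - flen - len(tail))
            seq = seq + tail
        else:
            seq = seq[: cfg.read_length]

        rid = f"{id_prefix}{i:07d}"
        reads.append(Read(rid, seq, (35,) * len(seq)))
        truth.read_sources[rid] = label
        truth.origins[rid] = (label, contig.name, pos, strand, flen)
        if damaged:
            truth.damage_positions[rid] = tuple(k for k in damaged if k < cfg.read_length)
    return reads, truth


def simulate_reads(
    genomes: GenomeDB, cfg: SimReadConfig
) -> tuple[list[Read], TruthRecord]:
    """Simulate single-end reads from a mixture of sources.

    Mix keys: ``"target"`` (the configured target genome),
    ``"second_individual"`` (a sparsely substituted copy of the target, a
    same-species contaminant), or any genome name in ``genomes``.
    """
    if cfg.target_genome not in genomes:
        raise DataError(f"target genome {cfg.target_genome!r} not in GenomeDB")
    sources: dict[str, list[Contig]] = {}
    for label in cfg.mix:
        if label == "target":
            sources[label] = genomes.contigs(cfg.target_genome)
        elif label == "second_individual":
            sources[label] = second_individual(
                genomes, cfg.target_genome, cfg.seed, cfg.individual_divergence
            )
        elif label in genomes:
            sources[label] = genomes.contigs(label)
        else:
            raise DataError(f"mix names unknown source {label!r}")
    return _simulate_from_sources(sources, cfg.mix, cfg)


def simulate_mito_reads(
    haplotypes: dict[str, str],
    target: str,
    contaminant: str,
    rho: float,
    cfg: SimReadConfig,
) -> tuple[list[Read], TruthRecord]:
    """Simulate an mtDNA read set: target haplotype with a contaminant fraction.

    Haplotypes must be equal-length and gap-free; diagnostic sites (positions
    where target and contaminant differ) are recorded in the truth record.
    """
    if not 0.0 <= rho <= 1.0:
        raise ConfigError(f"rho {rho} outside [0, 1]")
    if target == contaminant:
        raise ConfigError("target and contaminant haplotypes must differ")
    for name in (target, contaminant):
        if name not in haplotypes:
            raise DataError(f"haplotype {name!r} not provided")
    t_seq, c_seq = haplotypes[target], haplotypes[contaminant]
    if len(t_seq) != len(c_seq):
        raise DataError("haplotypes must be equal length")
    if "-" in t_seq or "-" in c_seq:
        raise DataError("read simulation requires gap-free haplotypes")

    diagnostic = [i for i, (a, b) in enumerate(zip(t_seq, c_seq)) if a != b]
    sources = {
        "target": [Contig("chrM", t_seq, "mito")],
        "contaminant": [Contig("chrM", c_seq, "mito")],
    }
    probs = {"target": 1.0 - rho, "contaminant": rho}
    reads, truth = _simulate_from_sources(sources, probs, cfg, id_prefix="m")
    truth.diagnostic_sites = diagnostic
    return reads, truth


# ---------------------------------------------------------------------------
# SNP panel


def panel_sites_from_genome(
    contigs: list[Contig], n_sites: int, seed: int
) -> list[PanelSite]:
    """Place panel sites on real contig coordinates; allele_a is the contig
    base, allele_b a random alternative (transitions twice as likely)."""
    rng = np.random.default_rng(derive_seed(seed, "panel_sites"))
    nuclear = [c for c in contigs if c.contig_class != "mito"]
    total = sum(len(c) for c in nuclear)
    if n_sites > total // 10:
        raise ConfigError("too many panel sites for the genome size")
    sites: list[PanelSite] = []
    cum = np.cumsum([len(c) for c in nuclear])
    positions = np.sort(rng.choice(total, size=n_sites, replace=False))
    for i, gpos in enumerate(positions):
        ci = int(np.searchsorted(cum, gpos, side="right"))
        offset = int(gpos - (cum[ci - 1] if ci else 0))
        contig = nuclear[ci]
        ref = contig.sequence[offset]
        if ref not in BASES:
            ref = "A"
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        others = [b for b in BASES if b != ref and b != transition]
        u = rng.random()
        alt = transition if u < 0.5 else others[int(u * 4) % 2]
        sites.append(PanelSite(f"snp{i:05d}", contig.name, offset, ref, alt))
    return sites


def simulate_panel(
    cfg: SimPanelConfig, sites: Optional[list[PanelSite]] = None
) -> tuple[SnpPanel, pd.Series]:
    """Balding-Nichols structured multi-breed panel plus a target individual.

    Per site, an ancestral frequency p ~ U(0.05, 0.95) is drawn for allele_b;
    each breed's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F); genotypes are
    Hardy-Weinberg within breed. Returns the panel and the target individual's
    diploid genotypes (a Series over site ids), drawn from ``target_breed``.
    """
    rng = np.random.default_rng(derive_seed(cfg.seed, "panel"))
    if sites is None:
        pair_idx = rng.choice(len(_ALLELE_PAIRS), size=cfg.n_sites, p=_ALLELE_PAIR_P)
        sites = [
            PanelSite(f"snp{i:05d}", "chr1", 100 * i, *_ALLELE_PAIRS[pair_idx[i]])
            for i in range(cfg.n_sites)
        ]
    n_sites = len(sites)

    if cfg.ancestral_freq is None:
        p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    else:
        p_anc = np.full(n_sites, float(cfg.ancestral_freq))
    fst = cfg.fst
    degenerate = (p_anc <= 0.0) | (p_anc >= 1.0)
    p_safe = np.clip(p_anc, 1e-9, 1.0 - 1e-9)
    a = p_safe * (1.0 - fst) / fst
    b = (1.0 - p_safe) * (1.0 - fst) / fst

    breed_names = cfg.breed_names
    if cfg.target_breed not in breed_names:
        raise ConfigError(f"target_breed {cfg.target_breed!r} not among breeds")

    columns: dict[str, list[str]] = {}
    breeds: dict[str, str] = {}
    breed_freqs: dict[str, np.ndarray] = {}
    for breed in breed_names:
        freq = np.where(degenerate, p_anc, rng.beta(a, b))
        breed_freqs[breed] = freq
        counts = rng.binomial(2, freq[:, None], size=(n_sites, cfg.n_per_breed))
        for j in range(cfg.n_per_breed):
            ind = f"{breed}_ind{j}"
            breeds[ind] = breed
            col = []
            for i, site in enumerate(sites):
                c = counts[i, j]
                if c == 0:
                    col.append(site.allele_a + site.allele_a)
                elif c == 1:
                    col.append(site.allele_a + site.allele_b)
                else:
                    col.append(site.allele_b + site.allele_b)
            columns[ind] = col

    genotypes = pd.DataFrame(columns, index=[s.site_id for s in sites])
    genotypes.index.name = "site_id"
    coords = pd.DataFrame(
        list(cfg.coords), index=breed_names, columns=["lon", "lat"]
    ).loc[sorted(breed_names)]

    panel = SnpPanel(sites, genotypes, pd.Series(breeds), coords)

    t_counts = rng.binomial(2, breed_freqs[cfg.target_breed])
    target = pd.Series(
        [
            s.allele_a + s.allele_a
            if c == 0
            else (s.allele_a + s.allele_b if c == 1 else s.allele_b + s.allele_b)
            for s, c in zip(sites, t_counts)
        ],
        index=[s.site_id for s in sites],
        name=f"target:{cfg.target_breed}",
    )
    return panel, target


def pseudo_haploid_from_diploid(
    genotypes: pd.Series, missing_rate: float, seed: int
) -> pd.Series:
    """Sample one allele per site and double it, with random missingness —
    the low-coverage genotyping pattern of a parchment sample."""
    rng = np.random.default_rng(derive_seed(seed, "pseudo_haploid"))
    out = {}
    for site_id, geno in genotypes.items():
        if rng.random() < missing_rate or geno == MISSING_GENOTYPE:
            out[site_id] = MISSING_GENOTYPE
        else:
            allele = geno[int(rng.random() < 0.5)]
            out[site_id] = allele + allele
    return pd.Series(out, name=genotypes.name)
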
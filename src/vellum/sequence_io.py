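"""Readers and writers for the formats the pipeline touches.

Internal conventions: coordinates are 0-based half-open everywhere; FASTQ
qualities are Phred+33; genome sequences are stored uppercase. Alignment
records are an internal type with a minimal SAM export for interoperability.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tree import PhyloTree
from .util import DataError, reverse_complement

PathLike = Union[str, Path]

CONTIG_CLASSES = ("autosome", "X", "mito")
MISSING_GENOTYPE = ".."


@dataclass(frozen=True)
class Read:
    """A single-end sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if not self.id:
            raise DataError("read id must be nonempty")
        if len(self.sequence) != len(self.qualities):
            raise DataError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Contig:
    name: str
    sequence: str
    contig_class: str = "autosome"

    def __post_init__(self):
        if self.contig_class not in CONTIG_CLASSES:
            raise DataError(f"unknown contig class {self.contig_class!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


class GenomeDB:
    """Named genomes, each a set of contigs tagged autosome/X/mito."""

    def __init__(self):
        self._genomes: dict[str, dict[str, Contig]] = {}

    def add_genome(self, name: str, contigs: Iterable[Contig]) -> None:
        table: dict[str, Contig] = {}
        for contig in contigs:
            if contig.name in table:
                raise DataError(f"duplicate contig {contig.name!r} in genome {name!r}")
            table[contig.name] = contig
        self._genomes[name] = table

    @property
    def names(self) -> list[str]:
        return list(self._genomes)

    def __contains__(self, name: str) -> bool:
        return name in self._genomes

    def contigs(self, genome: str) -> list[Contig]:
        return list(self._genomes[genome].values())

    def contig(self, genome: str, contig: str) -> Contig:
        return self._genomes[genome][contig]

    def contigs_of_class(self, genome: str, contig_class: str) -> list[Contig]:
        return [c for c in self.contigs(genome) if c.contig_class == contig_class]

    def genome_length(self, genome: str, exclude_mito: bool = False) -> int:
        return sum(
            len(c)
            for c in self.contigs(genome)
            if not (exclude_mito and c.contig_class == "mito")
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One end-to-end placement of a read on a genome."""

    read_id: str
    genome: str
    contig: str
    start: int        # 0-based
    strand: str       # '+' or '-'
    mismatches: int
    length: int
    mapq: Optional[int] = None

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime_start(self) -> int:
        """Position of the read's 5' end on the reference (dedup key)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PanelSite:
    site_id: str
    contig: str
    pos: int          # 0-based
    allele_a: str
    allele_b: str

    def __post_init__(self):
        if self.allele_a == self.allele_b:
            raise DataError(f"site {self.site_id}: alleles must differ")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.allele_a, self.allele_b))


@dataclass
class SnpPanel:
    """SNP sites x individuals genotype table with breed metadata.

    Genotypes are two-character strings like "AC"; missing is "..".
    """

    sites: list[PanelSite]
    genotypes: pd.DataFrame          # index site_id, columns individual ids
    breeds: pd.Series                # individual id -> breed name
    coords: pd.DataFrame             # breed -> columns [lon, lat]

    def __post_init__(self):
        site_ids = [s.site_id for s in self.sites]
        if list(self.genotypes.index) != site_ids:
            raise DataError("genotype table index must match site order")

    @property
    def individuals(self) -> list[str]:
        return list(self.genotypes.columns)

    def site(self, site_id: str) -> PanelSite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)


# ---------------------------------------------------------------------------
# FASTQ — strict 4-line records so malformed input reports a line number.

def read_fastq(path: PathLike) -> list[Read]:
    reads: list[Read] = []
    with open(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise DataError(f"{path}:{lineno}: FASTQ header must start with '@'")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline().rstrip("\n")
            if not qual and not plus:
                raise DataError(f"{path}:{lineno}: truncated FASTQ record")
            lineno += 3
            if not plus.startswith("+"):
                raise DataError(f"{path}:{lineno - 1}: expected '+' separator line")
            if len(seq) != len(qual):
                raise DataError(
                    f"{path}:{lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            reads.append(
                Read(
                    id=header[1:].split()[0],
                    sequence=seq.upper(),
                    qualities=tuple(ord(c) - 33 for c in qual),
                )
            )
    return reads


def write_fastq(reads: Iterable[Read], path: PathLike) -> None:
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA via Biopython.

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read FASTA into an ordered {name: uppercase sequence} mapping."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise DataError(f"{path}: duplicate FASTA record {record.id!r}")
        out[record.id] = str(record.seq).upper()
    return out


def write_fasta(sequences: dict[str, str], path: PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_genome_fasta(
    path: PathLike, classes: Optional[dict[str, str]] = None
) -> list[Contig]:
    """Read a genome FASTA; contig classes come from an explicit map or from a
    `class=...` token in the description line (default autosome)."""
    contigs = []
    for record in SeqIO.parse(str(path), "fasta"):
        cls = "autosome"
        if classes and record.id in classes:
            cls = classes[record.id]
        else:
            for token in record.description.split():
                if token.startswith("class="):
                    cls = token[len("class="):]
        contigs.append(Contig(record.id, str(record.seq), cls))
    return contigs


def write_genome_fasta(contigs: Iterable[Contig], path: PathLike) -> None:
    with open(path, "w") as handle:
        for contig in contigs:
            handle.write(f">{contig.name} class={contig.contig_class}\n")
            seq = contig.sequence
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Panel TSV dialect: one row per site, fixed columns then one per individual.
# Sidecar metadata TSV: individual, breed, lon, lat.

_PANEL_FIXED = ["site_id", "contig", "pos", "allele_a", "allele_b"]


def write_panel(panel: SnpPanel, path: PathLike, meta_path: PathLike) -> None:
    rows = []
    for site in panel.sites:
        row = {
            "site_id": site.site_id,
            "contig": site.contig,
            "pos": site.pos,
            "allele_a": site.allele_a,
            "allele_b": site.allele_b,
        }
        row.update(panel.genotypes.loc[site.site_id].to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    meta = pd.DataFrame(
        {
            "individual": panel.individuals,
            "breed": [panel.breeds[i] for i in panel.individuals],
        }
    )
    meta["lon"] = [panel.coords.loc[b, "lon"] for b in meta["breed"]]
    meta["lat"] = [panel.coords.loc[b, "lat"] for b in meta["breed"]]
    meta.to_csv(meta_path, sep="\t", index=False)


def read_panel(path: PathLike, meta_path: PathLike) -> SnpPanel:
    table = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    missing_cols = [c for c in _PANEL_FIXED if c not in table.columns]
    if missing_cols:
        raise DataError(f"{path}: missing panel columns {missing_cols}")
    individuals = [c for c in table.columns if c not in _PANEL_FIXED]
    sites = [
        PanelSite(r.site_id, r.contig, int(r.pos), r.allele_a, r.allele_b)
        for r in table.itertuples()
    ]
    genotypes = table[individuals].copy()
    genotypes.index = [s.site_id for s in sites]
    genotypes.index.name = "site_id"

    meta = pd.read_csv(meta_path, sep="\t", dtype={"individual": str})
    breeds = pd.Series(meta.breed.values, index=meta.individual)
    coords = (
        meta.groupby("breed")[["lon", "lat"]].first().loc[sorted(meta.breed.unique())]
    )
    return SnpPanel(sites=sites, genotypes=genotypes, breeds=breeds, coords=coords)


def read_ped_map(
    ped_path: PathLike,
    map_path: PathLike,
    coords: Optional[pd.DataFrame] = None,
) -> SnpPanel:
    """Convert PLINK ped/map text files to the internal panel representation.

    The ped family id is taken as the breed label. `coords` (breed -> lon/lat)
    is optional; breeds without coordinates get NaN.
    """
    sites: list[PanelSite] = []
    with open(map_path) as handle:
        for lineno, line in enumerate(handle, 1):
            parts = line.split()
            if len(parts) < 4:
                raise DataError(f"{map_path}:{lineno}: expected 4 map columns")
            chrom, snp_id, _cm, pos = parts[:4]
            # alleles are discovered from the ped genotypes below
            sites.append((snp_id, chrom, int(pos)))

    individuals: list[str] = []
    breeds: dict[str, str] = {}
    geno_rows: list[list[str]] = []
    with open(ped_path) as handle:
        for lineno, line in enumerate(handle, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(sites):
                raise DataError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(sites)} fields, "
                    f"got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            individuals.append(iid)
            breeds[iid] = fid
            alleles = parts[6:]
            row = []
            for i in range(len(sites)):
                a, b = alleles[2 * i], alleles[2 * i + 1]
                row.append(MISSING_GENOTYPE if "0" in (a, b) else a + b)
            geno_rows.append(row)

    matrix = np.array(geno_rows, dtype=object).T if geno_rows else np.empty((len(sites), 0))
    panel_sites: list[PanelSite] = []
    keep_rows = []
    for idx, (snp_id, chrom, pos) in enumerate(sites):
        observed = sorted(
            {a for g in matrix[idx] for a in g if g != MISSING_GENOTYPE}
        ) if len(individuals) else []
        if len(observed) == 1:
            observed.append("N")  # monomorphic in this file; placeholder allele
        if len(observed) != 2:
            continue  # drop sites that are all-missing or multi-allelic
        panel_sites.append(PanelSite(snp_id, chrom, pos, observed[0], observed[1]))
        keep_rows.append(idx)

    genotypes = pd.DataFrame(
        matrix[keep_rows] if len(individuals) else [],
        index=[s.site_id for s in panel_sites],
        columns=individuals,
    )
    genotypes.index.name = "site_id"
    breed_series = pd.Series(breeds)
    if coords is None:
        coords = pd.DataFrame(
            {"lon": np.nan, "lat": np.nan}, index=sorted(set(breeds.values()))
        )
    return SnpPanel(panel_sites, genotypes, breed_series, coords)


# ---------------------------------------------------------------------------
# Newick + SAM export.

def write_newick(tree: PhyloTree, path: Optional[PathLike] = None) -> str:
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def write_sam(
    hits: Iterable[AlignmentHit],
    reads: dict[str, Read],
    genomes: GenomeDB,
    genome: str,
    path: PathLike,
) -> None:
    """Minimal SAM export (mandatory columns + NM tag) of hits on one genome."""
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig in genomes.contigs(genome):
            handle.write(f"@SQ\tSN:{contig.name}\tLN:{len(contig)}\n")
        for hit in hits:
            if hit.genome != genome:
                continue
            read = reads[hit.read_id]
            if hit.strand == "+":
                seq = read.sequence
                qual = "".join(chr(q + 33) for q in read.qualities)
                flag = 0
            else:
                seq = reverse_complement(read.sequence)
                qual = "".join(chr(q + 33) for q in reversed(read.qualities))
                flag = 16
            mapq = hit.mapq if hit.mapq is not None else 255
            handle.write(
                f"{hit.read_id}\t{flag}\t{hit.contig}\t{hit.start + 1}\t{mapq}\t"
                f"{hit.length}M\t*\t0\t0\t{seq}\t{qual}\tNM:i:{hit.mismatches}\n"
            )
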
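"""Mitochondrial consensus, contamination statistic, and haplogroup placement.

Contamination is bounded from the consensus support at haplotype-informative
positions: sites where the sample consensus differs from the reference
(outside the hard-to-align tandem repeat of the control region), at depth
>= 10. Summing read-base observations over those sites, the fraction carrying
the consensus base floors to the support percentage and the remainder ceils
to the maximum contamination percentage — both conservative in the direction
of over-stating contamination.

Phylogenetic placement uses Jukes-Cantor distances (complete deletion of
gapped columns) and Saitou-Nei neighbour joining, with nonparametric
bootstrap over alignment columns for split support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import AlignmentHit, Read
from .tree import PhyloTree, TreeNode
from .util import DataError, ceil_pct, derive_seed, floor_pct, reverse_complement

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class Pileup:
    reference: str
    counts: np.ndarray  # (L, 5) observation counts of A/C/G/T/N

    @property
    def depth(self) -> np.ndarray:
        return self.counts[:, :4].sum(axis=1)


@dataclass
class DiagnosticSiteSet:
    positions: list[int]
    excluded_intervals: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ContaminationEstimate:
    consensus_reads: int
    total_reads: int
    consensus_support_pct: int
    max_contamination_pct: int

    @classmethod
    def from_counts(cls, consensus_reads: int, total_reads: int) -> "ContaminationEstimate":
        if total_reads <= 0:
            raise DataError("total read observations must be positive")
        if consensus_reads > total_reads:
            raise DataError("consensus observations exceed total")
        return cls(
            consensus_reads=consensus_reads,
            total_reads=total_reads,
            consensus_support_pct=floor_pct(consensus_reads, total_reads),
            max_contamination_pct=ceil_pct(total_reads - consensus_reads, total_reads),
        )

    @property
    def point_estimate(self) -> float:
        """Unrounded contaminant fraction (total - consensus) / total."""
        return (self.total_reads - self.consensus_reads) / self.total_reads

    def to_dict(self) -> dict:
        return {
            "consensus_reads": self.consensus_reads,
            "total_reads": self.total_reads,
            "consensus_support_pct": self.consensus_support_pct,
            "max_contamination_pct": self.max_contamination_pct,
        }


def pileup_and_consensus(
    mito_hits: Iterable[AlignmentHit],
    reads: dict[str, Read],
    reference: str,
) -> tuple[Pileup, str, float]:
    """Stack duplicate-removed mito hits into a pileup and call the majority
    consensus (ties and zero depth give N). Returns (pileup, consensus,
    mean depth = aligned bases / reference length)."""
    length = len(reference)
    counts = np.zeros((length, 5), dtype=np.int64)
    aligned_bases = 0
    for h in mito_hits:
        read = reads[h.read_id]
        seq = read.sequence if h.strand == "+" else reverse_complement(read.sequence)
        if h.start < 0 or h.end > length:
            raise DataError(f"hit for read {h.read_id} outside reference")
        for offset, base in enumerate(seq):
            counts[h.start + offset, _BASE_INDEX.get(base, 4)] += 1
        aligned_bases += h.length
    consensus = []
    for pos in range(length):
        acgt = counts[pos, :4]
        depth = int(acgt.sum())
        if depth == 0:
            consensus.append("N")
            continue
        best = int(acgt.max())
        winners = np.nonzero(acgt == best)[0]
        consensus.append("ACGT"[winners[0]] if len(winners) == 1 else "N")
    return Pileup(reference, counts), "".join(consensus), aligned_bases / length


def diagnostic_sites(
    pileup: Pileup,
    consensus: str,
    excluded: Sequence[tuple[int, int]] = (),
    min_depth: int = 10,
) -> DiagnosticSiteSet:
    """Positions where the sample consensus differs from the reference at
    depth >= min_depth, outside the excluded (half-open) intervals."""
    depth = pileup.depth
    positions = []
    for pos, (cons, ref) in enumerate(zip(consensus, pileup.reference)):
        if cons in "N" or ref not in "ACGT":
            continue
        if cons == ref or depth[pos] < min_depth:
            continue
        if any(start <= pos < end for start, end in excluded):
            continue
        positions.append(pos)
    return DiagnosticSiteSet(positions, list(excluded))


def estimate_contamination(
    pileup: Pileup, consensus: str, sites: DiagnosticSiteSet
) -> ContaminationEstimate:
    """Sum read-base observations over the diagnostic sites; the consensus
    share floors to the support percentage, the remainder ceils to the
    maximum contamination percentage."""
    if len(sites) == 0:
        raise DataError(
            "no diagnostic sites: contamination cannot be estimated "
            "(sample consensus identical to the reference outside exclusions)"
        )
    total = 0
    consensus_obs = 0
    for pos in sites.positions:
        acgt = pileup.counts[pos, :4]
        total += int(acgt.sum())
        cons = consensus[pos]
        if cons in _BASE_INDEX and cons != "N":
            consensus_obs += int(pileup.counts[pos, _BASE_INDEX[cons]])
    return ContaminationEstimate.from_counts(consensus_obs, total)


# ---------------------------------------------------------------------------
# Distances and trees


def jc_distance(
    aligned_a: str, aligned_b: str, gap_policy: str = "complete_deletion"
) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) with p the mismatch
    fraction over retained columns. Columns with a gap or ambiguous base in
    either sequence are removed first (complete deletion)."""
    if len(aligned_a) != len(aligned_b):
        raise DataError("aligned sequences must have equal length")
    if gap_policy != "complete_deletion":
        raise DataError(f"unknown gap policy {gap_policy!r}")
    kept = 0
    mism = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        kept += 1
        if x != y:
            mism += 1
    if kept == 0:
        raise DataError("no comparable columns after gap removal")
    p = mism / kept
    if p >= 0.75:
        raise DataError(f"saturated distance (p = {p:.3f} >= 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def jc_distance_matrix(alignment: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    labels = list(alignment)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jc_distance(alignment[labels[i]], alignment[labels[j]])
            D[i, j] = D[j, i] = d
    return D, labels


def neighbour_joining(D: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbour joining with the standard Q-criterion.

    Negative branch lengths are clamped to zero. On an additive matrix the
    tree's leaf-to-leaf path lengths reproduce D exactly.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise DataError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise DataError("distance matrix must be symmetric with zero diagonal")
    if n < 3:
        raise DataError("neighbour joining needs at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in labels]
    active = list(range(n))
    D = D.copy()

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        Q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        i_s, j_s = divmod(int(np.argmin(Q)), m)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = active[i_s], active[j_s]
        dij = D[i, j]
        li = 0.5 * dij + (totals[i_s] - totals[j_s]) / (2.0 * (m - 2))
        lj = dij - li
        left, right = nodes[i], nodes[j]
        left.length = max(li, 0.0)
        right.length = max(lj, 0.0)
        parent = TreeNode(children=[left, right])

        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for k_s, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # terminal three-way (or two-way) join
    if len(active) == 3:
        i, j, k = active
        vi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        vj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        vk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, v in zip((i, j, k), (vi, vj, vk)):
            nodes[idx].length = max(v, 0.0)
        root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    else:
        i, j = active
        nodes[i].length = max(D[i, j], 0.0)
        nodes[j].length = 0.0
        root = TreeNode(children=[nodes[i], nodes[j]])
    return PhyloTree(root)


def nj_from_alignment(alignment: dict[str, str]) -> PhyloTree:
    D, labels = jc_distance_matrix(alignment)
    return neighbour_joining(D, labels)


def bootstrap_support(
    alignment: dict[str, str], replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree from the full alignment with per-split bootstrap counts.

    Columns are resampled with replacement per replicate; each replicate's
    tree is rebuilt (JC + NJ) and every original internal split that recurs
    increments that edge's support. Replicate column draws come from
    counter-derived streams of one seed, so results do not depend on
    evaluation order.
    """
    labels = list(alignment)
    if len(labels) < 4:
        raise DataError("bootstrap support needs >= 4 taxa")
    length = len(next(iter(alignment.values())))
    for seq in alignment.values():
        if len(seq) != length:
            raise DataError("alignment sequences must have equal length")

    tree = nj_from_alignment(alignment)
    if replicates <= 0:
        return tree
    splits = tree.bipartitions()
    support = {key: 0 for key in splits}
    matrix = np.array([list(alignment[lbl]) for lbl in labels])
    for rep in range(replicates):
        rng = np.random.default_rng(derive_seed(seed, f"bootstrap:{rep}"))
        cols = rng.integers(0, length, size=length)
        resampled = {
            lbl: "".join(matrix[i, cols]) for i, lbl in enumerate(labels)
        }
        try:
            rep_tree = nj_from_alignment(resampled)
        except DataError:
            continue  # saturated or empty replicate: counts as non-support
        rep_splits = rep_tree.bipartitions()
        for key in support:
            if key in rep_splits:
                support[key] += 1
    for key, node in splits.items():
        node.support = support[key]
    return tree


@dataclass
class PlacementReport:
    tree: PhyloTree
    nearest: str
    nearest_distance: float
    clade: list[str] = field(default_factory=list)  # leaves sharing the sample's attachment


def place_sample(
    sample_consensus: str,
    reference_alignment: dict[str, str],
    sample_label: str = "sample",
    replicates: int = 0,
    seed: int = 0,
) -> PlacementReport:
    """Place a sample consensus among aligned reference mitogenomes.

    The sample must already be in the reference alignment's coordinates
    (equal length). Returns the joint NJ tree plus the nearest reference
    taxon by JC distance and the leaf set of the subtree the sample joins.
    """
    length = len(next(iter(reference_alignment.values())))
    if len(sample_consensus) != length:
        raise DataError(
            f"sample length {len(sample_consensus)} != alignment length {length}"
        )
    if sample_label in reference_alignment:
        raise DataError(f"label {sample_label!r} already in reference alignment")
    if all(c not in "ACGT" for c in sample_consensus.upper()):
        raise DataError("sample consensus has no called bases")

    joint = dict(reference_alignment)
    joint[sample_label] = sample_consensus
    if replicates > 0 and len(joint) >= 4:
        tree = bootstrap_support(joint, replicates=replicates, seed=seed)
    else:
        tree = nj_from_alignment(joint)

    distances = {
        lbl: jc_distance(sample_consensus, seq)
        for lbl, seq in reference_alignment.items()
    }
    nearest = min(distances, key=lambda k: (distances[k], k))

    leaf = tree.find_leaf(sample_label)
    clade: list[str] = []
    for node in tree.root.walk():
        if leaf in node.children:
            clade = [name for name in node.leaf_names() if name != sample_label]
            break
    return PlacementReport(tree, nearest, distances[nearest], clade)
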
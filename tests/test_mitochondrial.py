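import dendropy
import numpy as np
import pytest

from oracles import nj_three_taxon_branches
from vellum import mitochondrial as mito
from vellum.sequence_io import AlignmentHit, Read
from vellum.util import DataError


def mito_hit(read_id, start, strand="+", length=10):
    return AlignmentHit(read_id, "ref", "chrM", start, strand, 0, length, 37)


class TestPileupConsensus:
    def test_majority_tie_and_zero_depth_rules(self):
        ref = "AAAATTTT"
        reads = {
            # 9 A's vs 1 T at position 0; 5/5 tie at position 1
            **{f"a{i}": Read(f"a{i}", "AA", (35, 35)) for i in range(4)},
            **{f"t{i}": Read(f"t{i}", "TT", (35, 35)) for i in range(5)},
            "mixed": Read("mixed", "AA", (35, 35)),
        }
        hits = (
            [mito_hit(f"a{i}", 0, length=2) for i in range(4)]
            + [mito_hit("mixed", 0, length=2)]
            + [mito_hit(f"t{i}", 1, length=2) for i in range(5)]
        )
        # position 0: 5 A; position 1: 5 A + 5 T; position 2: 5 T
        pileup, consensus, depth = mito.pileup_and_consensus(hits, reads, ref)
        assert consensus[0] == "A"
        assert consensus[1] == "N"   # exact tie
        assert consensus[2] == "T"
        assert consensus[3] == "N"   # zero depth
        assert depth == pytest.approx(20 / 8)

    def test_minus_strand_bases_reverse_complemented(self):
        ref = "ACGT"
        reads = {"r": Read("r", "ACGT", (35,) * 4)}
        hits = [AlignmentHit("r", "ref", "chrM", 0, "-", 0, 4, 37)]
        pileup, consensus, _ = mito.pileup_and_consensus(hits, reads, ref)
        assert consensus == "ACGT"  # revcomp of ACGT placed back equals ACGT


class TestDiagnosticSites:
    def _pileup(self, ref, consensus, depth=20):
        counts = np.zeros((len(ref), 5), dtype=np.int64)
        for i, base in enumerate(consensus):
            if base in "ACGT":
                counts[i, "ACGT".index(base)] = depth
        return mito.Pileup(ref, counts)

    def test_no_differences_gives_empty_set(self):
        ref = "ACGTACGT"
        sites = mito.diagnostic_sites(self._pileup(ref, ref), ref)
        assert sites.positions == []

    def test_difference_inside_excluded_interval_ignored(self):
        ref = "ACGTACGT"
        cons = "ACGAACGT"  # differs at position 3
        pileup = self._pileup(ref, cons)
        assert mito.diagnostic_sites(pileup, cons).positions == [3]
        assert mito.diagnostic_sites(pileup, cons, excluded=[(2, 5)]).positions == []

    def test_low_depth_sites_ignored(self):
        ref = "ACGTACGT"
        cons = "ACGAACGT"
        pileup = self._pileup(ref, cons, depth=5)
        assert mito.diagnostic_sites(pileup, cons, min_depth=10).positions == []


class TestContaminationEstimate:
    @pytest.mark.parametrize(
        "consensus, total, support, contamination",
        [
            (282, 291, 96, 4),
            (381, 398, 95, 5),
            (100, 100, 100, 0),
        ],
    )
    def test_floor_ceil_convention(self, consensus, total, support, contamination):
        est = mito.ContaminationEstimate.from_counts(consensus, total)
        assert est.consensus_support_pct == support
        assert est.max_contamination_pct == contamination

    def test_support_plus_contamination_overlap_at_most_one(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            total = int(rng.integers(1, 1000))
            consensus = int(rng.integers(0, total + 1))
            est = mito.ContaminationEstimate.from_counts(consensus, total)
            assert est.consensus_support_pct + est.max_contamination_pct in (100, 101)
            assert (est.max_contamination_pct == 0) == (consensus == total)

    def test_empty_site_set_refused(self):
        pileup = mito.Pileup("ACGT", np.zeros((4, 5), dtype=np.int64))
        with pytest.raises(DataError, match="no diagnostic sites"):
            mito.estimate_contamination(
                pileup, "ACGT", mito.DiagnosticSiteSet([], [])
            )


class TestJukesCantor:
    def test_identical_sequences_have_zero_distance(self):
        assert mito.jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_known_value_at_ten_percent(self):
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "G" * 10
        assert mito.jc_distance(a, b) == pytest.approx(0.107326, abs=1e-6)

    def test_gapped_columns_excluded(self):
        assert mito.jc_distance("AC-T", "ACGT") == 0.0
        assert mito.jc_distance("ACT-", "ACTG") == 0.0

    def test_saturation_rejected(self):
        with pytest.raises(DataError, match="saturated"):
            mito.jc_distance("AAAA", "CCCC")

    def test_monotone_in_mismatch_fraction(self):
        base = "A" * 100
        prev = -1.0
        for k in (0, 5, 10, 20, 40):
            other = "C" * k + "A" * (100 - k)
            d = mito.jc_distance(base, other)
            assert d > prev
            prev = d


class TestNeighbourJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = mito.neighbour_joining(D, ["a", "b", "c"])
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        va, vb, vc = nj_three_taxon_branches(2, 3, 4)
        assert lengths == pytest.approx({"a": va, "b": vb, "c": vc})
        assert (va, vb, vc) == (0.5, 1.5, 2.5)

    def test_four_taxon_additive_topology_recovered(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = mito.neighbour_joining(D, ["a", "b", "c", "d"])
        split_sides = {side for split in tree.bipartitions() for side in split}
        assert frozenset({"a", "b"}) in split_sides
        paths = tree.path_lengths()
        for (x, y), expected in {
            ("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6,
            ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7,
        }.items():
            assert paths[(x, y)] == pytest.approx(expected, abs=1e-12)

    def test_additive_six_taxon_paths_reproduced(self, rng):
        # random additive matrix from a random binary tree with known paths
        labels = [f"t{i}" for i in range(6)]
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=6,
            rng=__import__("random").Random(5),
        )
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = labels[i]
        pdm = tree.phylogenetic_distance_matrix()
        D = np.zeros((6, 6))
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(6):
            for j in range(6):
                if i != j:
                    D[i, j] = pdm.patristic_distance(
                        taxa[labels[i]], taxa[labels[j]]
                    )
        out = mito.neighbour_joining(D, labels)
        paths = out.path_lengths()
        for i in range(6):
            for j in range(i + 1, 6):
                key = tuple(sorted((labels[i], labels[j])))
                assert paths[key] == pytest.approx(D[i, j], abs=1e-10)

    def test_ultrametric_three_taxa_equal_branches(self):
        D = np.full((3, 3), 2.0)
        np.fill_diagonal(D, 0.0)
        tree = mito.neighbour_joining(D, ["a", "b", "c"])
        lengths = [leaf.length for leaf in tree.root.leaves()]
        assert lengths == pytest.approx([1.0, 1.0, 1.0])

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [9, 0, 3], [2, 3, 0]], dtype=float)
        with pytest.raises(DataError):
            mito.neighbour_joining(D, ["a", "b", "c"])

    def test_agrees_with_dendropy_nj_topology(self, rng):
        """Independent cross-check: our NJ and dendropy's produce the same
        unrooted splits on a noisy distance matrix."""
        n = 7
        labels = [f"s{i}" for i in range(n)]
        base = rng.random((n, 2)) * 10
        D = np.sqrt(((base[:, None, :] - base[None, :, :]) ** 2).sum(-1))
        ours = mito.neighbour_joining(D, labels)

        csv_rows = ["," + ",".join(labels)]
        for i in range(n):
            csv_rows.append(labels[i] + "," + ",".join(str(D[i, j]) for j in range(n)))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO("\n".join(csv_rows)), delimiter=","
        )
        theirs = pdm.nj_tree()
        theirs.encode_bipartitions()
        all_taxa = frozenset(labels)
        their_sides = set()
        for b in theirs.bipartition_encoding:
            side = frozenset(
                str(t.label) for t in b.leafset_taxa(theirs.taxon_namespace)
            )
            if 2 <= len(side) <= n - 2:
                their_sides.add(frozenset({side, all_taxa - side}))
        our_sides = set(ours.bipartitions().keys())
        assert our_sides == their_sides


class TestBootstrap:
    def _two_clade_alignment(self, rng, n_fixed=20, length=400):
        anc = rng.choice(list("ACGT"), size=length)
        positions = rng.choice(length, size=n_fixed, replace=False)
        group2 = anc.copy()
        for p in positions:
            group2[p] = "ACGT"[("ACGT".index(group2[p]) + 1) % 4]
        aln = {}
        for i, base in enumerate([anc, anc, group2, group2]):
            seq = base.copy()
            # light private noise so taxa are distinct
            for p in rng.choice(length, size=3, replace=False):
                seq[p] = "ACGT"[("ACGT".index(seq[p]) + 1) % 4]
            aln[f"x{i}"] = "".join(seq)
        return aln

    def test_strong_split_gets_high_support(self, rng):
        aln = self._two_clade_alignment(rng)
        tree = mito.bootstrap_support(aln, replicates=100, seed=7)
        splits = tree.bipartitions()
        target = frozenset(
            {frozenset({"x0", "x1"}), frozenset({"x2", "x3"})}
        )
        assert target in splits
        assert splits[target].support >= 95

    def test_zero_replicates_leaves_supports_absent(self, rng):
        aln = self._two_clade_alignment(rng)
        tree = mito.bootstrap_support(aln, replicates=0, seed=7)
        assert all(
            node.support is None for node in tree.root.walk()
        )

    def test_taxon_order_invariance(self, rng):
        aln = self._two_clade_alignment(rng)
        t1 = mito.bootstrap_support(aln, replicates=50, seed=9)
        reordered = {k: aln[k] for k in reversed(list(aln))}
        t2 = mito.bootstrap_support(reordered, replicates=50, seed=9)
        s1 = {k: v.support for k, v in t1.bipartitions().items()}
        s2 = {k: v.support for k, v in t2.bipartitions().items()}
        assert s1 == s2


class TestPlacement:
    def _alignment(self, rng):
        length = 300
        anc = rng.choice(list("ACGT"), size=length)
        cladeA = anc.copy()
        for p in rng.choice(length, size=30, replace=False):
            cladeA[p] = "ACGT"[("ACGT".index(cladeA[p]) + 1) % 4]
        aln = {}
        for name, base in (("B1", anc), ("B2", anc), ("A1", cladeA), ("A2", cladeA)):
            seq = base.copy()
            for p in rng.choice(length, size=4, replace=False):
                seq[p] = "ACGT"[("ACGT".index(seq[p]) + 1) % 4]
            aln[name] = "".join(seq)
        return aln, "".join(anc)

    def test_identical_sample_attaches_at_zero_distance(self, rng):
        aln, anc = self._alignment(rng)
        report = mito.place_sample(aln["B1"], aln)
        assert report.nearest == "B1"
        assert report.nearest_distance == 0.0

    def test_sample_placed_in_its_clade(self, rng):
        aln, anc = self._alignment(rng)
        report = mito.place_sample(anc, aln)
        assert report.nearest in {"B1", "B2"}

    def test_all_gap_sample_rejected(self, rng):
        aln, _ = self._alignment(rng)
        with pytest.raises(DataError):
            mito.place_sample("-" * 300, aln)

    def test_length_mismatch_rejected(self, rng):
        aln, anc = self._alignment(rng)
        with pytest.raises(DataError):
            mito.place_sample(anc[:-10], aln)
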
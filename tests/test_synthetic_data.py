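import math

import numpy as np
import pytest

from vellum import synthetic_data as sim
from vellum.mitochondrial import DiagnosticSiteSet
from vellum.util import ConfigError, reverse_complement


def small_genome_cfg(**kw):
    defaults = dict(
        seed=11,
        n_species=2,
        contig_spec=(("chr1", 10_000, "autosome"),),
        divergence=(0.0, 0.0),
        shared_repeat=None,
    )
    defaults.update(kw)
    return sim.SimGenomeConfig(**defaults)


class TestSimulateGenomes:
    def test_deterministic_under_fixed_seed(self):
        cfg = sim.SimGenomeConfig(seed=5)
        db1, _ = sim.simulate_genomes(cfg)
        db2, _ = sim.simulate_genomes(sim.SimGenomeConfig(seed=5))
        for name in db1.names:
            for c1, c2 in zip(db1.contigs(name), db2.contigs(name)):
                assert c1.sequence == c2.sequence

    def test_zero_divergence_gives_identical_genomes(self):
        db, _ = sim.simulate_genomes(small_genome_cfg())
        a = db.contig("sheep_like", "chr1").sequence
        b = db.contig("cow_like", "chr1").sequence
        assert a == b

    def test_divergence_matches_substitution_model(self):
        """Pairwise mismatch fraction vs the binomial expectation: each genome
        substitutes sites independently at rate d (to a uniform other base),
        so two genomes differ at a site with probability
        2d(1-d) + (2/3)d^2."""
        d = 0.2
        db, _ = sim.simulate_genomes(small_genome_cfg(divergence=(d, d)))
        a = db.contig("sheep_like", "chr1").sequence
        b = db.contig("cow_like", "chr1").sequence
        n = len(a)
        observed = sum(1 for x, y in zip(a, b) if x != y) / n
        expected = 2 * d * (1 - d) + (2 / 3) * d * d
        sd = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * sd

    def test_shared_repeat_verbatim_in_every_genome(self):
        cfg = sim.SimGenomeConfig(seed=3, shared_repeat=(100, 5))
        db, truth = sim.simulate_genomes(cfg)
        # extract the repeat from the first genome's recorded position
        species0 = cfg.species_names[0]
        contig_name, start = truth.repeat_positions[species0][0]
        motif = db.contig(species0, contig_name).sequence[start : start + 100]
        for name in db.names:
            assert db.contig(name, contig_name).sequence.count(motif) >= 5

    def test_mito_tandem_motif_planted(self):
        db, truth = sim.simulate_genomes(sim.SimGenomeConfig(seed=3))
        contig_name, start, end = truth.mito_repeat["sheep_like"]
        seq = db.contig("sheep_like", contig_name).sequence[start:end]
        half = (end - start) // 2
        assert seq[:half] == seq[half:]

    def test_divergence_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            small_genome_cfg(divergence=(0.6, 0.0))


@pytest.fixture(scope="module")
def clean_db():
    db, _ = sim.simulate_genomes(
        sim.SimGenomeConfig(
            seed=21,
            n_species=2,
            contig_spec=(("chr1", 20_000, "autosome"),),
            divergence=(0.0, 0.15),
            shared_repeat=None,
        )
    )
    return db


class TestSimulateReads:
    def test_noise_free_reads_are_exact_substrings(self, clean_db):
        cfg = sim.SimReadConfig(seed=1, n_reads=300, delta5=0.0, seq_error=0.0)
        reads, truth = sim.simulate_reads(clean_db, cfg)
        genome = clean_db.contig("sheep_like", "chr1").sequence
        for read in reads:
            _, _, pos, strand, flen = truth.origins[read.id]
            core = read.sequence[: min(flen, cfg.read_length)]
            assert core in genome or reverse_complement(core) in genome

    def test_mix_proportions_binomial(self, clean_db):
        cfg = sim.SimReadConfig(
            seed=2, n_reads=10_000, mix={"target": 0.95, "cow_like": 0.05}
        )
        _, truth = sim.simulate_reads(clean_db, cfg)
        counts = truth.source_counts()
        assert counts["target"] + counts["cow_like"] == 10_000
        sd = math.sqrt(10_000 * 0.05 * 0.95)
        assert abs(counts["cow_like"] - 500) <= 3 * sd

    def test_short_fragments_carry_adapter(self, clean_db):
        cfg = sim.SimReadConfig(
            seed=3, n_reads=500, fragment_mean=30, fragment_sd=5
        )
        reads, truth = sim.simulate_reads(clean_db, cfg)
        short = [
            r for r in reads if truth.origins[r.id][4] < cfg.read_length
        ]
        assert short, "expected read-through fragments"
        for read in short:
            flen = truth.origins[read.id][4]
            tail = read.sequence[flen:]
            assert cfg.adapter.startswith(tail[: len(cfg.adapter)])

    def test_saturated_damage_converts_terminal_c(self, clean_db):
        cfg = sim.SimReadConfig(seed=4, n_reads=500, delta5=1.0, lam=0.0)
        reads, truth = sim.simulate_reads(clean_db, cfg)
        genome = clean_db.contig("sheep_like", "chr1").sequence
        checked = 0
        for read in reads:
            _, _, pos, strand, flen = truth.origins[read.id]
            frag = genome[pos : pos + flen]
            if strand == "-":
                frag = reverse_complement(frag)
            if frag[0] == "C":
                assert read.sequence[0] == "T"
                checked += 1
        assert checked > 20

    def test_damage_profile_geometric_decay(self, clean_db):
        """Empirical 5' C->T rate at position k ~= delta5 (1-lambda)^k."""
        delta5, lam = 0.3, 0.3
        cfg = sim.SimReadConfig(
            seed=5, n_reads=100_000, delta5=delta5, lam=lam, seq_error=0.0
        )
        reads, truth = sim.simulate_reads(clean_db, cfg)
        genome = clean_db.contig("sheep_like", "chr1").sequence
        c_total = np.zeros(5)
        c_to_t = np.zeros(5)
        for read in reads:
            _, _, pos, strand, flen = truth.origins[read.id]
            frag = genome[pos : pos + flen]
            if strand == "-":
                frag = reverse_complement(frag)
            for k in range(5):
                if frag[k] == "C":
                    c_total[k] += 1
                    # 3' G->A damage never touches a C, so any T here is 5' damage
                    if read.sequence[k] == "T":
                        c_to_t[k] += 1
        for k in range(5):
            expected = delta5 * (1 - lam) ** k
            rate = c_to_t[k] / c_total[k]
            sd = math.sqrt(expected * (1 - expected) / c_total[k])
            assert abs(rate - expected) <= 4 * sd

    def test_source_label_conservation_and_determinism(self, clean_db):
        cfg = sim.SimReadConfig(
            seed=6, n_reads=2_000,
            mix={"target": 0.8, "second_individual": 0.1, "cow_like": 0.1},
            delta5=0.2, seq_error=0.01,
        )
        reads1, truth1 = sim.simulate_reads(clean_db, cfg)
        reads2, _ = sim.simulate_reads(clean_db, cfg)
        assert reads1 == reads2
        assert sum(truth1.source_counts().values()) == 2_000

    def test_unknown_mix_source_rejected(self, clean_db):
        cfg = sim.SimReadConfig(seed=7, n_reads=10, mix={"yeti": 1.0})
        with pytest.raises(Exception, match="unknown source"):
            sim.simulate_reads(clean_db, cfg)


class TestSimulatePanel:
    def test_vanishing_fst_gives_near_identical_breed_frequencies(self):
        def mean_abs_freq_diff(fst):
            cfg = sim.SimPanelConfig(
                seed=31, n_breeds=2, n_sites=5_000, fst=fst, n_per_breed=100
            )
            panel, _ = sim.simulate_panel(cfg)
            freqs = []
            for breed in ("breed0", "breed1"):
                inds = [i for i in panel.individuals if i.startswith(breed)]
                sub = panel.genotypes[inds]
                f = np.array(
                    [
                        np.mean([g.count(s.allele_b) for g in sub.loc[s.site_id]]) / 2
                        for s in panel.sites
                    ]
                )
                freqs.append(f)
            return float(np.mean(np.abs(freqs[0] - freqs[1])))

        low = mean_abs_freq_diff(0.001)
        high = mean_abs_freq_diff(0.3)
        assert low < 0.06
        assert low < high / 3

    def test_fixed_ancestral_frequency_gives_monomorphic_panel(self):
        cfg = sim.SimPanelConfig(
            seed=32, n_breeds=1, n_sites=1, fst=0.2, n_per_breed=10,
            ancestral_freq=1.0,
        )
        panel, target = sim.simulate_panel(cfg)
        site = panel.sites[0]
        homo = site.allele_b + site.allele_b
        assert all(panel.genotypes.iloc[0] == homo)
        assert target.iloc[0] == homo

    def test_deterministic(self):
        cfg = sim.SimPanelConfig(seed=33, n_breeds=3, n_sites=50, n_per_breed=4)
        p1, t1 = sim.simulate_panel(cfg)
        p2, t2 = sim.simulate_panel(cfg)
        assert p1.genotypes.equals(p2.genotypes)
        assert t1.equals(t2)


class TestSimulateMitoReads:
    def _haplotypes(self, rng, n_diff=20, length=2_000):
        ref = "".join(rng.choice(list("ACGT"), size=length))
        pos = sorted(rng.choice(length, size=n_diff, replace=False))
        alt = list(ref)
        for p in pos:
            alt[p] = "ACGT"[("ACGT".index(alt[p]) + 1) % 4]
        return ref, "".join(alt), pos

    def test_zero_rho_reads_all_from_target(self, rng):
        ref, alt, pos = self._haplotypes(rng)
        cfg = sim.SimReadConfig(seed=41, n_reads=400)
        reads, truth = sim.simulate_mito_reads(
            {"t": alt, "c": ref}, "t", "c", 0.0, cfg
        )
        assert set(truth.read_sources.values()) == {"target"}
        assert truth.diagnostic_sites == pos

    def test_contaminant_fraction_binomial(self, rng):
        ref, alt, _ = self._haplotypes(rng)
        cfg = sim.SimReadConfig(seed=42, n_reads=5_000)
        _, truth = sim.simulate_mito_reads(
            {"t": alt, "c": ref}, "t", "c", 0.05, cfg
        )
        n_cont = truth.source_counts().get("contaminant", 0)
        sd = math.sqrt(5_000 * 0.05 * 0.95)
        assert abs(n_cont - 250) <= 3 * sd

    def test_identical_haplotypes_give_empty_diagnostic_set(self, rng):
        ref, _, _ = self._haplotypes(rng)
        cfg = sim.SimReadConfig(seed=43, n_reads=50)
        _, truth = sim.simulate_mito_reads(
            {"t": ref, "c": ref}, "t", "c", 0.1, cfg
        )
        assert truth.diagnostic_sites == []
        assert len(DiagnosticSiteSet(truth.diagnostic_sites, [])) == 0

    def test_rho_out_of_range_rejected(self, rng):
        ref, alt, _ = self._haplotypes(rng)
        with pytest.raises(ConfigError):
            sim.simulate_mito_reads(
                {"t": alt, "c": ref}, "t", "c", 1.5,
                sim.SimReadConfig(seed=44, n_reads=10),
            )
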
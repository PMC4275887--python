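# Methods

`vellum` re-implements, at desk scale, the analysis chain used to
characterise ancient DNA recovered from parchment: identify the source
species of a skin, quantify how much of the sequencing library is endogenous,
bound the within-species contamination rate from the mitochondrial genome,
place the sample's mitochondrial haplotype among modern references, and
locate the individual among modern breeds by SNP allele sharing. A collagen
peptide-mass-fingerprint (ZooMS) module provides the independent proteomic
species call. Because the package is exercised entirely on synthetic data, a
first-class generator produces every input with a full truth record.

## Synthetic data generator

**Genomes.** `n_species` genomes are produced as independently substituted
copies of one ancestral sequence, so all genomes share contig structure and
coordinates. Per-species divergence `d_i` substitutes each site with
probability `d_i` to a uniformly chosen other base; the expected pairwise
difference between species *i* and *j* is `2·d(1-d)` terms plus a `(2/3)·d²`
coincident-hit term (the binomial oracle used in tests). Shared repeats
(default 100 bp × 5 copies) are written verbatim at identical coordinates in
every genome to create genuine multi-genome multi-mapping; each
mitochondrial contig additionally carries a 75 bp tandem motif × 2 near its
end, emulating the hard-to-align control-region repeat that contamination
estimation must exclude. Default contigs: one 40 kb autosome, an 8 kb X and
a 16.5 kb mitochondrial contig — large enough for coverage, uniqueness and
sex-ratio behaviour to be non-trivial, small enough that exhaustive
brute-force alignment remains a usable test oracle.

**Reads.** Single-end 49 bp reads are drawn from a source mixture (target
individual, a second same-species individual derived by sparse substitution
at rate 10⁻³ — roughly within-population nucleotide diversity — and any
other genome). Fragment lengths are lognormal (mean 55, sd 20) truncated to
[18, 150] bp, typical of ancient-DNA libraries; fragments shorter than the
read length run into the 3′ adapter exactly as real read-through does.
Damage follows the double-stranded deamination model: C→T at the 5′ end and
the mirrored G→A at the 3′ end, with probability `delta5·(1−lambda)^k` at
distance *k* from the end — geometric decay inward. Damage, fragment
sampling and sequencing error consume independent derived random streams and
damage draws are consumed for every position regardless of the rate, so
changing `delta5` alone never perturbs which fragments are sampled (this is
what makes the damage-robustness test an exact paired comparison). Base
qualities are a constant Q35; downstream only thresholds at Q15/Q30 are
applied, so modelling quality variation would add nothing the pipeline can
see.

**SNP panel.** Breed structure follows the Balding–Nichols model: per site
an ancestral frequency `p ~ U(0.05, 0.95)`, per breed a frequency drawn from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with a single differentiation parameter `F`
(default 0.15, an upper-range livestock-breed value that makes breed
assignment feasible from a few hundred loci); genotypes are Hardy–Weinberg
within breed. Allele pairs are drawn with transitions twice as likely as
each transversion pair, so the transition/strand-ambiguity filters remove a
realistic majority (~75%) of sites. Each breed has fixed coordinates on a
Europe-sized grid. The simulated parchment individual is drawn from a named
target breed; low-coverage genotyping is emulated by sampling one allele per
site, doubling it, and masking a configurable fraction as missing.

**What the generator does not model** (and what passing tests therefore do
not show): indels and structural variation, recombination, realistic
chromosome counts and repeat landscapes, reference-bias between genome
builds of unequal quality, library-prep chemistry beyond a simple duplicate
fraction, heteroplasmy, and diploidy of the nuclear target (reads come from
one haploid sequence per individual, so heterozygous-site sampling noise in
pseudo-haploid calls is absent).

## Alignment and screening

The aligner is an exhaustive seeded, ungapped, end-to-end search. A read is
split into non-overlapping seeds of length `seed_len`; exact seed hits from
a k-mer index propose placements which are scored by full-length mismatch
count on both strands, with N matching nothing. By pigeonhole, a placement
with ≤ m mismatches must contain an exact seed whenever the read holds
≥ m+1 seeds, so `seed_len = 7` is complete for ≥ 30 bp (post-filter) reads
at m ≤ 3; reads too short for that guarantee fall back to a full
sliding-window scan, making completeness unconditional (verified against a
brute-force oracle). `seed_len = 12` is allowed for speed, with the
documented completeness loss. Ungapped only: the reads are ~49 bp and the
screening question is homology attribution, not variant discovery.

Screening classifies each read, per mismatch tolerance 0–3, by (number of
genomes with ≥ 1 hit, maximum hit count within any such genome) into
unique-to-one-genome / multi-one-genome / unique-multi-genome /
multi-multi-genome / no-hit; multi-genome reads are tallied once per genome
involved, so per-genome fractions are attribution shares, not a partition.
All reads are screened (no subsampling). The species call is the genome
maximising the unique-to-one-genome fraction at zero mismatches, refusing
when the runner-up is within 2 percentage points.

The mapping-quality surrogate is a deliberate three-tier simplification of
aligner practice: a unique best placement with no alternative within 2
mismatches scores 37, a unique best with a close alternative 25, tied bests
0. The standard "mapping quality ≥ 30" filter therefore keeps exactly the
uniquely-and-confidently placed tier.

## Endogenous filtering

Order is fixed and explicit: mapq ≥ 30 → duplicate removal → contaminant
subtraction → uniqueness; permutations are available because
dedup-before/after-mapq measurably changes counts. Duplicates share
(contig, strand, 5′ start); the survivor is the read with the highest base
quality sum, ties broken by read id, so removal is total and deterministic.
Contaminant subtraction drops any read with a ≤ 3-mismatch alignment to the
contaminant (human-like) genome regardless of its target mapping quality.
Uniqueness keeps reads whose best placement is their only placement at the
best mismatch count with no alternative within 2 mismatches. The
mitochondrial contig is excluded from the nuclear chain. Summary
percentages round half-up to one decimal through a single formatter; genome
retrieval is the fraction of nuclear bases covered ≥ 1×. Sex is called from
the X:autosome mean-depth ratio with thresholds 0.8 (XX) and 0.6 (XY) — the
expected ratios are ≈ 1 and ≈ 0.5, and the band between is an explicit
refusal zone; the thresholds are a design choice, not estimated.

## Mitochondrial contamination and placement

The consensus is the per-position majority base (ties and zero depth give
N). Haplotype-informative positions are operationalised as sites where the
consensus differs from the reference at depth ≥ 10, outside the excluded
control-region repeat interval. The statistic sums read-base observations
over those sites (one read overlapping two sites contributes two
observations — documented because the alternative, counting reads once, is
equally defensible); the consensus share is **floored** to the support
percentage and the complement **ceiled** to the maximum contamination
percentage — the only rounding pair that is conservative in the direction
the quantity is named for, and the two may overlap by one point. With no
diagnostic sites the estimator refuses rather than reporting 0%.

Distances are Jukes–Cantor, `d = −(3/4)·ln(1 − 4p/3)`, with complete
deletion of columns containing a gap or ambiguous base and a hard error at
saturation (p ≥ 0.75). Neighbour joining is the standard Saitou–Nei
Q-criterion agglomeration; negative branch lengths are clamped to zero, and
on additive matrices the tree reproduces the input path lengths exactly
(tested to 1e-9, closed form to 1e-12 for three taxa). Bootstrap resamples
alignment columns with replacement; each replicate's column draw comes from
a counter-derived stream of one seed, so support values are independent of
taxon order and evaluation order. Placement joins the sample consensus to a
user-supplied reference alignment (multiple alignment itself is out of
scope), reports the nearest reference by distance and the leaf set of the
subtree the sample attaches to.

A known statistical limit, measured and documented rather than hidden: with
20 diagnostic sites at 25× the estimator sees ~500 observations, so the
sampling error of the contaminant fraction is ~1.3 percentage points at
ρ = 0.10; recovery within ±2 points therefore succeeds in only ~85–87% of
runs at that operating point (and ≥ 95% for ρ ≤ 0.05). Reliable ±2-point
recovery at ρ = 0.10 needs roughly 900 observations (~45× with 20 sites).

## Affinity

Pseudo-haploid calling samples one read base per panel site among those with
mapping quality ≥ 30 and base quality ≥ 15, using a random stream keyed by
(seed, site id) so calls do not depend on processing order; the base is
doubled to a homozygous pseudo-diploid genotype, an off-panel base becomes
missing. Transition SNPs (C/T, G/A) are excluded at the panel level before
calling, because deamination damage is indistinguishable from those alleles.
Merging removes strand-ambiguous A/T and C/G sites and reconciles strand
orientation at the site level: a call whose site allele pair equals the
panel's is kept, one whose pair is the reverse complement is complemented,
anything else is removed as irreconcilable; only A/C and G/T pairs can
survive, which is asserted.

Allele sharing is mean identity-by-state, `s = Σ IBS / 2L` over the loci
both genotypes cover (pairwise deletion — parchment calls are sparse), with
distance `1 − s`. Breed affinity averages individuals within breed
(individuals, not loci, are the exchangeable unit here; the alternative
weighting is noted as an open choice). The geographic surface is
inverse-distance-weighted interpolation (power 2) over the breed
coordinates' bounding box — exact at breed coordinates and bounded by the
input range — emitted as gridded data, not a rendered map.

## ZooMS

Tryptic digestion cleaves after K/R except before P (up to two missed
cleavages); peptide masses are monoisotopic [M+H]⁺ from an in-package
residue table, with hydroxyproline as +15.994915 Da per modified proline —
the characteristic collagen modification. A marker is matched when any peak
lies within ± tolerance (0.2 Da default, typical external-calibration
MALDI-TOF accuracy; ppm also supported) of any of its masses, and a species'
score is its matched fraction of diagnostic markers; the call is the argmax
with a 0.2 refusal margin. The bundled marker table is synthetic
(collagen-like peptides invented for demonstration); real analyses must
supply their own curated marker TSV, and discrimination quality is entirely
a property of that table.

## Problem sizes and numerical conventions

Simulated studies in the test suite use 2–50 k reads on 10–65 kb genomes,
100-replicate recovery experiments on 2 kb mitochondrial haplotypes at ~25×,
and 8-breed × 8 k-site panels — sizes chosen so every stochastic claim is
backed by an explicit binomial or Monte-Carlo error budget while the whole
suite stays interactive. Coordinates are 0-based half-open internally and
1-based only in SAM export. All randomness flows from named streams derived
from one master seed (`derive_seed(seed, name)`, SHA-256 based, < 2³¹), so
every pipeline output is byte-reproducible from its manifest.
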
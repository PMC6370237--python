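# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## 1. The scientific setting

A recessive syndrome (piglet leg weakness) segregates in a closed nucleus
herd. Homozygotes (TT) are essentially never seen at the end of performance
test; carriers (GT) out-perform wild type (GG) on the muscle/fat selection
index. The analysis chain asks, in order: is the inheritance monogenic
recessive (segregation analysis, variance components)? where is the locus
(homozygosity mapping)? what is the mutation (variant filtering +
consequence annotation)? is the demographic signature consistent with
selective loss of homozygotes (per-stage Hardy–Weinberg analysis)? and how
large is the carrier advantage (mixed-model association)?

## 2. Population simulator (`popsim`)

The generator produces the data *structure* this chain assumes, not a
calibrated copy of any real herd.

**Pedigree and selection.** `n_founders` unrelated animals found the herd;
each subsequent generation selects `n_sires` males and `n_dams` females
among survivors to the 110 kg stage by truncation on a phenotypic index
I = w_m·muscle − w_f·fat + ε. The noise term ε ~ N(0, `index_noise_sd`²)
(default SD 25, against genotype index differences of ≈6.6) is a stand-in
for ranking on an EBV of limited accuracy inside a broader economic index:
with raw-phenotype truncation the carrier advantage is so strong that the
lethal sweeps toward q ≈ 0.5 within nine generations, whereas the emulated
situation is a *slight* carrier advantage holding the allele near its
moderate equilibrium (q ≈ 0.2). The realised trajectory still drifts —
with tens of parents per generation the allele can be lost or exceed 0.3
in individual runs, which we regard as realistic for a nucleus herd.

**Genetics.** Markers are laid out uniformly at random over the configured
chromosomes; gametes recombine under a Haldane (Poisson) process at
1 cM/Mbp with no interference. Every copy of the lethal allele T descends
from one ancestral haplotype: carrier founder haplotypes copy a fixed
marker segment across the window ±`ibd_window_bp` (default 4 Mbp) around
the causal position, and the segment travels intact with T through meiosis
(complete LD within the window). Consequently every TT individual is
homozygous and identical across the whole window — the exact
identity-by-descent signal homozygosity mapping exploits. Outside the
window, recombination erodes sharing normally. This is deliberately
idealised: real IBD segments erode at the edges, so real top segments are
ragged where ours are sharp.

**Survival.** Per-genotype survival to 40 kg and 110 kg; defaults
GG/GT 0.80 and 0.75 (mirroring survey-cohort attrition 486→374→265) and
TT 0.02 and 0.0 — nearly all affected piglets die or are euthanized before
40 kg and none complete the test.

**Phenotypes.** Quantitative traits are genotype mean + polygenic breeding
value + litter + maternal + residual effects. Breeding values follow the
standard midparent + Mendelian-sampling rule with variance
σ²ₐ/2·(1−(F_s+F_d)/2); the inbreeding correction matters because the
pedigree closes. Default genotype means and phenotypic SDs are at the
scale of a commercial pig performance test (muscle depth GG 48.4 / GT 53.2
mm, σ_P ≈ 5.95; fat depth 10.2 / 8.4 mm, σ_P ≈ 2.72; live weight 87.1 /
84.9 kg). TT means are additively extrapolated (2·GT − GG) since TT
animals are rarely measured. The binary leg-weakness trait is
penetrance·1{TT} plus an optional background liability with litter /
maternal / polygenic / residual components (default background prevalence
0, i.e. the trait is exactly the TT indicator).

**Deterministic recursion.** One-locus viability selection with fitnesses
wGG = 1−s₁, wGT = 1, wTT = 1−s₂. This parametrisation makes the interior
equilibrium exactly q* = s₁/(s₁+s₂) and reduces, at s₁ = 0, s₂ = 1, to the
classical lethal decline q' = q/(1+q). It is the validation oracle for the
simulator's allele-frequency dynamics.

**Reproducibility.** All randomness derives from `SimConfig.seed` through
named sub-streams (map, founders, mating, meiosis, survival, phenotypes),
so stages can be reproduced independently.

**What the simulator does not emulate.** Linkage disequilibrium between
ordinary markers (founder haplotypes are independent Bernoulli draws per
marker outside the IBD window); genotyping error; real litter-size and
parity distributions; overlapping generations; genetic trends in the
polygenic background. Tests passing on this generator therefore
demonstrate correctness of the *inference machinery* under the assumed
model, not robustness to real-data artefacts.

## 3. Pedigree and kinship (`pedkin`)

Numerator relationship matrix by the tabular recursion
a_ij = (a_{j,s(i)} + a_{j,d(i)})/2, a_ii = 1 + a_{s(i),d(i)}/2; inbreeding
F_i = a_{s,d}/2; unknown parents are unrelated non-inbred founders. Dense
storage — at the package's scale (≤ tens of thousands) dense arithmetic is
simpler and fast enough; a sparse A⁻¹ (Henderson) path would be the
extension for very large pedigrees. Verified against an independent
Malecot-kinship recursion in the tests.

## 4. Segregation analysis (`segregation`)

**Litter ratio test.** Pools offspring of litters with ≥1 affected and
tests the affected proportion against 0.25 (1-df χ²). Conditioning on ≥1
affected biases the pooled proportion upward for small litters (for
Poisson(12) litters the conditional limit is ≈0.260, not 0.250); the test
suite checks convergence against the exact conditional limit and treats
0.25 as the large-litter limit. The unconditional check on known carrier
matings is the TT frequency itself.

**Gibbs sampler.** Model and parametrisation as in the README. Updates:
single-site genotype scan in pedigree order (full conditional = parental
transmission × transmission to offspring given current mates × Gaussian
phenotype likelihood; founders use HWE at current q; a single known parent
is handled by marginalising the unknown mate over HWE); q ~ Beta(1+·, 1+·)
on founder allele counts; (μ, a, d) jointly from the conjugate normal
update with a ridge precision of 1e−8 standing in for a flat prior;
σ²e ~ scaled-inv-χ² with the flat prior ν = −2. Defaults: 20,000
iterations, 5,000 burn-in, thin 5. The genotype sweep is numba-compiled;
a full 20k-iteration run on ~4,000 individuals takes ~15 s on one core.

*Identifiability.* The likelihood is invariant to relabelling alleles
(q↔1−q, a↔−a, genotypes mirrored); draws are reported in the canonical
orientation a ≥ 0.

*Degenerate data.* A deterministic 0/1 trait drives σ²e to its floor
(1e−12) without upsetting the genotype updates; monomorphic data drive the
q posterior to the boundary and are reported, not rejected. The flat
effect prior is weak: on very small pedigrees with free (μ, a, d) the
chain can wander into near-unidentified regions, which is why
oracle comparisons on toy pedigrees fix the parameters (`fix_params`) —
the configuration in which the chain provably targets the same
distribution as the exact 3ⁿ enumeration.

## 5. Variance components and heritability (`varcomp`)

Conjugate Gibbs for y = Xβ + Σ Z_k u_k + e on the observed 0/1 scale, with
**A**-structured genetic terms (animal, sire, dam) and identity litter /
maternal terms; variances from scaled-inv-χ²(ν = −2). Identity-covariance
blocks are sampled elementwise (their posterior precision is diagonal);
**A**-blocks by dense Cholesky. Heritability: σ²ᵤ/σ²ₚ (animal),
4σ²ₛ/σ²ₚ (sire), 2(σ²ₛ+σ²_d)/σ²ₚ (sire+dam), with σ²ₚ the sum of fitted
components; sire-model estimates can exceed 1 in small samples and are
flagged rather than truncated. The Dempster–Lerner transform
h²·p(1−p)/φ(Φ⁻¹(1−p))² converts observed-scale h² of a binary trait to
the liability scale (multiplier π/2 at p = 0.5, ≈3.86 at p = 0.063).

A threshold (logit/probit) mixed model is *not* implemented; the
observed-scale fit plus the liability transform is the supported route.

## 6. Homozygosity mapping (`rohmap`)

After dropping non-autosomal, fixed and completely heterozygous SNPs, the
scan finds, per chromosome, maximal runs of consecutive SNPs at which all
non-missing cases are homozygous for a shared allele; runs are ranked by
SNP count, ties broken by bp span then position. Missing case calls do not
interrupt a run but are counted and reported. `allow_case_het` relaxes the
predicate by tolerating that many heterozygous cases per SNP (useful when
one "control" may be a misclassified case or a chip call is wrong);
defaults are strict. The bp span is last − first (an 8,316,475 bp interval
prints as 8.3 Mbp). Consensus "summary rows" per group (shared-homozygote
colour vs heterozygote colour) reproduce the standard mapping-figure
rendering as data. Correctness is tested against a brute-force
all-intervals scan.

## 7. Variant filtering and annotation (`varfilter`)

Hard filters fail a site iff QD < 2.0, FS > 60.0, MQ < 40.0,
MQRankSum < −12.5 or ReadPosRankSum < −8.0 — strict inequalities, so
boundary values pass; a missing metric passes its clause and is flagged.
Candidate criteria: cases homozygous for one shared allele (≤
`max_het_cases` heterozygous exceptions), carriers heterozygous (≤
`max_homref_carriers` homozygous-for-the-other-allele exceptions; a
carrier homozygous for the case allele always disqualifies), controls
homozygous for the other allele. Missing genotypes never count against a
clause — at low sequencing depth heterozygotes are systematically
under-called, so absence of evidence is not treated as contradiction.
Multi-allelic records are decomposed to biallelic before filtering; InDels
pass through the candidate filter but are rejected by the consequence
annotator (out of scope).

Annotation maps genomic position to CDS coordinate through the exon table
(strand-aware), translates reference and mutated codons by the standard
genetic code, and emits HGVS-like c./p. strings; codon index =
⌈cds_pos/3⌉. A stop_gained call is equivalent to the mutant protein being
a strict prefix of the reference protein, which the tests assert.

## 8. Per-stage Hardy–Weinberg analysis (`hwe`)

q by allele counting; α = 1 − H_obs/H_exp with H_exp = 2q(1−q); the 3-class
HWE χ² on 1 df, which algebraically equals n·α² (asserted on every input,
and used as a consistency check of any published (n, α, χ²) triple). The
genotype-change test is the ordinary contingency χ² on the surviving
genotype classes (GG, GT) across stages: non-significance there, combined
with strongly negative α, is the signature of selective loss of TT
homozygotes rather than selection against the allele.

Two caveats surfaced by simulation and documented here deliberately:
(i) under random mating in a dioecious population α is expected to be
slightly negative, order −1/(2N) (the reports carry this note); (ii) the
1-df χ² assumes independent individuals — birth cohorts drawn from few
sires or few large full-sib litters are over-dispersed (we measured 18–25%
rejection at the nominal 5% level under such designs, vs ~10% under a
study-like design of hundreds of parents and small litters). The
generator-level HWE tests therefore use the many-parent design.

The published per-stage genotype counts are supplementary data not
bundled here; the test fixtures use the integer counts most consistent
with the printed (n, q, α, χ²) summaries — birth (298, 163, 25), 40 kg
(250, 123, 1), 110 kg (174, 91, 0) — which reproduce q to 2 decimals and
χ² to ~1% (rounding of the published summaries precludes exact recovery;
a published "P > 0.001" alongside χ² = 11.45 on 1 df is read as the
typographical inversion of P < 0.001).

## 9. Association (`assoc`)

GLS via the eigendecomposition of **A** (one O(n³) factorisation, then
each λ evaluation is O(np²)); REML profile over λ on a 50-point log grid
spanning [1e−3, 1e3] with golden-section refinement. b and its SE come
from σ̂²ₐ(X'H⁻¹X)⁻¹; Wald = (b/se)² on 1 df. σ_P is reported as
√(σ̂²ₐ+σ̂²ₑ) (ignoring the small diag(A) − 1 inbreeding contribution).
Genotype means are reported as least-squares means at covariate means —
the convention, since raw means confound genotype with covariates. The
published analysis smoothed test start dates with cubic splines; here a
categorical batch effect stands in (splines are an extension hook).
`locus_variance_share` uses the explicit convention locus variance =
frequency-weighted variance of genotype means, share = locus/(locus +
background polygenic σ²ₐ); published percentages for this quantity are
not asserted anywhere because their formula is not stated.

## 10. Problem sizes and runtime

Defaults were chosen so the full test suite runs in well under a minute of
simulation time per fixture: the shared population is ~2,000 individuals ×
1,200 markers; segregation acceptance runs 500 litters (~3,000 offspring)
× 20,000 Gibbs iterations; association recovery uses n = 1,000 with a
dense 1,000 × 1,000 **A**. These sizes are a deliberate scale-down of the
emulated study (19,006 records, 38,570 SNPs) that preserves every
structural feature the methods rely on.

## 11. Known limitations

* The Gibbs segregation model is Gaussian-penetrance on the 0/1 scale; a
  probit/threshold penetrance is noted as an extension, not implemented.
* Single-site genotype updates can mix slowly on deep pedigrees with
  strong phenotype constraints; mixing is adequate at the tested scales,
  but blocked (peeling-based) updates would be the upgrade path.
* REML in `assoc` profiles a single variance ratio; multi-trait and
  repeatability models are out of scope.
* `varfilter` annotates SNVs against a single supplied gene model; it is
  not a genome-wide annotator and knows nothing of splice sites, UTRs or
  pseudogenes.
* Dense **A** limits pedigrees to ~10⁴ individuals in memory.
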
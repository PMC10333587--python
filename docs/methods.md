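# Methods

`rrsim` simulates reciprocal recurrent selection (RRS) hybrid-breeding
programs on diploid, biallelic SNP genomes. This note documents the
model, its assumptions, the defaults and why they were chosen, and what
the synthetic data do and do not emulate.

## Genetic model

An individual is a pair of binary haplotypes over a single linear
genome; entry 1 codes the locus's major allele. The trait is fully
determined by per-locus additive effects α and dominance effects β
through the linear score

v_i = Σ_j α_j g_ij + Σ_j β_j d_ij,

where g_ij ∈ {0,1,2} counts major alleles and d_ij flags a
heterozygote. Dominance acts only on heterozygous loci, which is how
heterosis — F1 superiority over inbred parents — enters: a cross of two
complementary inbreds is heterozygous wherever they differ and collects
the β⁺ effects there. There is no epistasis and no genotype-by-
environment interaction; these are deliberate exclusions, and any
conclusion drawn from the simulator is conditional on them.

### Transparent and opaque regimes

Two genotype-to-phenotype regimes are supported:

* **transparent** — the L observed markers are the whole genome.
  Phenotypes, meiosis, prediction and selection all see the same loci.
* **opaque** — the true genome has L̄ ≫ L loci; phenotypes and meiosis
  run on all of them, but prediction and selection only ever receive
  the L marker columns. The hidden loci carry their own effects, so
  phenotypes leak information that no decision module can model.

The architecture object therefore carries two effect sets, each
calibrated to the same totals (below): an observed-basis set of length
L driving the transparent regime, and a full-genome set of length L̄
driving the opaque one. Spreading the same effect totals over ten
times as many loci makes each opaque-regime effect roughly an order of
magnitude smaller, which is precisely why genetic gains accumulate more
slowly there — the opacity penalty the framework exists to expose.
(Collapsing both sets into one vector would force the hidden effects to
sum to zero and erase the distinction, so the two-set design is the
only internally consistent one.)

### Effect calibration

Ground-truth effects are drawn as exponential magnitudes on a sparse
support (dominance support: 10% of loci by default, at least one locus
per sign; additive: dense) with a configurable fraction (default ½) of
dominance loci negative, then rescaled exactly so that

Σ α = 30, Σ β⁺ = 20, Σ β⁻ = −5

for the observed vectors and, independently, for the full-genome
vectors. The long-tailed magnitude distribution produces the sparse,
spiky effect profiles typical of quantitative-trait architectures; the
three sums are the only quantitative anchors of the calibration and are
reproduced exactly (to one rescaling ulp) by construction.

## Phenotypes and heritability

Phenotypes are p_i = v_i + e_i with e_i ~ N(0, σ²_e) i.i.d. The noise
variance is set from broad-sense heritability H² via

σ²_e = Var(v) · (1 − H²) / H²,

with Var(v) the (n−1) sample variance of the true genetic values of
the population being phenotyped. Defining σ²_e from the *phenotypic*
variance instead would be circular (phenotypes already contain e); the
identity above is the unique non-circular reading of
H² = Var(genotype)/Var(phenotype). In the opaque regime Var(v) uses the
full-genome values, since hidden loci contribute genetic variance. The
noise level is recomputed for every phenotyping event by default
(population variances shrink as selection proceeds); a config flag
freezes it at the cycle-0 hybrid value instead. Realized heritability
Var(v)/Var(p) converges to the configured H² at large n and is logged
as a diagnostic.

## Meiosis

Gametes follow the per-interval independent-switch model: the source
homolog starts uniformly at random and switches between loci j and j+1
with probability r_j, independently per interval — a Markov (Haldane,
no-interference) crossover model. Crossing draws one gamete per
parent. Doubled-haploid conversion duplicates one uniformly chosen
existing homolog (a meiotic-gamete variant is available by flag);
self-crossing is provided as the alternative route to homozygosity.
No mutation or gene conversion.

Between-marker recombination rates for the observed genome are derived
from the full map by folding consecutive intervals with
r₁₂ = r₁(1−r₂) + r₂(1−r₁) (probability of an odd number of
crossovers), which is exactly consistent with the independent-switch
model, so projecting full-genome offspring onto the markers is
distributionally identical to crossing the projected parents.

The generator parameterizes the map by the expected number of
crossovers per meiosis over the whole genome (default 15, a maize-like
total map length of roughly ten chromosomes × 1.5 Morgans), so genomes
of different locus counts remain comparable. Chromosome structure is
emulated, not modelled: a single linear genome with interval rates
approaching 0.5 behaves like separate linkage groups.

## GEBV predictors

* **perfect** — returns the ground-truth v of the active regime; the
  upper reference for any learned predictor.
* **phenotypic** — returns the phenotype itself; its accuracy is
  √H² in expectation.
* **bayesian** — the marker regression
  p_i = μ + Σ a_j g_ij + Σ b_j d_ij + ε_i with zero-mean normal priors
  on every effect and scaled-inverse-χ² priors on variances, fitted by
  Gibbs sampling. Default prior regime gives each marker its own
  variance (the BayesA-style heavy-tailed marginal); a shared
  per-class variance regime is available. Defaults: 3,000 iterations,
  1,000 burn-in, thinning 5, prior df 4, prior scales set from a
  ½ additive / ¼ dominance / ¼ residual partition of the phenotypic
  variance. Convergence is not formally diagnosed; adequacy is
  established by simulation-recovery tests (held-out accuracy ≥ 0.8 at
  N=500, L=100, H²=0.9; accuracy collapses under phenotype
  permutation). Point estimates are posterior means; prediction is the
  plug-in linear score. Multi-cycle pipeline runs use a shortened
  desk chain (600/200/2) because the model is refitted at every stage
  (test cross, each intra-population round, and the doubled-haploid
  down-selection) on the currently phenotyped group.

## Selection and mating

Truncation selection (top-M by predicted value) is the exact solution
of the "pick M maximizing the summed score" integer program. The test
cross builds the N_A×N_B matrix of predicted hybrid GEBVs — each F1 of
two inbreds is deterministic, so the whole true matrix is three matrix
products. GCA selection takes the top-2K row (or column) means; SCA
takes the top-2K row maxima, crediting each parent with its single
best mate. Both reductions are exact for the assignment formulation
with one chosen mate per selected parent (the printed constraint set
is repaired to Σ_l y_kl = x_k, y_kl ≤ x_k, the only reading under
which the "row-wise maximum" narrative and the objective agree) and
are verified against brute-force subset enumeration. Ties are always
broken by lowest index for reproducibility.

Mating designs pair the 2K selected parents sorted by predicted value:
*adjacent* pairs ranks (1,2), (3,4), …; *complementary* pairs rank i
with rank K+i (the uniform-stride matching consistent with the
pair-the-best-with-the-middle intent; the naive "1 with K, 2 with K+1"
reading double-uses middle ranks and leaves others unmatched). Each
pair yields S progeny.

## The RRS cycle and the experiment harness

One cycle: (1) test cross and combining-ability selection of 2K
parents per pool (rows of the matrix for pool A, columns for B);
(2) mating, K·S progeny per pool; (3) n_intra rounds (default 1) of
intra-population breeding — phenotype, predict, truncation-select M,
mate, S progeny per pair; (4) doubled-haploid conversion and
truncation down-selection back to the pool size, scored by the
configured predictor (the criterion for this step is a design choice;
the true value is used only by the perfect predictor). Evaluation
mutually crosses the pools and averages the *true* GEBV of the top-n
hybrids ("population C"); genetic gain is that mean minus its cycle-0
baseline, evaluated before any selection.

Defaults mirror the headline study conditions: 369 founders, L=1,000
markers in an L̄=10,000-locus genome, pools of 100 from a 200-founder
split (the split is uniformly random; a published heterotic-separation
rule is not specified, so random partition is used and flagged),
M=40, K=10, S=20, T=6 cycles, H²=0.2, top-100 evaluation, 100
replicates. The harness enumerates the 24-cell factorial
{transparent, opaque} × {perfect, phenotypic, bayesian} ×
{adjacent, complementary} × {GCA, SCA} and a heritability sweep
H² ∈ {0.2, 0.5, 0.8} for the two noise-sensitive predictors, with the
perfect predictor as the noise-independent reference.

Every stochastic step draws from a generator derived from
(master seed, replicate), so a whole grid is a pure function of its
seeds and configs.

## Desk scale

Tests and interactive runs use a scaled-down study: 60 founders,
L=200 markers in a 2,000-locus genome (same 10:1 hidden ratio, same
15-crossover map length), pools of 20, K=5, T=3 cycles, 20
replicates, with M=40, S=20 and the top-100 evaluation kept at their
defaults. These sizes keep a full factorial cell under a few seconds
(minutes for the Bayesian predictor) while preserving the full-scale
qualitative behaviour: positive gains under the perfect predictor,
transparent gains roughly double opaque gains, and the perfect
predictor as the upper reference. Shrinking the genome or the
evaluated top-n much further makes the cycle-0 top-hybrid mean an
extreme order statistic of a very diverse founder split, and the
post-bottleneck diversity loss can then mask real selection response —
the main caveat when scaling the simulator down.

## A caution on predictor rankings under the top-n hybrid metric

Intuition says the perfect predictor bounds every learned predictor.
For the response of the pools themselves it does: in matched runs at
the default scale the perfect predictor gains more pool mean than the
phenotypic predictor (e.g. 5.7 vs 4.8 effect units over six cycles at
H²=0.2). The top-n hybrid metric, however, is an order statistic: it
rewards hybrid-tail *variance* as well as mean. High-accuracy
truncation drives both pools toward the same additive optimum,
eroding genetic variance and between-pool complementarity (and with
it the dominance contribution of hybrids) faster than noisy selection
does, so the phenotypic predictor can and does outgain the perfect
one on the top-100 hybrid mean in this simulator (mean gain over all
hybrids is essentially equal). The effect persists at full scale,
under a rare-skewed allele-frequency spectrum, with a random instead
of truncation-based doubled-haploid down-selection, and with extra
intra-population rounds. The Bayesian predictor, whose shrinkage
produces *correlated* selection errors, sits below the perfect
predictor on both metrics. The practical reading: when the quantity
of interest is the extreme tail of a hybrid cross, selection accuracy
is not a free lunch, and diversity-preserving selection schemes
deserve the attention they get in the genomic-selection literature.
One acceptance test documents the naive expected ordering and is
expected to fail for exactly this reason (its docstring says so).

## What the synthetic founders do not emulate

Founder haplotypes are drawn independently per locus (major-allele
frequency uniform on the MAF-range complement), so there is no founder
linkage disequilibrium, no population structure, and no allele-
frequency spectrum skew; LD builds up only through breeding. Real
inbred panels have block-wise LD, related subfamilies, and rare-allele
excess, all of which change prediction accuracy and the value of
combining-ability selection. Passing tests therefore demonstrate the
internal correctness and qualitative behaviour of the breeding
machinery, not calibrated gains for any real crop program. Imported
genotypes (VCF or the delimited dialect) are treated as observed-scope
markers; opaque runs on imported data require synthetic hidden
augmentation.

## Numerical notes

* Genotypes are int8 tensors (N, L, 2); dosage and GEBV arithmetic is
  exact integer/float linear algebra, and the test-cross matrix uses a
  bilinear identity instead of materializing N_A·N_B genotypes.
* Rescaling to the calibration sums is a single multiplication; sums
  are exact to one floating ulp, and tests assert 1e-9 absolute.
* Degenerate inputs: zero-variance phenotypes return a null model with
  a warning; constant genetic values give σ²_e = 0 with a warning;
  H² = 0 is rejected (infinite noise).
* Gibbs updates sweep markers in index order on a running residual;
  the per-marker conditional is conjugate normal, variances are
  scaled-inverse-χ² draws.
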
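# Methods

## The synthetic population

The simulator (`crossgen_gs.synthetic_data`) emulates a two-generation
open-pollinated (OP) conifer breeding population at the scale of a
two-trial progeny test:

* **Founders (G0).** `n_founders = 500` unrelated plus-tree clones,
  genotyped at `n_markers = 5000` unlinked biallelic SNPs drawn under
  Hardy–Weinberg equilibrium with per-marker allele frequencies uniform
  on `maf_range = (0.1, 0.5)`. Loci are unlinked: no LD map is simulated,
  which is sufficient for relationship-matrix and prediction-recovery
  work where the signal travels through realized relatedness rather than
  marker–QTL LD.
* **Open pollination.** The first `n_families_phenotyped = 65` founders
  are dams; each contributes `progeny_per_family_per_trial = 6` offspring
  to each of `n_trials = 2` trials. Every progeny receives one Mendelian
  gamete from its dam and one from a father drawn from the founder pollen
  pool (never the dam: no selfing). With probability
  `full_sib_fraction` the father is recycled from an earlier sibling,
  hiding full-sibs inside nominal half-sib families. The pedigree records
  only the dam — sires are logged separately as ground truth — so ABLUP
  sees exactly the information a real OP program has. The default
  `full_sib_fraction = 0.04` was fixed from the identity
  E[within-family G] = 0.25 + 0.25·P(shared father), which maps an
  observed within-family mean of 0.26 to ≈ 0.04.
* **Trait architecture.** `n_qtl = 200` markers receive zero-mean normal
  effects, rescaled so the founder-generation additive variance equals
  `target_h2` exactly; residual variance is budgeted as `1 − target_h2`,
  so total phenotypic variance is ~1 before design effects. `target_h2 =
  0` yields a pure-noise trait (all breeding values zero).
* **Trial design.** Each progeny gets a uniform random block within its
  trial (`n_blocks_per_trial = 20`, single-tree plots); block effects are
  N(0, `block_sd²`), `block_sd = 0.5`. G0 archive clones have no block
  design.
* **Radial profiles.** Each tree carries consecutive annual rings from
  the pith (21 for G0, 16 for G1). Ring value = saturating cambial trend
  `amplitude·(1 − e^{−r/scale})` (defaults 2.0 and 6.0, i.e. a ~2-SD
  juvenile-to-mature rise; the trend form is a modeling choice, it is
  qualitative only) + breeding value + block effect + a tree-level
  deviation + independent ring noise (sd 0.1). Ring widths decline with
  cambial age and are strictly positive.

**Variance budget of the tree-level deviation.** The non-additive
tree-level variance `1 − target_h2` is split into a *permanent*
whole-core component (fraction `perm_env_fraction = 0.85`) and an AR(1)
component over rings (fraction 0.15, lag-1 correlation
`ring_age_correlation = 0.7`), a compound-symmetry + AR(1) age-age
correlation structure. The permanent share is deliberately dominant: a
pure AR(1) deviation would largely average out of the area-weighted
whole-core value, deflating its residual variance far below `1 − h²` and
inflating whole-core heritability well above the target. With the 85/15
split the whole-core AWE keeps variance ≈ 0.92–0.95 and heritability
within ~0.03 of the target (both checked by test), while single-ring
values still fluctuate along the core so AWE- and SAD-trained models can
disagree ring by ring.

**What the generator does *not* emulate.** No linkage or marker–QTL LD;
no genotype-by-environment interaction (trials differ only through block
draws, so across-trial predictions are exchangeable by construction); no
age-specific genetic effects — a tree's breeding value is constant across
rings, so age–age *genetic* correlations are 1. Consequently the
cambial-age sweep shows the feasibility and relative smoothness of AWE-
vs SAD-trained prediction, but not the mid-rotation accuracy peak that
real data show when juvenile and mature wood are under partially
different genetic control. Passing tests therefore certify the machinery
and its statistical calibration, not those biological features.

## Phenotype derivation and design adjustment

Rings are summarized assuming circular rings: cumulative radius
`r_i = Σ_{j≤i} w_j`, annulus area `a_i = π(r_i² − r_{i−1}²)`, and
`AWE_k = Σ_{i≤k} a_i d_i / Σ_{i≤k} a_i`. SAD at ring k is the ring value
itself; the juvenile value is the AWE over the innermost
`min(10, n_rings)` rings. Ring indices are 1-based from the pith.

Adjustment fits, per trait and per trial, `y = μ + W b + Z u + e` with
blocks random (the incomplete-block convention; a `block_as="fixed"` flag
exists for sensitivity checks) and an optional additive term whose kernel
the caller supplies — the adjustment is runnable with A, G or no genetic
term, since the convention is not fixed by the estimator. Adjusted values
are `y′ = y − μ̂ − (W b̂)`; genetic and residual variation stay in `y′`.
Trials with fewer than two blocks (the G0 archive) are mean-centered with
a warning. Segment traits travel through the same machinery as extra
value columns; no earlywood/latewood boundary detection is attempted
(that happens upstream of ring tables).

## Relationship matrices and QC

QC applies, in order: minor-allele frequency < 0.05; individual
missingness > 70%; site missingness > 70%; heterozygote excess
(observed het rate > 0.6) or exact Hardy–Weinberg deviation (two-sided
exact SNP-HWE test, p < 1e-6). The het/HWE thresholds are package
defaults — standard practice rather than externally fixed values — and
are parameters. The exact HWE test is implemented in-house (no installed
package exposes it) and unit-tested against direct enumeration.

`A` is built by the tabular method over a topological order; unknown
parents contribute zero, and with genetic groups enabled each
unknown-parent slot of a labeled record is filled by a phantom founder
shared by that group (one phantom per group; group solutions inside the
MME are out of scope). `G` follows VanRaden: allele-sharing matrix
centered by `2pᵢ` and scaled by `2Σpᵢ(1−pᵢ)`. Sources occasionally print
the centering as `2(pᵢ − 0.5)`; that variant is available as
`centering="as-printed"` but is not the default, because only `2pᵢ`
centering is VanRaden's construction and only it yields the zero-row-sum
identity under observed frequencies. Frequencies default to observed
values over all genotyped individuals (G0 + G1 combined), matching how
the kernel is built once over everyone before any training split.
Missing codes are mean-imputed (`2pᵢ`) after QC. Singular kernels
(duplicate individuals, n < markers edge cases) are handled by blending,
`wG + (1−w)I` with default `w = 0.98`; blending toward an A-submatrix is
also supported.

## REML and mixed-model equations

The single-kernel animal model is fitted in the eigenbasis of the
training-set kernel: one `eigh` turns every EM or AI iteration into O(n)
work, and a cambial-age sweep reuses the decomposition across rings. EM
updates are the classical expectation-maximization recursions and are
monotone in the restricted likelihood (asserted by test on the recorded
trace). The AI path takes average-information Newton steps, falling back
to an EM step whenever the proposal leaves the parameter space or lowers
the likelihood, plus a decade-shrink move toward the boundary where EM's
geometric crawl would stall. When `σ²_a` approaches zero the profiled
boundary likelihood (`σ²_a = 0`, `σ²_e` = OLS REML) is evaluated and
accepted if no worse; boundary fits return `converged=True` with a
`boundary` flag — negative variance estimates are never reported.
Convergence: relative parameter change < 1e-6 (default), max 500
iterations. Standard errors come from the inverse average-information
matrix at convergence and are approximate. A kernel that is a multiple of
the identity on the training set (e.g. a pedigree matrix over mutually
unrelated founders) makes `σ²_a` and `σ²_e` unidentifiable; the fit warns
in that case — this is exactly why pedigree-only (ABLUP) forward
prediction from unrelated plus trees reports no meaningful heritability.

Henderson's equations are then solved once over *all* kernel individuals
with `λ = σ²_e/σ²_a` and a dense Cholesky of K (problem sizes ≤ ~3,000
permit it), so unphenotyped validation individuals receive EBVs through
their relationship covariances. `σ²_a = 0` short-circuits to zero EBVs
with a flag. A separate dense multi-kernel REML engine (blocks + genetic
term) serves the adjustment model; the two engines are cross-checked
against each other and against closed-form GLS and likelihood-grid
oracles in the tests.

## Validation design

Approach A trains on G0 and validates on each progeny trial (forward);
Approach B trains on the first trial and validates on the second trial
and on G0 (across-environment + backward); Approach C mirrors B from the
other trial. Training and validation id sets are disjoint by
construction and a hard runtime check enforces it. ACC uses the
heritability of the *training* fit (the only one available at selection
time; a flag allows the validation-set h² for sensitivity analyses) and
is reported as NA with reason "inestimable" when h² < 1e-3. For GBLUP,
individuals without genotypes are excluded entirely; ABLUP uses all
pedigree-connected phenotyped individuals — the two models legitimately
see different sample sizes, as they do in practice.

The early-training sweep trains GBLUP on G0 density summarized to each
ring k = 1..21 (AWE or SAD mode), mean-centering the archive phenotypes,
and validates against progeny juvenile-10 and whole-core adjusted AWE per
trial. Rings reached by fewer than 50% of G0 trees are skipped (a package
default; trees lacking ring k are dropped from training at that k), and
ACC rows beyond ring 16 carry a low-reliability flag.

## Problem sizes and numerical defaults

Replicated experiments run at reduced scale chosen to keep each study's
Monte-Carlo error well inside its decision margin: heritability recovery
uses 1,000 individuals × 2,000 markers × 20 replicates; the approach
comparison 320 individuals × 800 markers × 20 replicates; the sweep
comparison 210 individuals × 600 markers × 20 replicates; relatedness
studies run at the full default scale (890 × 5,000). Blend weight 0.98,
REML tolerance 1e-6, ACC estimability threshold 1e-3, histogram bin width
0.05 throughout.

## Known limitations

* OP sires are drawn from the founder set itself; external pollen
  migration is not modeled.
* The simulator's age–age genetic correlation is 1 (see above), so sweep
  *peak locations* are not biologically meaningful.
* Standard errors of variance components are AI-matrix approximations;
  no SEs are attached to PA/ACC.
* Genetic groups enter only through phantom parents in A; ABLUP with
  fully unrelated founders remains unidentifiable by design rather than
  silently regularized.
* Dominance/epistasis are not modeled or fitted; the two-variance
  additive model is the scope.
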
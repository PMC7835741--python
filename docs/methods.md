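# Methods

This note documents the models, algorithms, numerical choices and study
conditions behind `sswgwas`, in the order the pipeline runs them.

## Trait standardization (`sswgwas.traits`)

Off-test measurements are standardized to a 100 kg endpoint with the
CCSI-style sex-specific correction factors: days to 100 kg uses
CF1 = (weight/age)·1.826 for males and ·1.715 for females; average daily
gain is 100 kg divided by the adjusted age (reported in g/day); backfat
and loin muscle depth use the ratio adjustments A/(A+B·(w−100)) with
(A,B) = (13.47, 0.1115) male / (15.65, 0.1566) female for backfat and
(50.52, 0.228) / (52.01, 0.228) for loin depth; lean meat percentage is
61.21920 − 0.77665·BF + 0.15239·LMD.  Two conventions are deliberate:
"sire"/"dam" factor tracks are read as the animal's own sex, and the
lean-percentage equation is applied to the *adjusted* BF and LMD (the
source formulas are written at the 100 kg endpoint).  Animals measured
outside 100 ± 5 kg are flagged (`off_target_weight`), never dropped —
the downstream model can exclude them if wanted.

## Pedigree relationships (`sswgwas.pedigree`)

The numerator relationship matrix A is built by the tabular method
(dense; intended for pedigrees up to a few thousand animals, the scale
of a nucleus herd).  Inbreeding coefficients come from the Meuwissen–Luo
path-coefficient algorithm, and A⁻¹ is assembled sparse directly by
Henderson's rules with the Mendelian-sampling variances
dᵢ = ½ − ¼(F_s + F_d); the dense tabular inverse is kept as a test
oracle.  Unknown parents are unrelated non-inbred founders; genetic
groups and metafounders are out of scope.  A22 for the genotyped animals
is the principal submatrix of A in genotype-file order, inverted densely.

## Genotype QC and G (`sswgwas.genomic`)

QC applies, in order: animal call rate (<90% excluded, strict
inequality), SNP call rate (<90%), Hardy–Weinberg chi-square (1 df, no
continuity correction) p < 10⁻⁶, minor allele frequency < 0.01, and
non-autosomal or unmapped position.  Surviving missing dosages are
imputed with the column mean 2p, which is exactly neutral under
centering.  A Fisher-exact HWE variant was considered and rejected: at
array scale the chi-square test is the convention and the threshold is
extreme enough that the difference is immaterial.

G follows VanRaden: Z is the column-centered dosage matrix (centering by
the observed frequency of the counted allele — 2p(1−p) is symmetric in
p↔1−p so the scaling constant λ = Σ2pᵢ(1−pᵢ) does not depend on which
allele is called "minor"), D a diagonal weight matrix, G = ZDZ′/λ.  With
observed frequencies G is singular by construction (centered columns sum
to zero), so every consumer that needs G⁻¹ uses the blend
G* = (1−α)G + αA22 with α = 0.05 — the standard single-step remedy.
Further "tuning" of G's mean diagonal/off-diagonal to A22 is not
implemented; the blend alone keeps H⁻¹ well conditioned at these sizes.

## Variance components and MME (`sswgwas.ssgblup`)

AI-REML for (σ²ₐ, σ²ₑ) is run in the eigenbasis of M = Z_inc K Z_inc′:
one symmetric eigendecomposition per dataset, after which every
iteration's P-weighted traces, gradients and the 2×2
average-information matrix are diagonal arithmetic.  Starting values are
var(y)/2 for both components; convergence is relative parameter change
< 10⁻⁸ with at most 50 iterations; an AI step that would leave the
parameter space is step-halved (down to 1/16) and otherwise replaced by
an EM-style update, with components floored at 10⁻¹⁰·var(y).
Non-convergence is reported in the returned object, never silently
accepted.  The standard error of h² comes from the inverse AI matrix by
the delta method.  Fixed effects use full-rank drop-first dummy coding
with an explicit intercept.

`em_reml` is a second, deliberately independent route — classical
EM-REML on the dense mixed-model equations
(σ²ₐ ← (û′K⁻¹û + σ²ₑ·tr(K⁻¹C^uu))/q) — used to cross-check the AI
implementation; the two agree to better than 10⁻⁵ (relative to var(y))
on the test problems.

Henderson's MME are assembled dense and solved by Cholesky; estimates
are returned for every animal in the relationship structure, phenotyped
or not.  Variance components are estimated once per relationship
structure (the unweighted D = I single-step model) and held fixed during
the weight iterations — the weight loop re-estimates GEBVs and SNP
effects, not variances.

## The weighted scan (`sswgwas.scan`)

The three-iteration loop follows the standard weighted single-step
recipe (D⁽¹⁾ = I; rebuild G; solve the MME; back-solve; reweight;
renormalize).  One printed-formula ambiguity is resolved algebraically:
the back-solve is implemented as u = DZ′G⁻¹ĝ / Σ2p(1−p), the scaling
under which Zu reproduces ĝ exactly for an unblended G — treating the
λ that sometimes appears as a multiplier in this formula as the
*reciprocal* of Σ2p(1−p).  Weights are dᵢ = uᵢ²·2pᵢ(1−pᵢ), renormalized
each iteration so Σdᵢ equals the SNP count exactly.

Windows are fixed, non-overlapping, half-open 0.8 Mb bins from each
chromosome's origin (1-based positions; a SNP exactly at 0.8 Mb starts
the second bin); sliding windows are deliberately not implemented, and
SNP-empty bins are dropped, which is consistent with counting only
SNP-containing bins as "genomic regions".  A window's share is
var(Z_w u_w) over genotyped animals divided by var(Zu), ×100, both with
population (n-denominator) variances so the convention cancels;
dividing by the REML σ²ₐ instead is a config option
(`denominator_sigma_a2`).  Shares of different windows need not sum to
100% because between-window LD covariance is reported as-is, not
rescaled.  Region reports select windows strictly above 1%, sort by
descending share (ties: lower chromosome, then lower start) and extend
the top three by 0.4 Mb flanks clipped at chromosome bounds.

## The population simulator (`sswgwas.synthetic`)

The generator emulates a closed three-generation Duroc nucleus herd.

* **Pedigree.** Discrete generations; each post-founder generation makes
  n_founders/2 sire–dam pairs from the previous generation (boars reused
  freely) with a fixed litter size; sexes alternate within litters;
  birth year tracks generation (2015 + g) and farm is drawn uniformly.
  Defaults (600 founders, 3 offspring generations of 1500) give ~5100
  pedigree animals with ~53% genotyped, youngest first — the selective-
  genotyping pattern of a nucleus herd, where genotyping budgets go to
  current selection candidates.  Which generations were genotyped in any
  given herd is a modelling assumption, not an observable of this
  package.
* **Founder haplotypes and LD.** Founders are mosaics of a pool of K = 4
  ancestral haplotypes (Li & Stephens style) whose marker frequencies
  are Uniform(0.1, 0.9), switching ancestors with mean segment length
  0.5 Mb.  The small pool mimics the small effective size of a closed
  nucleus line and yields short-range r² ≈ 0.3 decaying to background
  within roughly a megabase — the LD regime in which an 0.8 Mb window
  scan is the natural analysis unit — while the Uniform frequency pool
  reproduces a post-QC-like MAF spectrum (mean MAF ≈ 0.3) without any
  external reference panel.  Roughly a quarter of simulated markers come
  out monomorphic or rare and are removed by QC, close to the attrition
  of a real 50K array.
* **Transmission.** Gametes recombine as a Poisson process at a uniform
  1 cM/Mb (no interference); offspring dosages are gamete sums, so
  Mendelian consistency holds exactly and ungenotyped ancestors carry
  genomic information through the pedigree, as single-step requires.
* **Genetic architecture.** Each planted QTL window receives up to five
  causal SNPs (MAF ≥ 0.05) scaled so the window contributes exactly its
  target fraction of additive variance — QTL *regions* with a few linked
  causal variants, matching the observation that candidate windows
  typically harbor several plausible genes.  The polygenic remainder is,
  by default, thousands of small marker effects spread over all
  remaining SNPs, so the genomic relationship matrix is the true
  covariance of the genetic background and REML estimates are well
  calibrated.  A pedigree-recursion remainder (parental average +
  Mendelian sampling, untracked by markers) is available as
  `polygenic_mode='pedigree'`; it deliberately violates the ssGBLUP
  model (markers then tag none of the background) and in our experiments
  biases genomic heritability estimates down by ~0.03–0.05 — useful for
  robustness studies, wrong as a default.
* **Scaling.** Residual variance is set from the *realized* additive
  variance so realized h² matches the target; fixed-effect level values
  are N(0, 0.5²) in additive-SD units (`fixed_effect_sd=0` disables
  them).  All randomness flows from one seed through named SeedSequence
  streams (pedigree / founders / gametes / phenotypes / mask).

What the generator does **not** emulate: selection (matings are random,
so no directional allele-frequency change or Bulmer effect),
non-additive effects, genotyping error, age/parity structure within
generations, or a sex chromosome.  Passing tests therefore demonstrate
the machinery's correctness and calibration under a neutral additive
herd, not robustness to selection-induced pedigree–genomic conflicts.

## Validation studies (`sswgwas.studies`, `scripts/acceptance.py`)

Problem sizes are scaled-down study conditions chosen once: the
recovery study uses 20 replicates of 2000 pedigree animals (1000
genotyped) with 5000 SNPs on four 60 Mb chromosomes — the marker density
(~21 SNPs/Mb, ~17 per window) of a post-QC porcine 50K array — h² = 0.33
and one window planted at 3% of additive variance; the null study uses
20 replicates of 1000 animals (500 genotyped) and 4000 SNPs with no QTL.

Findings the studies compute (and the numbers in
`results/acceptance.json` reproduce):

* the algebraic identities of the single-step algebra hold to machine
  precision, and the three dual-route checks (dense GLS pedigree BLUP,
  direct SNP-BLUP, EM-REML) agree with the production paths to 10⁻⁶–10⁻⁸;
* heritability is recovered essentially unbiased (mean absolute bias
  < 0.01 over 20 replicates);
* the null scan is conservative: ~4% of windows exceed the 1% threshold
  under a purely polygenic trait;
* **known limitation** — the window-share estimator is noisy at these
  sample sizes.  Across replicates the planted 3% window's estimated
  share is bimodal (individual replicates range from ~0 to ~8%), its
  20-replicate mean moves between ~0.9% and ~1.8% across seed batches,
  and it ranks first in only ~5–35% of replicates.  The cause is visible in a controlled
  experiment: feeding the *true* breeding values to the back-solve still
  yields only ~1–2.4% for the planted window, because the
  minimum-norm attribution of ĝ to SNPs leaks variance into spuriously
  correlated markers genome-wide (m ≫ n), while the three weighting
  iterations amplify whichever windows — signal or noise — start ahead.
  With 1000 genotyped animals and a QTL at 1% of phenotypic variance,
  detection is genuinely borderline; the estimator's behavior, including
  occasional amplified background windows in the 1–2% range, mirrors
  what window scans report on real data of comparable size.
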
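# Methods

This note documents the statistical models, the synthetic-cohort
generator, and the numerical and design choices behind `twinbiome`.

## Phenotype inference

ABO alleles are called per phased haplotype by exact lookup in a
three-SNP tag table over (rs651007, rs8176746, rs8176704): the
all-reference pattern is O, the rs651007 minor allele tags A1 (rs651007
is a close proxy of rs507666), the rs8176704 minor allele tags A2, and
the rs8176746 minor allele tags B. This default table is a
reconstruction from the tag-SNP literature and is deliberately a plain
TSV the user can replace; any pattern not in the table is *unresolved*
and the sample is excluded from phenotype analyses rather than guessed.
Diploid phenotype follows classical dominance. Secretor status comes
from rs601338 in *FUT2*: A/A homozygotes (two nonsense alleles) are
non-secretors; any G allele secretes. When both serotyped and
genotype-inferred ABO are available and disagree, the genotype-inferred
call wins.

## The twin linear mixed model

All abundance and diversity associations use the Gaussian LMM

    y_i = x_i'β + u_fam(i) + u_mz(i) + ε_i,
    u_fam ~ N(0, σ²_f),  u_mz ~ N(0, σ²_m),  ε ~ N(0, σ²_e),

where `fam` is shared by co-twins and `mz` is shared only by MZ co-twins
(every other individual gets a unique level). σ²_f captures shared
family environment plus half the additive genetic variance common to
both twin types; σ²_m captures the *extra* covariance of MZ pairs.
Significance of a model's fixed-effect block is a likelihood-ratio test
against the model with the block removed, with χ² degrees of freedom
equal to the number of removed columns. Both fits use maximum
likelihood, not REML, because REML likelihoods are not comparable across
fixed-effect structures.

Because families here have at most two members, the marginal covariance
is block diagonal with 2×2 blocks, and the within-pair sum/difference
transform diagonalizes it exactly (MZ: variances σ²_e(1+2γ_f+2γ_m) and
σ²_e; DZ: σ²_e(1+2γ_f+γ_m) and σ²_e(1+γ_m); singletons:
σ²_e(1+γ_f+γ_m), with γ = σ²/σ²_e). The profile likelihood over
(γ_f, γ_m) therefore costs one weighted least-squares solve per
evaluation; it is optimized by a 5×5 log-scale grid followed by a
Nelder-Mead polish. The test suite verifies agreement with statsmodels'
general-purpose `MixedLM` (ML) to ~10⁻⁴ in log-likelihood — the profile
optimizer occasionally terminates at a very slightly *better* optimum —
and verifies variance-component recovery (±0.15 SD at 1000 pairs) and
type-I error (0.05-level LRT rejects 3–7% under the null). A
non-convergent or rank-deficient fit yields a flagged missing p-value
rather than aborting a scan.

The nine model contrasts (m1–m9) code ABO indicators against an O
baseline (m1), O vs rest (m2), B vs rest (m3), B-or-AB (m4), secretor
(m5), m1/m3 restricted to secretors (m6/m7), the full ABO × secretor
interaction (m8), and B × secretor (m9). q-values are computed within
each model across taxa (Storey, smoother π₀; with π₀ = 1 they reduce
exactly to Benjamini-Hochberg, which the tests assert), and a global
variant across all models is also reported. Reduced-model fits are
cached across models sharing an analysis subset (m1–m4; m6–m7; m8–m9).
Adjustment covariates (top-5 ancestry PCs, or the rs1446585 LCT dosage
for bifidobacterial taxa) enter both full and reduced models so the LRT
still isolates the phenotype block.

## Twin-aware permutation

The permutation scheme preserves the dependence structure that makes
twins exchangeable only with twins: unrelated individuals' phenotypes
are permuted among the unrelated; within the MZ group and the DZ group
separately, each family's ordered phenotype pair moves intact to another
family. Within-pair order is preserved (first member → first member),
which keeps within-pair concordance patterns exactly — the property the
scheme exists to protect. A sample missing the permuted phenotype is
excluded and its co-twin is treated as unrelated for that analysis, so
the pair strata stay well-formed. Empirical p-values count ties as
extreme and apply no small-sample correction, so p = 0 is possible with
few draws; every (seed, draw index) pair is fully deterministic.
Relatedness tests use two simpler nulls: family IDs permuted across all
individuals (twin-vs-unrelated) and zygosity labels permuted across
pairs (MZ-vs-DZ), with one-sided "more similar" (≤) alternatives.

## Processing and diversity conventions

- Rarefaction draws without replacement (multivariate hypergeometric);
  samples under the depth are dropped.
- Prevalence thresholds use the ceiling: "present in ≥ 50%" means
  ≥ ⌈n/2⌉ samples, and the reference sample set is configurable because
  common-taxon filters are often computed on a superset cohort.
- Box-Cox adds an offset of 1 for zeros and takes the
  maximum-profile-likelihood λ (scipy's Brent optimization; a grid-search
  oracle in the tests confirms the optimum); λ = 0 is the log limit.
- Residualization is OLS on intercept + numeric covariates +
  treatment-coded categoricals; a rank-deficient design is an error that
  names the offending columns.
- Shannon is log₂ (bits); Chao1 is the classic S + F1²/(2F2) with the
  bias-corrected form when F2 = 0; Faith's PD includes the branch path
  to the root; weighted UniFrac is normalized by default (a flag gives
  the raw form). The Gini index is computed on relative abundances over
  the full taxon set including zeros, with the population denominator
  2S²·mean(p) so it stays within [0, 1]; the sample-denominator variant
  is available.
- PCoA is classical scaling; axes with non-positive eigenvalues are
  dropped with a warning rather than corrected (Cailliez/Lingoes), and
  variance fractions are relative to the positive spectrum. The PC scans
  use an overall F-test per axis (status-only by default, covariates
  optional) and never pad beyond the available axes.
- Genotype QC: MAF filter plus a two-sided exact Hardy-Weinberg test
  (monomorphic SNPs are removed, not errors). LD pruning is greedy and
  windowed (1000 kb, step 50 SNPs, r² > 0.2), scanning pairs in index
  order and removing the lower-MAF member (tie → higher index); the rule
  is deterministic and a brute-force oracle reproduces it exactly.
  Ancestry PCA standardizes each SNP by √(2p(1−p)).
- DAPC predicts by nearest centroid in discriminant space (uniform
  priors); the a-score uses 10 label permutations per candidate by
  default. CV folds are stratified by class at the *family* level so
  co-twins never straddle a training/test boundary — stricter than fold
  construction that ignores relatedness, and the conservative choice
  given that shared genetics would otherwise leak. Random forests use
  ⌊√p⌋ features per split; down-sampling draws an equal per-class
  bootstrap of the smallest class size for every tree, with OOB error
  accumulated from per-tree out-of-bag votes.

## The synthetic cohort

The generator emulates an adult twin registry: MZ pairs, DZ pairs and
unrelated singletons (defaults 315/314/245 → 1503 individuals), ~9%
male, age ~ N(61, 10), BMI ~ N(26, 4.5²), negative-binomial sequencing
depth, and categorical shipment/technician batches. Genotypes arise by
explicit parental haplotype transmission — two simulated parents per twin
family, one transmitted haplotype each; MZ co-twins duplicate the same
transmission, DZ co-twins draw independently — so genotype sharing and
microbiome sharing are jointly coherent rather than imposed by a
correlation shortcut. ABO haplotypes are drawn from allele frequencies
(defaults A1 0.18, A2 0.065, B 0.065, O 0.69, matching a UK phenotype
mix under Hardy-Weinberg) and mapped to tag patterns by running the
lookup table in reverse; the rs601338 A allele defaults to 0.52 so the
expected non-secretor fraction matches the cohort's ~27%. Background
SNPs can come from two subpopulations for ancestry structure. A
configurable fraction of samples carries a serotyped ABO value equal to
the truth except for a 2% typing error rate — the serology/genotype
discordance observed in the real cohort — and a small fraction has
unknown secretor status.

OTU counts are multinomial draws at each sample's depth from the softmax
of Gaussian latent log-abundances: per-OTU baseline (SD 2), family
effect (shared within family), additive genetic effect built from
mid-parent values plus a segregation residual (correlation 1 within MZ,
0.5 within DZ, 0 otherwise), technical covariate effects, injected
phenotype effects (in units of the residual SD), and residual noise.
Taxonomy comes from nested tree clades so collapse-by-rank is exact on
synthetic data, with a small fraction of OTUs left genus-unassigned to
exercise the `unclassified-<parent>` path.

What the generator does *not* emulate: sequencing error and chimeras,
overdispersion beyond the multinomial+log-normal compound, realistic
taxonomic name structure, age- or diet-driven composition shifts, and
linkage disequilibrium between background SNPs. Passing tests therefore
show that the pipeline recovers structure *of the kinds modeled* —
heritable composition, single-taxon phenotype effects, ancestry
stratification — not that it would detect any particular effect in real
data.

## Validation experiment design

The experiment drivers (`twinbiome.experiments`) fix their problem sizes
as follows. Null calibration runs m1–m9 on 20 replicate cohorts at full
cohort scale (1503 samples, 200 OTUs, no phenotype effects) and checks
per-model KS uniformity of the LRT p-values and the rarity of q ≤ 0.1
discoveries; permutation-test calibration uses many small replicate
cohorts (concordance: 140 samples, 200 draws; DAPC: 80 samples, 50
draws) because the quantity of interest is the p-value distribution
across datasets, not any single test's power. Power uses a 0.5
residual-SD secretor shift on the most prevalent OTU at n = 1503 —
injecting an effect does not perturb the generator's random streams, so
the target taxon can be chosen from the matched no-effect realization.
The heritability-signature experiment uses cohort scale with
additive_sd = 1.0 (latent heritability ≈ 0.45): a design-time power
analysis showed the MZ-vs-DZ contrast needs roughly the real cohort's
629 twin pairs to be reliably detectable, which is itself a faithful
property of twin designs; Bray-Curtis is the default metric there
because its detection behaviour matched unweighted UniFrac at a fraction
of the cost. The acceptance script reports the same quantities at
reduced replicate counts (6–10) to stay fast; the test suite runs the
full replicate counts.

## Known limitations

- The default ABO tag table is a literature reconstruction, not a
  transcribed reference; real studies should supply their own.
- The LMM assumes Gaussian residuals after Box-Cox; heavily zero-
  inflated taxa below the prevalence filter would violate it (they are
  excluded by design).
- The analytic χ² p-values in the presence/absence scan are reported for
  diagnostics only and flagged when any expected cell is below 5; the
  permutation p is primary.
- Empirical p-values can be exactly 0; with N draws the smallest
  nonzero resolution is 1/N.
- `permute_family_ids` preserves family-label multiplicities, so
  "pairs" under that null are any two samples sharing a label; pair-level
  zygosity is undefined there and only the paired/unpaired distinction
  is used.
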
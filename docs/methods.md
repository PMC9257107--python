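# Methods

`tracegp` studies multi-trait genomic prediction of rice grain trace
elements (Cd, Fe, Mn, Cu, Zn) on simulated panels that reproduce the
statistical structure of a 250-accession diversity panel: ~36k post-QC
SNPs thinned to ~5k for the packaged fixture, linkage disequilibrium (LD)
decaying through r² = 0.1 around 250–300 kb, weak family structure, and
five traits with genomic heritabilities 0.62/0.50/0.35/0.21/0.14 and
genetic correlations 0.39–0.95. No real accession data are redistributed;
everything downstream is exercised on the simulator.

## Genotype simulator

Each haplotype is a mosaic over a pool of F founder haplotypes
(default F = 40). Walking left to right along a chromosome, the copied
founder switches between adjacent SNPs with probability
`1 − exp(−Δbp / ld_decay_halflen)`. The founder pool itself carries
ancestral LD: each founder is a latent Gaussian AR(1) along the
chromosome (autocorrelation `exp(−Δbp / ld_decay_halflen)`), thresholded
at the normal quantile of a per-SNP allele frequency drawn from
U(0.1, 0.9). Both layers are needed — mosaic copying over an LD-free pool
leaves only ~1/F background correlation between sites. Minor-allele
frequencies are kept ≥ 0.05 by re-thresholding the same latent field at
offending SNPs (this preserves local LD), and the combined process gives
an approximately exponential population r²(d).

The single scale parameter was calibrated once against the package's own
LD diagnostic: with `ld_decay_halflen = 800 kb`, mean r² in 25-kb distance
bins crosses 0.1 between 250 and 300 kb on 250-accession panels (the
realized decay rate is roughly 4× faster than the nominal half-length
because founder switching and ancestral decay compound, and thresholding
attenuates the latent correlation). Weak family structure comes from 10
full-sib clusters of 4, whose gametes recombine parental mosaics at
1 cM/Mb; the remaining accessions are unrelated mosaics. The number of
families is a guess exposed as configuration — the emulated panel is only
described as containing "several" families.

What the simulator does **not** emulate: population splits (no
indica/japonica subpopulation axis, only families), allele-frequency
spectra from real site-frequency data, multi-allelic sites, genotyping
error and missingness (QC handles missingness, the simulator never emits
it), and any environmental or GxE structure. Passing tests therefore
demonstrate correctness of the estimators under the model's assumptions
and realistic LD/kinship scales — not robustness to ecotype
stratification or assay artifacts.

## Phenotype simulator

Traits are simulated on a standardized scale (phenotypic variance ≈ 1,
mean 0), so the genetic covariance diagonal doubles as heritability; the
emulated study analyzes correlations, not concentration units, and its
phenotypes are single adjusted means per accession (field-design
adjustment is out of scope). Two architectures:

- **infinitesimal**: `g ~ N(0, Ψu ⊗ G)` drawn exactly through the
  eigendecomposition of the realized VanRaden GRM — model-matched, used
  for variance-component recovery experiments;
- **qtl** (default): `n_qtl = 50` loci per trait, 80% shared across
  traits with effect vectors drawn with the target genetic correlation,
  20% private, plus an infinitesimal tail carrying 30% of genetic
  variance. Because LD and private loci dilute cross-trait correlations,
  the genetic-value matrix is recolored across traits (empirical
  whitening followed by the target Cholesky) so the realized genetic
  covariance equals the target exactly in-sample; genetic values remain
  in the span of the sparse marker effects plus the tail, so GWAS has
  true positives to find.

Residuals are independent across traits and individuals (diagonal Ψε).
The five-trait fixture uses the printed heritability/correlation table;
that correlation matrix is mildly non-PSD as printed and is projected
once to the nearest PSD correlation matrix (eigenvalue clipping).

## Marker QC and LD

QC order: MAF ≥ 0.05, call rate ≥ 0.9, then windowed greedy LD pruning
(50-SNP windows, step 5; the later SNP of any pair above the r²
threshold is dropped, ties keep the lower map index). The default prune
threshold follows the emulated pipeline's printed value (r² > 0.01),
which is extreme; it is prominently configurable. The printed MAF
threshold ("0.5") is treated as a typo for 0.05. r² is the squared
Pearson correlation of dosage vectors; the decay diagnostic averages r²
in distance bins, smooths with a 3-bin running mean, and reports the
midpoint of the first bin below the cutoff that is never followed by a
re-crossing.

## Kernels

- **G** (additive): VanRaden method 1, `Z Z′ / (2 Σ p(1−p))` on dosages
  centered at 2p̂, frequencies from the same panel; monomorphic SNPs
  excluded.
- **H** (haplotypic): fixed-length windows of 2–5 SNPs partition each
  chromosome (non-overlapping, remainder forms a shorter window);
  the profile matrix counts each individual's copies (0/1/2) of every
  observed window haplotype; H is the VanRaden analogue on centered count
  columns, normalized by `2 Σ q(1−q)` over haplotype-allele frequencies.
  This normalization was chosen (over trace-scaling, also available)
  because it puts H's variance components on the same scale as G and
  makes H with 1-SNP windows coincide with G to machine precision — the
  additive model is exactly nested in the haplotype model. Rare
  haplotype alleles are kept; dropping them would break the row-sum
  invariant.
- **Mixed panel kernels** concatenate centered singleton-SNP dosage
  columns and centered block haplotype counts under a single joint
  normalization, so each reduction (no blocks / no singletons)
  reproduces G / H exactly.

All kernels are Gram matrices; a ridge of 1e−6 is added before any
solve because wide-panel Gram matrices at n = 250 are numerically
rank-deficient.

## Mixed models

**Single trait.** REML profiles the restricted likelihood to a 1-D search
in δ = σe²/σg² via the kernel eigendecomposition (bounded search on
log δ ∈ [−12, 12]; boundary solutions are flagged, e.g. noiseless data
drive ĥ² → 1). BLUP predictions for unobserved individuals use the
cross-covariance block. The Gibbs engine is the multi-trait sampler with
t = 1.

**Multi trait.** One Gibbs sampler covers the stacked model
`y = μ + u + ε`, `u ~ N(0, Ψu ⊗ K)`, `ε ~ N(0, Ψε ⊗ I)` with diagonal Ψε
(as in the emulated analysis; a full residual covariance is deliberately
not offered). Rotating `u` into the kernel eigenbasis turns the genetic
full conditional into n independent t×t Gaussian solves per sweep
(batched). Ψu updates by structure: per-trait scaled-inverse-χ²
(diagonal), inverse-Wishart (unstructured), or factor-analytic
`Ψu = ΛΛ′ + Π` with normal updates for loadings (k latent factors,
default 1, PSD by construction every sweep). Missing phenotype cells are
drawn from their full conditionals each sweep; this augmentation is what
makes auxiliary phenotypes of test-set individuals (the CV2/CV3 designs)
inform predictions. Priors, unstated in the emulated analysis, are
weakly-informative and proper: scaled-inverse-χ²(df 4, scale = half the
phenotypic variance) for scalar variances; inverse-Wishart(df t+2,
scale = 0.5·diag of phenotypic variances) for unstructured Ψu; N(0,1)
loadings. A near-flat inverse-Wishart is *not* offered: with latent u the
chain is then absorbed at the |ρ| = 1 boundary. The analysis-profile
chain length is 20,000 sweeps with 12,000 burn-in; cross-validation work
uses reduced chains (documented per experiment), no thinning, posterior
summaries over all post-burn-in sweeps. Fixing (Ψu, Ψε) turns the sampler
into a draw from the exact BLUP posterior, which the tests compare
against a dense closed-form solve.

**BMORS.** Two-stage stacking: per-trait GBLUP (stage 1; REML engine by
default — the stage-1 quantity is the BLUP mean, which REML computes
directly), with stage-1 values for observed individuals taken
out-of-sample from an internal 5-fold split of the training portion to
avoid leakage into stage 2 — whether the original procedure did this is
not stated; the out-of-sample reading was chosen deliberately. Stage 2 is
a per-target ridge regression of observed phenotypes on all t stage-1
prediction columns.

## Cross-validation designs

5 folds × 20 repeats (reduced repeat counts in desk-scale experiments);
accuracy is the Pearson correlation between predictions pooled over the
five test folds of a repeat and observed phenotypes — 20 values per cell
(a per-fold mode is available). The target trait is always hidden in the
test fold; the designs differ in auxiliary-trait visibility: ST-CV1
(hidden everywhere), MT-CV1 (training only), MT-CV2 (everywhere), MT-CV3
(test fold only). Models are compared with a paired t-test on per-repeat
accuracies (the compared cells share fold partitions; Welch mode
available). Relative gains are `100·(improved − base)/base`; the
reporting layer renders both rounded and truncated percentages because
published gain tables mix the two conventions.

## GWAS and selective panels

The association scan fits the null kernel model once per training set by
REML and then tests every SNP by generalized least squares with that
fixed covariance (the population-parameters-previously-determined
shortcut; exact per-SNP REML would be ~m times slower and changes p-values
negligibly here). The Wald statistic uses a t reference with n−2 df and a
per-SNP re-estimated residual scale, so with K = I the test reduces
exactly to textbook simple regression. TA-SNP selection takes the union
of (a) all SNPs with p < 0.01 and (b) the minimum-p SNP of every 300-kb
bin (anchored at position 0 per chromosome; anchoring shifts bins by less
than one width and is immaterial). Rule (b) is implemented literally — one
SNP per non-empty bin regardless of p — with a stricter
`only_bins_with_signal` variant. Chosen SNPs are chain-merged: adjacent
chosen SNPs on a chromosome with gap ≤ 300 kb join one block (a chained
block may span more than 300 kb end-to-end), blocks become haplotype
profiles, singletons stay as dosage columns, and both feed the mixed
kernel. Inside cross-validation the GWAS sees training-fold phenotypes
only; shuffling test-fold phenotypes provably leaves the panel unchanged.

## Desk-scale experiment sizes

The packaged recovery experiments are sized to run on one CPU in minutes,
as the package's standard configurations:

- heritability recovery: 20 replicates, n = 250, ~2,000 markers
  (generator defaults thinned), infinitesimal truth h² = 0.62, REML;
- correlation recovery: 10 replicates, two traits (h² 0.50/0.62,
  ρ = 0.95), MT-UN with 4,000/2,000 chains. At this design the posterior
  mean of ρ carries genuine downward shrinkage (~0.07): direct ML on the
  same replicates scatters from 0.73 to 0.98, and the proper
  inverse-Wishart prior (required, see above) pulls the bounded, skewed
  posterior slightly toward 0. The experiment reports the honest
  posterior summary rather than a debiased ratio;
- scheme ordering: 10 panel seeds × 4 repeats of 5-fold CV, target Zn
  (lowest h², strongest correlations), MT-UN with 800/400 chains;
  ordering MT-CV2 ≥ MT-CV3 ≥ ST-CV1 expected in ≥ 8/10 seeds.

## Known limitations

- The simulated diversity panel is *harder* than a structured breeding
  panel: most accession pairs are unrelated, so absolute ST-GBLUP
  accuracies for low-h² traits sit near zero rather than at the levels a
  real panel with ecotype structure shows. Scheme orderings and model
  contrasts, not absolute accuracies, are the supported comparisons.
- Multi-trait inference is MCMC-only (matching the emulated software
  lineage); there is no multi-trait REML.
- REML heritability at n = 250 on ~2,000 linked markers has a replicate
  SD of ~0.13 and a small positive ratio bias (~+0.03 at h² = 0.62),
  measured by simulation; means over 20 replicates inherit an SE of
  ~0.03.
- Haplotype models require fully phased, fully called genotypes; panels
  with sporadic missingness fall back to dosage kernels
  (mean-imputation, logged).
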
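# Methods

This note documents the statistical models behind each stage, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that a user extending the package
should know.

## Alignment handling

Sequences are restricted to {A, C, G, T, N, -}; IUPAC ambiguity codes are
collapsed to N on input (with a logged count) because every downstream
statistic treats a site as one of four nucleotides or missing. All column
coordinates in interfaces are 1-based inclusive. Cleanup removes an
explicit region mask (e.g. the AT-rich control region, which is prone to
assembly error) and, by default, every column containing a gap or N in any
sequence. The cleaned length is data-dependent output, never a constant.

Missing data inside a group are handled by **complete deletion**: columns
with N/- in the analysed group are excluded and `L_effective` records the
remainder. This makes π = K/L_effective, θ_W = S/(a₁·L_effective) and the
haplotype statistics internally consistent (haplotype identity compares
full cleaned sequences, so sequences differing only at removed columns are
identical by construction). Pairwise deletion is used only for the
distance matrices, matching standard practice for substitution-model
corrections.

## Diversity and neutrality statistics

Definitions are the classical ones for n haploid sequences: S = polymorphic
columns; singletons = columns with folded minor-allele count exactly 1 (no
outgroup polarisation is attempted); shared polymorphisms = S − singletons;
K = mean pairwise difference count (multi-allelic sites handled exactly
through per-column base counts); H and HD with the n/(n−1) correction;
Tajima's D with the e₁/e₂ normalisation. Statistics undefined on a
degenerate group (S = 0, or n too small for the variance normalisation)
are NaN sentinels, never 0, so summary tables cannot silently absorb
degenerate groups.

**Significance of D** is assessed against the fixed-S neutral null: a
standard-coalescent genealogy for n lineages with exactly S mutations
placed on branches with probability proportional to branch length. This
conditions on the observed number of segregating sites and avoids
estimating θ. Empirical p-values use the add-one correction
(1 + hits)/(1 + reps) so p is never zero. Note that the *conditional* mean
of D under this null is slightly negative (≈ −0.10 at n=20, S=30); that is
a property of fixed-S conditioning, not a bias of the sampler.

**Achaz's Y** removes the singleton classes from both estimators in the
Tajima-style difference. Because the spectrum here is folded, both
unfolded classes 1 and n−1 receive zero weight (folding cannot separate
them); the two estimators are then computable from minor-allele counts:
θ̂_π\* uses weights i(n−i) over classes 2..n−2, θ̂_W\* = S\*/(a₁ − 1 − 1/(n−1))
with S\* the singleton-free segregating-site count. The denominator is the
neutral-model SD of the numerator assembled from the Fu (1995) second
moments of the unfolded spectrum, with θ and θ² plugged in unbiasedly from
S\* (the θ² plug-in uses S\*(S\*−1)/(W² + Σσ), mirroring the S(S−1) device
in D's variance). A Monte-Carlo standardisation (SD of the numerator over
fixed-S replicates) is provided as a cross-check; on neutral data the two
denominators agree to within ~8%.

**Divergence and split times.** D_xy is the mean difference count over
cross-group pairs, with complete deletion over the union of the two groups
so D_xy, π_A and π_B share one effective length; net divergence
D_a = D_xy − (π_A+π_B)/2. Split times assume a strict clock:
t = d/(2μ) generations, divided by generations per year (default 10, the
usual figure for tropical anophelines). Pass D_a to correct for ancestral
polymorphism or raw D_xy for the uncorrected clock.

## Rarefaction

Diversity is standardised across unequal sample sizes by resampling each
group at sizes 3..min(50, n). Resampling is **with replacement** by
default — the procedure standardised here — with classical
without-replacement rarefaction as an option; the output labels which was
used. Under replacement, duplicate draws reduce H and HD of a subsample;
that is a direct consequence of the scheme and is left visible. Because
the intended spread convention differs between authors, both the replicate
SD and the Monte-Carlo standard error SD/√reps are emitted as separate
columns. Undefined replicate values (e.g. D at S=0) are excluded with a
logged count.

## Distances, AMOVA, FST, isolation by distance

Distance models use their closed forms (HKY85 is evaluated with the TN93
closed form, of which it is a special case; base frequencies are pooled
over the whole alignment, as in ape's `dist.dna`, against which the
implementation is tested). The gamma variant applies the standard
rate-heterogeneity transform −ln(w) → α(w^(−1/α) − 1); the shape defaults
to α = 1.0, is config-exposed, and is reported in output headers because
no canonical value exists for this marker. Saturated pairs yield NaN.

AMOVA follows Excoffier–Smouse–Quattro on squared distances: SSD_total =
Σ d²/N over pairs, partitioned into between-group, among-population and
within-population levels, variance components extracted from the expected
mean squares with unequal-sample-size coefficients, and
Φ_CT = σ_a/σ_total, Φ_SC = σ_b/(σ_b+σ_c), Φ_ST = (σ_a+σ_b)/σ_total.
Negative components are reported as computed and clamped to zero only in
the percentage display. The three permutation schemes are: samples among
all populations (Φ_ST), samples among populations within groups (Φ_SC),
whole populations among groups (Φ_CT). Pairwise F_ST is the two-population
Φ_ST from the same decomposition, with p-values by shuffling samples
between the two populations. Designs with singleton populations are
rejected; monomorphic data yield a NaN Φ (no differentiation signal), not
zero.

Isolation by distance correlates F_ST/(1−F_ST) (NaN sentinel at F_ST = 1)
with log₁₀ great-circle km (haversine, R = 6,371 km) between population
centroids, tested by a Mantel permutation of the geographic matrix
(rows/columns jointly; scikit-bio's implementation). One-sided positive
association is the default — IBD predicts a positive slope — with a
two-sided flag.

## Lineage delimitation

The p-distance matrix is embedded by Kruskal non-metric MDS (stress-1,
isotonic regression of embedded distances on dissimilarity ranks; best of
several random starts plus one classical-scaling start; the stored stress
is recomputable from the stored coordinates). Agglomerative clustering
(Ward on the embedding by default, average linkage on raw distances as the
alternative) cuts the samples into a *required, never defaulted-silently*
number of clusters. The cluster with maximal mean divergence from the rest
is labelled **cryptic**; with exactly two clusters that quantity is
symmetric, so the tie is broken towards the minority cluster (a divergent
introgressed lineage is the rarer one; in these data the cryptic lineage
is ~20–30% overall) and then towards the tighter cluster. Singleton
clusters are labelled outlier. Per-population frequencies are ordered west
to east by mean longitude to expose gradients.

The neighbor-joining tree uses the standard Q-matrix joins; negative
branch lengths are clamped to zero with the difference moved to the sister
branch, preserving the path length through the joined pair (scikit-bio's
NJ, which simply zeroes, is the cross-check on additive inputs).

## Endosymbiont read screen

Reads are matched to the marker panel by exact 15-mer seeds extended with
a local Smith–Waterman alignment (match +1, mismatch −1, gap open −2, gap
extend −1; numba kernel). Identity is matches over read bases consumed by
the local alignment; "length" means aligned length. A sample is infected
under a preset when ≥ min_reads passing matches share one panel record id
(a supergroup roll-up can be derived from record ids). Both presets —
strict (3 reads, 98 bp, 95%) and lenient (90 bp, 90%) — are evaluated in
one pass, and tightening any threshold can only shrink the infected set.
The matcher is deliberately transparent rather than a re-implementation of
any particular spliced-read mapper; only the acceptance thresholds are
normative. No claim is made about true infection biology — marker-matching
reads can originate from food or parasites.

## Kinship, LD pruning, PCA, x2y, GWAS

KING-robust kinship is allele-frequency-free:
φ = (N_het,het − 2N_opp,hom)/(N_het,i + N_het,j), computed over shared
non-missing variants (pairs below a configurable floor, default 1,000, are
skipped with a reason). Degrees use the standard powers-of-two ranges
(>0.354 duplicate/MZ; then 1st, 2nd, 3rd at successive halvings). Pruning
is greedy and deterministic: repeatedly remove the sample with the most
relationships at or above the threshold degree (default 2nd), ties broken
by ascending alpha-numeric id.

LD pruning slides base-pair windows (default 500 bp by 200 bp), dropping
the later variant of any retained pair with dosage r² ≥ 0.1, repeated five
passes or until stable; a SNP-count window convention is available by
flag. PCA covariates come from a random LD-pruned subset with Patterson
scaling (centre by 2p, scale by √(p(1−p))), top components z-normalised.

The **x2y** metric reports the percent reduction in prediction error from
a single-feature model (linear regression for continuous responses; a
one-split decision rule for categorical ones) over a baseline (mean /
majority class). Errors are estimated **out of sample** by 5-fold
cross-validation and the reduction is floored at 0: an in-sample threshold
rule chosen from ~n candidates reduces training error by ~12% on pure
noise at n = 200, which would make independent features appear associated;
cross-validation restores the calibration (null point estimate 0, 95%
bootstrap CI covering 0).

The **GWAS** regresses the binary lineage label on additive dosage plus
covariates (PCs, sex, infection status) by logistic regression, tested
with the likelihood ratio against the covariate-only model. Fits run as
Newton iterations batched across SNPs with the covariate block shared (the
implementation matches statsmodels per-SNP fits to ~1e-9 and a full 10k
scan at n=1,000 takes ~15 s on one CPU). Quasi-complete separation is
detected as a runaway dosage effect (|β| > 10 on the log-odds scale); such
variants are flagged non-converged and fall back to the 1-df score test at
the null fit. Genomic control uses λ = median(χ²)/0.4549; the significance
threshold is α divided by the number of independent (LD-pruned) variants.
Hits are annotated to genes whose CDS ± 1 kb (1-based inclusive) contains
them; intergenic hits get the nearest-gene distance.

## Synthetic data: what it does and does not emulate

The mtDNA generator draws haploid genealogies from msprime (no
recombination anywhere — mtDNA is maternally inherited) under island/split
demographies, with finite-site Jukes–Cantor mutations by default (an
infinite-sites mode exists); richer mutation models are unnecessary
because downstream distances support TN93 regardless of the simulator.
Sample coordinates are laid on a west-to-east axis with jitter so distance
gradients are meaningful. The cryptic scenario splits two lineages
t = 5×10⁵ generations ago (50 kyr at 10 generations/year) with μ = 10⁻⁸
per site per generation and haploid N = 5×10⁴ per lineage — values inside
the ranges reported for these species — giving between-lineage divergence
roughly ten times within-lineage diversity; the per-deme cryptic
frequencies default to (0.49, 0.31, 0.10), echoing the observed hybrid /
coluzzii / gambiae prevalences and keeping the planted lineage a clear
minority so the labelling rule is identifiable. The two-deme island helper
sets the pairwise migration rate to Nm/(2N), the convention under which
the equilibrium differentiation equals the classical haploid island value
1/(1+2Nm) (with the naive rate the two-deme expectation carries the
(d/(d−1)) correction instead).

The nuclear cohort uses Balding–Nichols per-deme allele frequencies at a
configurable FST, Hardy–Weinberg genotypes within demes, a logistic
phenotype with per-deme intercepts and log-odds-ratio effects at planted
loci, and gene-dropped relatives (duplicates, parent-offspring, full sibs,
half sibs). The read-set generator emits marker substrings with
independent per-base errors plus uniform-random background reads at
constant base quality.

None of this emulates selection, chromosomal inversions, sequencing-depth
heterogeneity, NUMT contamination, reference bias, or realistic error
profiles; passing tests demonstrate that the estimators and decision rules
are correct and calibrated under their stated models, not that the
biological conclusions for any particular dataset are robust to those
artefacts.

## Numerical conventions and problem sizes

All randomised procedures take explicit integer seeds and are
bit-reproducible; simulation seeds handed to msprime are drawn in
[1, 2³¹). The test suite runs its heavier checks at deliberately modest
problem sizes — 2,000 fixed-S replicates for neutrality calibration, 2,000
two-deme replicates per migration rate, 20 cryptic-scenario seeds, 500/200
read-screen samples, one 10k-SNP null scan plus 50 single-locus power
replicates at n = 1,000 — sizes at which every Monte-Carlo band in the
suite is comfortably wider than the corresponding standard error. The
acceptance script scales the same computations to about a minute of
runtime.

## Known limitations

* Tajima's D variance constants assume the biallelic infinite-sites model;
  at very high divergence finite-site effects perturb D slightly.
* The fixed-S null draws genealogies unweighted (mutations placed on
  branches proportionally to length); it does not reweight genealogies by
  their probability of producing S under a given θ, which is the other
  common convention for conditioning.
* The distance-based Φ_ST estimator is a ratio of variance components and
  sits a few percent below the coalescent expectation at small sample
  sizes (visible in the island-model checks); a frequency-only haplotype
  F_ST is available for sensitivity analysis.
* NJ, nMDS and clustering are deterministic given seeds, but cluster
  labels beyond cryptic/common/outlier are arbitrary.
* The GWAS assumes unrelated samples (run pruning first) and offers no
  mixed-model or saddle-point corrections.
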
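# mitopop

Population genetics of complete mitochondrial genomes, with a mitonuclear
association stage — built for studies of the *Anopheles gambiae* species
complex, where a divergent ("cryptic") maternal lineage segregates along a
west-to-east geographic gradient, but applicable to any haploid,
non-recombining alignment plus a nuclear SNP cohort.

The pipeline covers, end to end:

* **Diversity and neutrality** per group: segregating sites *S*, singletons,
  mean pairwise differences *K*, haplotype count *H* and diversity *HD*,
  nucleotide diversity π, Watterson's θ_W, Tajima's
  *D* = (K − S/a₁)/√(e₁S + e₂S(S−1)) with a coalescent p-value conditioned
  on the observed *S*, and Achaz's *Y* (a Tajima-like statistic whose
  estimators ignore singletons, robust to sequencing error), plus
  between-group divergence *D*<sub>xy</sub> and molecular-clock split times
  t = d/(2μg).
* **Rarefaction** of *S*, *H*, π, *D* and *Y* across sample sizes 3–50
  (resampling with replacement, 5,000 replicates by default).
* **Structure**: p/JC69/K80/HKY85/TN93(+Γ) distances, the three-level
  Excoffier–Smouse–Quattro AMOVA with Φ<sub>CT</sub>/Φ<sub>SC</sub>/Φ<sub>ST</sub>
  and permutation tests, distance-based pairwise F<sub>ST</sub>, and Mantel
  isolation-by-distance tests of F<sub>ST</sub>/(1−F<sub>ST</sub>) against
  log₁₀ great-circle distance.
* **Lineage delimitation**: non-metric MDS of the distance matrix,
  hierarchical clustering, per-population cryptic-lineage frequencies, and
  a neighbor-joining tree.
* **Endosymbiont screening**: reads vs a *Wolbachia* marker panel
  (k-mer-seeded Smith–Waterman), strict (≥3 reads, ≥98 bp, ≥95% identity)
  and lenient (≥90 bp, ≥90%) infection calls.
* **Mitonuclear association**: KING-robust kinship
  φ = (N<sub>het,het</sub> − 2N<sub>opp,hom</sub>)/(N<sub>het,i</sub> + N<sub>het,j</sub>)
  with greedy relatedness pruning, sliding-window LD pruning, PCA
  covariates (Patterson scaling), the x2y percent-error-reduction metric,
  and a per-SNP logistic GWAS of cryptic-lineage membership with
  likelihood-ratio tests, genomic-control λ, and a Bonferroni threshold
  over the number of independent SNPs.

A first-class synthetic-data module (`mitopop.simulate`, built on msprime)
generates every input the pipeline needs — structured-coalescent mtDNA
gene pools with an admixed divergent lineage, Balding–Nichols nuclear
cohorts with planted associated loci and pedigree relatives, and
marker-derived read sets — so the whole analysis is testable without any
download.

## Worked example

```python
from mitopop import simulate, structure as st, haplogroups as hg, diversity as dv

aln, truth = simulate.simulate_cryptic_scenario(seed=7)   # 90 samples, 3 demes
rec = dv.diversity_summary(aln, tajima_p_reps=200, seed=1)
dm = st.genetic_distance_matrix(aln, "p")
assign = hg.cluster_lineages(dm, n_clusters=2)
print(hg.lineage_frequencies(assign, aln.metadata))
```

prints (seed 7):

```
n=90 L_eff=15000 S=262 singletons=41 H=38 HD=0.962 pi=5.08e-03
thetaW=3.44e-03 D=1.62 (p=0.050) Y=1.59

population  n  n_cryptic  mean_longitude  pct_cryptic
      POP0 30         13      -15.030114    43.333333
      POP1 30         10      -10.060246    33.333333
      POP2 30          1       -5.082511     3.333333
       ALL 90         24             NaN    26.666667
```

The positive Tajima's *D* reflects the two-lineage mixture (an excess of
intermediate-frequency variants), and the recovered cryptic-lineage
frequencies fall west to east exactly as planted. Continuing,

```python
cry = assign.loc[assign.lineage == "cryptic", "sample_id"]
com = assign.loc[assign.lineage == "common", "sample_id"]
div = dv.between_group_divergence(aln, list(cry), list(com))
dv.split_time_estimate(div.da, mu=1e-8, generations_per_year=10)
```

gives *D*<sub>xy</sub> = 1.19 × 10⁻² per site (net divergence
1.13 × 10⁻²) and a clock estimate of ≈ 57,000 years — close to the
50,000-year split planted by the simulator, and the clustering matches the
simulated lineage labels exactly.

Each stage is also a CLI subcommand (`mitopop simulate | clean | diversity
| rarefy | amova | fst | ibd | haplogroups | wolbachia | kinship | gwas`),
reading FASTA/TSV/VCF/FASTQ and writing TSV/JSON.

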
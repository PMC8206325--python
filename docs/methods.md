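# Methods

This note documents the statistical models, estimators and simulator behind
`barrierpop`, the choices made where several defensible conventions exist,
and what the validation suite does and does not establish.

## Study design and data model

The unit of inference is the *plot pair*: an experimental plot bisected by a
road-type barrier (conventional road R, 4-lane highway H, or combined
barrier CB) matched to a control plot bisected by an unpaved track (T).
Within each plot, individuals carry a side label (A/B, arbitrary), a
sampling-point label (trap station) and planar coordinates in metres; a
Euclidean metric is assumed valid at plot scale (≤ 3 km). Genotypes are
unordered diploid allele pairs at a panel of microsatellite loci, integer
coded (fragment length in bp for real data, repeat index for simulated
data), stored sorted with `0` as the missing sentinel; a genotype is either
fully typed or fully missing at a locus. GenePop files are read through
biopython; 2- vs 3-digit allele encoding is auto-detected on read and
explicit on write. The sample table is authoritative for plot and side
membership, so GenePop POP blocks may group by plot or by plot-side.

## Quality control

* **HWE**: Monte-Carlo exact test conditional on allele counts (default
  10,000 shuffles of the gene-copy vector). A chi-square test is unusable
  with up to ~28 alleles per locus; the MC test ranks resampled genotype
  tables by their conditional probability 2^h / Πc! and reports the
  (b+1)/(B+1)-smoothed tail. Monomorphic loci return p = 1 with a flag.
* **LD**: log-likelihood-ratio G on the joint two-locus genotype table,
  permuting one locus across individuals.
* **Null alleles**: Brookfield estimator 1, r̂ = (He − Ho)/(1 + He), clipped
  at zero with an excess-heterozygosity flag.
* **Genotyping error**: duplicate-concordance rates. E1 counts
  heterozygote↔homozygote-sharing-one-allele discordances (allelic dropout
  pattern), E2 any discordance introducing a non-shared allele; denominators
  are comparable duplicate pairs per locus. This is a deliberate,
  transparent per-comparison estimator rather than a maximum-likelihood
  dropout model.
* **Full-sib removal**: within each sampling point, pairs with doubled
  Lynch–Ritland relatedness ≥ 0.35 are linked and connected components are
  treated as putative litters, of which one random (seeded) member is kept.
  0.35 is the midpoint between the full-sib (0.5) and half-sib (0.25)
  expectations; on simulated data it resolves ~90% of four-pup litters
  exactly while discarding < 5% of unrelated same-point pairs, and it never
  has to discard a whole litter (one member is always kept). Siblings at
  different sampling points are retained — only within-point litters distort
  local allele frequencies. This threshold clustering stands in for
  full-likelihood sibship reconstruction, which is outside this package's
  scope; its operating characteristics are measured in the test suite
  against simulator pedigree truth. Reference allele frequencies for all
  relatedness calculations are the unweighted mean of per-plot frequency
  vectors, so each plot contributes equally.

## Diversity

Per locus: Ho (fraction heterozygous), He = 1 − Σp², uHe = 2n/(2n−1) He,
allele count A, rarefied allelic richness
Ar(g) = Σ_i [1 − C(N−N_i, g)/C(N, g)] (hypergeometric expectation of the
allele count in g gene copies), and F_IS in the Weir & Cockerham
small-sample form (single-population reduction, f = 1 − Σc/Σ(b+c) over
alleles); the simpler 1 − Ho/uHe variant is available (`nei_fis`). Plot- and
side-level summaries average over loci with standard errors across loci
(n = number of loci). The rarefaction base is g = 2 × the smallest per-locus
typed sample over the units being compared, computed per locus — the
standard convention that makes Ar comparable across unequal samples. The
paired-design summary statistic is the absolute between-side difference
(*_DIF) of each metric, one value per plot; a Pearson correlation of every
*_DIF metric against plot sample size is reported as a sample-size-artefact
check.

Individual metrics follow the classical panel: PHt (proportion of typed
loci heterozygous), Hs_obs = PHt / mean Ho of the typed loci, Hs_exp =
PHt / mean uHe, internal relatedness IR = (2H − Σf_i)/(2N − Σf_i) with H the
homozygous-locus count and f_i the reference frequencies of the individual's
alleles, and HL = ΣE_hom/(ΣE_hom + ΣE_het) weighting loci by their reference
expected heterozygosity.

## AMOVA and Φ-statistics

Each plot gets a three-level partition of gene-copy distances: between
sides (σ²_a), among individuals within sides (σ²_b), within individuals
(σ²_c). The squared distance between two gene copies is the allele-mismatch
count over loci typed in both (missing loci dropped pairwise). Stratum sums
of squares come from the standard pairwise-distance identities
(SS_group = Σ_{i<j∈group} d²/n_group); components from nested-ANOVA expected
mean squares with the unequal-n coefficient n₀ for the among-sides stratum
(each individual contributes exactly two copies, so E[MS_among-ind] =
σ²_c + 2σ²_b). Negative components are retained, not truncated — Φ_ST may
legitimately be slightly negative in panmictic plots, and the all-
heterozygote limit gives Φ_IS = −1 (complete heterozygote excess); results
carry a flag when any component is negative. Φ_ST = σ²_a/Σσ², Φ_IS =
σ²_b/(σ²_b+σ²_c), Φ_IT = (σ²_a+σ²_b)/Σσ², satisfying
(1−Φ_IT) = (1−Φ_ST)(1−Φ_IS). σ_bw is the ratio of the between-sides to the
among-individuals-within-sides variance percentage.

Permutation p-values (default 999, seeded, (b+1)/(B+1)) use the
exchangeable unit appropriate to each statistic: whole individuals across
sides (Φ_ST), gene copies among individuals within sides (Φ_IS), gene copies
across the plot (Φ_IT). The permutation loop recomputes only the sums of
squares that the scheme can change, so it is O(copies²) per permutation.

The implementation is verified to 1e-10 against an independent brute-force
oracle that embeds gene copies as indicator vectors and computes every SS as
a deviation-from-centroid sum.

## Differentiation

The two sides are k = 2 subpopulations. Per locus, H_S and H_T use the
Nei–Chesser small-sample estimators (harmonic-mean ñ, observed
heterozygosity correction); the uncorrected parameter-scale variant is kept
behind a flag because the closed-form test vectors are defined on that
scale. Multi-locus values average H_S and H_T over loci before forming
ratios. From (H_S, H_T): G_ST, Hedrick's G′_ST, the standardized G″_ST and
Jost's D as in the README formulas. With H_S ≥ 0.8 and fixed frequency
divergence G_ST is strongly suppressed while G″_ST and D reach 1 — the
motivation for carrying the standardized measures with hypervariable
markers. FST is the AMOVA Φ_ST (permutation-tested by shuffling individuals
across sides); Weir–Cockerham θ is emitted alongside, clearly labelled. The
G-test sums per-locus log-likelihood-ratio statistics on side × allele
count tables; its p-value permutes pooled gene copies between sides.

## Mantel stage

The barrier hypothesis matrix is binary: 0 for same-side, 1 for
opposite-side pairs. The partial Mantel statistic is the first-order partial
correlation of the upper off-diagonal triangles,
r = (r_GB − r_GE r_BE)/√((1−r_GE²)(1−r_BE²)); the null distribution permutes
the barrier matrix's labels (simultaneous row/column), the simplest scheme
consistent with a hypothesis-matrix test. Both one-tailed (r > 0, the
directional barrier alternative) and two-tailed p are reported. Relatedness
matrices are treated as similarities — their Mantel r flips sign relative to
distance-based matrices under the same signal, which the treatment-level
summary preserves rather than hiding by conversion. Note the attainable
p-floor is a few parts in B+1, not exactly 1/(B+1), because label
permutations that swap the two side blocks wholesale reproduce the observed
barrier partition.

## Inference layer

Candidate metrics are pruned greedily in a declared priority order (the
canonical non-redundant set Ho, uHe, Ar, their *_DIF counterparts, σ_bw,
FST, G″_ST, r_Gd, r_Dps, r_Lrm), dropping any metric with Pearson |r| ≥ 0.80
against an already-retained one. Paired t-tests run on within-pair
differences, oriented experimental − control. Hedges' g = (mean d / sd d)·J
with J = 1 − 3/(4·df − 1), df = n_pairs − 1; its 95% CI resamples pairs with
replacement (999 resamples, seeded), BCa where defined with a percentile
fallback. Magnitude labels: |g| < 0.2 negligible, 0.2–0.5 small, 0.5–0.8
medium, > 0.8 large; f²: 0.02–0.15 small, 0.15–0.35 medium, ≥ 0.35 large.
The mixed model is a REML random-intercept fit value ~ Type + (1 | pair id)
with the control level T as reference; its Cohen's f² uses the marginal-R²
difference between full and reduced models, (R²_f − R²_r)/(1 − R²_f), with
marginal R² = var(Xβ)/(var(Xβ) + σ²_pair + σ²_resid). Age/Width effects are
simple regressions of within-pair differences on the highway subset (the
only treatment with contrasting ages and widths), f² = R²/(1 − R²), after a
Pearson collinearity check between Age and Width. No multiple-testing
correction is applied across metrics, matching the design's
effect-size-first reporting.

Relatedness estimators: symmetrized Queller–Goodnight (ratio of locus sums,
averaged over the two reference directions), Ritland's kinship-based moment
estimator (locus weights A_l − 1), and the weighted Lynch–Ritland estimator
(locus weights equal to the regression denominator over 2 p_a p_b,
symmetrized). The Lynch–Ritland value is reported doubled, matching the
common half-scale spreadsheet convention, so all three estimators share the
expectation 0.5 for parent–offspring and full-sib dyads; negative estimates
are informative and never truncated. Loci where the reference frequency of
an observed allele is missing use a small pseudo-frequency; fixed loci are
skipped.

## Simulator

Each plot holds two monoecious Wright–Fisher demes. Generation t has size
N_peak inside peak windows ((t−1) mod cycle_length < peak_width) and N_low
otherwise. An offspring draws two distinct parents from the opposite deme
with probability m_eff(t) = min(0.5, m·b·(ρ in peaks)) — b is the barrier
factor (1 for controls and null landscapes, 0 for a sealed barrier), ρ ≥ 1
the peak migration pulse. Each transmitted allele mutates with probability μ
by ±1 repeat with reflecting bounds on [1, K]. All plots are founded from
one shared symmetric-Dirichlet frequency draw per locus, mimicking regional
homogeneity; per-plot randomness comes from independent spawned streams so
plots are statistically independent. Sampling takes a without-replacement
draw per side, uniform coordinates in each side's 2500 × 1500 m rectangle,
and snaps capture points to a trap grid; optional full-sib litters
(Mendelian draws from two simulated parents) are appended at a sampling
point with truth records.

Default preset: 15 pairs (6 R, 6 H, 3 CB), 9 loci, K = 30,
α_Dirichlet = 0.3, N_low = 50, N_peak = 1000, cycle 4, peak width 1, G = 21,
m = 0.2, ρ = 2, μ = 5×10⁻⁴, 15–40 samples per side. These land sampled
diversity (uHe ≈ 0.8) and between-side Φ_ST (≈ 0) in the ranges typical of a
well-connected cyclic vole population; barrier age/width attributes per
treatment are plausible round numbers, since only their within-treatment
contrasts matter. The simulator does not model continuous-space dispersal,
selection, sex-biased dispersal or overlapping generations; passing tests
therefore demonstrate correctness of the estimators and calibration of the
tests under an idealized island-like demography, not robustness to every
spatial pattern of real landscapes.

## Validation experiments and problem sizes

The simulation experiments (shared by the test suite and
`scripts/acceptance.py`) use reduced problem sizes chosen to run in minutes
on one CPU:

* **Permutation-test calibration**: 200 independent panmictic plots
  (m_eff = 0.5 — the no-barrier null for a within-plot test is one deme
  arbitrarily split in two), shallow history (G = 8, N 40/160 boom–bust),
  12 samples per side, 199 permutations; rejection counts at α = 0.05 are
  checked against the exact binomial 95% band. The landscape-level null
  uses b = 1 (experimental and control exchangeable, sides may retain the
  slight substructure of finite migration): 100 landscapes × 15 pairs, full
  metric pipeline, paired t-tests pooled over the 12 canonical metrics.
* **Barrier recovery**: b = 0, μ = 0, constant N = 100 per deme, 50
  post-barrier generations, control migration m = 0.05, 20 samples per
  side — 100 single pairs for the Φ_ST ordering check and 50 landscapes of
  15 pairs for detection power.
* **Relatedness recovery**: 500 dyads per relationship from the default
  ancestral pool.
* **Drift–migration equilibrium**: two demes of N = 100, m = 0.01, μ = 0,
  400 generations, 100 replicates; the pooled Nei–Chesser G_ST is compared
  with the island-model form 1/(4Nm(k/(k−1))² + 1), k = 2. The comparison
  deliberately uses the G_ST-family estimator and a small m: the closed form
  is the total-vs-within (G_ST-type) definition and a small-m limit — the
  exact two-deme coalescent solution shows θ-style estimators (Φ_ST)
  converge to a different constant (factor k/(k−1), not squared) and that at
  m ≳ 0.05 the approximation itself degrades by ~15%.

## Degenerate inputs and numerical conventions

Monomorphic plots make FST/Φ undefined and raise; monomorphic loci within a
polymorphic plot are simply uninformative. Exactly-zero among-individual
variance (possible in small samples with discrete distances) leaves σ_bw
undefined; pipeline-level consumers skip the affected pair rather than
fabricate a value. All permutation/MC p-values use (b+1)/(B+1) and every
stochastic routine takes an explicit seed; landscape-level functions spawn
per-plot child streams from one master seed. Oracle comparisons in the test
suite use an absolute tolerance of 1e-10; closed-form spot checks use the
printed precision of the value.

## Known limitations

The headline field result this machinery was built around (no detectable
road-barrier effect in ~1700 genotyped voles) cannot be recomputed from raw
data here because those genotypes are not deposited; the package instead
reproduces the published plot-level summary statistics exactly through its
inference layer and validates everything upstream of them on simulated
ground truth. The sibship filter is a calibrated proxy, not a pedigree
reconstruction; E1/E2 are concordance rates, not ML estimates; the
G″_ST/D estimators average H_S, H_T over loci (not harmonic-mean-of-D
pooling); and the partial Mantel test uses raw-matrix label permutation,
which is known to be slightly anticonservative under strong spatial
autocorrelation.
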
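# Methods

`hlapop` re-implements, as a tested library plus CLI, the statistical
machinery of a population-immunogenetics study of the HLA region: haplotype
frequency estimation from unphased diploid genotypes, linkage-disequilibrium
block and conserved-extended-haplotype (CEH) statistics, forensic diversity
metrics, rule-based ancestry assignment of blocks, a permutation statistic
for non-overlapping allele associations, inter-population distance/tree/PCA
analyses, and diversity-vs-geography regressions. This note records the
models, the defaults and why, the numerical choices, and the limits of what
the synthetic tests demonstrate.

## Nomenclature and resolution

Alleles use the colon-delimited field convention (`A*31:01:02:01`), with
expression/annotation suffixes (`L`, `N`, `e1`) retained on parse. DRB3,
DRB4 and DRB5 are one composite analysis locus, `DRB3/4/5`, whose alleles
keep their gene prefix; the structural absence of all three paralogues on a
chromosome is the allele-like state `NULL`. The default analysis resolution
is two fields: sub-alleles aggregate onto their two-field parent and
suffixes are ignored for identity (both configurable). Truncation never
pads, is idempotent, and drops a suffix when the field it annotates is
removed.

## Haplotype frequency estimation

Two routes are combined, as is standard for HLA cohorts that contain a
minority of families:

* **Family segregation counting.** In a parent/parent/child trio the
  maternal/paternal origin of the child's alleles is resolved locus by
  locus. When the assignment is unique at every locus, the two transmitted
  and two untransmitted parental chromosomes are each counted once. A trio
  with any ambiguous locus contributes nothing (left to EM, never guessed);
  a child allele absent from both parents is reported as a Mendelian
  inconsistency and the trio is dropped.
* **Expectation-maximization.** Genotype-likelihood EM over the set of
  haplotypes compatible with at least one subject (a subject with h
  heterozygous loci contributes 2^(h−1) unordered pair configurations). The
  E-step distributes each subject's unit mass over its compatible pairs
  proportional to 2·f_i·f_j (f_i² when homozygous); the M-step renormalizes
  expected chromosome counts. Candidates below a pruning threshold (default
  1e-7) are dropped between iterations, as haplotype-EM implementations
  commonly do to keep the candidate set tractable. The log-likelihood is
  asserted non-decreasing every iteration; convergence is a log-likelihood
  change below 1e-7 (default), capped at 1000 iterations. Because the
  likelihood is multimodal under strong LD, the best of 5 seeded restarts
  (uniform start plus Dirichlet draws) is returned, ties broken by
  log-likelihood then lexicographic haplotype order.

The hybrid estimate enters family-resolved chromosomes as fixed counts and
spreads the EM mass over the remaining chromosomes:
final frequency = (fixed count + EM frequency · EM chromosomes) / total.

The EM is validated against a brute-force likelihood grid (0.02-step walk of
the 3-simplex for 4-haplotype pools): at n = 200 subjects the mean absolute
error against the grid optimum stays below 0.03, and the error against the
generating pool shrinks as the cohort grows (tested at n = 50/200/800).

## Linkage disequilibrium and blocks

For units A and B (alleles, or whole sub-haplotypes treated as composite
alleles) with haplotype frequency h and marginals pA, pB over 2N
chromosomes:

* Δ = h − pA·pB.
* Δ′ = Δ/Δmax (Lewontin), Δmax = min(pA(1−pB), pB(1−pA)) for Δ > 0 and
  min(pA·pB, (1−pA)(1−pB)) for Δ < 0; clamped to [−1, 1] against rounding;
  Δ = 0 maps to Δ′ = 0.
* p — two-sided Fisher exact test on the 2×2 chromosome table (carrier vs
  non-carrier), valid at the small counts block tables contain; a chi-square
  option exists for comparison.
* t = Δ/SE(Δ) with Var(Δ) = [pA(1−pA)pB(1−pB) + Δ(1−2pA)(1−2pB) − Δ²]/2N.
  This is a documented variant: published block tables in this field often
  print a sample-size-adjusted t whose exact formula varies by author; the
  variant here is validated qualitatively (|t| grows with |Δ| and with 2N)
  and the conventional significance threshold t ≥ 2.0 is exposed as a
  configurable cutoff.

All statistics are computed from unrounded count ratios, never from
4-decimal printed frequencies; comparisons against published 4-decimal
tables tolerate ±0.005. Block scans marginalize a haplotype table onto the
block loci, drop haplotypes seen fewer than `min_count` times (default 2,
the "found more than once" convention), and order rows by descending
frequency then name. CEHs (e.g. B~C against DRB1~DQB1) and their HLA-A
extension reuse the same pair statistics with sub-haplotypes as composite
alleles.

## Diversity metrics

Per locus: observed heterozygosity OH (fraction of heterozygous subjects);
expected heterozygosity EH = 1 − Σp² (the unbiased 2N/(2N−1) factor is an
option, off by default because published EH tables in this field are
reproduced by the plain estimator); PIC = 1 − Σp² − Σ_{i<j}2p_i²p_j² via the
identity Σ_{i<j}2p_i²p_j² = (Σp²)² − Σp⁴; PD = 1 − ΣG² over observed
genotype frequencies (forensic convention; an HWE-expected variant is
provided). PIC < EH strictly for any polymorphic locus.

The Hardy-Weinberg test is a seeded Monte-Carlo exact test: the 2N allele
copies are shuffled into N random genotypes (default 10⁴ steps), the
heterozygote count is compared two-sidedly with the observed value, and the
p-value doubles the smaller tail with the usual +1 correction. Measured
type-I error at α = 0.05 over 200 seeded replicates (n = 100, four alleles)
is 0.06, inside 3 SE of the nominal level; under whole-haplotype inbreeding
F = 0.5 at n = 200 the test rejects in ≥ 90% of replicates and OH < EH as
expected. A monomorphic locus returns p = 1 with a warning.

## Ancestry assignment (MPA) and aggregate block frequencies (ABF)

A block receives a continental label (NativeAmerican, European, African,
Asian) when its frequency reaches a threshold (default 1%) in at least one
reference panel of that group; among qualifying groups the highest
supporting panel frequency wins, with the fixed precedence NativeAmerican >
European > African > Asian breaking exact ties (the conflict rule is not
dictated by published practice; this one is deterministic and documented).
Panels of admixed populations never confer a label: a block found only there
is NotPreviouslyReported for the four-group accounting, with the admixed
evidence kept in the supporting-panel list. Block lookups truncate to
two-field resolution and match on the block's own loci. ABF(label) is the
summed study frequency of blocks with that label; conservation
Σ_labels ABF = total included mass holds exactly, and raising the threshold
can only move labels toward NotPreviouslyReported.

## Non-overlapping associations

For chromosome-level allele pairs of two loci, the directional best-partner
mass is f(X→Y) = Σ_a max_b h(a,b); the score symmetrizes as the larger
direction and is chance-corrected, f*adj = (f* − e)/(1 − e), where e is the
value expected under exact independence from the marginals (the modal
partner of every allele is then the globally modal allele of the other
locus, so e is the larger of the two marginal maxima; a degenerate e = 1
yields f*adj = 0). Significance is a seeded permutation null: one column is
shuffled (5000 draws by default; both allele-frequency marginals are
preserved exactly by construction) and z = (observed − null mean)/null sd is
the ranking quantity — the score's absolute calibration cancels out of z. A
master seed spawns per-pair child seeds so adding a locus pair does not
perturb the other nulls; a zero-variance null yields a +∞ sentinel with a
warning, which happens naturally at near-monomorphic loci. On synthetic
cohorts with a rigid one-to-one B~C pairing and loose class I-class II
coupling, the B~C z is extreme (> 10) and outranks every class I-to-class II
pair, while fully independent loci stay within |z| < 3.

## Population structure

Nei's DA distance, DA = 1 − (1/L)·Σ_loci Σ_alleles √(x_i y_i), over a shared
allele universe (outer join on two-field names, absent = 0; a source vector
summing below 0.995 is renormalized with a warning). Neighbor joining is the
standard Saitou-Nei agglomeration with a deterministic tie-break (smallest
Q, then the lexicographic pair of node labels, an internal node labeled by
its smallest leaf) so the topology is invariant to input order; negative
branch lengths are clamped to zero. Bootstrap support resamples alleles
within loci with replacement — with as few as three loci the classic
resample-loci unit is degenerate — recomputes DA and NJ (default 1200
replicates), and reports the fraction of replicates containing each internal
bipartition, written as internal node labels in the newick output. NJ is
verified to recover random additive trees up to eight taxa, with an
exhaustive all-15-topology least-squares oracle at five. PCA is the
column-centered SVD of the concatenated per-locus frequency vectors, not
scaled (frequencies share units); explained-variance fractions are
non-increasing and sum to one.

## Diversity vs geography and pathogen richness

Distances are summed great-circle legs (haversine, mean Earth radius
6371 km) from Addis Ababa through land-migration waypoints to each
population. The five default waypoints (Cairo, Istanbul, Anadyr, Anchorage,
Panama City) approximate an Africa exit, a Eurasian hub, Beringia and two
American relays; the table and the per-region routing map are explicitly
replaceable inputs, not claims about the historical routes. The response is
logit(PIC); models are ordinary least squares on an intercept, distance and
one richness covariate, with t-based 95% CIs, two-sided p-values, R², and a
Bonferroni family equal to the number of models in the run (locus ×
richness-covariate, 6 by default). A singular design raises a collinearity
error naming the dependent columns.

Outliers are removed in a single pass (no re-iteration): a population is
excluded when its logit(PIC) at ANY analysis locus is beyond mean ± 2 SD for
that locus. Because this trims the tails of the response, it measurably
attenuates a genuinely strong slope (selection on the response); the
coefficient-recovery calibration is therefore stated for the untrimmed fit,
and the attenuation is itself a tested property. On noise-free scenario data
the fit interpolates the generating coefficients to 1e-8 with R² = 1; under
noise the slope CI covers the truth at ≈ 95% across seeded replicates.

## Synthetic data: what it emulates, and what it does not

`SyntheticConfig` draws a diploid cohort from a small pool of nine-locus
haplotypes in strong LD. Defaults mirror an isolated, partly consanguineous
community: 218 unrelated subjects plus 12 parent-parent-child trios,
inbreeding F = 0.05 implemented as whole-haplotype identity-by-descent
copying (the second chromosome duplicates the first with probability F —
a population-level reading of consanguinity that preserves multi-locus LD,
unlike per-locus copying), and a 2% scramble rate under which a sampled
chromosome recombines two pool haplotypes at a uniform crossover point.
Trio children inherit one parental chromosome each, without recombination.
The default pool of 14 haplotypes carries the block structure typical of
such a population — rigid B~C and DRB1~DQ coupling, one European and one
African admixture haplotype, an Asian-traceable class I block — with
ancestry labels used by the panel generator (multinomial resamples of each
ancestry's sub-pool). A fixed seed yields byte-identical cohorts.

What the generator does **not** model: mutation, coalescent/demographic
history, genotyping error or ambiguity, missing data mechanisms, sex
chromosomes, or realistic allele-frequency spectra beyond the pool. Passing
tests therefore demonstrate the correctness and calibration of the
estimators under the stated generative model, not robustness to the
artefacts of real typing data.

`GeoScenario` generates per-population covariates and per-locus PIC with
logit(PIC) = b0 + b1·distance + b2·richness + N(0, sd), defaults n = 122
populations, b1 = −5e-5 per km (diversity lost with distance), b2 = 0,
sd = 0.15 on the logit scale — a strong but realistic distance signal.

## Determinism and numerics

Every stochastic operation takes an explicit seed (numpy `default_rng`;
`SeedSequence.spawn` for per-pair child streams). Pipeline outputs embed the
seed and an input/settings checksum (the output directory is excluded from
the hash) so identical inputs re-produce byte-identical tables. Frequencies
are validated to sum to 1 within 1e-6; count/frequency consistency within
0.5/2N; Δ′ is clamped against floating-point overshoot; EM monotonicity is
asserted at 1e-9 tolerance.

## Test problem sizes

The suites run the stochastic checks at reduced but statistically meaningful
sizes, chosen once as the package's own test conditions: HWE calibration at
200 replicates × 1000 shuffle steps (n = 100 subjects), permutation nulls at
400 draws (5000 remains the analysis default), bootstrap at 50–100
replicates (1200 remains the default), EM-vs-grid at n = 50 and 200 with a
0.02 simplex grid, GLM coverage at 150–200 replicates. The full suite
completes in well under a minute on one CPU.

## Known limitations

* The t statistic is a variant, not a reproduction of any specific published
  block-table t; only its qualitative behavior is guaranteed.
* The f*adj operationalization is one of several reasonable readings of the
  non-overlap score family; conclusions should rest on the permutation z.
* EH/PIC values printed in published summary tables are occasionally
  irreproducible from the same publication's allele tables (dataset-size
  mismatches); only reproducible rows are asserted.
* MPA labels depend entirely on the reference panels supplied; the bundled
  synthetic panels demonstrate the mechanics, not real ancestry.
* The KIR-ligand table is a small editable lookup, not residue-level logic;
  alleles absent from it are counted as "none" with a warning.
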
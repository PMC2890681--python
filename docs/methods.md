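# Methods

## Problem setting

Commercial sugar-beet (*Beta vulgaris* ssp. *vulgaris*) varieties are F1
hybrids produced by pollinating a diploid cytoplasmic male-sterile (CMS)
mother line with a selected father line — diploid fathers give diploid
varieties, tetraploid fathers give triploid ones. A variety is therefore a
*mixture* of genotypes, not a clone, and morphological distinctness testing
is hard. Microsatellite (SSR) panels address this: a few dozen plants per
variety are genotyped at a common set of loci, and varieties are compared
through the resulting allele pools.

Because plants of different ploidy are scored in the same panel and allele
dosage cannot be read reliably from fragment intensities, genotypes are
reduced to the **allelic phenotype**: the set of distinct alleles observed
per plant per locus (AAB and ABB both record as AB). ssrkit implements the
whole analysis chain on this representation, plus a codominant
re-interpretation restricted to diploid plants, and a forward simulator of
the breeding system so every estimator can be exercised against known
ground truth.

## Data model and scoring

A panel is plants × loci with per-locus call *sets*; an empty amplification
is a distinct missing state, never conflated with a monomorphic call.
Missingness is handled per (plant, locus): a dropout removes that plant
from that locus only, never the whole row. Allele labels (`a`, `b`, ...)
are attached to fragment lengths either in first-seen order or by
calibration against designated reference varieties (labels ascending by
length over the lengths seen in the references; non-matching lengths keep
provisional `?<length>` labels and are reported). Calibration requires an
*exact* length match by default — the laboratory workflow this mirrors bins
against reference alleles run in every batch, so a tolerance is
deliberately not applied unless configured.

Codominant scoring assumes diploidy and no null alleles: one observed
allele → homozygote (x, x); two → heterozygote (x, y). Plants from
declared-diploid varieties with ≥3 distinct alleles at any locus are
classified `suspected_triploid` (the signature of stray tetraploid pollen);
such loci are masked per plant for codominant statistics, keeping the
plant's clean loci. For the paired dominant-vs-codominant comparison the
suspected triploids are excluded entirely so both scorings see identical
plants; this whole-plant rule is the package's choice — the appropriate
exclusion rule is not fixed by the field's practice, and per-locus masking
is the least destructive default everywhere else.

## Diversity statistics

Frequencies come in two modes. Dominant mode counts *carriers*:
p_i = (plants carrying allele i) / Σ_j (plants carrying allele j), the only
frequency notion available without dosage and the one that stays meaningful
across ploidy levels. Codominant mode counts allele copies among scored
diploids, p_i = copies / 2n.

From a frequency vector: gene diversity He = 1 − Σp_i²; effective number of
alleles n_e = 1/Σp_i², so n_e = 1/(1 − He) exactly (asserted to 1e-12);
allelic richness by hypergeometric rarefaction
Ar(g) = Σ_i [1 − C(N−N_i, g)/C(N, g)]. The optional small-sample factor
2n/(2n−1) on He is off by default. An allele is *rare* within a variety
when carried by fewer than 10 % of its scored plants (≤2 of 30);
"rare" has no canonical definition for such panels, and the 0.10 carrier
fraction is this package's configurable default.

## Hierarchical F-statistics

The estimator family is gene-diversity based, because the dominant mode is
defined only through allele-presence frequencies. Per locus:
Ho = mean within-group observed heterozygote fraction (codominant only),
Hs = mean within-group 1 − Σp_i², Ht = 1 − Σp̄_i² on the unweighted mean of
group frequency vectors. Coefficients: Fis = 1 − Ho/Hs, Fst = 1 − Hs/Ht,
Fit = 1 − Ho/Ht, satisfying (1−Fit) = (1−Fis)(1−Fst) identically (tested to
1e-9). Undefined coefficients (monomorphic loci) are reported as missing,
never coerced to 0.

Multilocus coefficients are ratios of summed numerators and denominators
(not means of ratios) — the jackknife-stable convention. Uncertainty is a
delete-one-locus jackknife; the reported mean is the average of the L
delete-one estimates and SE = sqrt((L−1)/L · Σ(θ_(l) − θ̄)²).

Significance of Fst comes from permuting whole plants among groups (all
loci move together, group sizes preserved), with
p = (1 + #{permuted ≥ observed}) / (1 + n_permutations); default 999
permutations, seeded.

Options: Nei & Chesser small-sample corrections
(Hs′ = ñ/(ñ−1)·(Hs − Ho/2ñ) with ñ the harmonic-mean group size,
Ht′ = Ht + Hs′/ñs − Ho/2ñs) for codominant data — used where estimator bias
matters, e.g. parameter-recovery checks, since the uncorrected Hs is biased
low by the factor (2n−1)/2n; and Weir & Cockerham's θ as an alternative
codominant estimator. Exact algebraic identities are guaranteed only for
the uncorrected gene-diversity estimators.

Note that published per-locus Fst/Fis values for panels of this kind depend
on the scoring conventions and ploidy weighting of the original analysis
software, which are generally not recoverable from summary tables; this
package therefore certifies its estimators against internal identities,
independent oracles and simulation recovery rather than against printed
per-locus values.

## Distances, trees, ordination, assignment

Jaccard distance d = 1 − |A∩B|/|A∪B| over (locus, allele) presence columns
ignores absence/absence agreement — important because dominant scoring
inflates shared absences. Columns of a locus missing in either member of a
pair are skipped; a pair with no co-scored locus is undefined (NaN, with a
warning, and a −1 sentinel in the PHYLIP writer). Variety-level profiles
are presence unions over plants (any carrier ⇒ present), the minimal
dominant consensus; a carrier-frequency-threshold variant can be built from
the frequency tables if needed.

Neighbour-joining uses scikit-bio's Saitou–Nei implementation; negative
branch lengths are retained as computed (optional clamp), and Q-criterion
ties resolve deterministically in input label order (scikit-bio's
first-minimum scan). NJ is exact on additive matrices — asserted to 1e-9 on
random additive matrices in the tests.

Principal coordinates use Gower double-centering of −½d² and a symmetric
eigendecomposition; coordinates are eigenvectors scaled by √λ for positive
eigenvalues, and negative eigenvalues are *reported unaltered* as the
diagnostic of non-Euclidean input.

Variety assignment: for each plant the k = 10 most similar partner plants
panel-wide (similarity 1 − Jaccard, self excluded); the plant is assigned
to the majority variety among partners, ties broken by summed similarity.
Aggregating partner origins per source variety gives the
similarity-by-assignment matrix Sa[x, y] (rows sum to 1).

## The simulator

The generator emulates the breeding system, not the laboratory: per locus a
skewed base frequency vector (Dirichlet with concentration 0.25, chosen to
reproduce the observed pattern of many low-frequency alleles — effective
allele numbers of 2–4 despite up to 21 alleles); per breeder a pool drawn
around the base by a Balding–Nichols Dirichlet at `breeder_divergence`; per
variety a mother line and a father line drawn around the breeder pool at
`line_divergence` (with `paired_pools=False` the two collapse, making each
variety a single random-mating island — the island-model configuration).
Diploid plants get one maternal + one paternal allele per locus; triploids
get one maternal allele plus two from a simulated autotetraploid father
(four independent pool draws, two retained without replacement, i.e. no
double reduction). Pools are infinite gamete sources: no drift within a
seed lot, no mutation, no linkage.

Defaults are the reference study conditions: the published 40-variety
layout (11 diploid, 29 triploid, with their breeders) × 30 plants × 12 loci
with the published per-locus allele counts (3–21). Divergence defaults are
`breeder_divergence = 0.06` (the published among-breeder differentiation)
and `line_divergence = 0.15` (between the published triploid 0.100 and
diploid 0.232 among-variety values). Artifact defaults: dropout 0.01
(dropouts are a documented feature of such data), null alleles and
contamination 0 — they are switched on explicitly per experiment.

Artifacts: a null allele is an extra invisible allele segregating at the
configured frequency (visible frequencies rescaled); a plant whose whole
call is null becomes a dropout. Contamination re-sires a diploid-variety
seed with a tetraploid donor drawn from a random triploid variety's father
line, producing a true triploid inside a declared-diploid variety. Ground
truth (pools, gametes, true ploidies, artifact assignments) is emitted
alongside the genotypes, and every run is byte-reproducible from
(config, seed).

What the simulator does *not* emulate: stutter/sizing errors and allele
binning noise, linkage, selection, finite parental pools, multi-generation
crossing schemes, and dosage information. Passing tests therefore certify
the statistics under the idealised breeding model, not the electrophoresis
process.

## Verification strategy and known behaviour

* Exact oracles: Jaccard vs naive per-pair set computation (100 random
  masked matrices, exact); NJ path-length recovery on random additive
  matrices (1e-9); jackknife vs explicit delete-one enumeration (1e-12);
  rarefaction vs brute-force enumeration of all C(N, g) draws.
* Parameter recovery: island-model panels (40 varieties × 30 plants × 12
  loci) at target Fst 0.2 recover a corrected multilocus Fst within 0.04
  over 100 replicates.
* Calibration: the permutation test's type-I error at α = 0.05 is within
  two binomial standard deviations of nominal over 500 null datasets
  (small panels: 4 varieties × 10 plants × 3 loci, 199 permutations each —
  sizes chosen to make the 500-replicate calibration cheap).
* Mechanisms: paired mother/father pools yield mean codominant Fis < 0
  (hybrid heterozygote excess — algebraically Ho − Hs = ¼Σ(p_m − p_f)² ≥ 0
  in expectation); null-allele injection at 0/0.1/0.2 inflates apparent
  Fis monotonically; tetraploid-pollen contamination at rate 1/6 in
  30-plant diploid varieties flags ≈5 suspected triploids per variety
  (slightly under 5 × detection < 1, since a contaminated triploid shows a
  third allele at ≥1 of 12 loci with probability ≈0.9 under default
  divergences).
* The uncorrected codominant Fis centres near −1/(2n) under panmixia (the
  known small-sample bias of plug-in Hs); the corrected estimator centres
  on 0 and is the one used in recovery checks.

## Numerical and degenerate-input choices

Frequencies are exact ratios of integer counts; no smoothing. Groups with
an all-missing locus are dropped from that locus's Hs/Ht means. Distances
for pairs with no co-scored locus, coefficients with zero denominators, and
correlations over <3 paired loci are errors or NaN, never silent zeros.
Permutation p-values can never be 0 by construction. All randomness flows
from a single `numpy` Generator seeded explicitly; identical seeds give
identical outputs including emitted files.
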
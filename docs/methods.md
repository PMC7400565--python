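# Methods

This note documents the statistical models implemented in `popkit`, the
assumptions behind them, the defaults of the synthetic-data generator, and
the numerical choices that were genuinely open.

## Genotype representation

Genotypes are alt-allele counts per SNP per individual, SNP-major, with 9
marking missing data (the EIGENSTRAT convention). Pseudo-haploid
individuals — one randomly sampled sequence read per covered site, the
standard representation for low-coverage ancient DNA — carry calls in
{0, 1}; diploid individuals in {0, 1, 2}. A pseudo-haploid call
contributes one observed allele draw to group counts, a diploid call two.
Genetic positions are stored in Morgans; a heuristic (median
per-chromosome span > 3) flags files whose third `.snp` column is in
centimorgans, and an explicit flag rescales by 1/100 on read. CpG
transition status cannot be derived from the allele pair alone (it needs
the flanking base), so it is an optional panel annotation; requesting the
CpG filter without it is an error rather than a silent no-op.

Jackknife blocks are contiguous runs of at most 5 Mb within one
chromosome, half-open windows anchored at the chromosome's first SNP
position. Anchoring at the first SNP makes the partition a deterministic
function of the data. Block weights are statistic-specific: the number of
SNPs the statistic actually used in the block.

## f-statistics

Per-SNP estimators, with p̂ the observed alt frequency and n the observed
allele draws:

- f2(A,B): (p̂−q̂)² − p̂(1−p̂)/(n_A−1) − q̂(1−q̂)/(n_B−1); SNPs with fewer
  than two draws in either group are skipped (the bias correction is
  undefined there).
- f3(C;A,B): (ĉ−p̂)(ĉ−q̂) − ĉ(1−ĉ)/(n_C−1). The correction denominator
  counts observed allele draws — for pseudo-haploid groups, individuals —
  which is the "inbreed"-style semantics appropriate when each individual
  contributes a single random allele. Diploid groups use 2n draws with
  the same formula. A significantly negative f3 (Z < −3) is evidence that
  C is admixed between A- and B-related sources.
- f4(A,B;C,D): (p̂_A−p̂_B)(p̂_C−p̂_D), no correction, complete-case over
  the four groups.

Estimates are plain means of per-SNP values (not ratios of sums); this
makes block weights well-defined and the estimate linear in per-block
sums. SNP usage is complete-case per statistic.

Standard errors use the weighted block jackknife: with B blocks of weight
m_j, M = Σm_j, h_j = M/m_j, full estimate θ̂ and leave-one-block-out
estimates θ̂₋ⱼ, the variance is (1/B) Σ (τ_j − θ_J)²/(h_j − 1) with
pseudovalues τ_j = h_jθ̂ − (h_j−1)θ̂₋ⱼ and jackknife mean
θ_J = Bθ̂ − Σ(1 − m_j/M)θ̂₋ⱼ. Equal weights reduce this to the ordinary
delete-one jackknife; the result is exactly invariant to rescaling all
weights. The same formula, applied to vectors with outer products,
provides the jackknife covariance used by the mixture fitter.

Conditional heterozygosity — the probability that one allele drawn from
each of two random group members differs — is estimated per SNP as
2n₁n₂/(n(n−1)) from the haploid ref/alt draw counts, averaged over SNPs
(conventionally transversions only, which are immune to post-mortem
deamination). Kinship screening uses the mean pseudo-haploid mismatch
rate per pair; the relatedness call compares the pair's rate to the
cohort baseline at ratios 0.55 and 0.85. Those cutoffs are this package's
operationalization of "compare to known relationships": for an outbred
cohort a same-individual pair sits at 0.5× the unrelated rate and a
parent-offspring pair at 0.75×, so 0.55/0.85 split the three regimes at
roughly equal odds. Pairs below the overlap threshold (default 5,000
SNPs) are indeterminate.

## Shared-drift summaries

The outgroup-f3 matrix f3(Outgroup; i, j) measures shared drift of i and
j since their divergence from the outgroup. Entries are computed with the
inbreed-style correction on the outgroup; targets below a minimum SNP
threshold (default 100,000 usable sites, configurable; applied
per-individual by default rather than per-pair) are excluded and listed.
Two distance transforms feed the embeddings: 1 − f3 for classical MDS and
f3⁻¹ for neighbor joining. The inverse transform refuses nonpositive
entries — these cannot occur with a sane outgroup.

MDS is classical (Torgerson double-centering + eigendecomposition),
chosen over stress-minimizing variants for determinism; axis signs follow
the convention that the largest-magnitude loading is positive. A rigid
2-D rotation (e.g. 30°) is available for display. Neighbor joining is the
standard Saitou–Nei agglomeration with the Q-criterion; ties are broken
by the lexicographically smallest pair of subtree labels, so output is
independent of input order. Negative branch lengths are clamped to zero
with a warning. For display the tree can be rooted on the outgroup's
pendant edge (split at its midpoint), and `topology_only` zeroes the
branch lengths.

## Admixture proportions (qpAdm-style)

The target T is modeled as a mixture Σ w_i S_i of k sources, judged
against m+1 "right" reference populations. With r₀ the first right, the
moment conditions are f4(T, r₀; r_j, r₀) = Σ_i w_i f4(S_i, r₀; r_j, r₀)
for j = 1..m. The fitter solves the constrained GLS (Σw = 1, closed-form
Lagrange solution) with residual covariance Ω estimated by the weighted
block jackknife of the per-block residual vectors. Because the residual —
per SNP, (p̂_T − Σw_i p̂_{S_i})(p̂_{r_j} − p̂_{r₀}) — depends on w, the
solve is iterated to a fixed point (typically 2–4 iterations). The fit
statistic is the minimized quadratic form, referred to χ² with
dof = m − k + 1; this implements the block-jackknife likelihood-ratio fit
test with the conventional classes: P > 0.02 pass, P < 0.005 fail,
borderline between (boundaries inclusive of borderline). Weights are not
constrained to [0, 1] (matching standard practice); feasibility is
reported separately, and weight SEs come from re-solving with each block
deleted (Ω held fixed) combined by the weighted jackknife. An
ill-conditioned Ω (condition number > 1e10) receives a small ridge
(1e−6 × trace/m) with a warning. Proportions are conventionally reported
as estimate ± 1 SE.

## Admixture graphs

An admixture graph is a rooted DAG whose drift edges carry lengths in f2
units (text files use the familiar "F_ST × 1000" display scale, converted
on parsing); admixture nodes have two parents with mixing proportions
summing to 1 and no drift on the incoming edges. Expected f-statistics
follow from the leaf covariance relative to the root,
C(i,j) = Σ_e P_i(e)P_j(e)·len(e), where P_i(e) is the probability that a
lineage from leaf i traverses edge e (products of mixing proportions,
summed over paths). f2, f3 and f4 are the usual bilinear combinations of
C. The fit report compares observed statistics (with jackknife SEs) to
these expectations by Z-score, with no refitting; graph topology search
is out of scope.

## Admixture dating by covariance decay

For a target cohort descended from a two-source admixture g generations
ago, the ancestry correlation between loci at genetic distance d decays
as e^(−gd). The implementation weights each SNP by the reference
frequency difference w_s = p̂_A(s) − p̂_B(s), and for every
intra-chromosome SNP pair within 10 cM accumulates
w_s·w_t·cov(g_s, g_t) — the sample covariance of calls across target
individuals covered at both SNPs (pairwise-complete, at least two
individuals) — into distance bins of 0.05 cM. The binned curve is fit by
nonlinear least squares to A·e^(−nd) + c from 0.45 cM outward
(log-linear initialization); n is the admixture date in generations. The
bin width, fit start and maximum distance are configuration keys; the
defaults follow the conventions of the admixture-LD literature. The date
SE is a leave-one-chromosome-out weighted jackknife (chromosome weight =
pair count in the fit range). A fit with nonpositive — or numerically
negligible — amplitude is flagged "no decay"; nonconvergence is flagged
rather than reported as a date. The sample covariance across individuals
was chosen as the simplest estimator consistent with the weighted-
covariance description; it is validated by parameter recovery on mosaic
simulations, not against any particular reference implementation's
internals. Calendar conversion: years BP = mean sample age + n × 28.5
(generation time in years; configurable), with the SE scaled linearly;
the sample-age anchor reflects that dates for ancient cohorts are
reported relative to when the samples lived, and can be disabled.

At the default desk scale (20 chromosomes × 1 Morgan, ~6,000 SNPs, 200
admixed targets), recovery is accurate to a few percent for g = 40–70 and
median relative error ≲ 15% at g = 10, where the decay over the fit
window is shallowest and the estimate is biased slightly downward.

## Explanatory distance matrices

Four rule-based matrices over individuals, mirroring a five-region
coastal study system:

- time: |midpoint₁ − midpoint₂| of the 95.4% calibrated date ranges;
  modern individuals count as 0 calBP.
- diet: maritime regions (Western Archipelago, Beagle Channel) vs
  terrestrial regions (North Tierra del Fuego, South Continent) = 2; the
  mixed-resource Mitre Peninsula to anything else = 1; same strategy
  class = 0.
- language: within-Chonan distances Mitre–NorthTdF = 1 and either to
  South Continent = 2; the two isolate-speaking maritime regions are 3
  from each other and 4 from all Chonan regions; same region = 0.
- geography: same site = 0; same region = great-circle straight line;
  different regions = spur to the nearest route waypoint + shortest path
  through the route network + spur. Route networks are user data
  (waypoint polylines); maritime/terrestrial crossings are encoded as
  network topology, not as algorithmic rules, and no GIS coastline
  routing is attempted. The rules are deliberately rule-based rather than
  metric-consistent: a network path may be shorter or longer than the
  within-region straight line, and no such inequality is asserted.

The marine-diet helper maps δ15N linearly between the anchors 11.5‰
(wholly terrestrial, fraction 0) and 22.0‰ (~90% marine), clamped to
[0, 1], and assigns the nearest of the five calibration-mixing categories
{0, 20, 40, 60, 80}% (±10% uncertainty by convention); exact ties round
down, a choice the source rules leave open. The marine reservoir
correction ΔR = 221 ± 40 is stored as a named constant for provenance;
radiocarbon calibration itself is out of scope (performed upstream).

## Matrix association tests

Simple Mantel correlates the strictly-lower-triangle vectors (Spearman by
default; Pearson available), with the null built by jointly permuting the
rows and columns of the dependent (genetic) matrix only — the convention
of the multi-matrix regression literature. p-values are two-sided on |r|:
(1 + #{|r_perm| ≥ |r_obs|})/(nperm + 1); with ≤ 7 labels all n!
permutations are enumerated and the p-value is exact. The multiple matrix
regression is OLS with intercept on the triangle vectors, per-coefficient
permutation p on |t|, reporting the multiple R². The partial Mantel first
residualizes the genetic triangle on the covariate triangles by
multivariate linear regression, then Mantel-tests the residual matrix
against the focus matrix. Two-sided p-values were chosen where the
convention was unstated. Seeded runs are bit-reproducible.

Treating individuals as independent observations is documented behavior:
shared drift within groups makes this only approximate, and no
correction is applied.

Uncertainty in the regression coefficients themselves (as opposed to
permutation significance) comes from the genetic side: the genetic
distance matrix (1 − f3 or f3⁻¹) is recomputed with each 5-Mb block
deleted, the regression refit, and the spread combined with the weighted
jackknife (block weights = outgroup-usable SNPs per block, the common
base of every f3 entry); the CI is ±1.96 SE.

## Synthetic-data generator

The generator is first-class, tested code; it defines the study
conditions under which everything above is validated.

- Panel: SNPs spread over 20 chromosomes of 1 Morgan each on a uniform
  1 cM/Mb map, so 5-Mb blocks and centimorgan bins interoperate without a
  map file. About half the panel is transversions.
- Frequencies: ancestral p ~ U(0.05, 0.95) (bounded away from fixation so
  panels stay polymorphic); each drift edge of f2-length F resamples via
  Balding–Nichols with per-SNP F′ = F/(p(1−p)), which makes the expected
  parent–child f2 equal the nominal length exactly at every SNP. SNPs
  whose current frequency is too extreme to carry the full edge variance
  have F′ clipped at 0.98; an edge needing clipping at more than 20% of
  SNPs is refused as too long for the frequency distribution. Admixture
  nodes mix parental frequencies linearly. Balding–Nichols was chosen
  over discrete Wright–Fisher for speed and closed form; it matches
  f-statistic expectations, which is all the estimators consume.
- Genotypes: pseudo-haploid sampling is one Bernoulli(freq) draw per
  site, with per-individual missingness drawn from U(0.5, 0.95) by
  default — the heavy, uneven missingness typical of ancient capture
  data. Recovery studies that fix their own cohort sizes set missingness
  explicitly.
- Admixed cohorts for dating: two source haplotype panels (Bernoulli
  draws from the source frequencies, 100 haplotypes each); each admixed
  chromosome is a Markov mosaic with crossover points Poisson(g per
  Morgan) and each segment copying a random haplotype from a source
  chosen Bernoulli(α). Realized ancestry fraction and mean segment length
  (≈ 1/g Morgans) are reported for verification.
- Study structure: the five regions form an admixture cline between two
  endpoint lineages (region k carries k/4 ancestry from one endpoint),
  which reproduces the key geometry of a neighbor-mixing coastal cline —
  genetic distance increasing with coastal separation — and gives MDS a
  genuinely one-dimensional dominant axis. A deep outgroup is attached
  for outgroup-f3 work. Site metadata places sites on a parametric
  coastal arc with five contiguous regions, language/diet labels assigned
  by region, date ranges spanning roughly 6,600–100 calBP, δ15N values
  matching each region's subsistence, and a chain of coastal waypoints as
  the route network.

What the generator does not emulate: post-mortem damage profiles,
contamination, reference bias, real linkage-disequilibrium structure
(frequencies are independent across SNPs given the graph), non-uniform
recombination maps, and selection. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated models, not
robustness to those real-data complications.

## Validation scales and determinism

The default validation sizes are desk-scale choices: mixture recovery at
50,000 SNPs, 20 pseudo-haploid samples per group, 30 replicates per
mixing proportion; dating at 200 targets and 5–9 replicates per date;
Mantel null calibration at 1,000 replicates × 600 permutations (the
package default for real analyses remains 10,000 permutations); MDS cline
recovery at 100 replicates of 5,000 SNPs. All generators are
seed-deterministic: identical configuration and seed give bit-identical
outputs, and the pipeline fans a master seed out to stages through a
counter-keyed seed sequence so stages can be rerun independently.

## Known limitations

- The qpAdm implementation uses a designated base right and the residual
  χ² test; it preserves the pass/borderline/fail semantics but does not
  implement full rank-deficiency (qpWave) testing across nested ranks.
- The dating estimator's small-g regime (g ≈ 10) is biased low by a few
  percent at desk scale because the decay is shallow relative to the
  default fit window.
- Mantel-family tests inherit the independence caveat above; spatial
  autocorrelation corrections and mixed-model alternatives are out of
  scope.
- No BAM/FASTQ/VCF ingestion; EIGENSTRAT digit-string files only.
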
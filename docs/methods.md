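# Methods

## The inference chain

The package estimates the genome-wide rate of mutation to the heat-sensitive
mortal-germline (Mrt) phenotype from mutation-accumulation (MA) data,
infers the strength of selection against Mrt alleles from their frequency
in a wild-isolate panel, and tests the consistency of the two under
mutation–selection balance (MSB).

### Phenotype classification

A line's assay consists of replicates, each recorded as the generation at
which it went sterile at 25°C or as right-censored at the assay horizon.
Classification applies threshold rules with strict inequalities:

| class | rule |
|---|---|
| ts_sterile | all replicates sterile at generation 1 |
| excluded_low_fitness | majority of replicates annotated `non_mrt_failure` |
| strong | all informative replicates sterile, mean < 10, max < 15 |
| moderate | all informative replicates sterile by generation 21, mean < 16 |
| weak | ≥ 2/3 of informative replicates sterile by generation 21 |
| wild_type | otherwise |

Precedence is top to bottom; every line receives exactly one class.
"Informative" excludes replicates annotated as non-Mrt failures
(low-fitness deaths); the mean time to sterility is computed over sterile
informative replicates only, with the censored count reported alongside.
Design choices here, made where the verbal criteria leave room:

* The "2 out of 3" wild-isolate rule generalizes to the fraction 2/3
  (integer arithmetic `3·n_sterile ≥ 2·n_informative`), which reproduces
  the 3-replicate rule exactly and extends proportionally to 10-replicate
  designs. With more than 3 replicates the weak and wild-type conditions
  no longer exhaust the possibilities (e.g. 5 of 10 sterile); the
  classifier's precedence order resolves this by falling through to wild
  type.
* `strong` requires every informative replicate sterile: a replicate still
  fertile at a horizon ≥ 15 has a time to sterility above the max-< 15
  bound, and at horizon 14 its status is unknowable, so the conservative
  reading applies in both cases.
* Assays censored before generation 21 (the PB306 design at 14) cannot
  score moderate or weak, which are defined by generation-21 fertility;
  the classifier then returns only ts_sterile/strong/excluded/wild_type
  and logs a warning.
* Low-fitness exclusion is driven by the `failure_mode` annotation, not
  inferred from timing: in the real assay that call is made by visual
  inspection of the worms, which a data table cannot reproduce.
* ts-sterile sits above strong in the severity ordering used by the
  monotonicity tests; it is immediate, fully penetrant sterility rather
  than progressive Mrt kinetics.

The MA-vs-pseudoline distribution comparison uses the two-sample
Kolmogorov–Smirnov distance on replicate-level times to failure (censored
replicates assigned the horizon value) with a label-permutation p-value
(+1 smoothing, never exactly 0). Permutation exchangeability holds at the
replicate level; when replicates are clustered within lines (shared line
class), replicate-level permutation is anti-conservative, so comparisons
between tables with strong line-level heterogeneity should be read as
descriptive. The calibration tests therefore use independent replicates.

### Rate estimation

`U = k/(n·t)` per genome per generation. This is the haploid rate:
mutations arise in diploids at rate 2U, but a new neutral heterozygous
mutation survives single-descent selfing propagation with probability 1/2
(verified by simulation in `popgen_sim`), and the factors cancel. The
exact Poisson interval is Garwood's: `2λ_L` is the α/2 fractile of a
chi-square with 2k df (λ_L = 0 for k = 0, the standard convention for the
degenerate 0-df case, matching the one-sided use of the interval for an
observed zero count), `2λ_U` the 1−α/2 fractile with 2(k+1) df; chi-square
quantiles come from scipy. The test suite keeps an independent brute-force
solver of the defining Poisson tail sums (root-finding on
`P(X ≥ k) = α/2`, `P(X ≤ k) = α/2`) as the oracle; production code never
uses it. Note the published interval for k = 1 in 16,750 meioses differs
from the recomputed one by ~1–2% (1.53 vs 1.51 ×10⁻⁶ and 3.28 vs 3.33
×10⁻⁴), consistent with rounding during the original calculation; the
implementation follows the chi-square identity and is not adjusted to the
printed digits.

Target size: `n_sites = U/μ_site` with defaults μ_site = 2.8×10⁻⁹ per
generation and genome size 10⁸ bp.

### Mutation–selection balance

For a (nearly) completely selfing population the equilibrium frequency of
a deleterious allele is `q̂ ≈ μ/s` with s the homozygous effect; summed
over loci the phenotype frequency is ≈ U/s̄. Inverting gives
`s = U/q̂`. Written q̂ ≈ μs in some renderings, the quotient is the
standard MSB result for selfers and is what the package implements. When
the carrier count is a lower bound, the inferred s is an upper bound, and
reports carry that one-sided semantics. Frequencies get exact
Clopper–Pearson intervals (statsmodels, `method="beta"`); the `msb` CLI
propagates U's interval and q̂'s interval to s by interval arithmetic
(smallest U over largest q̂, and vice versa).

The deterministic check models the population as fully homozygous selfing
lineages — the heterozygous phase is ignored, justified by near-complete
self-fertilization — with irreversible mutation (back mutation from
loss-of-function Mrt alleles is assumed negligible):
`q → q + U(1−q)` then `q → q(1−s)/(1−sq)`, iterated until the per-step
change is below `tol·q` (defaults tol = 10⁻¹², max 10⁶ iterations;
non-convergence is flagged, not raised). The exact fixed point is
`q* = U(1−s)/(s(1−U))`, so the relative deviation from U/s is
`(s−U)/(1−U)` — first order in s, which the property tests assert. Note
q = 1 is also a fixed point (unstable): with irreversible mutation an
all-mutant population cannot leave it, so "independence of q0" holds for
q0 < 1 only.

### Simulators

* `ma_transmission`: from a heterozygote, the single surviving selfed
  offspring per generation is homozygous mutant / heterozygous / homozygous
  wild type with probabilities 1/4 : 1/2 : 1/4 — a lazy symmetric random
  walk absorbed at fixation or loss with probability 1/2 each, absorbing
  after Geometric(1/2) generations (mean 2). The model deliberately ignores
  the 3-L4 transfer detail of the Mrt assay: the 1/2 figure describes MA
  line maintenance by single-individual descent. Absorption times are
  reported so the adequacy of a finite (≤ 250 generation) horizon can be
  checked.
* `wf_selfing`: N selfing lineages; each generation, irreversible mutation
  wild-type→Mrt with probability U per lineage, then resampling of the N
  lineages with relative fitness 1 vs 1−s (two classes, so the multinomial
  resampling reduces to a binomial). No diploid genotype tracking, no
  outcrossing, no linkage — a lineage model matching the recursion's
  assumptions, converging to it as N grows.
* `recover_U`: simulate MA experiments (`generate_ma_experiment`), classify
  each assay table, count lines classified strong, estimate the rate with
  its interval, and report mean k, mean point estimate, and interval
  coverage. Because k counts mutant *lines*, its analytic expectation is
  `n(1−exp(−U·t))`, which the tests use; at the study's U·t = 0.015 this is
  indistinguishable from n·U·t (1.00497 vs 1.005), while at U·t ≳ 0.25
  multiple hits per line make the estimator visibly downward-biased.

### Tree analysis

Phenotypes map onto a Newick tree (dendropy); distances are patristic
(sum of branch lengths — the haplotype dendrogram's lengths are
meaningful; a `hops` edge-count alternative is provided). The scatter
statistic counts focal-class tips whose nearest *phenotyped* neighbor is
wild type; unphenotyped tips stay in the tree but are never neighbors;
distance ties break lexicographically by tip label. The permutation null
shuffles class labels over the phenotyped tips; one-sided p-values
(`scattered`: statistic ≥ observed; `clustered`: ≤) use +1 smoothing.
The statistic depends only on patristic distances, hence is invariant
under re-rooting. No ancestral-state reconstruction or tree estimation is
attempted, and no attempt is made to formalize which placements are
"ambiguous".

## Synthetic data

`generate_assay_table` draws each line's latent class from a mixture, then
its replicates from the class's sterility model. Defaults emulate the
study conditions: designs of 34×10×21 (N2 MA), 33×10×14 (PB306 MA),
18×10×21 (pseudolines), 95×3×21 (wild isolates); a ~5% per-replicate
sporadic failure rate for wild-type lines (10 of 180 ancestral pseudoline
replicates failed in the N2 block); ts-sterile lines fully penetrant at
generation 1; low-fitness lines failing 85% of replicates with the
`non_mrt_failure` annotation.

Generation-at-sterility distributions are shifted negative binomials
truncated at the horizon (`1 + NB(mean−1, shape)`), with per-class
defaults strong(mean 6, shape 50), moderate(13, 80), weak(19, 200 with
per-replicate sterility probability 0.9). The class definitions fix only
thresholds, not a generative law, so these are package conventions chosen
once so that a generated line satisfies its class's defining rules with
high probability (≈99% at 10 replicates; lower with 3 replicates, which
mirrors the real difficulty of scoring wild isolates). Within-class
variances are conventions, not estimates — the source data report only
means with error bars. `uniform` and `degenerate` families are available
for fully controlled tests. Consequences for interpretation: passing
classification tests on synthetic tables shows the classifier implements
the rules and the generator meets them; it does not validate the rules
against biology, nor the generator against the empirical within-class
distributions.

`generate_ma_experiment` gives each line Poisson(2U·t) arising mutations,
thinned by the survival probability 1/2 (so surviving mutations are
Poisson(U·t)); carrier lines express the strong-Mrt model. Seeding uses
`numpy` `SeedSequence.spawn` per line, so enlarging an experiment never
perturbs earlier lines, and identical configurations and seeds give
byte-identical CSV output.

## Problem sizes and numerical choices

Monte-Carlo checks in the tests use 10⁵ transmission walks (loss
probability to ±0.005), 2,000 simulated MA experiments for parameter
recovery, a Wright–Fisher run of N = 10⁵ for 20,000 generations (averaging
the second half, several multiples of the 1/s = 1,000-generation
relaxation time), and 1,000 null datasets for permutation calibration —
sizes at which the targeted 3-standard-error bands are decisive while the
full suite stays fast. All stochastic code takes explicit seeds and is
bit-reproducible.

## Known limitations

* The classifier cannot reproduce exclusions made by visual inspection of
  worm morphology; it relies on the `failure_mode` annotation.
* The weak/moderate boundary is sensitive to the 3-vs-10 replicate design;
  with 3 replicates per line, ~10% of moderate/weak lines fall on the
  wrong side of the boundary under the default generator, an inexactness
  inherent to the small design rather than to the rules.
* The MSB machinery has no dominance, no partial outcrossing, and no
  linkage; the selfing recursion and the Wright–Fisher model share these
  assumptions, so their agreement validates the equilibrium approximation,
  not the biology.
* Replicate-level permutation is anti-conservative under line-level
  clustering (see above).
* No survival-curve (Kaplan–Meier/Cox) modeling: the classification rules
  are thresholds, not hazard models, and the package follows them.
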
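# Methods

## The problem

Multiplex-PCR targeted sequencing measures a genomic region through the
read counts ("coverage") of a few hundred amplicons.  The coverage of an
amplicon is the endpoint of exponential amplification,
`N = N0 * (1 + e)^c`, where `N0` is the amount of input template, `e` the
amplicon's amplification efficiency and `c` the number of PCR cycles.
Because `e` responds to uncontrollable reaction conditions, absolute and
library-normalised coverages are not comparable between samples, which
defeats the usual read-depth CNV callers.  The premise of this package is
that in a large primer pool some amplicons respond to the reaction
conditions in the same way: within such a group, log coverages are highly
correlated across samples, and a germline copy-number change in one sample
shows up as an *outlier* from the relationship — shifted by log 0.5 for a
heterozygous deletion, log 1.5 for a heterozygous duplication (a sum of
independent maternal/paternal contributions scales the Poisson rate by the
copy-number multiplier).  CNV detection thus becomes robust anomaly
detection, with no library-size normalisation anywhere.

Calls are reported at CNV-site (exon) resolution because CNV breakpoints
usually fall in introns.  The model assumes each particular CNV is carried
by at most ~20 % of the cohort and that one run (one coverage matrix)
contains at least 25 samples; run-to-run condition shifts are larger than
within-run ones, so each run is analysed separately.

## Quality control

1. Samples with fewer than 15 000 total reads are dropped (stochastic
   amplification noise dominates below that).
2. Cells with coverage below 10 on an amplicon whose cohort mean is at
   least 50 are flagged homozygous deletions (zero template means zero
   product) and masked out of every downstream estimator; masked values are
   replaced by the amplicon's median log coverage wherever an estimator
   needs a rectangular matrix, so they can never influence a statistic.
3. Amplicons with cohort mean coverage below 50, or without enough
   correlating partners (below), fail QC; a site whose amplicons all fail
   is excluded everywhere.  Failing an amplicon removes it from the
   candidate pool and can strip partners from others, so this filter
   iterates to a fixpoint — which also makes the whole QC pass idempotent.
4. "Irregular" samples — profiles with no analogue in the cohort — are
   detected per gene: coverages are normalised by the gene total (so a
   whole-gene CNV does not masquerade as irregularity), log-transformed,
   and compared to a per-amplicon Hodges–Lehmann reference with Sn scales;
   the sum of the smallest ceil(0.8 m) squared standardised coordinates is
   referred to a chi-square with that many degrees of freedom.  A sample is
   dropped when more than n/2 of n genes fail (only when n > 2).

   The chi-square reference assumes independent coordinates, but the
   within-gene coordinates share efficiency-group factors — the method's
   own premise — so the statistic's true tail is heavier than chi-square
   and no textbook significance level is calibrated.  The default level
   (1e-6) was therefore chosen by calibration on CNV-free synthetic
   cohorts: typical runs lose ≲0.1 % of samples while genuinely distorted
   profiles, whose statistics land orders of magnitude above any threshold,
   are still caught.  The level is exposed in `QcThresholds.gene_alpha`.

## Unsupervised caller (per amplicon)

For amplicon `a_j`, the caller ranks candidate partners from *other* genes
(so no single CNV can span target and partner) by the Sn-correlation of
log coverages — a robust correlation built from Sn scales of the sum and
difference of MAD-standardised variables — and keeps the top L = 5 above a
threshold T.  T is data-driven: the largest value on a 0.01 grid such that
every analysable site keeps at least one amplicon with L qualifying
partners.  At most `votes_required − 1` partners may come from any single
gene; without that cap, a CNV carried by the tested sample in one partner
gene can shift most residuals by −log(multiplier) at once and fabricate a
confident call in an unaffected gene (observed in simulation).  A
consequence of the cap is that panels need at least three genes at the
default settings; two-gene panels should raise `max_partners_per_gene`.

Each partner yields a Theil-Sen regression (median of pairwise slopes;
breakdown point 1 − 1/√2 ≈ 29.3 %) of log cov(a_j) on log cov(partner)
over QC-passed samples, with the residual scale estimated by Sn.  A sample
is outlier-low when its Sn-studentized residual
`r_i = e_i / (Sn · sqrt(1 − h_i))` falls below the Student-t quantile at
α = 0.02 (df = n − 2), outlier-high above the α = 0.05 quantile — the
asymmetry reflects the lower power against duplications (variance grows
with the multiplier).  An outlier supports HET_DEL (DUP) only when the
simple Bayes factor K between normal likelihoods centred on the line
shifted by log 0.5 (log 1.5) and on the fitted line, both with the Sn
residual scale, exceeds 1 — i.e. the point lies closer to the CNV line.
A state is called when at least N = 4 of the L = 5 models agree.  Copy
numbers ≥ 3 are all reported as DUP; their prediction intervals overlap
too much to separate.  Homozygous deletions come from the QC mask and
carry votes = L by convention.

## Supervised classifier (per site, against controls)

Samples with no unsupervised outlier form the control set (an a-priori
CNV-free list can override it); at least 20 controls are required.  Per
amplicon:

* a cluster of k = 5 highly correlated amplicons from other genes is
  chosen on control samples (Pearson correlation when |Control| > 20,
  Sn-correlation otherwise; at most 3 per gene);
* the normalised statistic is `x_j = log cov(a_j) − mean_k log cov(a_jk)`,
  which cancels any per-sample global factor;
* three models: NORMAL with Hodges–Lehmann location and Sn scale over
  control `x_j`; HET_DEL shifted by log 0.5 with variance ×2; DUP shifted
  by log 1.5 with variance ×2/3.  The variance factors follow from the
  delta method for log-Poisson counts (Var log X ≈ 1/λ) and are verified
  by Monte Carlo in the test suite and the acceptance script.

A test sample's site is **suspicious** for a state when every amplicon of
the site is admissible under that state's model (chi-square(1) test at
α = 0.05 / expected altered amplicons, the latter estimated as half the
amplicon cells of the test set, per the ≤20 % CNV-frequency assumption).
For suspicious sites the squared normalised Euclidean distance to the
NORMAL profile is referred to chi-square with one degree of freedom per
amplicon (the cluster normalisation leaves the covariance approximately
diagonal; block size one); Benjamini–Hochberg controls the FDR across all
suspicious site–sample pairs of the iteration.  Finally the Bayes factor
of the state's model over NORMAL (independent per-amplicon normal
densities, equal priors) must reach 100.  Test samples left without calls
join the controls and the procedure repeats (at most 5 iterations; the
control set grows monotonically).

Duplications confined to a single site are flagged and suppressed from the
default report — the NORMAL and DUP models overlap too much for one exon
to be decisive — but remain in the full report.  Runs of adjacent called
amplicons/sites with the same state are merged; fragments separated by a
single uncalled amplicon merge too, so one dropout does not split an event.

## Coverage simulator

The generator emulates the structure the method assumes, with defaults
modelling one sequencing run of a three-gene, ~130-amplicon disease panel:

* 48 samples; per-run mean depth 500 reads per amplicon (per-sample
  averages land inside the 120–1200 window typical of such assays) with
  lognormal amplicon-to-amplicon spread (sd 0.25 in log space);
* 6 efficiency groups interleaved across genes; efficiencies uniform on
  [0.5, 1.0] per group centre with within-group spread 0.01; c = 25
  cycles.  A per-sample, per-group lognormal condition factor (sd 0.02)
  drives the shared variation: exponential amplification amplifies it to
  ~0.2 sd in log coverage, giving within-group correlations ≈ 0.95–0.99
  and near-zero across groups;
* Poisson counts around the expected coverage (an over-dispersion knob
  exists, default off); CNV events as contiguous site runs within one gene
  with multipliers {0, 0.5, 1.5, 2.0} and per-site carrier fraction capped
  at 20 %.

What the generator does **not** emulate: GC/primer-specific biases beyond
the group structure, run-to-run batch shifts (one matrix is one run by
construction), mosaic fractions, mapping artefacts and the heavy depth
tails of degraded libraries.  Passing tests therefore demonstrate the
machinery is correct under the model's own assumptions, not performance on
real instruments.

## Numerical choices

* Natural log everywhere; zero counts get a pseudo-count of 0.5 (cells
  below the homozygous-deletion threshold are already masked).
* Sn uses the 1.1926 consistency constant and the Rousseeuw–Croux
  finite-sample corrections; inner high median over j ≠ i, outer low
  median; O(n²) vectorised with chunking.  Medians average the two central
  order statistics for even counts.  Walsh averages include singletons.
* Theil-Sen skips pairs with equal predictors; the intercept is
  median(y − slope·x).  Degenerate inputs (MAD 0, perfect fits, constant
  predictors) raise a dedicated error and the affected model is skipped.
* The studentized-residual denominator uses the standard internally
  studentized form — squared leverage numerator under a square root —
  with Sn in place of the residual standard deviation.
* Partner/cluster ties break by correlation, then genomic distance
  (descending), then amplicon id: runs are fully deterministic, and the
  whole pipeline is a pure function of (matrix, panel, configuration).

## Test-suite problem sizes

Estimator oracles run 1000 random instances per estimator at n ≤ 8
(exhaustive brute force); Sn consistency uses 10⁴ normal draws; null
calibration uses 50 CNV-free runs of 48 × 130 and parameter recovery 20
runs with four carriers each (events of 2–10 amplicons, multipliers 0.5
or 1.5).  These sizes keep the full suite within a few minutes while
leaving the binomial noise on the asserted rates well inside the asserted
margins.

## Known limitations

* Two-gene panels cannot satisfy the default partner diversity cap.
* The irregular-sample filter's significance level is a calibrated
  constant, not a nominal error rate (see above).
* Sensitivity for single-amplicon events rests entirely on the
  unsupervised stage, and single-exon duplications are deliberately not
  reported.
* The supervised Bayes factor treats amplicons as independent given the
  cluster normalisation; residual within-site correlation makes the
  factor optimistic, which the hard admissibility gate and FDR step
  mitigate but do not remove.
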
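# ampcnv

Germline copy-number-variant (CNV) detection in multiplex-PCR targeted
sequencing, from amplicon read counts alone.

## Who this is for

Targeted panels enriched by multiplex PCR (e.g. AmpliSeq disease panels)
give each amplicon a coverage `N = N0 (1 + e)^c` whose efficiency `e`
drifts with reaction conditions, so the usual library-size-normalised
read-depth CNV callers break down — especially for events spanning one or
a few exons.  `ampcnv` is for people analysing such panels (tens of
samples per run, hundreds of amplicons, exon-level events): it exploits the
fact that subsets of amplicons respond to the conditions *together*, so a
real copy-number change in one sample appears as a robust-regression
outlier against the sample's own correlated amplicons, with no
normalisation step at all.

## The method in brief

**Unsupervised stage (per amplicon `a_j`).**  Pick the L = 5 amplicons from
other genes whose log-coverage vectors maximise the Sn-correlation
r = (Sn²(u) − Sn²(v)) / (Sn²(u) + Sn²(v)) (u, v the sum/difference of
MAD-standardised variables), each above a data-driven threshold T.  Fit
Theil-Sen lines (median of pairwise slopes, breakdown 1 − 1/√2 ≈ 29.3 %)
of log cov(a_j) on each partner; studentize residuals with the Sn scale,
`r_i = ε̂_i / (Sn √(1 − h_i))`; flag outliers at Student-t quantiles
(α = 0.02 deletions / 0.05 duplications) and require the Bayes factor
K = P(cov | M_HetDel) / P(cov | M_Normal) > 1.  Call a state when N = 4 of
the L = 5 models agree.  Cells under 10 reads on well-covered amplicons are
homozygous deletions by QC.

**Supervised stage (per CNV site, against ≥ 20 controls).**  Normalise each
amplicon by the mean log coverage of a 5-amplicon cross-gene cluster,
`x_j = log cov(a_j) − mean_k log cov(a_jk)`; model x_j as NORMAL
(Hodges–Lehmann location, Sn scale), HET_DEL (shift log 0.5, variance ×2)
and DUP (shift log 1.5, variance ×2/3) — the variance factors are the
log-Poisson delta-method ratios.  A site is called when (a) every amplicon
is admissible under the CNV model (χ²₁ at α = 0.05 / expected altered
amplicons), (b) the squared normalised Euclidean distance
d²(x, y) = Σ (x_i − y_i)²/s_i² to the NORMAL profile rejects it (χ² with
one df per amplicon, Benjamini–Hochberg across suspicious site–sample
pairs), and (c) the Bayes factor over NORMAL reaches 100.  CNV-free test
samples join the controls and the procedure iterates.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate one run (48 samples, 130 amplicons over 3 genes) with three
planted CNVs, call it, and score the calls against the truth set:

```
ampcnv simulate --out-dir sim --seed 5 --n-carriers 3
ampcnv call --panel sim/panel.bed --coverage sim/coverage.tsv --out-dir calls
ampcnv score --panel sim/panel.bed --calls calls/calls.tsv \
             --truth sim/truth.tsv --n-samples 48
```

The `call` step prints:

```
Amplicon CNV calling summary
============================
samples analysed:        48
samples failed QC:       0
irregular samples:       0
amplicons failed QC:     2
sites excluded:          0
homozygous-deletion cells: 0
correlation threshold T: 0.98
control/test split:      45/3 (2 iteration(s))
non-normal amplicon calls (unsupervised): 12
reported CNV calls:      2

sample  gene   state first_site  last_site  n_amplicons  first_index  last_index         adj_p  bayes_factor  votes stage
   S25 GENE2 HET_DEL  GENE2_ex1  GENE2_ex1            3           44          46 6.095529e-169 1.276345e+168      5  both
   S26 GENE3 HET_DEL GENE3_ex12 GENE3_ex13            7          123         129 1.115249e-128 2.558865e+128      5  both
```

Reading the rows: sample S25 carries a heterozygous deletion of site
(exon) GENE2_ex1 (3 amplicons) and S26 one spanning GENE3_ex12–ex13; the
adjusted p-value is the BH-corrected probability of the site's normalised
distance from the wild-type profile under no CNV, the Bayes factor weighs
the deletion model against wild type (≥ 100 required), `votes` is the
number of the 5 unsupervised regression models that flagged it, and
`stage` records that both stages agree.  The third planted event is a
duplication confined to a single exon, which the caller deliberately does
not report (wild-type and duplication models overlap too much on one
exon); the `score` step accordingly excludes it and reports sensitivity
1.0 (95 % CI 0.34–1.00) and specificity 1.0 (0.998–1.000) for this run.

The same objects are available in Python:

```python
from ampcnv import AmpliconCnvModel
results = AmpliconCnvModel.from_files("sim/panel.bed", "sim/coverage.tsv").fit()
print(results.summary())
results.save("calls/")
```

Input can also be per-sample SAM/BAM alignments (`ampcnv count`), with
reads assigned to the amplicon of maximal overlap.

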
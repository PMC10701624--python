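# Methods

`accipiter` implements a complete osteometric workflow for studying long-term
body-size change in Northern Goshawks (*Accipiter gentilis*): from raw
measurement tables through cohort assembly, descriptive and multivariate
summaries, temporal models, and a permutation comparison of Medieval
archaeological bones against modern museum skeletons.  This note records the
statistical model behind each stage, the defaults and why they were chosen,
and what the synthetic test bed does and does not establish.

## Data model

The canonical container is a long-format table: one measurement of one
skeletal element of one specimen per row, with provenance (country, region,
period, site, collection year), the museum's recorded sex, an analysis sex,
the element, an osteometric measurement code and the value in mm.  Long
format was chosen because the material is dominated by partial skeletons —
wide per-specimen matrices would be mostly missing.  Measurement codes follow
standard archaeozoological conventions (GL = greatest length, Bp/Bd =
proximal/distal breadth, ...), plus the wing-element codes KB, Tp and HS.
Mm values are reported to two decimals, the precision of digital callipers.

Validation enforces: positive values inside configurable per-(element, code)
plausibility windows; enum membership for all categorical fields; no
collection year on archaeological records and modern years in [1800, 2100];
uniqueness of (specimen, element, code, side).  Violations are reported, not
raised, and the clean subset is retrievable, so no record is silently lost.

Skeletons measured on both sides are collapsed to one value per
(specimen, element, code).  The original measuring protocol for paired
elements is unknown, so the policy is explicit and configurable:
prefer-left (default), prefer-right, or mean.  It matters only for the
minority of skeletons with bilateral measurements.

## Cohort assembly

**Subspecies filter.** Goshawks of northern Fennoscandia likely belong to
the larger subspecies *A. g. buteoides*, and young inland birds winter along
the northern Norwegian coast; modern records from the northern regions of
Norway, Sweden and Finland are therefore excluded by default (configurable
(country, region) exclusion list).  Archaeological records are never
dropped — the Medieval sites (Oslo, Bergen, Trondheim) lie within the
nominate range.

**Population groups.** One-way ANOVA between countries (within sex) finds no
Norway–Sweden difference, while Denmark differs from the others, so modern
records are grouped NS (Norway + Sweden), DK, FI.  Archaeological records
are grouped by period (MEDIEVAL, VIKING), not country.

**Sex reclassification.** Goshawks show reversed sexual size dimorphism with
essentially non-overlapping sex ranges per element, and museum sex labels
are occasionally wrong (paired ovaries mistaken for testes).  Each measured
element casts a vote: female if the value lies inside the observed female
range and outside the male range, male for the converse, otherwise
ambiguous.  A specimen is reassigned when its definite votes are unanimous
over at least `min_elements` elements (default 1 — real mis-sexed specimens
are known from few elements); ambiguous or conflicting votes keep the
recorded sex.  The reference ranges are computed from the data themselves
with two safeguards, because the original decision procedure is not
documented and had to be reconstructed:

* leave-one-out — the evaluated specimen is excluded from its own
  recorded-sex range, so a mislabeled skeleton cannot widen it;
* iteration to a fixed point — specimens whose votes contradict their label
  are removed from the reference set and everyone is re-voted, so one
  mislabeled skeleton cannot pollute the ranges used for the others.  On
  clean data with disjoint sexes and k injected label swaps this recovers
  exactly the k swapped specimens, and re-running on the corrected table
  changes nothing.

Votes use GL by default because PCA shows greatest length carries almost all
the size variance; other codes can be enabled.

## Descriptive statistics

Cell summaries report n, observed range, mean and the standard error of the
mean using the n−1 sample standard deviation; a two-specimen cell therefore
has se = (max − min)/2 exactly, which is how the published two-specimen
cells were verified.  Singleton cells report no se.

Two percentage indices, both invariant under unit rescaling:

* sexual-dimorphism index = 100 · (mean_F − mean_M) / mean_F.  The female
  mean is the denominator; with the published means this lands the Medieval
  humerus at 13.9% and the modern NS six-element average at 10.9%, inside
  the reported 13.5–15% and 10–12% bands, whereas a male denominator does
  not.
* temporal shift = 100 · (mean_old − mean_new) / mean_new, so "Medieval
  females are 3% larger than modern" reads directly.  The six-element
  average of the published Medieval vs. modern NS female means is 3.03%.

Normality is checked with Shapiro–Wilk (scipy), supported for 3 ≤ n ≤ 5000;
a constant sample is an error rather than a silent p-value.

## PCA

Per element, complete-case specimens (no imputation — none is documented for
the source material) form a specimen × code matrix.  The default scaling is
the covariance matrix on raw mm, because "greatest length drives size
variation" is a claim about absolute variance; correlation scaling is
available for scale-free loadings.  The decomposition is a symmetric
eigendecomposition with a deterministic sign convention (each component's
largest-magnitude loading is made positive).  The dominant variable is the
code with the largest |loading| on PC1; exact ties break alphabetically with
a warning.

## Temporal models

**Per-group trends.** OLS of GL on calendar year per (population, sex,
element), n ≥ 3 and non-constant years required.  Calendar year is used
as-is so intercepts are at year 0, matching the published trend equations.
A helper converts a fit into a percentage decline over an interval relative
to its start.

**Sequential ANCOVA.**  GL ~ Year + Sex + Country + Year:Sex + Year:Country
over modern NS + DK complete cases, with Type I (sequential) sums of
squares in exactly that order: each term's SS is the drop in residual SS
when added after the preceding terms, so the decomposition sums exactly to
the total corrected SS.  The published table is order-dependent
(the museum data are unbalanced) and uses this order.  The decomposition is
computed by explicit nested OLS fits rather than a formula interface:
formula machinery (patsy) reorders same-degree terms with categoricals
before the numeric covariate and cannot produce a Year-first Type I table.
Factors use treatment coding with the alphabetically first level as
reference; sequential SS and F are invariant to that choice.  Rank-deficient
designs raise an error naming the aliased term.

**Country ANOVA.** One-way ANOVA of GL by country within sex (scipy
`f_oneway`), with pooled-variance pairwise t-tests (uncorrected); used for
the pooling decision above, not for inference about trends.

## The permutation test

The modern-vs-Medieval comparison uses Fisher's permutation test on the
difference of means, with the statistic oriented as
mean(modern) − mean(Medieval) so a negative difference means moderns are
smaller.  Under exchangeability the null distribution is generated by
repartitioning the pooled values into groups of the original sizes
(sampling without replacement within each relabelling).

Numerical conventions, fixed and documented because the source analysis
does not state them:

* **Exact vs Monte-Carlo.** When C(n_a + n_b, n_a) ≤ 200 000 (configurable)
  all partitions are enumerated and the p-value is exact — the fraction of
  partitions with |null difference| ≥ |observed|, a rational number whose
  denominator is the partition count, with the observed partition always
  included (so p > 0).  Otherwise B random relabellings are drawn and the
  two-sided Monte-Carlo p-value is (b + 1)/(B + 1) (add-one convention,
  which cannot report p = 0).  Monte-Carlo p-values converge to the
  exhaustive ones within binomial error; this is tested.
* **Tie handling.** |null| ≥ |observed| comparisons use a small relative
  tolerance so exactly-tied partitions (e.g. the mirrored observed
  partition) are counted, keeping exhaustive p-values exact in floating
  point.
* **The 95% interval** of the null is the empirical 2.5 and 97.5 percentile
  (linear-interpolation definition) of the null differences;
  `outside_interval` flags an observed difference beyond it, mirroring the
  observed-line-versus-histogram reading of a permutation plot.  Under a
  true null this flag fires ≈ 5% of the time, verified by simulation.
* **Reproducibility.** Per-cell seeds are derived from a base seed and a
  CRC of the cell label, so per-(sex, element) results are independent,
  stable across runs, and a fixed seed gives a bitwise-identical result.

Cells missing a period entirely (there are, for instance, no Medieval male
tibiotarsi) are skipped with a warning.

## Synthetic data

The generator draws measurement tables with the statistical structure the
analysis assumes, so every stage is testable without access to the museum
accession data.  Per specimen:

    value = anchor + slope · (year − 1900)
            + sd · (√ρ · z + √(1 − ρ) · ε)

with z a per-skeleton latent size factor shared across elements (inducing
inter-element correlation ρ, default 0.8 — the real correlation is not
published; 0.8 reflects the strongly size-dominated PCA) and ε independent
Gaussian noise.  Residuals are Gaussian because the source analysis
checked and passed Shapiro–Wilk normality on its cells.

Defaults are anchored to the published summary tables: cell means as anchors
at reference year 1900; residual sd = SE · √n per cell; per-element presence
probabilities n(element)/n(best element) so simulated tables reproduce the
published partial-skeleton pattern (including the empty Medieval male
tibiotarsus cell); the published humerus and femur slopes per group and sex,
other elements falling back to the group's mean published slope, Finland to
zero (no published Finnish trend); collection years uniform on 1861–2015.
The Medieval stratum carries no years and is generated as the NS anchor
scaled by a configurable shift — default +3% for females and 0 for males,
the effect size the archaeological comparison is designed to detect.  A
small fraction (default 2%) of modern labels is flipped to emulate mis-sexed
museum specimens; secondary codes (breadths/shaft widths) are derived from
GL with small independent noise so covariance PCA is GL-dominated.

What passing tests on this generator show: that the pipeline recovers known
trends, shifts and mislabels under realistic noise, sample sizes and
missingness, and that the permutation machinery is correctly calibrated.
What they do not show: robustness to non-Gaussian residuals, taphonomic or
falconry-driven selection of archaeological bones, clinal structure within
populations, measurement error correlated between sides, or NISP-vs-
individual double counting — none of which the generator emulates.

## Recovery experiment and operating characteristics

`recovery_experiment` runs the full inferential stack per simulated
replicate — reclassify sex from size ranges, fit the NS female year trend,
run all modern-NS-vs-Medieval permutation cells, fit the sequential
ANCOVA — and aggregates slope bias/RMSE, per-sex outside-interval rates and
the Year:Sex detection rate.  Reclassification is part of the loop
deliberately: regressing on raw recorded sex leaks mis-sexed males into the
female sample (the male cells are larger and better sampled), biasing the
female slope toward the male one by roughly the contamination fraction times
the slope difference; reclassifying first removes this, exactly as the real
workflow intends.  Under the null configuration (no trends, no shift, no
mislabels) flag rates sit near the nominal 5%; under the study-anchored
configuration female cells reject far more often than male cells, the
qualitative fingerprint of the published comparison.

Problem sizes used by the shipped checks (chosen to make simulation error
small relative to the effects under study): 2 000 replicates for null
calibration of the outside-interval flag, 100 instances for Monte-Carlo vs
exhaustive agreement at B = 2 000, 50 random designs for the ANCOVA
decomposition check, and 500 replicates at B = 2 000 for the power /
recovery experiment.

## Known limitations

* The sex-reclassification rule is a reconstruction; the original study
  reports reclassified specimens but not its decision procedure.
* Published group means mix collection eras, so using them as year-1900
  anchors slightly offsets simulated modern means from the printed ones;
  this affects realism, not correctness of any test.
* Residual sds for tiny archaeological cells (n = 2–3) inherit the
  instability of the printed standard errors they derive from.
* The between-country pairwise t-tests are uncorrected for multiplicity;
  they inform a pooling decision, not formal inference.
* Exhaustive enumeration is pure-Python over combinations and is capped
  (default 2 × 10⁵ partitions); larger cells switch to Monte-Carlo.
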
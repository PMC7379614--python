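# Methods

## The decay model

After rifampicin blocks transcription initiation, a transcript pool N(t) is
modelled in two phases: a delay of unknown length (drug uptake, polymerase
run-off) during which N stays at its peak, then first-order decay
N(t) = N₀ · 2^(−(t−t₀)/T½). The estimator (`rifdecay.decay.fit_two_phase`)
does not model the delay explicitly; it anchors the fit at the timepoint of
maximal expression and treats everything before it as delay:

1. **Peak selection.** t₀ is the *latest* timepoint attaining the maximum
   value. Ties go to the latest point because an early plateau is delay
   phase, not decay.
2. **Window selection.** Candidate windows run from t₀ to every later
   timepoint. Windows need ≥ `min_window_points` (default 3) points; when
   no 3-point window exists (peak next to the last point) a 2-point window
   is used and its R² reported as undefined. Among candidates, ordinary
   least squares of ln N on t is computed and the window with maximal R²
   wins; ties go to the longer window (more data at equal fit quality).
3. **Half-life.** T½ comes from the *endpoints* of the chosen window,
   T½ = (t − t₀)/(log₂ N₀ − log₂ N), not from the OLS slope. The slope m
   (ln units per minute) and R² are reported alongside; for clean
   exponential decay ln 2/|m| equals the endpoint T½ exactly, and the test
   suite asserts both to 10⁻⁹ relative on noiseless input. On real data the
   two can disagree slightly; the endpoint formula is authoritative because
   it is the study design's definition of the half-life.
4. **Classification.** `no_decay` when the slope is non-negative or the
   half-life is undefined, non-positive, or above `max_halflife_min`
   (default 1000 min); `non_exponential` when a defined R² falls below
   `r2_min` (default 0.5); otherwise `exponential`. The source protocol
   states no thresholds for either rule, so both are explicit settings.
5. **Pre-treatment control.** The sample taken before rifampicin addition
   is carried separately and never enters the fit: pre-treatment abundance
   is typically 6–9× below the post-treatment peak, and including it would
   manufacture apparent growth.
6. **Non-detections.** Zero counts are flagged undetected, never
   log-transformed with a pseudocount. With `require_full_detection` (the
   default) any undetected timepoint makes the series `insufficient_data`;
   otherwise undetected points are dropped before fitting.

### Known limitation: pseudo-decay from counting noise

With only four timepoints, the argmax-R² window search actively looks for
the best-looking decay in noise. For a truly constant pool measured by
count sampling, the endpoint formula turns a small spurious decline into a
finite half-life — typically hundreds of minutes over a 60-minute chase —
and the window search often finds an R² above 0.5 for it. Under the default
classification cap (1000 min) roughly one in five simulated non-decaying
families is therefore misclassified as a slow exponential decayer at
10⁶-read depth; the misclassified half-lives concentrate in low-abundance
features and in the 100–1000 min range, i.e. beyond the chase duration.
Consumers should treat half-lives much longer than the chase with caution,
or lower `max_halflife_min` to the longest half-life they consider
resolvable. We deliberately keep the permissive default rather than tune it
to make recovery simulations look better.

## qPCR quantification

Standard curves are OLS fits of Cq on log₁₀(copies) over a 10⁷→1 dilution
series (≥ 3 distinct levels required; non-monotone or non-negative-slope
curves are rejected). Amplification efficiency is the dilution-series
definition E = 10^(−1/slope) − 1; fitted efficiencies outside 68.7–98.9% —
the range observed for the assays this package was built around — warn but
proceed. Unknowns are quantified per replicate as 10^((Cq−intercept)/slope)
and then averaged on the copies scale: averaging Cq first and exponentiating
after biases the copy number low (Jensen's inequality), which the tests
demonstrate. The no-RT control measures undigested genomic DNA; its copy
number is subtracted from the cDNA signal, floored at zero, with the
background fraction rna/cdna reported for QC and a flag when the control
exceeds the signal.

## Metatranscriptome pipeline

**Normalization.** For each taxon (family path, or bacterial class), the
mRNA assignment count is divided by the rRNA assignment count in the same
sample. This cancels sequencing depth and cell abundance, leaving a
quantity proportional to transcripts per unit ribosome; its decay over the
chase estimates the mRNA half-life of that taxon's transcript pool. A
timepoint with zero mRNA or zero rRNA counts is undetected.

**QC.** Two per-sample screens: (1) samples retaining ≤ 50% of their
pre-QC mRNA reads are dropped (the raw totals are an optional input; when
absent, no loss is assumed); (2) a disagreement screen drops outlier
samples. The source protocol reports screening on ">30% disagreement"
without defining the statistic, so this package defines it: disagreement of
sample s = 1 − Spearman rank correlation between s's per-family mRNA:rRNA
profile and the element-wise median profile across samples, computed over
features detected in every sample. It is rank-based (free of per-sample
scale), uses the median profile as a robust consensus, and its 0.30
threshold mirrors the reported rule. The pre-treatment sample is screened
like any other but never enters decay fits. Fewer than three surviving
post-treatment samples abort the run with a named-sample diagnostic.

**Eligibility and tallies.** Families are *jointly assigned* when both
tables contain them with non-zero totals. A family undetected at any
retained timepoint is excluded as `insufficient_data`; fitted families
classify as exponential or are excluded (no-decay and non-exponential are
tallied together, matching how such studies report their exclusions). The
tally partitions the jointly assigned set exactly, and a test asserts the
conservation. For the functional analysis, mRNA features are keyed
`Class|X` with X one of the 18 COG subcategory letters (V N T U M O D F C
H G P E I Q J K L); classes with mean rRNA ≤ 1000 or mean mRNA ≤ 200
assignments per sample are too sparse for subcategory fits and are
excluded. rRNA carries no COG label, so the class-level rRNA count is the
divisor; an rRNA table keyed `Class|X` is aggregated to class first.

**Statistics.** All tests are two-tailed with no multiple-testing
correction. In one-sample t-tests against the 16S rRNA reference, "no
decay" entries are replaced by a 100-minute surrogate (the convention for
treating a non-decaying pool as very long-lived); in medians, ranges and
threshold fractions they are simply excluded. Mann–Whitney uses the exact
null distribution for small tie-free samples and the tie-corrected normal
approximation otherwise. The CV-vs-mean regression computes, per COG
subcategory, the mean and coefficient of variation of half-lives across
classes (subcategories with fewer than two class values are dropped with a
warning), then Pearson r and the OLS line with a 95% CI on the slope.

The bundled isolate table (`rifdecay.datasets`) carries the published
per-gene half-lives, slopes and R² of three marine isolates at three
temperatures. The statistics layer reproduces the published t-test row and
the four mean-half-life correlations from it; one flagged outlier gene
(*rpoB* at 25 °C in *Croceibacter*) is excluded via an explicit exclusions
argument, not a hard-coded rule.

## Synthetic data

The generators emulate the experimental structure, not the biology of any
particular sample:

* **Half-lives** are lognormal with median 28 min and log-SD 0.6. A
  lognormal cannot place 95% of its mass exactly on the observed 9–400 min
  range while keeping the median at 28; σ = 0.6 keeps ~97% of draws inside
  that range (95% interval ≈ 8.6–91 min), trading tail coverage for the
  correct centre. 16% of families are rifampicin-resistant: their mRNA
  pools do not decay.
* **rRNA** is quasi-stable: it decays with the family half-life times 20,
  so the mRNA:rRNA ratio overestimates the mRNA half-life by a known
  ~5% (1/(1−1/20)); this bias is inherent to ratio normalization whenever
  the denominator is not perfectly stable.
* **Abundance and expression.** Family abundances are lognormal (σ = 1);
  mRNA pools additionally carry a per-family expression level (lognormal,
  σ = 1.5) because real taxa differ by orders of magnitude in mRNA per
  unit rRNA. This expression structure is what keeps the rank order of
  ratio profiles stable across chase samples — the condition under which
  the disagreement screen retains legitimate samples, as observed in real
  chase series.
* **Sampling.** Each sample draws a read depth uniformly from
  3.2×10⁵–2.2×10⁶ and distributes it multinomially over the *combined*
  mRNA + rRNA pool; the community's initial mRNA fraction is drawn once
  per run from 56.3–93.5% and the realized per-sample fraction declines as
  mRNA decays, as in shotgun sequencing. Multinomial counting noise is the
  only measurement noise by default (`noise_cv` adds lognormal pool noise
  if wanted); the qPCR generator instead applies 20% lognormal noise to
  abundances before converting to Cq through an ideal standard curve.
* **Delay and lag.** Decay starts after a uniform 0–5 min delay; the
  pre-treatment pool sits a lognormal factor below the peak (mean 6.1 for
  the community, 9.3 for isolates; SD larger than the mean, so the factor
  is drawn truncated at > 1 rather than normal).
* **Growth curves** are piecewise lag/log/stationary with a programmed
  doubling time and optional lognormal noise, for exercising the
  generation-time formula G = t/log₂(N/N₀).

Every generator is driven by a single seed and emits a truth table per
entity; identical config and seed give bit-identical output.

**What passing recovery tests do and do not show.** The generators omit
annotation error, chimeras, read-length effects, taxon-specific biases and
any real taxonomic structure; recovery of half-lives from synthetic tables
therefore validates the estimator and pipeline logic, not the accuracy of
half-lives derived from real, database-annotated reads. The headline
figures of real community analyses (family half-life range and median, COG
subcategory range, the CV-vs-mean correlation strength) are emulated in
regime — cohort medians land near 28 min and the CV-mean correlation is
positive when class variance scales with the mean — but are not
reproductions and are not claimed as such.

## Problem sizes

The default simulation sizes (100 families, 4 timepoints, 10⁶ reads per
sample for recovery runs; 1000 families for distribution-conformance
checks; 50 genes for the qPCR lag check) keep the full test suite and the
acceptance script in the seconds-to-a-minute range while leaving per-family
counts large enough that counting noise, not sample size, dominates the
recovery error.
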
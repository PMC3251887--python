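# Methods

## Scope and model

`nbprofile` implements the genomic-type analysis used for infant
neuroblastoma array-CGH cohorts: per-probe copy-number status, the
NCA / SCA / silent classification, breakpoint localisation, DNA-index
ploidy classes, contingency-table association tests and PFS modelling.
The original smoothing algorithm used for probe-status assignment (GLAD)
is deliberately **not** reimplemented: the downstream classification
rules consume only per-probe statuses, so a transparent penalised
least-squares changepoint segmentation stands in for it. This is a
documented substitution, not an emulation of GLAD internals.

## Genome model

Coordinates are 0-based half-open throughout. A bundled hg18-like table
gives chromosome lengths and p/q boundaries; the boundaries are
cytoband-derived approximations (the build is a packaged constant, and
users can substitute their own config). Probe grids are deterministic
contiguous tiles per arm — 1 Mb (BAC, 2996 probes genome-wide) and 40 kb
(oligo, 74 360 probes, within 10% of the 72 000-probe platform they
emulate). Centromeric gaps carry no probes, so no probe spans an arm
boundary.

## Segmentation and status calling

Per chromosome, the observed (non-missing) log2 ratios are fitted with a
piecewise-constant model minimising `SSE + beta * (#changepoints)`:
exact O(n²) dynamic programming up to 1500 probes, greedy binary
segmentation beyond (oligo grids). The noise scale sigma is estimated
per chromosome by the median absolute successive difference
(`median|diff| / (0.6745·√2)`), and the default penalty is

    beta = 5 * sigma² * log(n).

The multiplier 5 is a deliberate design choice: a chromosome-edge
segment costs a single changepoint, so the minimum fluctuation that
survives the penalty has `|mean| ≈ sigma · √(mult · log n)` regardless of
run length — about 2.1 sd at multiplier 1 (which floods a 3000-probe
genome with spurious above-threshold segments and drives planted-type
recovery far below 95%) versus about 4.7 sd at multiplier 5, while the
smallest planted events (≥ 5 probes at ≥ 0.38 log2) sit near 8.5 sd.
The penalty is floored at 1e-12 so noise-free profiles still prefer the
fewest segments, making noiseless recovery exact and the procedure
idempotent on fitted means.

The NORMAL reference level is the probe-weighted median of segment means
— the analogue of "the median copy number across the genome" — so status
calls are invariant to adding a constant to all ratios, and a uniformly
trisomic genome is alteration-free. Status thresholds default to
±0.1 log2 (GAIN when `mean − baseline ≥ 0.1`, LOSS symmetric), which
clears a single-copy event mixed with ≥ 10% normal cells by a wide
margin. Missing probes are skipped, not imputed; contiguity downstream
is counted over observed probes (a run broken by a missing probe is two
runs).

## Classification

Per chromosome: all observed probes sharing one non-NORMAL status give a
whole-chromosome (numerical) call. Otherwise "different from the rest of
the chromosome" is operationalised as different from the probe-majority
status, ties broken toward NORMAL then GAIN; each maximal constant run
differing from the majority with ≥ 3 (BAC) / ≥ 100 (oligo) probes is a
segmental call, its direction taken relative to the majority (a NORMAL
run on a gained chromosome is a relative loss). Sub-threshold runs are
discarded, so "silent" means zero calls after thresholding. A whole-arm
alteration is segmental, not numerical — it does not span the entire
chromosome. Segmental calls are assigned to arms by base-pair overlap; a
centromere-straddling call is reported once per overlapped arm. The
recurrent ("typical") set is {1p−, 1q+, 2p+, 3p−, 4p−, 11q−, 17q+}.
Breakpoints take the start coordinate of the left probe of each status
transition, which biases recorded positions left by up to one probe
spacing (≤ 1 Mb on BAC) relative to the true change.

## Statistics

Pearson chi-square is computed without continuity correction (the
uncorrected statistic reproduces the published bounds, e.g. 19.2 for the
NCA/SCA ploidy rows). The exact test enumerates all 2×k tables with the
observed margins over the smaller row (at most `C(r+k−1, k−1)` tables)
and sums multivariate-hypergeometric probabilities ≤ that of the
observed table — two-sided by probability ordering, reducing to Fisher's
two-sided test at k = 2. Test selection follows the usual expected-count
rule (exact when any expected count < 5). Single-marker tables exclude
silent profiles; the genomic-profile table keeps them as a third row for
the ploidy stratifier. No multiple-testing correction is applied.

## Survival

PFS is time from diagnosis to first progression, with the stage-4s rule:
in INES99.2 patients without upfront treatment, a progression within the
first 2 months of observation is ignored as an event and follow-up
continues (censored at last follow-up unless a later event is recorded).
The clinical record carries a single progression time, so at most one
early progression per patient can be discounted. Kaplan–Meier carries
Greenwood standard errors. The Cox partial likelihood is maximised by
Newton–Raphson with step-halving (monotone likelihood guaranteed),
Breslow ties by default (Efron optional; adequate at this cohort's ~30
events), convergence at max |Δβ| < 1e-8, Wald 95% CIs. A diverging
coefficient (|β| > 30, separation) stops iteration with a warning and an
unconverged flag rather than a silent failure; rank-deficient covariate
matrices are rejected. Backward selection refits after dropping the
largest Wald *P* > 0.05 until all retained covariates are significant.
The score test at β = 0 equals the log-rank statistic, which the test
suite uses as a cross-module identity, with lifelines as an independent
oracle for KM, log-rank and Cox estimates.

## Synthetic cohort: what it emulates, and what not

Defaults state the published cohort structure: 93/93/32 patients per
trial, SCA prevalence 0.11/0.20/0.59, global silent rate 8/218,
segmental-event frequencies conditional on SCA from the observed
spectrum (17q+ 0.81, 2p+ 0.43, 1p− 0.41, 11q− 0.39, 4p− 0.29, 3p− 0.15,
1q+ 0.10), 11q breakpoints uniform in [70, 82) Mb, di-/tetraploid
fractions 16/81 (NCA), 16/24 (SCA), 1/3 (silent), DNA index observed for
108/218, oligo platform for 33/218, and exponential hazards pinned to
5-year PFS 0.92 / 0.707 / 0.625 (NCA / SCA / silent) with administrative
censoring at 60 months. Values the published record does not state were
chosen once as field-plausible: Gaussian noise sd 0.1 on log2 ratios,
tumour fraction uniform on (0.6, 1.0] (inclusion requires > 50% tumour
cells), whole-chromosome event counts 3–8 (NCA; 70% gains), a bone-
metastasis odds multiplier of 6 for SCA tumours on trial-specific base
odds (0 / 0.04 / 1.0), stage-4s symptom rate 40/91 (symptoms ⇒ upfront
chemotherapy), planted events ≥ 5 Mb and breakpoint-to-telomere, and age
means 6.7 vs 5.1 months (SCA vs NCA).

The generator renders ratios with the tumour-fraction mixture
`log2((f·c + (1−f)·2) / (f·c_med + (1−f)·2))` against the tumour's
genome-median copy number plus i.i.d. Gaussian noise. It does **not**
model probe-specific (GC/mappability) bias, wavy baselines, subclonal
events, allele-specific copy number, *MYCN* amplification (excluded by
design) or interval-censored follow-up — so a green end-to-end test
establishes that the classification rules and statistics behave
correctly under the stated forward model, not that the segmentation is
robust to real-array artefacts. Randomness flows from one seed through
per-patient spawned generators: identical seeds give byte-identical
fixtures; changing the seed changes noise realisations but not the
design.

## Numerical choices and degenerate inputs

Weighted medians use `numpy.median` over per-probe expanded means (even
splits average the two central values). Exact-test tie comparison uses a
1e-9 relative tolerance. Chromosomes with fewer than `2·min_probes`
observed probes yield a single segment (`min_probes` defaults to 2).
Empty profiles, non-positive thresholds, negative noise, non-positive
DNA indices and zero-margin tables raise explicit errors; frequency
tables drop empty rows/columns before testing and report `method: NONE`
when fewer than 2×2 informative cells remain. The pipeline skips the
multivariate model below 5 events rather than fitting an unstable one.

## Known limitations

Binary segmentation (oligo scale) is greedy and may misplace boundaries
between adjacent events of similar level; arm assignment of calls uses
base-pair overlap against approximate arm boundaries; the published
per-trial breakdown of silent profiles is not stated, so the silent rate
is a single global parameter; overall survival is carried only as a
death flag and has no dedicated analysis (the published analysis itself
restricts to PFS beyond 5 deaths).
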
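# nbprofile

Genomic-profile analysis of array-CGH data for infant neuroblastoma
cohorts: probe-status calling, classification of tumours into **NCA**
(numerical chromosome alterations only), **SCA** (segmental chromosome
alterations, with or without NCA) and **silent** genomic types, arm-level
alteration and breakpoint calling, DNA-index ploidy classification, and
the cohort statistics (contingency tests, Kaplan–Meier / log-rank, Cox
proportional hazards with backward selection) used to relate genomic type
to metastatic pattern and progression-free survival (PFS).

The package is aimed at methodologists who want a tested, reusable and
fully synthetic-data-testable implementation of this classification
pipeline, structured after the INES infant-neuroblastoma trials
(INES99.1 localised unresectable, INES99.2 stage 4s, INES99.3 stage 4;
*MYCN*-non-amplified infants).

## The classification rules

Per-probe log2 ratios on a BAC (~1 Mb) or oligonucleotide (~40 kb) grid
are reduced to GAIN / LOSS / NORMAL status relative to the genome-median
level by a penalised least-squares changepoint segmentation (exact
dynamic programming at BAC scale, binary segmentation at oligo scale;
BIC-style penalty). Then, per chromosome:

- **NCA**: every observed probe homogeneously altered relative to the
  genome median ⇒ one whole-chromosome call;
- **SCA**: a run of ≥ 3 contiguous BAC probes or ≥ 100 contiguous
  oligonucleotide probes whose status differs from the rest of the
  chromosome (operationalised as the probe-majority status);
- a tumour with ≥ 1 SCA has a *SCA genomic profile*; only-NCA tumours a
  *NCA profile*; no calls at all ⇒ *silent*.

Breakpoints are recorded at the start coordinate of the probe on the left
side of each status transition. Ploidy from the DNA index *I*:
di-/tetraploid if *I* ≤ 1.2 or *I* ≥ 1.8, pseudotriploid in between
(strict mode: diploid iff *I* ≤ 1).

Survival: PFS records (with the stage-4s rule that an early progression
under observation only, within 2 months, is not counted), Kaplan–Meier
with Greenwood standard errors, the log-rank test, and a Cox partial
likelihood maximised by Newton–Raphson (Breslow ties, Efron optional)
with backward elimination at Wald *P* ≤ 0.05.

A forward model (`nbprofile.simulate`) generates fully synthetic cohorts:
planted genomic types at the trial-specific SCA prevalences (11% / 20% /
59%), the recurrent alteration spectrum (17q+ most frequent; 11q− with
breakpoints in a 70–82 Mb cluster), tumour-fraction mixture rendering of
log2 ratios, ploidy and bone-metastasis associations, and exponential
progression hazards pinned to 5-year PFS of 0.92 (NCA) / 0.71 (SCA).

## Worked example

```python
import nbprofile as nb

report = nb.run_pipeline(nb.RunConfig(cohort_spec=nb.CohortSpec(seed=1)))
```

On the default 218-patient synthetic cohort (93 / 93 / 32 per trial) this
prints, among other blocks:

- `genomic_type_counts`: 10/93, 18/93 and 23/32 SCA tumours in
  INES99.1/2/3 — the planted prevalence gradient recovered from the
  rendered, noisy profiles;
- `survival.overall.groups`: 5-year PFS 91.9% (±2.1) for NCA vs 74.5%
  (±6.1) for SCA, log-rank χ² = 11.1 (*P* = 0.0038);
- `cox`: from nine candidate covariates (SCA profile, six single markers,
  two trial indicators) backward selection retains only `sca_profile`,
  HR 3.43 (95% CI 1.59–7.40, *P* = 0.0017) — single alterations are
  dropped because the SCA profile subsumes them;
- `breakpoint_cluster_11q`: extracted 11q breakpoints span 11 Mb
  (69.4–80.4 Mb), matching the planted 70–82 Mb cluster at 1 Mb probe
  resolution.

`nbprofile.worked_examples()` recomputes table-level quantities from the
bundled published counts (marker totals, the 81% 17q-gain frequency among
48 SCA tumours, the bone-metastasis and ploidy chi-squares, the
relapse-listing summaries).

The same stages are available from the shell:

```bash
nbprofile simulate --seed 1 --out cohort/
nbprofile segment  --in cohort/profiles.tsv --out segments.tsv
nbprofile classify --in cohort/profiles.tsv --out calls/
nbprofile run-all  --seed 1 --out run/
nbprofile ref-check
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic cohort from the seed, runs the full
pipeline (segmentation → classification → association tests → survival
models) and the published-count worked examples, and writes the
target-value JSON (plus a `*_report.json` sidecar with the full pipeline
report) to the requested path.
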
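"""Synthetic INES-like cohort generator.

Produces tumour copy-number profiles with planted NCA/SCA/silent structure
plus linked clinical covariates and follow-up, emulating the structure of
the infant neuroblastoma INES trials: per-trial SCA prevalence (11% /
20% / 59% in INES99.1/99.2/99.3), the recurrent segmental-alteration
spectrum (17q gain the most frequent, 11q-loss breakpoints clustered in
[70, 82) Mb), enrichment of SCA tumours among di-/tetraploid DNA indices
and among infants with bone metastases, and exponential progression
hazards pinned to 5-year PFS of ~0.92 (NCA) and ~0.71 (SCA).

The forward model for probe log2 ratios mixes the tumour copy number with
a diploid normal background at the tumour-cell fraction f:

    log2( (f*c + (1-f)*2) / (f*c_med + (1-f)*2) ) + Gaussian noise,

where c is the local copy number and c_med the tumour's genome-median
copy number (the array reference level).  All randomness flows from a
single seed through per-patient spawned generators, so cohorts are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import NCA, SCA, SILENT
from .genome import GenomeBuild, ProbeGrid, build_probe_grid, default_build
from .segmentation import CopyNumberProfile

__all__ = [
    "TumorSpec",
    "CohortSpec",
    "Cohort",
    "sample_tumor_spec",
    "render_log_ratios",
    "sample_clinical",
    "simulate_followup",
    "generate_cohort",
    "write_cohort",
]

TRIALS = ("INES99.1", "INES99.2", "INES99.3")

#: probability of each recurrent segmental event given a SCA tumour,
#: from the observed frequencies among 48 SCA tumours
DEFAULT_SCA_EVENT_FREQ = {
    ("17", "q", +1): 0.81,
    ("2", "p", +1): 0.43,
    ("1", "p", -1): 0.41,
    ("11", "q", -1): 0.39,
    ("4", "p", -1): 0.29,
    ("3", "p", -1): 0.15,
    ("1", "q", +1): 0.10,
}

#: P(di-/tetraploid DNA index | genomic type), from the published ploidy
#: repartition (16/81 NCA, 16/24 SCA, 1/3 silent)
DEFAULT_PLOIDY_MIX = {NCA: 16 / 81, SCA: 16 / 24, SILENT: 1 / 3}

_FIVE_YEARS = 60.0


def _hazard_from_pfs(pfs_5y: float, horizon: float = _FIVE_YEARS) -> float:
    """Constant hazard per month matching a 5-year survival level."""
    return -np.log(pfs_5y) / horizon


DEFAULT_HAZARDS = {
    NCA: _hazard_from_pfs(0.92),
    SCA: _hazard_from_pfs(0.707),
    SILENT: _hazard_from_pfs(0.625),
}


@dataclass
class TumorSpec:
    """Ground-truth description of one simulated tumour."""

    genomic_type: str
    whole_chromosome_events: list[tuple[str, int]]
    segmental_events: list[tuple[str, str, tuple[int, int], int]]
    ploidy: float  # DNA index
    tumor_fraction: float
    platform: str

    def __post_init__(self) -> None:
        if not 0.5 < self.tumor_fraction <= 1.0:
            raise ValueError("tumour fraction must be in (0.5, 1] (sample-inclusion rule)")
        if self.genomic_type == SILENT and (self.whole_chromosome_events or self.segmental_events):
            raise ValueError("silent tumours carry no events")
        if self.genomic_type == NCA and (self.segmental_events or not self.whole_chromosome_events):
            raise ValueError("NCA tumours carry whole-chromosome events only")
        if self.genomic_type == SCA and not self.segmental_events:
            raise ValueError("SCA tumours need at least one segmental event")


@dataclass
class CohortSpec:
    """All knobs of the simulated cohort, with INES-like defaults."""

    n_per_trial: tuple[int, int, int] = (93, 93, 32)
    sca_prevalence_by_trial: tuple[float, float, float] = (0.11, 0.20, 0.59)
    silent_rate: float = 8 / 218
    sca_event_freq: dict = field(default_factory=lambda: dict(DEFAULT_SCA_EVENT_FREQ))
    cluster_11q: tuple[int, int] = (70_000_000, 82_000_000)
    min_segment_bp: int = 5_000_000
    bone_base_odds: dict = field(
        default_factory=lambda: {"INES99.1": 0.0, "INES99.2": 0.04, "INES99.3": 1.0}
    )
    bone_odds_multiplier: float = 6.0
    ploidy_mix: dict = field(default_factory=lambda: dict(DEFAULT_PLOIDY_MIX))
    dna_index_available: float = 108 / 218
    hazards: dict = field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    death_given_event: float = 5 / 30
    horizon_months: float = _FIVE_YEARS
    noise_sd: dict = field(default_factory=lambda: {"BAC": 0.1, "OLIGO": 0.1})
    oligo_fraction: float = 33 / 218
    tumor_fraction_range: tuple[float, float] = (0.6, 1.0)
    symptoms_rate_4s: float = 40 / 91
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (*self.sca_prevalence_by_trial, self.silent_rate, self.oligo_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for v in self.hazards.values():
            if v < 0:
                raise ValueError("hazards must be non-negative")


@dataclass
class Cohort:
    """A generated cohort: profiles, clinical table and ground truth."""

    spec: CohortSpec
    build: GenomeBuild
    grids: dict[str, ProbeGrid]
    profiles: list[CopyNumberProfile]
    clinical: pd.DataFrame
    truth: pd.DataFrame  # planted labels, kept separate from clinical


def _sample_genomic_type(spec: CohortSpec, trial: str, rng: np.random.Generator) -> str:
    p_sca = spec.sca_prevalence_by_trial[TRIALS.index(trial)]
    if rng.random() < p_sca:
        return SCA
    # conditional silent rate keeps the marginal silent fraction at silent_rate
    p_silent = spec.silent_rate / (1.0 - p_sca) if p_sca < 1 else 0.0
    return SILENT if rng.random() < p_silent else NCA


def _draw_segmental_interval(
    spec: CohortSpec, build: GenomeBuild, chrom: str, arm: str, rng: np.random.Generator
) -> tuple[int, int]:
    """Breakpoint-to-telomere interval; 11q breakpoints drawn in the
    configured cluster window, all events at least ``min_segment_bp``."""
    a0, a1 = build.arm_interval(chrom, arm)
    if (chrom, arm) == ("11", "q"):
        lo, hi = spec.cluster_11q
        bp = int(rng.uniform(lo, min(hi, a1 - spec.min_segment_bp)))
        return bp, a1
    if arm == "q":  # distal q event from an interior breakpoint
        bp = int(rng.uniform(a0 + 0.05 * (a1 - a0), a1 - spec.min_segment_bp))
        return bp, a1
    # p-arm event from the telomere down to a breakpoint
    bp = int(rng.uniform(a0 + spec.min_segment_bp, a1 - 0.05 * (a1 - a0)))
    return a0, bp


def sample_tumor_spec(spec: CohortSpec, trial: str, rng: np.random.Generator) -> TumorSpec:
    """Draw one tumour's ground truth for a given trial arm."""
    gtype = _sample_genomic_type(spec, trial, rng)
    build = _BUILD_CACHE.setdefault("default", default_build())

    whole: list[tuple[str, int]] = []
    segmental: list[tuple[str, str, tuple[int, int], int]] = []
    if gtype in (NCA, SCA):
        with_nca = gtype == NCA or rng.random() < 0.5
        if with_nca:
            n_chrom = int(rng.integers(3, 9)) if gtype == NCA else int(rng.integers(1, 5))
            chroms = rng.choice([str(i) for i in range(1, 23)], size=n_chrom, replace=False)
            whole = [(c, +1 if rng.random() < 0.7 else -1) for c in chroms]
    if gtype == SCA:
        whole_chroms = {c for c, _ in whole}
        for (chrom, arm, delta), p in spec.sca_event_freq.items():
            if rng.random() < p and chrom not in whole_chroms:
                segmental.append((chrom, arm, _draw_segmental_interval(spec, build, chrom, arm, rng), delta))
        if not segmental:  # every SCA tumour carries >=1 segmental event
            chrom, arm, delta = "17", "q", +1
            whole = [w for w in whole if w[0] != chrom]
            segmental.append((chrom, arm, _draw_segmental_interval(spec, build, chrom, arm, rng), delta))

    p_di = spec.ploidy_mix[gtype]
    if rng.random() < p_di:
        dna_index = (
            float(np.clip(rng.normal(1.02, 0.05), 0.85, 1.2))
            if rng.random() < 0.5
            else float(np.clip(rng.normal(1.9, 0.06), 1.8, 2.1))
        )
    else:
        dna_index = float(np.clip(rng.normal(1.5, 0.12), 1.25, 1.75))

    lo, hi = spec.tumor_fraction_range
    return TumorSpec(
        genomic_type=gtype,
        whole_chromosome_events=whole,
        segmental_events=segmental,
        ploidy=dna_index,
        tumor_fraction=float(rng.uniform(lo, hi)),
        platform="OLIGO" if rng.random() < spec.oligo_fraction else "BAC",
    )


_BUILD_CACHE: dict[str, GenomeBuild] = {}


def render_log_ratios(
    tumor: TumorSpec,
    grid: ProbeGrid,
    noise_sd: float,
    rng: np.random.Generator,
    patient_id: str = "sim",
) -> CopyNumberProfile:
    """Forward-model per-probe log2 ratios for one tumour."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if grid.platform != tumor.platform:
        raise ValueError(f"grid platform {grid.platform} != tumour platform {tumor.platform}")
    probes = grid.probes
    chrom_col = probes["chrom"].to_numpy()
    mid = (probes["start"].to_numpy() + probes["end"].to_numpy()) // 2

    copy = np.full(len(grid), 2.0)
    for chrom, delta in tumor.whole_chromosome_events:
        copy[chrom_col == chrom] += delta
    for chrom, _arm, (lo, hi), delta in tumor.segmental_events:
        copy[(chrom_col == chrom) & (mid >= lo) & (mid < hi)] += delta

    f = tumor.tumor_fraction
    c_med = np.median(copy)
    ratios = np.log2((f * copy + (1 - f) * 2.0) / (f * c_med + (1 - f) * 2.0))
    if noise_sd > 0:
        ratios = ratios + rng.normal(0.0, noise_sd, size=len(ratios))
    return CopyNumberProfile(
        patient_id=patient_id, grid=grid, ratios=ratios, platform=tumor.platform
    )


def sample_clinical(
    spec: CohortSpec,
    tumor: TumorSpec,
    trial: str,
    rng: np.random.Generator,
    patient_id: str = "sim",
) -> dict:
    """Draw clinical covariates linked to the tumour's genomic type.

    INES99.1 (localised unresectable) patients carry no metastases; bone
    metastasis odds are multiplied by ``bone_odds_multiplier`` for SCA
    tumours; the DNA index is observed for a subset of patients.
    """
    is_sca = tumor.genomic_type == SCA
    if trial == "INES99.1":
        liver = skin = bone_marrow = bone = False
    else:
        if trial == "INES99.2":
            liver, skin, bone_marrow = (
                bool(rng.random() < 0.55),
                bool(rng.random() < 0.20),
                bool(rng.random() < 0.45),
            )
        else:
            liver, skin, bone_marrow = (
                bool(rng.random() < 0.30),
                bool(rng.random() < 0.10),
                bool(rng.random() < 0.80),
            )
        odds = spec.bone_base_odds[trial] * (spec.bone_odds_multiplier if is_sca else 1.0)
        bone = bool(rng.random() < odds / (1.0 + odds))

    if trial == "INES99.2":
        symptoms = bool(rng.random() < spec.symptoms_rate_4s)
        upfront = symptoms
    else:
        symptoms = trial == "INES99.3"
        upfront = True

    age_mean = 6.7 if is_sca else 5.1
    age = float(np.clip(rng.normal(age_mean, 2.5), 0.5, 11.9))
    dna_index = tumor.ploidy if rng.random() < spec.dna_index_available else np.nan
    return {
        "patient_id": patient_id,
        "trial": trial,
        "age_months": age,
        "liver": liver,
        "skin": skin,
        "bone_marrow": bone_marrow,
        "bone": bone,
        "symptoms_at_diagnosis": symptoms,
        "upfront_chemo": upfront,
        "dna_index": dna_index,
    }


def simulate_followup(
    spec: CohortSpec,
    record: dict,
    genomic_type: str,
    rng: np.random.Generator,
) -> dict:
    """Exponential progression time with administrative censoring.

    Returns ``followup_months`` (horizon), ``event``, the progression
    time when an event occurred, and a death flag drawn among events.
    """
    lam = spec.hazards[genomic_type]
    t = rng.exponential(1.0 / lam) if lam > 0 else np.inf
    if t <= spec.horizon_months:
        event, prog = 1, float(t)
        death = bool(rng.random() < spec.death_given_event)
    else:
        event, prog, death = 0, np.nan, False
    return {
        "followup_months": spec.horizon_months,
        "progression_months": prog,
        "event": event,
        "death": death,
    }


def generate_cohort(spec: CohortSpec, build: GenomeBuild | None = None) -> Cohort:
    """Generate the full cohort: profiles, clinical table, ground truth.

    Fully reproducible from ``spec.seed``: each patient consumes an
    independent spawned generator, so marginal structure is stable under
    seed changes while noise realisations differ.
    """
    build = build or default_build()
    _BUILD_CACHE["default"] = build
    grids = {p: build_probe_grid(build, p) for p in ("BAC", "OLIGO")}

    n_total = sum(spec.n_per_trial)
    streams = np.random.SeedSequence(spec.seed).spawn(n_total)

    profiles: list[CopyNumberProfile] = []
    clinical_rows: list[dict] = []
    truth_rows: list[dict] = []
    pid = 0
    for trial, n in zip(TRIALS, spec.n_per_trial):
        for _ in range(n):
            rng = np.random.default_rng(streams[pid])
            patient_id = f"P{pid + 1:04d}"
            tumor = sample_tumor_spec(spec, trial, rng)
            grid = grids[tumor.platform]
            profile = render_log_ratios(
                tumor, grid, spec.noise_sd[tumor.platform], rng, patient_id=patient_id
            )
            clin = sample_clinical(spec, tumor, trial, rng, patient_id=patient_id)
            clin.update(simulate_followup(spec, clin, tumor.genomic_type, rng))
            profiles.append(profile)
            clinical_rows.append(clin)
            truth_rows.append(
                {
                    "patient_id": patient_id,
                    "genomic_type": tumor.genomic_type,
                    "platform": tumor.platform,
                    "tumor_fraction": tumor.tumor_fraction,
                    "n_whole_chromosome": len(tumor.whole_chromosome_events),
                    "n_segmental": len(tumor.segmental_events),
                    "segmental_events": ";".join(
                        f"{c}{a}{'+' if d > 0 else '-'}:{lo}-{hi}"
                        for c, a, (lo, hi), d in tumor.segmental_events
                    ),
                }
            )
            pid += 1

    return Cohort(
        spec=spec,
        build=build,
        grids=grids,
        profiles=profiles,
        clinical=pd.DataFrame(clinical_rows),
        truth=pd.DataFrame(truth_rows),
    )


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write profiles (long TSV), clinical table and ground-truth sidecar.

    The truth table is a separate file so that the analysis pipeline
    cannot peek at planted labels.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": str(outdir / "profiles.tsv"),
        "clinical": str(outdir / "clinical.tsv"),
        "truth": str(outdir / "truth.tsv"),
    }
    frames = []
    for p in cohort.profiles:
        df = p.grid.probes.copy()
        df.insert(0, "patient_id", p.patient_id)
        df["log2_ratio"] = p.ratios
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        paths["profiles"], sep="\t", index=False, float_format="%.6f"
    )
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False, float_format="%.6f")
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6f")
    return paths
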
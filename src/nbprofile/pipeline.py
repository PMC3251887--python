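"""End-to-end orchestration: simulate -> segment -> classify -> stats -> survival.

:func:`run_pipeline` takes a :class:`RunConfig` holding either a
:class:`~nbprofile.simulate.CohortSpec` (synthetic mode) or paths to
profile/clinical TSVs, pushes every tumour through segmentation and
genomic-type classification, and assembles one structured report:
genomic-type counts per trial, frequency tables with association tests,
the 11q breakpoint-cluster summary, Kaplan-Meier / log-rank results per
stratum (including the stage-4s symptom subgroups) and the backward-
selected Cox model.  Runs are deterministic given the seed carried by the
cohort spec.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from .classify import NCA, SCA, SILENT, call_genomic_type, calls_to_frame, summarize_breakpoint_cluster
from .genome import GenomeBuild, build_probe_grid, default_build, load_genome_config
from .segmentation import CopyNumberProfile, segment_and_call
from .simulate import TRIALS, Cohort, CohortSpec, generate_cohort
from .stats import MARKERS, build_frequency_tables
from .survival import backward_select, derive_pfs, km_estimate, logrank_test

logger = logging.getLogger("nbprofile")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_profiles"]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    cohort_spec: CohortSpec | None = None
    profiles_path: str | None = None
    clinical_path: str | None = None
    genome_config: str | None = None  # None -> bundled default build
    gain_threshold: float = 0.1
    loss_threshold: float = 0.1
    penalty: float | None = None
    stratifiers: tuple[str, ...] = ("trial", "bone", "ploidy")
    outdir: str | None = None

    def __post_init__(self) -> None:
        synthetic = self.cohort_spec is not None
        from_files = self.profiles_path is not None or self.clinical_path is not None
        if synthetic == from_files:
            raise ValueError("provide exactly one of cohort_spec or input paths")


def load_profiles(path, build: GenomeBuild) -> list[CopyNumberProfile]:
    """Read a long-format profile TSV (patient_id, probe_id, chrom, start,
    end, log2_ratio) back into per-patient profiles.

    The platform is inferred per patient from the median inter-probe
    spacing; ratios are aligned to the package's deterministic grid by
    probe_id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    grids = {p: build_probe_grid(build, p) for p in ("BAC", "OLIGO")}
    profiles = []
    for patient_id, sub in df.groupby("patient_id", sort=True):
        spacing = float(np.median(sub["end"] - sub["start"]))
        platform = "BAC" if spacing > 200_000 else "OLIGO"
        grid = grids[platform]
        ratios = (
            sub.set_index("probe_id")["log2_ratio"]
            .reindex(grid.probes["probe_id"])
            .to_numpy(dtype=float)
        )
        profiles.append(
            CopyNumberProfile(patient_id=str(patient_id), grid=grid, ratios=ratios, platform=platform)
        )
    return profiles


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-labelled with stage
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s: %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("classify")
def classify_cohort(profiles, build, gain_threshold=0.1, loss_threshold=0.1, penalty=None):
    """Segment and classify every profile; returns list of GenomicTypeCall."""
    grids = {}
    calls = []
    for profile in profiles:
        seg = segment_and_call(
            profile,
            penalty=penalty,
            gain_threshold=gain_threshold,
            loss_threshold=loss_threshold,
        )
        grids[profile.platform] = profile.grid
        calls.append(call_genomic_type(seg, profile.grid, build))
    return calls


def _km_block(records, group_key: str) -> dict:
    """KM 5-year estimates per group plus the log-rank comparison."""
    by_group: dict = {}
    groups = sorted({r.groups[group_key] for r in records}, key=str)
    for gname in groups:
        sub = [r for r in records if r.groups[group_key] == gname]
        km = km_estimate(sub)
        by_group[str(gname)] = {
            "n": len(sub),
            "events": int(sum(r.event for r in sub)),
            "pfs_5y_pct": round(100.0 * km.survival_at(60.0), 1),
            "se_pct": round(100.0 * km.std_err_at(60.0), 1),
        }
    block = {"groups": by_group}
    n_events = sum(r.event for r in records)
    if len(groups) >= 2 and n_events > 0:
        lr = logrank_test(records, group_key)
        block["logrank"] = {"statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value}
    return block


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the structured report document."""
    # ---- input stage -------------------------------------------------
    try:
        build = (
            load_genome_config(config.genome_config) if config.genome_config else default_build()
        )
    except Exception as exc:
        raise PipelineError("genome", str(exc)) from exc

    if config.cohort_spec is not None:
        try:
            cohort = generate_cohort(config.cohort_spec, build=build)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        profiles, clinical = cohort.profiles, cohort.clinical
        seed = config.cohort_spec.seed
    else:
        try:
            profiles = load_profiles(config.profiles_path, build)
            clinical = pd.read_csv(config.clinical_path, sep="\t")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
        cohort = None
        seed = None

    # ---- segmentation + classification -------------------------------
    calls = classify_cohort(
        profiles,
        build,
        gain_threshold=config.gain_threshold,
        loss_threshold=config.loss_threshold,
        penalty=config.penalty,
    )
    type_by_patient = {c.patient_id: c.genomic_type for c in calls}
    clinical = clinical.copy()
    clinical["genomic_type"] = clinical["patient_id"].map(type_by_patient)

    counts_by_trial = {
        trial: {
            g: int(((clinical["trial"] == trial) & (clinical["genomic_type"] == g)).sum())
            for g in (NCA, SCA, SILENT)
        }
        for trial in TRIALS
        if (clinical["trial"] == trial).any()
    }

    # ---- breakpoint clustering on 11q --------------------------------
    bkpts_11q = [b for c in calls for b in c.breakpoints if b.chrom == "11"]
    cluster: dict | None = None
    try:
        lo, hi, span = summarize_breakpoint_cluster(bkpts_11q, "11", "q", build)
        cluster = {"min_bp": lo, "max_bp": hi, "span_bp": span, "n_breakpoints": len(bkpts_11q)}
    except ValueError:
        cluster = None

    # ---- association statistics --------------------------------------
    try:
        stats_block = {}
        for strat in config.stratifiers:
            tables = build_frequency_tables(calls, clinical, strat)
            stats_block[strat] = {
                name: {
                    "rows": table.rows,
                    "cols": [str(c) for c in table.cols],
                    "counts": table.counts.tolist(),
                    "method": res.method,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                }
                for name, (table, res) in tables.items()
            }
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc

    # ---- survival -----------------------------------------------------
    try:
        records = [derive_pfs(row) for _, row in clinical.iterrows()]
        surv_block = {"overall": _km_block(records, "genomic_type")}
        for trial in TRIALS:
            sub = [r for r in records if r.groups.get("trial") == trial]
            sub = [r for r in sub if r.groups["genomic_type"] in (NCA, SCA)]
            if sub and len({r.groups["genomic_type"] for r in sub}) == 2 and any(r.event for r in sub):
                surv_block[trial] = _km_block(sub, "genomic_type")
        # stage-4s subgroups by presence of symptoms / upfront treatment
        for label, flag in (("4s_upfront_chemo", True), ("4s_no_upfront_chemo", False)):
            sub = [
                r
                for r in records
                if r.groups.get("trial") == "INES99.2"
                and bool(r.groups.get("upfront_chemo")) is flag
                and r.groups["genomic_type"] in (NCA, SCA)
            ]
            if sub and len({r.groups["genomic_type"] for r in sub}) == 2 and any(r.event for r in sub):
                surv_block[label] = _km_block(sub, "genomic_type")

        # multivariate: genomic profile + single markers + treatment group,
        # on the NCA/SCA patients, backward-eliminated at alpha 0.05
        marker_status = {
            c.patient_id: {m: any(
                a.scope == cls.SEGMENTAL and (a.chrom, a.arm, a.direction) == MARKERS[m]
                for a in c.alterations
            ) for m in MARKERS}
            for c in calls
        }
        cox_records = []
        for r in records:
            if r.groups["genomic_type"] not in (NCA, SCA):
                continue
            r.groups.update(
                {
                    "sca_profile": 1.0 if r.groups["genomic_type"] == SCA else 0.0,
                    "trial_99_2": 1.0 if r.groups["trial"] == "INES99.2" else 0.0,
                    "trial_99_3": 1.0 if r.groups["trial"] == "INES99.3" else 0.0,
                    **{f"marker_{m}": float(marker_status[r.patient_id][m]) for m in MARKERS},
                }
            )
            cox_records.append(r)
        candidates = ["sca_profile", "trial_99_2", "trial_99_3"] + [f"marker_{m}" for m in MARKERS]
        # drop covariates without variation (e.g. a marker never called)
        candidates = [
            c
            for c in candidates
            if len({r.groups[c] for r in cox_records}) > 1
        ]
        n_events = sum(r.event for r in cox_records)
        if n_events < 5:
            fit, retained = None, []
            cox_block = {"candidates": candidates, "retained": [], "note": "too few events for a multivariate model"}
        else:
            fit, retained = backward_select(cox_records, candidates, alpha=0.05)
            cox_block = {"candidates": candidates, "retained": retained}
        if fit is not None:
            cox_block["model"] = {
                name: {
                    "coef": float(fit.coef[i]),
                    "hazard_ratio": float(fit.hazard_ratios[i]),
                    "ci95": [float(fit.ci_lower[i]), float(fit.ci_upper[i])],
                    "p_value": float(fit.p_values[i]),
                }
                for i, name in enumerate(fit.covariates)
            }
            cox_block["converged"] = fit.converged
            cox_block["n"] = fit.n
            cox_block["n_events"] = fit.n_events
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("survival", str(exc)) from exc

    report = {
        "seed": seed,
        "n_patients": int(len(clinical)),
        "genomic_type_counts": counts_by_trial,
        "breakpoint_cluster_11q": cluster,
        "association_tests": stats_block,
        "survival": surv_block,
        "cox": cox_block,
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import json

        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        calls_to_frame(calls).to_csv(outdir / "alteration_calls.tsv", sep="\t", index=False)
        clinical.to_csv(outdir / "clinical_with_types.tsv", sep="\t", index=False)
    return report


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper(), logging.INFO))
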
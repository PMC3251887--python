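"""Genomic-type classification: NCA / SCA / silent, breakpoints, ploidy.

The classification consumes per-probe statuses (from
:mod:`nbprofile.segmentation`) and applies the operational rules used for
infant neuroblastoma genomic typing:

* a numerical chromosome alteration (NCA) is a whole chromosome whose
  probes are homogeneously altered relative to the genome-median level;
* a segmental chromosome alteration (SCA) is a run of at least 3
  contiguous BAC probes or 100 contiguous oligonucleotide probes whose
  status differs from that of the rest of the chromosome (operationalised
  as the chromosome's probe-majority status, ties broken toward NORMAL);
* a tumour with at least one SCA (with or without NCAs) has a SCA genomic
  profile; only-NCA tumours have a NCA profile; tumours with no calls at
  all are "silent".

Breakpoints are recorded at the start coordinate of the probe on the left
side of each status transition.  DNA-index ploidy classification uses the
standard cutoffs (di-/tetraploid when the index is <=1.2 or >=1.8,
pseudotriploid in between) plus a stricter diploid-only mode with a cutoff
of 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBuild, ProbeGrid
from .segmentation import GAIN, LOSS, NORMAL, SegmentedProfile

__all__ = [
    "WHOLE_CHROMOSOME",
    "SEGMENTAL",
    "NCA",
    "SCA",
    "SILENT",
    "CONTIGUITY_THRESHOLD",
    "TYPICAL_ALTERATIONS",
    "AlterationCall",
    "GenomicTypeCall",
    "BreakpointRecord",
    "PloidyCall",
    "classify_alterations",
    "classify_profile",
    "flag_typical",
    "extract_breakpoints",
    "summarize_breakpoint_cluster",
    "classify_ploidy",
    "call_genomic_type",
]

WHOLE_CHROMOSOME = "WHOLE_CHROMOSOME"
SEGMENTAL = "SEGMENTAL"

NCA = "NCA"
SCA = "SCA"
SILENT = "SILENT"

#: minimum contiguous altered probes for a segmental call, per platform
CONTIGUITY_THRESHOLD = {"BAC": 3, "OLIGO": 100}

#: the recurrent (arm, direction) pairs of neuroblastoma
TYPICAL_ALTERATIONS = frozenset(
    {
        ("1", "p", LOSS),
        ("1", "q", GAIN),
        ("2", "p", GAIN),
        ("3", "p", LOSS),
        ("4", "p", LOSS),
        ("11", "q", LOSS),
        ("17", "q", GAIN),
    }
)

_STATUS_RANK = {LOSS: -1, NORMAL: 0, GAIN: 1}


@dataclass
class AlterationCall:
    scope: str  # WHOLE_CHROMOSOME | SEGMENTAL
    chrom: str
    arm: str | None  # for SEGMENTAL calls; None for whole-chromosome
    direction: str  # GAIN | LOSS
    n_probes: int
    start: int
    end: int
    typical: bool = False


@dataclass
class BreakpointRecord:
    chrom: str
    position: int  # start coordinate of the probe left of the transition
    left_status: str
    right_status: str


@dataclass
class GenomicTypeCall:
    patient_id: str
    genomic_type: str  # NCA | SCA | SILENT
    alterations: list[AlterationCall] = field(default_factory=list)
    breakpoints: list[BreakpointRecord] = field(default_factory=list)


@dataclass
class PloidyCall:
    dna_index: float
    klass: str
    cutoff_mode: str


def _majority_status(statuses: np.ndarray) -> str:
    """Most frequent status; ties resolved toward NORMAL, then GAIN."""
    counts = Counter(statuses.tolist())
    top = max(counts.values())
    tied = {s for s, c in counts.items() if c == top}
    for preferred in (NORMAL, GAIN, LOSS):
        if preferred in tied:
            return preferred
    raise AssertionError("unreachable")


def _runs(values: np.ndarray):
    """Yield (start, end, value) for maximal constant runs (end exclusive)."""
    if len(values) == 0:
        return
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    edges = [0, *change.tolist(), len(values)]
    for a, b in zip(edges[:-1], edges[1:]):
        yield a, b, values[a]


def _arms_of_interval(chrom: str, start: int, end: int, build: GenomeBuild) -> list[str]:
    """Arms overlapped by [start, end); majority-overlap first."""
    overlaps = []
    for arm in ("p", "q"):
        a0, a1 = build.arm_interval(chrom, arm)
        ov = max(0, min(end, a1) - max(start, a0))
        if ov > 0:
            overlaps.append((ov, arm))
    overlaps.sort(reverse=True)
    return [arm for _, arm in overlaps]


def classify_alterations(
    seg: SegmentedProfile,
    grid: ProbeGrid,
    build: GenomeBuild,
) -> list[AlterationCall]:
    """Call whole-chromosome and segmental alterations from probe statuses.

    Per chromosome: if every observed probe shares one non-NORMAL status,
    a single WHOLE_CHROMOSOME call is made.  Otherwise each maximal run of
    probes whose status differs from the chromosome's majority status is a
    candidate; runs of at least 3 (BAC) or 100 (oligo) contiguous observed
    probes become SEGMENTAL calls (direction relative to the majority),
    shorter runs are discarded.  A segmental call straddling the centromere
    is reported once per overlapped arm.
    """
    threshold = CONTIGUITY_THRESHOLD[grid.platform]
    probes = grid.probes
    chrom_col = probes["chrom"].to_numpy()
    starts = probes["start"].to_numpy()
    ends = probes["end"].to_numpy()
    status = seg.probe_status

    calls: list[AlterationCall] = []
    for chrom in dict.fromkeys(chrom_col):
        on_chrom = np.flatnonzero((chrom_col == chrom) & (status != ""))
        if len(on_chrom) == 0:
            continue
        st = status[on_chrom]
        uniq = set(st.tolist())
        if len(uniq) == 1 and st[0] != NORMAL:
            calls.append(
                AlterationCall(
                    scope=WHOLE_CHROMOSOME,
                    chrom=chrom,
                    arm=None,
                    direction=st[0],
                    n_probes=len(on_chrom),
                    start=int(starts[on_chrom[0]]),
                    end=int(ends[on_chrom[-1]]),
                )
            )
            continue
        majority = _majority_status(st)
        for a, b, value in _runs(st):
            if value == majority or (b - a) < threshold:
                continue
            direction = GAIN if _STATUS_RANK[value] > _STATUS_RANK[majority] else LOSS
            idx = on_chrom[a:b]
            s0, s1 = int(starts[idx[0]]), int(ends[idx[-1]])
            for arm in _arms_of_interval(chrom, s0, s1, build):
                call = AlterationCall(
                    scope=SEGMENTAL,
                    chrom=chrom,
                    arm=arm,
                    direction=direction,
                    n_probes=b - a,
                    start=s0,
                    end=s1,
                )
                call.typical = flag_typical(call)
                calls.append(call)
    return calls


def classify_profile(
    alterations: list[AlterationCall],
    patient_id: str = "",
    breakpoints: list[BreakpointRecord] | None = None,
) -> GenomicTypeCall:
    """Attribute the genomic type from the alteration-call list.

    SILENT when no calls; SCA when any call is SEGMENTAL (with or without
    whole-chromosome calls); NCA when all calls are whole-chromosome.
    """
    if not alterations:
        genomic_type = SILENT
    elif any(c.scope == SEGMENTAL for c in alterations):
        genomic_type = SCA
    else:
        genomic_type = NCA
    return GenomicTypeCall(
        patient_id=patient_id,
        genomic_type=genomic_type,
        alterations=list(alterations),
        breakpoints=list(breakpoints or []),
    )


def flag_typical(alteration: AlterationCall) -> bool:
    """True iff the (arm, direction) pair is in the recurrent set
    {1p-, 1q+, 2p+, 3p-, 4p-, 11q-, 17q+}."""
    if alteration.scope != SEGMENTAL or alteration.arm is None:
        return False
    return (alteration.chrom, alteration.arm, alteration.direction) in TYPICAL_ALTERATIONS


def extract_breakpoints(seg: SegmentedProfile, grid: ProbeGrid) -> list[BreakpointRecord]:
    """One record per adjacent observed-probe pair with differing status.

    The breakpoint position is the start coordinate of the left probe of
    the transition.
    """
    probes = grid.probes
    chrom_col = probes["chrom"].to_numpy()
    starts = probes["start"].to_numpy()
    status = seg.probe_status

    records: list[BreakpointRecord] = []
    for chrom in dict.fromkeys(chrom_col):
        on_chrom = np.flatnonzero((chrom_col == chrom) & (status != ""))
        st = status[on_chrom]
        for k in np.flatnonzero(st[1:] != st[:-1]):
            left = on_chrom[k]
            records.append(
                BreakpointRecord(
                    chrom=chrom,
                    position=int(starts[left]),
                    left_status=st[k],
                    right_status=st[k + 1],
                )
            )
    return records


def summarize_breakpoint_cluster(
    records: list[BreakpointRecord],
    chromosome: str,
    arm: str,
    build: GenomeBuild,
) -> tuple[int, int, int]:
    """(min, max, span) of breakpoint positions on one chromosome arm."""
    a0, a1 = build.arm_interval(chromosome, arm)
    positions = [
        r.position for r in records if r.chrom == chromosome and a0 <= r.position < a1
    ]
    if not positions:
        raise ValueError(f"no breakpoints on {chromosome}{arm}")
    lo, hi = min(positions), max(positions)
    return lo, hi, hi - lo


def classify_ploidy(dna_index: float, mode: str = "STANDARD") -> PloidyCall:
    """Classify ploidy from the DNA index.

    STANDARD mode: di-/tetraploid when the index is <=1.2 or >=1.8
    (boundaries inclusive), pseudotriploid strictly in between.
    STRICT_DIPLOID mode: diploid when the index is <=1, non-diploid
    otherwise.
    """
    if not np.isfinite(dna_index) or dna_index <= 0:
        raise ValueError(f"DNA index must be positive, got {dna_index}")
    if mode == "STANDARD":
        klass = "DI_TETRAPLOID" if (dna_index <= 1.2 or dna_index >= 1.8) else "PSEUDOTRIPLOID"
    elif mode == "STRICT_DIPLOID":
        klass = "DIPLOID" if dna_index <= 1.0 else "NON_DIPLOID"
    else:
        raise ValueError(f"unknown ploidy mode {mode!r}")
    return PloidyCall(dna_index=float(dna_index), klass=klass, cutoff_mode=mode)


def call_genomic_type(
    seg: SegmentedProfile,
    grid: ProbeGrid,
    build: GenomeBuild,
) -> GenomicTypeCall:
    """Full per-tumour classification: alterations, type and breakpoints."""
    alterations = classify_alterations(seg, grid, build)
    breakpoints = extract_breakpoints(seg, grid)
    return classify_profile(alterations, patient_id=seg.patient_id, breakpoints=breakpoints)


def calls_to_frame(calls: list[GenomicTypeCall]) -> pd.DataFrame:
    """Cohort-level alteration table (one row per alteration call)."""
    rows = []
    for c in calls:
        for a in c.alterations:
            rows.append(
                (c.patient_id, a.scope, a.chrom, a.arm, a.direction, a.n_probes, a.start, a.end, a.typical)
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "scope", "chrom", "arm", "direction", "n_probes", "start", "end", "typical"],
    )
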
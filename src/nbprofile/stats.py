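"""Contingency-table association tests for genomic-profile cohorts.

Pearson chi-square (no continuity correction) and a two-sided exact test
for 2xk tables (probability-ordering rule, reducing to Fisher's exact test
for 2x2), with automatic selection when expected counts are small.
Frequency-table builders cross-tabulate single-marker and genomic-profile
status against trial arm, metastatic sites or ploidy class; "silent"
profiles are excluded from single-marker comparisons but kept as a third
row of the genomic-profile tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import GAIN, LOSS, NCA, SCA, SEGMENTAL, SILENT, GenomicTypeCall

__all__ = [
    "ContingencyTable",
    "TestResult",
    "pearson_chi_square",
    "exact_test",
    "select_test",
    "build_frequency_tables",
    "MARKERS",
]

#: recurrent single markers tabulated in cohort reports: arm -> direction
MARKERS = {
    "1p": ("1", "p", LOSS),
    "2p": ("2", "p", GAIN),
    "3p": ("3", "p", LOSS),
    "4p": ("4", "p", LOSS),
    "11q": ("11", "q", LOSS),
    "17q": ("17", "q", GAIN),
}

_STRATIFIER_LEVELS = {
    "trial": ["INES99.1", "INES99.2", "INES99.3"],
    "liver": [False, True],
    "skin": [False, True],
    "bone_marrow": [False, True],
    "bone": [False, True],
    "ploidy": ["DI_TETRAPLOID", "PSEUDOTRIPLOID"],
}


@dataclass
class ContingencyTable:
    rows: list
    cols: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def expected(self) -> np.ndarray:
        n = self.counts.sum()
        return np.outer(self.counts.sum(axis=1), self.counts.sum(axis=0)) / n


@dataclass
class TestResult:
    statistic: float | None
    df: int | None
    p_value: float
    method: str  # CHI_SQUARE | EXACT


def pearson_chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-square without continuity correction.

    Raises if any row or column margin is zero (expected counts of 0).
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return TestResult(statistic=float(stat), df=int(df), p_value=float(p), method="CHI_SQUARE")


def _exact_enumerate(counts: np.ndarray):
    """Yield (table_probability,) for every 2xk table with the observed
    margins, enumerating free cells of the smaller row only."""
    r = counts.sum(axis=1)
    c = counts.sum(axis=0)
    if r[0] > r[1]:  # enumerate over the smaller row; probabilities are
        counts = counts[::-1]  # symmetric in row order
        r = r[::-1]
    # log binomials for the multivariate hypergeometric mass
    n = int(counts.sum())
    r0 = int(r[0])
    log_denom = _log_binom(n, r0)
    ranges = [range(0, min(r0, int(cj)) + 1) for cj in c[:-1]]
    for combo in itertools.product(*ranges):
        s = sum(combo)
        last = r0 - s
        if last < 0 or last > c[-1]:
            continue
        cells = (*combo, last)
        logp = sum(_log_binom(int(cj), aj) for cj, aj in zip(c, cells)) - log_denom
        yield cells, float(np.exp(logp))


def _log_binom(n: int, k: int) -> float:
    from math import lgamma

    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def exact_test(table: ContingencyTable) -> TestResult:
    """Two-sided exact test for a 2xk table.

    Enumerates every table sharing the observed margins (free cells taken
    in the smaller row, each bounded by its column margin), computes the
    multivariate hypergeometric probability of each, and sums those with
    probability <= that of the observed table (small relative tolerance
    for floating-point ties).  For 2x2 this is two-sided Fisher.
    """
    counts = table.counts
    if counts.shape[0] != 2:
        raise ValueError("exact test implemented for 2xk tables only")
    r = counts.sum(axis=1)
    obs = counts if r[0] <= r[1] else counts[::-1]
    obs_cells = tuple(int(x) for x in obs[0])

    p_obs = None
    entries = []
    for cells, p in _exact_enumerate(counts):
        entries.append((cells, p))
        if cells == obs_cells:
            p_obs = p
    assert p_obs is not None
    p_value = sum(p for _, p in entries if p <= p_obs * (1 + 1e-9))
    return TestResult(statistic=None, df=None, p_value=min(float(p_value), 1.0), method="EXACT")


def select_test(table: ContingencyTable, min_expected: float = 5.0) -> TestResult:
    """Chi-square when all expected counts are at least ``min_expected``,
    otherwise the exact test (the usual small-count rule)."""
    if (table.expected() >= min_expected).all():
        return pearson_chi_square(table)
    return exact_test(table)


def _marker_status(call: GenomicTypeCall, marker: str) -> bool:
    chrom, arm, direction = MARKERS[marker]
    return any(
        a.scope == SEGMENTAL and a.chrom == chrom and a.arm == arm and a.direction == direction
        for a in call.alterations
    )


def _patient_table(calls: list[GenomicTypeCall], clinical: pd.DataFrame) -> pd.DataFrame:
    """Join genomic calls onto the clinical table (inner, on patient_id)."""
    rows = []
    for c in calls:
        row = {"patient_id": c.patient_id, "genomic_type": c.genomic_type}
        for m in MARKERS:
            row[m] = _marker_status(c, m)
        rows.append(row)
    genomic = pd.DataFrame(rows)
    clinical = clinical.drop(columns=[c for c in ("genomic_type", *MARKERS) if c in clinical.columns])
    return clinical.merge(genomic, on="patient_id", how="inner")


def build_frequency_tables(
    calls: list[GenomicTypeCall],
    clinical: pd.DataFrame,
    stratifier: str,
    min_expected: float = 5.0,
) -> dict[str, tuple[ContingencyTable, TestResult]]:
    """Cross-tabulate markers and genomic profile against one stratifier.

    Parameters
    ----------
    calls : list of GenomicTypeCall
    clinical : DataFrame
        Must carry ``patient_id`` and the stratifier column (``trial``,
        ``liver``, ``skin``, ``bone_marrow``, ``bone`` or ``dna_index``
        for the ``ploidy`` stratifier; missing DNA index drops a patient
        from that table).
    stratifier : str

    Returns
    -------
    dict mapping marker name (and ``"genomic_profile"``) to a
    (ContingencyTable, TestResult) pair.  Single-marker tables have rows
    Normal/Altered and exclude silent profiles; the genomic-profile table
    has rows NCA/SCA (plus SILENT for the ploidy stratifier, mirroring the
    published layout).
    """
    if stratifier not in _STRATIFIER_LEVELS:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    joined = _patient_table(calls, clinical)

    if stratifier == "ploidy":
        from .classify import classify_ploidy

        joined = joined[joined["dna_index"].notna()].copy()
        joined["__stratum"] = [
            classify_ploidy(x).klass for x in joined["dna_index"]
        ]
    else:
        col = stratifier
        joined = joined[joined[col].notna()].copy()
        joined["__stratum"] = joined[col]
    levels = _STRATIFIER_LEVELS[stratifier]

    out: dict[str, tuple[ContingencyTable, TestResult]] = {}
    non_silent = joined[joined["genomic_type"] != SILENT]
    for marker in MARKERS:
        counts = np.array(
            [
                [int(((non_silent["__stratum"] == lv) & (~non_silent[marker])).sum()) for lv in levels],
                [int(((non_silent["__stratum"] == lv) & (non_silent[marker])).sum()) for lv in levels],
            ]
        )
        table = ContingencyTable(rows=["Normal", "Altered"], cols=list(levels), counts=counts)
        out[marker] = (table, select_test(table, min_expected))

    profile_rows = [NCA, SCA] + ([SILENT] if stratifier == "ploidy" else [])
    counts = np.array(
        [
            [int(((joined["__stratum"] == lv) & (joined["genomic_type"] == g)).sum()) for lv in levels]
            for g in profile_rows
        ]
    )
    table = ContingencyTable(rows=profile_rows, cols=list(levels), counts=counts)
    # empty rows/columns (e.g. no silent case with an observed DNA index)
    # carry no information and would zero a margin; the test runs on the rest
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    trimmed = counts[np.ix_(row_keep, col_keep)]
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        result = TestResult(statistic=None, df=None, p_value=float("nan"), method="NONE")
    else:
        tested = ContingencyTable(
            rows=[r for r, keep in zip(profile_rows, row_keep) if keep],
            cols=[c for c, keep in zip(levels, col_keep) if keep],
            counts=trimmed,
        )
        if trimmed.shape[0] == 2:
            result = select_test(tested, min_expected)
        else:
            result = pearson_chi_square(tested)
    out["genomic_profile"] = (table, result)
    return out
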
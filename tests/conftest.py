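import numpy as np
import pytest

import nbprofile as nb
from nbprofile.pipeline import classify_cohort


@pytest.fixture(scope="session")
def build():
    return nb.default_build()


@pytest.fixture(scope="session")
def bac_grid(build):
    return nb.build_probe_grid(build, "BAC")


@pytest.fixture(scope="session")
def oligo_grid(build):
    return nb.build_probe_grid(build, "OLIGO")


@pytest.fixture(scope="session")
def default_cohort():
    """The full default synthetic cohort (218 patients, seed 1)."""
    return nb.generate_cohort(nb.CohortSpec(seed=1))


@pytest.fixture(scope="session")
def default_cohort_calls(default_cohort):
    """Genomic-type calls for the default cohort (segmentation included)."""
    return classify_cohort(default_cohort.profiles, default_cohort.build)


def make_segmented(grid, probe_status, patient_id="t"):
    """Build a SegmentedProfile directly from a per-probe status vector.

    Used to test classification rules independently of segmentation.
    """
    from nbprofile.segmentation import SegmentedProfile

    status = np.asarray(probe_status, dtype="<U6")
    return SegmentedProfile(
        patient_id=patient_id,
        grid=grid,
        segments=[],
        baseline=0.0,
        probe_status=status,
    )


def brute_force_alteration_calls(probe_status, chrom_col, threshold):
    """Independent scanner enumerating every probe run per chromosome.

    Returns a set of (scope, chrom, direction, n_probes, first_idx) tuples
    using the same operational rules as the classifier: whole-chromosome
    when all observed probes share one non-NORMAL status, otherwise every
    maximal constant run differing from the chromosome's majority status
    (ties toward NORMAL, then GAIN) with at least ``threshold`` probes.
    """
    from collections import Counter

    out = set()
    rank = {"LOSS": -1, "NORMAL": 0, "GAIN": 1}
    for chrom in dict.fromkeys(chrom_col):
        idx = [i for i, (c, s) in enumerate(zip(chrom_col, probe_status)) if c == chrom and s != ""]
        st = [probe_status[i] for i in idx]
        if not st:
            continue
        if len(set(st)) == 1 and st[0] != "NORMAL":
            out.add(("WHOLE_CHROMOSOME", chrom, st[0], len(st), idx[0]))
            continue
        counts = Counter(st)
        top = max(counts.values())
        tied = {s for s, c in counts.items() if c == top}
        majority = next(s for s in ("NORMAL", "GAIN", "LOSS") if s in tied)
        i = 0
        while i < len(st):
            j = i
            while j < len(st) and st[j] == st[i]:
                j += 1
            if st[i] != majority and (j - i) >= threshold:
                direction = "GAIN" if rank[st[i]] > rank[majority] else "LOSS"
                out.add(("SEGMENTAL", chrom, direction, j - i, idx[i]))
            i = j
    return out
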
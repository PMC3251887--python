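import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nbprofile as nb
from nbprofile.classify import (
    NCA,
    SCA,
    SEGMENTAL,
    SILENT,
    WHOLE_CHROMOSOME,
    AlterationCall,
    BreakpointRecord,
    classify_alterations,
    classify_profile,
    classify_ploidy,
    extract_breakpoints,
    flag_typical,
    summarize_breakpoint_cluster,
)

from conftest import brute_force_alteration_calls, make_segmented


def _status_vector(grid, default="NORMAL"):
    return np.full(len(grid), default, dtype="<U6")


class TestClassifyAlterations:
    def test_whole_chromosome_gain_is_numerical(self, build, bac_grid):
        status = _status_vector(bac_grid)
        chrom = bac_grid.probes["chrom"].to_numpy()
        status[chrom == "7"] = "GAIN"
        calls = classify_alterations(make_segmented(bac_grid, status), bac_grid, build)
        assert len(calls) == 1
        assert calls[0].scope == WHOLE_CHROMOSOME and calls[0].chrom == "7"
        assert calls[0].direction == "GAIN"

    @pytest.mark.parametrize(
        "platform,n_altered,expect_call",
        [
            ("BAC", 2, False),
            ("BAC", 3, True),
            ("OLIGO", 99, False),
            ("OLIGO", 100, True),
        ],
    )
    def test_contiguity_threshold_boundary(self, build, request, platform, n_altered, expect_call):
        # the segmental definition flips exactly at 3 BAC / 100 oligo probes
        grid = request.getfixturevalue(f"{platform.lower()}_grid")
        status = _status_vector(grid)
        chrom = grid.probes["chrom"].to_numpy()
        q17 = np.flatnonzero((chrom == "17") & (grid.probes["start"].to_numpy() >= 23_200_000))
        status[q17[10 : 10 + n_altered]] = "GAIN"
        calls = classify_alterations(make_segmented(grid, status), grid, build)
        segmental = [c for c in calls if c.scope == SEGMENTAL]
        if expect_call:
            assert len(segmental) == 1
            assert (segmental[0].chrom, segmental[0].arm, segmental[0].direction) == ("17", "q", "GAIN")
            assert segmental[0].n_probes == n_altered
        else:
            assert segmental == []

    def test_run_relative_to_majority_status(self, build, bac_grid):
        # chromosome mostly GAIN with a NORMAL window: the window is the
        # minority run and is called as a relative LOSS
        status = _status_vector(bac_grid)
        chrom = bac_grid.probes["chrom"].to_numpy()
        on17 = np.flatnonzero(chrom == "17")
        status[on17] = "GAIN"
        status[on17[5:15]] = "NORMAL"
        calls = classify_alterations(make_segmented(bac_grid, status), bac_grid, build)
        segmental = [c for c in calls if c.scope == SEGMENTAL]
        assert len(segmental) == 1
        assert segmental[0].direction == "LOSS" and segmental[0].n_probes == 10

    def test_missing_probes_break_contiguity(self, build, bac_grid):
        status = _status_vector(bac_grid)
        chrom = bac_grid.probes["chrom"].to_numpy()
        on17 = np.flatnonzero(chrom == "17")
        status[on17[30:33]] = "GAIN"
        status[on17[31]] = ""  # missing probe splits the run into 1+1
        calls = classify_alterations(make_segmented(bac_grid, status), bac_grid, build)
        assert [c for c in calls if c.scope == SEGMENTAL] == []


class TestOracleEquivalence:
    """classify_alterations against an independent run-enumerating scanner."""

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_brute_force_on_small_grids(self, build, data):
        import pandas as pd

        from nbprofile.genome import ProbeGrid

        n = data.draw(st.integers(min_value=6, max_value=200))
        n_chrom = data.draw(st.integers(min_value=1, max_value=3))
        chrom_labels = ["17", "11", "2"][:n_chrom]
        chrom_col = [chrom_labels[i * n_chrom // n] for i in range(n)]
        statuses = data.draw(
            st.lists(
                st.sampled_from(["GAIN", "LOSS", "NORMAL", ""]),
                min_size=n,
                max_size=n,
            )
        )
        # 100 kb spacing keeps every probe inside the p arm of its chromosome
        probes = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(n)],
                "chrom": chrom_col,
                "start": np.arange(n) * 10**5,
                "end": (np.arange(n) + 1) * 10**5,
            }
        )
        grid = ProbeGrid(platform="BAC", probes=probes, spacing=10**6)
        seg = make_segmented(grid, statuses)
        calls = classify_alterations(seg, grid, build)
        starts = probes["start"].to_numpy()
        got = {
            (c.scope, c.chrom, c.direction, c.n_probes, int(np.flatnonzero(starts == c.start)[0]))
            for c in calls
        }
        expected = brute_force_alteration_calls(list(statuses), chrom_col, threshold=3)
        assert got == expected


class TestClassifyProfile:
    def test_only_numerical_changes_is_nca(self):
        calls = [
            AlterationCall(WHOLE_CHROMOSOME, "7", None, "GAIN", 57, 0, 10**6),
            AlterationCall(WHOLE_CHROMOSOME, "17", None, "GAIN", 77, 0, 10**6),
        ]
        assert classify_profile(calls).genomic_type == NCA

    def test_any_segmental_makes_sca_even_with_nca(self):
        calls = [
            AlterationCall(WHOLE_CHROMOSOME, "7", None, "GAIN", 57, 0, 10**6),
            AlterationCall(SEGMENTAL, "17", "q", "GAIN", 20, 0, 10**6),
        ]
        assert classify_profile(calls).genomic_type == SCA

    def test_no_changes_is_silent(self):
        assert classify_profile([]).genomic_type == SILENT

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from([WHOLE_CHROMOSOME, SEGMENTAL]), st.sampled_from(["GAIN", "LOSS"])),
            max_size=6,
        )
    )
    def test_partition_and_monotonicity(self, shapes):
        calls = [
            AlterationCall(scope, "7", "q" if scope == SEGMENTAL else None, direction, 5, 0, 10**6)
            for scope, direction in shapes
        ]
        gt = classify_profile(calls).genomic_type
        assert gt in (NCA, SCA, SILENT)
        # exactly one type, consistent with the defining rules
        assert (gt == SILENT) == (not calls)
        assert (gt == SCA) == any(c.scope == SEGMENTAL for c in calls)
        # adding a segmental call can only move toward / keep SCA
        extra = AlterationCall(SEGMENTAL, "11", "q", "LOSS", 5, 0, 10**6)
        assert classify_profile([*calls, extra]).genomic_type == SCA


class TestFlagTypical:
    @pytest.mark.parametrize(
        "chrom,arm,direction,expected",
        [
            ("17", "q", "GAIN", True),
            ("11", "q", "LOSS", True),
            ("1", "p", "LOSS", True),
            ("14", "q", "GAIN", False),  # recurrent set excludes 14q
            ("14", "q", "LOSS", False),
            ("11", "q", "GAIN", False),  # direction matters
        ],
    )
    def test_membership(self, chrom, arm, direction, expected):
        call = AlterationCall(SEGMENTAL, chrom, arm, direction, 5, 0, 10**6)
        assert flag_typical(call) is expected

    def test_whole_chromosome_never_typical(self):
        call = AlterationCall(WHOLE_CHROMOSOME, "17", None, "GAIN", 77, 0, 10**6)
        assert flag_typical(call) is False


class TestExtractBreakpoints:
    def test_left_probe_convention(self, build, bac_grid):
        status = _status_vector(bac_grid)
        chrom = bac_grid.probes["chrom"].to_numpy()
        on17 = np.flatnonzero(chrom == "17")
        k = 40
        status[on17[k:]] = "GAIN"
        records = extract_breakpoints(make_segmented(bac_grid, status), bac_grid)
        assert len(records) == 1
        left_probe = on17[k - 1]
        assert records[0].position == int(bac_grid.probes["start"].iloc[left_probe])
        assert (records[0].left_status, records[0].right_status) == ("NORMAL", "GAIN")

    def test_all_normal_profile_has_none(self, bac_grid):
        records = extract_breakpoints(make_segmented(bac_grid, _status_vector(bac_grid)), bac_grid)
        assert records == []

    def test_planted_11q_breakpoints_recovered_in_cluster_window(self, build, bac_grid):
        # render SCA tumours whose 11q-loss breakpoints are planted in
        # [70, 82) Mb and verify >= 90% of extracted 11q breakpoints fall
        # in that window (left-probe convention shifts each by <= 1 probe)
        from nbprofile.simulate import TumorSpec, render_log_ratios
        from nbprofile.segmentation import segment_and_call

        rng = np.random.default_rng(17)
        q_end = build.arm_interval("11", "q")[1]
        positions = []
        for _ in range(120):
            bp = int(rng.uniform(70_000_000, 82_000_000))
            t = TumorSpec(SCA, [], [("11", "q", (bp, q_end), -1)], 1.0, 0.8, "BAC")
            prof = render_log_ratios(t, bac_grid, 0.1, rng)
            seg = segment_and_call(prof)
            positions += [r.position for r in extract_breakpoints(seg, bac_grid) if r.chrom == "11"]
        in_window = np.mean([70_000_000 <= p < 82_000_000 for p in positions])
        assert in_window >= 0.90


class TestBreakpointCluster:
    def test_span_of_cluster_edges(self, build):
        records = [
            BreakpointRecord("11", 70_000_000, "NORMAL", "LOSS"),
            BreakpointRecord("11", 82_000_000, "NORMAL", "LOSS"),
        ]
        assert summarize_breakpoint_cluster(records, "11", "q", build) == (
            70_000_000,
            82_000_000,
            12_000_000,
        )

    def test_single_record_zero_span(self, build):
        records = [BreakpointRecord("11", 75_000_000, "NORMAL", "LOSS")]
        assert summarize_breakpoint_cluster(records, "11", "q", build)[2] == 0

    def test_other_arm_records_filtered_out(self, build):
        records = [
            BreakpointRecord("11", 75_000_000, "NORMAL", "LOSS"),  # q
            BreakpointRecord("11", 10_000_000, "NORMAL", "LOSS"),  # p
            BreakpointRecord("17", 30_000_000, "NORMAL", "GAIN"),  # other chrom
        ]
        lo, hi, span = summarize_breakpoint_cluster(records, "11", "q", build)
        assert (lo, hi, span) == (75_000_000, 75_000_000, 0)

    def test_no_records_raises(self, build):
        with pytest.raises(ValueError):
            summarize_breakpoint_cluster([], "11", "q", build)


class TestClassifyPloidy:
    @pytest.mark.parametrize(
        "index,klass",
        [
            (1.46, "PSEUDOTRIPLOID"),  # perfect triploid content
            (1.2, "DI_TETRAPLOID"),  # boundary inclusive
            (1.8, "DI_TETRAPLOID"),
            (1.0, "DI_TETRAPLOID"),
            (1.5, "PSEUDOTRIPLOID"),
            (2.0, "DI_TETRAPLOID"),
        ],
    )
    def test_standard_cutoffs(self, index, klass):
        assert classify_ploidy(index).klass == klass

    def test_strict_mode_flags_unit_index_diploid(self):
        assert classify_ploidy(1.0, mode="STRICT_DIPLOID").klass == "DIPLOID"
        assert classify_ploidy(1.05, mode="STRICT_DIPLOID").klass == "NON_DIPLOID"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_ploidy(0.0)
        with pytest.raises(ValueError):
            classify_ploidy(1.5, mode="LOOSE")
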
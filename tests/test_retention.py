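"""Read classification, IRS arithmetic and parameter recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest
from scipy import stats

from ieskit import retention
from ieskit.genome_io import IesAnnotation
from ieskit.retention import (
    IES_MINUS,
    IES_PLUS,
    UNINFORMATIVE,
    classify_read,
    compute_irs,
    irs_histogram,
)


@pytest.fixture()
def annotation():
    # 30 bp IES at MIC [1000, 1032); MAC junction at 500
    seq = "TA" + "G" * 28 + "TA"
    return IesAnnotation(
        ies_id="i1", scaffold="s1", start=1000, length=30, sequence=seq,
        mac_scaffold="s1", mac_junction=500,
    )


def _read(header, start, cigar, name="r1", scaffold=0):
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.reference_id = scaffold
    seg.reference_start = start
    seg.cigartuples = cigar
    seg.query_sequence = "A" * sum(n for op, n in cigar if op in (0, 1, 4))
    seg.mapping_quality = 60
    seg.flag = 0
    return seg


@pytest.fixture()
def header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "s1", "LN": 100000}]}
    )


class TestClassifyRead:
    def test_boundary_crossing_read_is_plus(self, header, annotation):
        read = _read(header, 980, [(0, 40)])  # covers [980, 1020): left end +/- 20
        assert classify_read(read, annotation) == IES_PLUS

    def test_interior_read_is_uninformative(self, header):
        big = IesAnnotation(
            ies_id="big", scaffold="s1", start=1000, length=5000,
            sequence="TA" + "G" * 4998 + "TA", mac_scaffold="s1", mac_junction=500,
        )
        read = _read(header, 3000, [(0, 100)])
        assert classify_read(read, big) == UNINFORMATIVE

    def test_junction_deletion_is_minus(self, header, annotation):
        read = _read(header, 970, [(0, 30), (2, 30), (0, 70)])
        assert classify_read(read, annotation) == IES_MINUS

    def test_mac_space_junction_crossing_is_minus(self, header, annotation):
        read = _read(header, 470, [(0, 62)])  # 30 nt each side of the TA at 500
        assert classify_read(read, annotation, space="mac") == IES_MINUS

    def test_read_spanning_both_ends_counts_once(self, header):
        short = IesAnnotation(
            ies_id="s", scaffold="s1", start=1000, length=26,
            sequence="TA" + "G" * 24 + "TA", mac_scaffold="s1", mac_junction=500,
        )
        read = _read(header, 980, [(0, 80)])  # covers the whole IES
        assert classify_read(read, short) == IES_PLUS  # single label, one count

    def test_insufficient_anchor_is_uninformative(self, header, annotation):
        read = _read(header, 997, [(0, 4), (2, 30), (0, 96)])
        assert classify_read(read, annotation) == UNINFORMATIVE

    def test_min_anchor_below_three_rejected(self, header, annotation):
        read = _read(header, 980, [(0, 40)])
        with pytest.raises(ValueError):
            classify_read(read, annotation, min_anchor=2)

    def test_left_policy_ignores_right_end(self, header, annotation):
        read = _read(header, 1012, [(0, 40)])  # crosses right end only
        assert classify_read(read, annotation, end_policy="both") == IES_PLUS
        assert classify_read(read, annotation, end_policy="left") == UNINFORMATIVE


class TestComputeIrs:
    def _records(self, header, annotation, n_plus, n_minus):
        recs = []
        for i in range(n_plus):
            recs.append(_read(header, 980, [(0, 40)], name=f"p{i}"))
        for i in range(n_minus):
            recs.append(_read(header, 970, [(0, 30), (2, 30), (0, 70)], name=f"m{i}"))
        return recs

    @pytest.mark.parametrize(
        "n_plus,n_minus,expect",
        [(7, 0, 1.0), (0, 12, 0.0), (5, 5, 0.5)],
    )
    def test_irs_arithmetic(self, header, annotation, n_plus, n_minus, expect):
        df = compute_irs(self._records(header, annotation, n_plus, n_minus), [annotation])
        row = df.iloc[0]
        assert (row["ies_plus"], row["ies_minus"]) == (n_plus, n_minus)
        assert row["irs"] == pytest.approx(expect)

    def test_undefined_irs_is_nan(self, header, annotation):
        df = compute_irs([], [annotation])
        assert np.isnan(df.iloc[0]["irs"])

    def test_read_order_invariance(self, header, annotation):
        recs = self._records(header, annotation, 4, 6)
        a = compute_irs(recs, [annotation])
        b = compute_irs(recs[::-1], [annotation])
        pd.testing.assert_frame_equal(a, b)

    def test_uninformative_duplication_invariance(self, header, annotation):
        recs = self._records(header, annotation, 4, 6)
        noise = [_read(header, 5000, [(0, 100)], name=f"n{i}") for i in range(50)]
        a = compute_irs(recs, [annotation])
        b = compute_irs(recs + noise, [annotation])
        assert a.iloc[0]["irs"] == b.iloc[0]["irs"]

    def test_simulation_recovery_within_binomial_ci(self, small_sim, small_mic_alignments):
        """IRS of each simulated IES falls in the exact binomial 99% CI of rho."""
        anns = small_sim["annotations"]
        truth = small_sim["truth"]
        df = compute_irs(small_mic_alignments, anns, genome=small_sim["mic"])
        df = df.dropna(subset=["irs"])
        rho = df["ies_id"].map(truth.rho).to_numpy()
        n = df["coverage"].to_numpy()
        lo = stats.binom.ppf(0.005, n, rho)
        hi = stats.binom.ppf(0.995, n, rho)
        inside = ((df["ies_plus"] >= lo) & (df["ies_plus"] <= hi)).mean()
        assert inside >= 0.95


class TestIrsHistogram:
    def test_all_zero_single_first_bin(self):
        counts, edges, undef = irs_histogram([0.0] * 10, bin_width=0.02)
        assert counts[0] == 10 and counts[1:].sum() == 0 and undef == 0

    def test_empty_input_all_zero(self):
        counts, _edges, undef = irs_histogram([], bin_width=0.02)
        assert counts.sum() == 0 and undef == 0

    def test_undefined_excluded_and_reported(self):
        counts, _edges, undef = irs_histogram([0.5, float("nan")], bin_width=0.02)
        assert counts.sum() == 1 and undef == 1

    def test_final_bin_right_closed(self):
        counts, _edges, _ = irs_histogram([1.0], bin_width=0.02)
        assert counts[-1] == 1

    def test_uniform_scores_approximately_flat(self):
        rng = np.random.default_rng(0)
        vals = rng.random(10_000)
        counts, _edges, _ = irs_histogram(vals, bin_width=0.02)
        _stat, p = stats.chisquare(counts)
        assert p > 0.01

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            irs_histogram([0.5], bin_width=0.03)
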
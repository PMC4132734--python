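"""Sub-terminal frequencies, EWMA, logos and two-sample logos."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ieskit._seq import random_seq, revcomp
from ieskit.end_bases import (
    ewma,
    frequency_vs_irs,
    logo_dataframe,
    sequence_logo,
    subterminal_frequencies,
    two_sample_logo,
)
from ieskit.genome_io import IesAnnotation


def _ann(seq, ies_id="i", scaffold="s1"):
    return IesAnnotation(
        ies_id=ies_id, scaffold=scaffold, start=0, length=len(seq) - 2,
        sequence=seq, mac_scaffold=scaffold, mac_junction=0,
    )


class TestSubterminal:
    def test_forced_position_one(self):
        anns = [_ann("TAG" + "A" * 30 + "TA", ies_id=str(i)) for i in range(10)]
        df = subterminal_frequencies(anns, grouping=None)
        g_at_1 = df[(df["position"] == 1) & (df["base"] == "G")]["freq"].iloc[0]
        assert g_at_1 == 1.0

    def test_palindromic_ends_pool_equals_left(self):
        # both ends read TAG inward in their own orientation
        seq = "TATAG" + "C" * 20 + revcomp("TATAG")
        anns = [_ann(seq, ies_id=str(i)) for i in range(5)]
        left = subterminal_frequencies(anns, grouping=None, end_policy="left_end_only")
        both = subterminal_frequencies(anns, grouping=None, end_policy="both_ends_pooled")
        merged = left.merge(both, on=["group", "position", "base"], suffixes=("_l", "_b"))
        assert np.allclose(merged["freq_l"], merged["freq_b"])

    def test_frequencies_sum_to_one_per_position(self, small_sim):
        df = subterminal_frequencies(small_sim["annotations"], grouping="length")
        sums = df.groupby(["group", "position"])["freq"].sum()
        assert np.allclose(sums, 1.0)

    def test_recovers_generator_end_table(self, small_sim):
        """Pooled short-IES sub-terminal frequencies match the generating table."""
        from ieskit.simulate import _SHORT_END

        anns = [a for a in small_sim["annotations"] if a.length <= 36]
        df = subterminal_frequencies(anns, grouping=None, end_policy="both_ends_pooled")
        for pos in (1, 2, 3):
            for base in "ACGT":
                row = df[(df["position"] == pos) & (df["base"] == base)]
                n = row["n"].iloc[0]
                p = _SHORT_END[pos][base]
                se = math.sqrt(p * (1 - p) / n)
                assert abs(row["freq"].iloc[0] - p) < 4 * se + 1e-9


class TestEwma:
    def test_constant_series(self):
        assert np.allclose(ewma([3.5] * 10, span=5), 3.5)

    def test_single_step_span5(self):
        out = ewma([0.0, 1.0], span=5)
        assert out[1] == pytest.approx(1 / 3)

    def test_empty(self):
        assert ewma([], 5).size == 0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([3, 5, 10, 50]))
    def test_matches_recursive_oracle(self, seed, span):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=200)
        alpha = 2 / (span + 1)
        s = x[0]
        expect = [s]
        for v in x[1:]:
            s = alpha * v + (1 - alpha) * s
            expect.append(s)
        assert np.allclose(ewma(x, span), expect, atol=1e-12, rtol=0)

    def test_matches_pandas_ewm(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        ours = ewma(x, span=7)
        theirs = pd.Series(x).ewm(span=7, adjust=False).mean().to_numpy()
        assert np.allclose(ours, theirs, atol=1e-12)


class TestLogo:
    def test_invariant_g_column(self):
        cols = sequence_logo(["G"] * 100)
        assert cols[0].total == pytest.approx(math.log2(10), abs=1e-9)
        assert cols[0].heights["G"] == pytest.approx(math.log2(10), abs=1e-9)

    def test_background_column_near_zero(self):
        rng = np.random.default_rng(1)
        seqs = [random_seq(rng, 1, {"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4}) for _ in range(10_000)]
        assert sequence_logo(seqs)[0].total < 0.02

    def test_invariant_ta_columns(self):
        cols = sequence_logo(["TA"] * 10)
        for c in cols:
            assert c.total == pytest.approx(math.log2(2.5), abs=1e-9)

    def test_zero_background_with_observation_errors(self):
        with pytest.raises(ValueError):
            sequence_logo(["G"], background={"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.0})

    def test_total_zero_iff_p_equals_q(self):
        cols = sequence_logo(
            ["A"] * 4 + ["C"] * 1 + ["G"] * 1 + ["T"] * 4,
            background={"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4},
        )
        assert cols[0].total == 0.0

    def test_dataframe_heights_sum_to_total(self):
        cols = sequence_logo(["TAG", "TAT", "TAG"] * 5)
        df = logo_dataframe(cols)
        sums = df.groupby("position")["height_bits"].sum()
        totals = df.groupby("position")["total_bits"].first()
        assert np.allclose(sums, totals)


class TestTwoSampleLogo:
    def test_identical_groups_nothing_significant(self):
        group = ["TAGAC"] * 50 + ["TATTC"] * 50
        res = two_sample_logo(group, list(group))
        assert not res["significant"].any()

    def test_fully_separated_position_significant(self):
        a = ["G" * 5] * 100
        b = ["G" * 2 + "T" + "G" * 2] * 100
        res = two_sample_logo(a, b, alpha=1e-4)
        hit = res[(res["position"] == 2) & (res["base"] == "G")]
        assert hit["significant"].iloc[0]
        assert hit["direction"].iloc[0] == "enriched"

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a = [random_seq(rng, 6, {"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4}) for _ in range(80)]
        b = [random_seq(rng, 6, {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}) for _ in range(80)]
        r1 = two_sample_logo(a, b)
        r2 = two_sample_logo(b, a)
        assert np.allclose(r1["p_raw"], r2["p_raw"])
        assert np.allclose(r1["diff"], -r2["diff"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_logo([], ["ACGT"])


class TestFrequencyVsIrs:
    def test_flat_when_ends_independent_of_rho(self, small_sim, small_mic_alignments):
        from scipy.stats import linregress

        from ieskit.retention import compute_irs

        anns = small_sim["annotations"]
        irs = compute_irs(small_mic_alignments, anns, genome=small_sim["mic"])
        prof = frequency_vs_irs(anns, irs, length_window=(26, 36), irs_bin=0.1)
        sub = prof[(prof["position"] == 1) & (prof["base"] == "T")]
        if len(sub) >= 5:
            fit = linregress(sub["bin_center"], sub["freq"])
            assert abs(fit.slope) <= 3 * fit.stderr + 1e-9

    def test_empty_window_empty_output(self, small_sim, small_mic_alignments):
        from ieskit.retention import compute_irs

        anns = small_sim["annotations"]
        irs = compute_irs(small_mic_alignments, anns, genome=small_sim["mic"])
        prof = frequency_vs_irs(anns, irs, length_window=(5001, 5002))
        assert prof.empty
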
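"""Generator distributions, construction invariants and truth consistency."""

from __future__ import annotations

import collections

import numpy as np
import pytest
from scipy import stats

from ieskit import simulate
from ieskit.simulate import (
    ConfigurationError,
    EndModel,
    GenerationError,
    LengthModel,
    RetentionModel,
    SimulationConfig,
    build_genomes,
    excise_all,
    generate_ies_sequence,
    sample_ies_lengths,
    simulate_dna_reads,
    simulate_srna_reads,
)


class TestLengthModel:
    def test_default_mode_is_28(self):
        rng = np.random.default_rng(1)
        draws = sample_ies_lengths(rng, LengthModel(), size=100_000)
        mode = collections.Counter(draws.tolist()).most_common(1)[0][0]
        assert mode == 28

    def test_minimum_length_26(self):
        rng = np.random.default_rng(2)
        draws = sample_ies_lengths(rng, LengthModel(), size=50_000)
        assert draws.min() >= 26

    def test_forbidden_window_fully_depleted_at_factor_zero(self):
        rng = np.random.default_rng(3)
        draws = sample_ies_lengths(rng, LengthModel(forbidden_factor=0.0), size=100_000)
        assert not np.any((draws >= 38) & (draws <= 46))

    def test_degenerate_single_peak(self):
        model = LengthModel(
            first_peak=50, n_peaks=1, peak_sd=0.0, tail_fraction=0.0,
            forbidden_factor=1.0,
        )
        rng = np.random.default_rng(4)
        draws = sample_ies_lengths(rng, model, size=1000)
        assert set(draws.tolist()) == {50}

    def test_invalid_weights_raise(self):
        with pytest.raises(ConfigurationError):
            LengthModel(weight_decay=-1.0).pmf()
        with pytest.raises(ConfigurationError):
            LengthModel(first_peak=20).pmf()
        with pytest.raises(ConfigurationError):
            LengthModel(forbidden_factor=1.5).pmf()


class TestIesSequence:
    def test_ta_bounded(self):
        rng = np.random.default_rng(5)
        for length in (26, 28, 50, 300):
            seq = generate_ies_sequence(rng, length)
            assert len(seq) == length + 2
            assert seq.startswith("TA") and seq.endswith("TA")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_ies_sequence(np.random.default_rng(0), 25)

    def test_forced_subterminal_tag_both_ends(self):
        forced = {
            1: {"T": 1.0}, 2: {"A": 1.0}, 3: {"G": 1.0},
        }
        model = EndModel(strata=[(10**9, forced)])
        rng = np.random.default_rng(6)
        for _ in range(20):
            seq = generate_ies_sequence(rng, 30, end_model=model)
            assert seq.startswith("TATAG")
            assert seq.endswith("CTATA")

    def test_interior_background_frequencies(self):
        rng = np.random.default_rng(7)
        pooled = collections.Counter()
        for _ in range(2000):
            seq = generate_ies_sequence(rng, 60)
            # positions > 10 bp from either TA
            pooled.update(seq[12:len(seq) - 12])
        n = sum(pooled.values())
        freq_a = pooled["A"] / n
        freq_g = pooled["G"] / n
        se = 3 / np.sqrt(n)
        assert abs(freq_a - 0.4) < se + 0.01
        assert abs(freq_g - 0.1) < se + 0.01

    def test_interior_chi_square_goodness_of_fit(self):
        rng = np.random.default_rng(8)
        pooled = collections.Counter()
        while sum(pooled.values()) < 100_000:
            seq = generate_ies_sequence(rng, 300)
            pooled.update(seq[12:len(seq) - 12])
        n = sum(pooled.values())
        obs = [pooled[b] for b in "ACGT"]
        exp = [0.4 * n, 0.1 * n, 0.1 * n, 0.4 * n]
        _stat, p = stats.chisquare(obs, exp)
        assert p > 0.01


class TestBuildGenomes:
    def test_excising_all_ies_recovers_mac(self, small_sim):
        assert excise_all(small_sim["mic"], small_sim["annotations"]) == small_sim["mac"]

    def test_zero_ies_gives_identical_genomes(self):
        cfg = SimulationConfig(seed=1, n_scaffolds=1, scaffold_len=5000, n_ies=0)
        mac, mic, anns, _truth = build_genomes(cfg)
        assert mic == mac and anns == []

    def test_annotation_slices_match_sequences(self, small_sim):
        mic = small_sim["mic"]
        for a in small_sim["annotations"]:
            assert mic[a.scaffold][a.start:a.end] == a.sequence
            assert a.sequence.startswith("TA") and a.sequence.endswith("TA")

    def test_mac_junction_is_ta(self, small_sim):
        mac = small_sim["mac"]
        for a in small_sim["annotations"]:
            assert mac[a.mac_scaffold][a.mac_junction:a.mac_junction + 2] == "TA"

    def test_identical_pair_duplication(self, small_sim):
        seqs = collections.Counter(a.sequence for a in small_sim["annotations"])
        duplicated = [s for s, c in seqs.items() if c >= 2]
        assert len(duplicated) >= 4

    def test_every_ies_has_one_rho(self, small_sim):
        truth = small_sim["truth"]
        ids = {a.ies_id for a in small_sim["annotations"]}
        assert set(truth.rho) == ids
        assert all(0.0 <= r <= 1.0 for r in truth.rho.values())

    def test_insufficient_sites_error_names_scaffold(self):
        cfg = SimulationConfig(seed=1, n_scaffolds=1, scaffold_len=3000, n_ies=100)
        with pytest.raises(GenerationError, match="scaffold_1"):
            build_genomes(cfg)

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(seed=9, n_scaffolds=1, scaffold_len=8000, n_ies=20)
        a = build_genomes(cfg)
        b = build_genomes(cfg)
        assert a[0] == b[0] and a[1] == b[1]
        assert [x.sequence for x in a[2]] == [x.sequence for x in b[2]]
        assert a[3].rho == b[3].rho


class TestDnaReads:
    def _sim(self, rho_kind, value=0.5, seed=21):
        cfg = SimulationConfig(
            seed=seed, n_scaffolds=1, scaffold_len=20000, n_ies=50, coverage=30,
            retention=RetentionModel(kind=rho_kind, value=value),
        )
        mac, mic, anns, truth = build_genomes(cfg)
        reads = simulate_dna_reads(mac, mic, anns, truth, cfg)
        return cfg, mac, mic, anns, truth, reads

    def test_rho_zero_reads_contain_no_ies_interior(self):
        _cfg, _mac, _mic, anns, _truth, reads = self._sim("constant", 0.0)
        for r in reads:
            for s, n in r.mic_blocks:
                for a in anns:
                    if a.scaffold != r.scaffold:
                        continue
                    # matched blocks may touch only the shared right TA
                    overlap = min(s + n, a.start + a.length) - max(s, a.start)
                    assert overlap <= 0

    def test_rho_one_no_junction_spanning_deletions(self):
        _cfg, _mac, _mic, _anns, _truth, reads = self._sim("constant", 1.0)
        assert all(len(r.mic_blocks) == 1 for r in reads)

    def test_boundary_read_fraction_binomial_at_half(self):
        # truth labels: fraction of boundary-crossing fragments that kept
        # the IES should be ~Binomial(n, 0.5)
        _cfg, _mac, _mic, anns, _truth, reads = self._sim("constant", 0.5, seed=22)
        plus = minus = 0
        for r in reads:
            if len(r.mic_blocks) > 1:
                minus += 1
            else:
                s, n = r.mic_blocks[0]
                if any(
                    a.scaffold == r.scaffold and s < a.start < s + n for a in anns
                ):
                    plus += 1
        n = plus + minus
        ci = stats.binom.interval(0.99, n, 0.5)
        assert ci[0] <= plus <= ci[1]

    def test_truth_completeness_each_read_once(self, small_sim):
        names = [(r.name, r.mate) for r in small_sim["reads"]]
        assert len(names) == len(set(names))

    def test_insert_shorter_than_two_reads_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(read_len=100, insert_mean=150).validate()


class TestSrnaReads:
    def test_scn_length_and_ies_mode(self, small_sim):
        srna = small_sim["srna"]
        scn = [r for r in srna if r.kind == "scn"]
        ies = [r for r in srna if r.kind == "ies"]
        assert {r.length for r in scn} == {25}
        mode = collections.Counter(r.length for r in ies).most_common(1)[0][0]
        assert mode == 27

    def test_ies_reads_never_cross_boundaries(self, small_sim):
        anns = small_sim["annotations"]
        for r in small_sim["srna"]:
            if r.kind != "ies":
                continue
            assert any(
                a.scaffold == r.scaffold and a.start <= r.start and r.start + r.length <= a.end
                for a in anns
            )

    def test_srna_determinism(self, small_config, small_sim):
        mac, mic, anns, truth = build_genomes(small_config)
        again = simulate_srna_reads(mic, anns, truth, small_config)
        first = [r for r in small_sim["srna"]]
        assert [(r.name, r.start, r.seq) for r in again] == [
            (r.name, r.start, r.seq) for r in first
        ]


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(
        seed=31, n_scaffolds=2, scaffold_len=30000, n_ies=60, coverage=10,
        retention=RetentionModel(kind="constant", value=0.0),
        errors=simulate.ErrorModel(n_cryptic=150, n_alt_boundary=50),
    )
    mac, mic, anns, truth = build_genomes(cfg)
    reads = simulate.plant_excision_errors(mac, anns, truth, cfg)
    return cfg, mac, anns, truth, reads


class TestPlantedErrors:
    def test_planted_deletions_are_ta_bounded(self, planted):
        _cfg, mac, _anns, truth, _reads = planted
        for p in truth.planted:
            seq = mac[p.scaffold]
            assert seq[p.start:p.start + 2] == "TA"
            assert seq[p.end - 2:p.end] == "TA"

    def test_zero_error_counts_is_noop(self, small_config, small_sim):
        mac, mic, anns, truth = build_genomes(small_config)
        extra = simulate.plant_excision_errors(mac, anns, truth, small_config)
        assert extra == [] and truth.planted == []

    def test_planted_length_mode_in_first_peak(self, planted):
        _cfg, _mac, _anns, truth, _reads = planted
        lengths = [p.length for p in truth.planted]
        mode = collections.Counter(lengths).most_common(1)[0][0]
        assert 26 <= mode <= 30
        assert len(truth.planted) == 200

    def test_error_read_sequences_match_deleted_reference(self, planted):
        _cfg, mac, _anns, _truth, reads = planted
        for r in reads[:100]:
            expect = "".join(mac[r.scaffold][s:s + n] for s, n in r.mac_blocks)
            assert r.seq == expect
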
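"""Synthetic germline/somatic genomes, IES annotations and reads with truth.

The generator emulates the study system: a somatic (MAC) genome, a germline
(MAC+IES) genome carrying TA-bounded IESs whose length distribution has
~10 bp periodic peaks (maximal at 28 bp, one-TA convention), a depleted
"forbidden" 38-46 bp window and a long tail; sub-terminal base-composition
tables that change with IES length; paired-end DNA-seq reads drawn from a
mixture of retained and excised molecules with known per-IES retention
fractions; 25 nt boundary-spanning scnRNAs and 21-31 nt (mode 27) iesRNAs
confined to IES intervals; and planted TA-bounded excision errors (cryptic
and alternative-boundary deletions).

Every emitted read carries ground-truth coordinates, written as SAM against
the MAC+IES reference (excised-form junction reads expressed as deletions)
and, for purely MAC-destined reads, against the MAC reference as well.
Identical configurations (including the seed) give bit-identical outputs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
import yaml

from ._seq import BASES, as_prob_vector, random_seq, revcomp
from .genome_io import IesAnnotation, sam_header, write_fasta, write_gff3


class ConfigurationError(ValueError):
    """Invalid simulation model parameters."""


class GenerationError(RuntimeError):
    """The requested structures could not be placed on the genome."""


# ---------------------------------------------------------------------------
# Model components
# ---------------------------------------------------------------------------

@dataclass
class LengthModel:
    """IES length distribution (one-TA convention).

    A discretized Gaussian mixture with peaks every ``period`` bp starting at
    ``first_peak``, geometrically decaying peak weights, a multiplicative
    depletion of the forbidden window, and a small exponential long tail.
    """

    first_peak: int = 28
    period: int = 10
    n_peaks: int = 12
    weight_decay: float = 0.6
    peak_sd: float = 1.5
    forbidden_window: tuple[int, int] = (38, 46)
    forbidden_factor: float = 0.2
    tail_fraction: float = 0.01
    tail_scale: float = 400.0
    min_length: int = 26
    max_length: int = 5000

    def validate(self) -> None:
        if self.first_peak < 26:
            raise ConfigurationError("peak centers must be >= 26")
        if not (0.0 <= self.forbidden_factor <= 1.0):
            raise ConfigurationError("forbidden depletion factor must be in [0, 1]")
        if self.weight_decay <= 0 or self.n_peaks < 1:
            raise ConfigurationError("peak weights must be positive")
        if self.peak_sd < 0 or self.tail_fraction < 0 or self.tail_scale <= 0:
            raise ConfigurationError("invalid length-model parameters")

    def pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Lengths and probabilities of the discretized distribution."""
        self.validate()
        lengths = np.arange(self.min_length, self.max_length + 1)
        probs = np.zeros_like(lengths, dtype=float)
        centers = self.first_peak + self.period * np.arange(self.n_peaks)
        weights = self.weight_decay ** np.arange(self.n_peaks)
        for c, w in zip(centers, weights):
            if self.peak_sd == 0:
                probs[lengths == c] += w
            else:
                z = (lengths - c) / self.peak_sd
                probs += w * np.exp(-0.5 * z * z)
        if probs.sum() <= 0:
            raise ConfigurationError("length model has no mass in range")
        probs /= probs.sum()
        lo, hi = self.forbidden_window
        probs[(lengths >= lo) & (lengths <= hi)] *= self.forbidden_factor
        probs /= probs.sum()
        if self.tail_fraction > 0:
            last = centers[-1]
            tail = np.where(
                lengths > last, np.exp(-(lengths - last) / self.tail_scale), 0.0
            )
            if tail.sum() > 0:
                probs = (1 - self.tail_fraction) * probs + self.tail_fraction * tail / tail.sum()
        return lengths, probs


def sample_ies_lengths(
    rng: np.random.Generator, model: LengthModel, size: int = 1
) -> np.ndarray:
    """Draw IES lengths (one-TA convention) from the length model."""
    lengths, probs = model.pmf()
    return rng.choice(lengths, size=size, p=probs)


# Sub-terminal base tables: position 1 is the base adjacent to the TA.
# The short stratum reflects the TA+TAG consensus of first-peak IESs; the
# long stratum shifts position 1 toward C (TA+CAG-like ends).
_SHORT_END = {
    1: {"A": 0.08, "C": 0.04, "G": 0.08, "T": 0.80},
    2: {"A": 0.78, "C": 0.05, "G": 0.05, "T": 0.12},
    3: {"A": 0.18, "C": 0.08, "G": 0.56, "T": 0.18},
}
_LONG_END = {
    1: {"A": 0.15, "C": 0.42, "G": 0.08, "T": 0.35},
    2: {"A": 0.62, "C": 0.06, "G": 0.06, "T": 0.26},
    3: {"A": 0.15, "C": 0.07, "G": 0.60, "T": 0.18},
}


@dataclass
class EndModel:
    """Length-stratified base-probability tables for sub-terminal positions 1-3.

    ``strata`` maps an upper length bound (inclusive) to a table; lengths
    above every bound use the last table.
    """

    strata: list[tuple[int, dict[int, dict[str, float]]]] = field(
        default_factory=lambda: [(36, _SHORT_END), (10**9, _LONG_END)]
    )

    def table_for(self, length: int) -> dict[int, dict[str, float]]:
        for bound, table in self.strata:
            if length <= bound:
                return table
        return self.strata[-1][1]

    def validate(self) -> None:
        for _bound, table in self.strata:
            for pos in (1, 2, 3):
                as_prob_vector(table[pos])


@dataclass
class RetentionModel:
    """Source of per-IES true retention fractions rho."""

    kind: str = "uniform"            # constant | uniform | table
    value: float = 0.5               # for kind == constant
    table: dict[str, float] | None = None  # for kind == table

    def draw(self, rng: np.random.Generator, ies_ids: Sequence[str]) -> dict[str, float]:
        if self.kind == "constant":
            return {i: float(self.value) for i in ies_ids}
        if self.kind == "uniform":
            return {i: float(r) for i, r in zip(ies_ids, rng.random(len(ies_ids)))}
        if self.kind == "table":
            if self.table is None:
                raise ConfigurationError("retention table not provided")
            return {i: float(self.table[i]) for i in ies_ids}
        raise ConfigurationError(f"unknown retention model kind {self.kind!r}")


@dataclass
class SrnaModel:
    """scnRNA/iesRNA generation parameters.

    scnRNAs are fixed-length windows placed uniformly over the MAC+IES
    scaffolds (hence some span IES boundaries); iesRNAs lie strictly within
    IES intervals with lengths over 21-31 nt (mode 27) and starts biased
    toward the IES ends.  Per-IES iesRNA abundance increases with the true
    retention fraction: weight = length * (floor + (1 - floor) * rho).
    """

    n_scn: int = 10000
    n_ies_reads: int = 5000
    scn_len: int = 25
    ies_len_min: int = 21
    ies_len_max: int = 31
    ies_len_mode: int = 27
    ies_len_sd: float = 2.0
    end_window: int = 5
    end_weight: float = 0.5
    abundance_floor: float = 0.25

    def length_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        lengths = np.arange(self.ies_len_min, self.ies_len_max + 1)
        z = (lengths - self.ies_len_mode) / self.ies_len_sd
        p = np.exp(-0.5 * z * z)
        return lengths, p / p.sum()


@dataclass
class ErrorModel:
    """Counts of planted TA-bounded excision errors."""

    n_cryptic: int = 0
    n_alt_boundary: int = 0
    reads_per_error: int = 3
    length_min: int = 26
    length_max: int = 30
    search_window: int = 400  # how far from a junction to look for the alt TA


@dataclass
class SimulationConfig:
    seed: int = 1
    n_scaffolds: int = 2
    scaffold_len: int = 30000
    n_ies: int = 120
    n_identical_pairs: int = 0
    min_ies_spacing: int = 260
    edge_margin: int = 300
    mac_background: dict[str, float] = field(
        default_factory=lambda: {"A": 0.35, "C": 0.15, "G": 0.15, "T": 0.35}
    )
    interior_background: dict[str, float] = field(
        default_factory=lambda: {"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4}
    )
    length_model: LengthModel = field(default_factory=LengthModel)
    end_model: EndModel = field(default_factory=EndModel)
    retention: RetentionModel = field(default_factory=RetentionModel)
    coverage: float = 30.0
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    base_error_rate: float = 0.0
    srna: SrnaModel = field(default_factory=SrnaModel)
    errors: ErrorModel = field(default_factory=ErrorModel)

    def validate(self) -> None:
        self.length_model.validate()
        self.end_model.validate()
        as_prob_vector(self.mac_background)
        as_prob_vector(self.interior_background)
        if self.errors.n_cryptic < 0 or self.errors.n_alt_boundary < 0:
            raise ConfigurationError("error counts must be >= 0")
        if self.insert_mean < 2 * self.read_len:
            raise ConfigurationError("insert_mean must be >= 2 * read_len")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        sub = {
            "length_model": LengthModel,
            "retention": RetentionModel,
            "srna": SrnaModel,
            "errors": ErrorModel,
        }
        for key, klass in sub.items():
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        if "end_model" in d and isinstance(d["end_model"], dict):
            strata = [
                (int(bound), {int(p): t for p, t in table.items()})
                for bound, table in sorted(d["end_model"].items(), key=lambda kv: int(kv[0]))
            ]
            d["end_model"] = EndModel(strata=strata)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PlantedDeletion:
    """A planted TA-bounded deletion on the MAC reference (canonical coords)."""

    scaffold: str
    start: int
    end: int
    klass: str               # cryptic | alternative_boundary
    reported_start: int      # aligner-style (left-shifted) placement
    reported_end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimulationTruth:
    seed: int
    rho: dict[str, float] = field(default_factory=dict)
    planted: list[PlantedDeletion] = field(default_factory=list)
    srna_expected: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

def generate_ies_sequence(
    rng: np.random.Generator,
    length: int,
    end_model: EndModel | None = None,
    interior_background: dict[str, float] | None = None,
) -> str:
    """Generate one IES sequence of one-TA ``length`` (returned length+2).

    The sequence starts and ends with TA; the three bases inward of each TA
    follow the end-model table for the length stratum (the right end is
    generated in reverse-complement orientation so both ends share one
    table); interior bases are i.i.d. from the interior background.
    """
    if length < 26:
        raise ValueError(f"IES length must be >= 26, got {length}")
    end_model = end_model or EndModel()
    interior_background = interior_background or {"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4}
    table = end_model.table_for(length)

    def draw_end() -> str:
        out = []
        for pos in (1, 2, 3):
            p = as_prob_vector(table[pos])
            out.append(BASES[rng.choice(4, p=p)])
        return "".join(out)

    left = "TA" + draw_end()
    right = revcomp("TA" + draw_end())
    interior = random_seq(rng, length - 8, interior_background)
    return left + interior + right


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def build_genomes(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], list[IesAnnotation], SimulationTruth]:
    """Build MAC and MAC+IES genomes plus annotations and truth.

    IESs are inserted at TA sites so that excising ``[start, start+length)``
    from the MAC+IES scaffold reproduces the MAC scaffold exactly.  A
    configurable number of IES sequence values are duplicated verbatim at
    distinct loci for identical-pair analyses.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mac: dict[str, str] = {}
    for i in range(config.n_scaffolds):
        mac[f"scaffold_{i + 1}"] = random_seq(rng, config.scaffold_len, config.mac_background)

    # Distribute IES loci over scaffolds: find TA insertion sites with
    # minimum spacing, away from scaffold edges.
    per_scaffold = np.full(config.n_scaffolds, config.n_ies // config.n_scaffolds)
    per_scaffold[: config.n_ies % config.n_scaffolds] += 1
    sites: list[tuple[str, int]] = []
    for (name, seq), want in zip(mac.items(), per_scaffold):
        if want == 0:
            continue
        candidates = [
            p
            for p in range(config.edge_margin, len(seq) - config.edge_margin)
            if seq[p:p + 2] == "TA"
        ]
        chosen: list[int] = []
        order = rng.permutation(len(candidates))
        for idx in order:
            p = candidates[idx]
            if all(abs(p - q) >= config.min_ies_spacing for q in chosen):
                chosen.append(p)
                if len(chosen) == want:
                    break
        if len(chosen) < want:
            raise GenerationError(
                f"scaffold {name!r}: only {len(chosen)} of {want} TA insertion sites available"
            )
        sites.extend((name, p) for p in sorted(chosen))

    lengths = sample_ies_lengths(rng, config.length_model, size=len(sites))
    seqs = [
        generate_ies_sequence(rng, int(n), config.end_model, config.interior_background)
        for n in lengths
    ]
    # Duplicate sequences for identical-pair analyses (pair i copies the
    # sequence of locus 2i into locus 2i+1).
    n_pairs = min(config.n_identical_pairs, len(sites) // 2)
    for k in range(n_pairs):
        seqs[2 * k + 1] = seqs[2 * k]
        lengths[2 * k + 1] = lengths[2 * k]

    mic: dict[str, str] = {}
    annotations: list[IesAnnotation] = []
    i_global = 0
    for name, seq in mac.items():
        here = [
            (p, seqs[k], int(lengths[k]), k)
            for k, (scaf, p) in enumerate(sites)
            if scaf == name
        ]
        here.sort(key=lambda t: t[0])
        parts: list[str] = []
        prev = 0
        offset = 0
        for p, ies_seq, ies_len, _k in here:
            parts.append(seq[prev:p])
            parts.append(ies_seq[:ies_len])
            i_global += 1
            annotations.append(
                IesAnnotation(
                    ies_id=f"IES.{name}.{i_global}",
                    scaffold=name,
                    start=p + offset,
                    length=ies_len,
                    sequence=ies_seq,
                    mac_scaffold=name,
                    mac_junction=p,
                )
            )
            offset += ies_len
            prev = p
        parts.append(seq[prev:])
        mic[name] = "".join(parts)

    truth = SimulationTruth(seed=config.seed)
    truth.rho = config.retention.draw(rng, [a.ies_id for a in annotations])
    return mac, mic, annotations, truth


def excise_all(mic: dict[str, str], annotations: Sequence[IesAnnotation]) -> dict[str, str]:
    """Delete every annotated IES ([start, start+length)) from MAC+IES scaffolds."""
    out = {}
    for name, seq in mic.items():
        anns = sorted((a for a in annotations if a.scaffold == name), key=lambda a: a.start)
        parts, prev = [], 0
        for a in anns:
            parts.append(seq[prev:a.start])
            prev = a.start + a.length
        parts.append(seq[prev:])
        out[name] = "".join(parts)
    return out


# ---------------------------------------------------------------------------
# DNA-seq read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    """One simulated mate with ground-truth alignments.

    ``mic_blocks`` are matched reference blocks on the MAC+IES scaffold
    (gaps between blocks are excised-IES deletions); ``mac_blocks`` are set
    for reads composed purely of MAC-destined bases (single block for
    regular reads; two blocks around the deletion for planted-error reads).
    ``seq`` is reference-forward; mate 2 is written to FASTQ reverse-
    complemented.
    """

    name: str
    mate: int
    scaffold: str
    seq: str
    mic_blocks: list[tuple[int, int]] | None
    mac_blocks: list[tuple[int, int]] | None
    is_reverse: bool


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = BASES[(BASES.index(arr[i]) + rng.integers(1, 4)) % 4]
    return "".join(arr)


def simulate_dna_reads(
    mac: dict[str, str],
    mic: dict[str, str],
    annotations: Sequence[IesAnnotation],
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Simulate paired-end DNA-seq reads from a retained/excised mixture.

    Fragment starts are uniform over MAC coordinates; walking rightward from
    the start, each encountered IES junction is independently expanded to
    the retained form with probability rho (the molecule state is shared by
    both mates of a fragment).  The number of fragments is
    ``coverage * scaffold_len / (2 * read_len)`` so that ``coverage`` is the
    mean per-base read depth.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    reads: list[SimRead] = []
    rl = config.read_len
    by_scaffold: dict[str, list[IesAnnotation]] = {}
    for a in sorted(annotations, key=lambda a: a.mac_junction):
        by_scaffold.setdefault(a.mac_scaffold, []).append(a)
    # cumulative inserted length ahead of each junction, for MAC->MIC lifting
    cum: dict[str, list[int]] = {}
    for name, anns in by_scaffold.items():
        c = [0]
        for a in anns:
            c.append(c[-1] + a.length)
        cum[name] = c

    for name, mac_seq in mac.items():
        anns = by_scaffold.get(name, [])
        junctions = [a.mac_junction for a in anns]
        c = cum.get(name, [0])
        n_frag = int(round(config.coverage * len(mac_seq) / (2.0 * rl)))
        starts = rng.integers(0, max(1, len(mac_seq) - rl), size=n_frag)
        inserts = np.maximum(
            2 * rl, np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_frag)).astype(int)
        )
        for fi in range(n_frag):
            start = int(starts[fi])
            want = int(inserts[fi])
            # walk from `start` on MAC, expanding retained IESs
            pieces: list[tuple[str, int, int, str]] = []  # (kind, mic_start, length, seq)
            pos = start
            k = bisect.bisect_left(junctions, pos)  # first junction >= pos
            # a fragment starting exactly on a junction TA begins downstream
            # of any retained IES at that junction
            if k < len(junctions) and junctions[k] == pos:
                k += 1
            remaining = want
            while remaining > 0 and pos < len(mac_seq):
                nxt = junctions[k] if k < len(junctions) else len(mac_seq)
                take = min(remaining, nxt - pos)
                if take > 0:
                    mic_start = pos + c[k]
                    pieces.append(("mac", mic_start, take, mac_seq[pos:pos + take]))
                    pos += take
                    remaining -= take
                if remaining > 0 and k < len(junctions) and pos == junctions[k]:
                    a = anns[k]
                    if rng.random() < truth.rho[a.ies_id]:
                        take = min(remaining, a.length)
                        pieces.append(("ies", a.start, take, a.sequence[:take]))
                        remaining -= take
                    k += 1
            frag = "".join(p[3] for p in pieces)
            if len(frag) < 2 * rl:
                continue
            qname = f"frag:{name}:{fi}"
            for mate, lo in ((1, 0), (2, len(frag) - rl)):
                blocks = _slice_blocks(pieces, lo, rl)
                seq = frag[lo:lo + rl]
                reads.append(
                    SimRead(
                        name=qname,
                        mate=mate,
                        scaffold=name,
                        seq=_apply_errors(rng, seq, config.base_error_rate),
                        mic_blocks=_merge_blocks(blocks),
                        mac_blocks=_mac_blocks(blocks, junctions, c),
                        is_reverse=(mate == 2),
                    )
                )
    return reads


def _slice_blocks(
    pieces: list[tuple[str, int, int, str]], lo: int, n: int
) -> list[tuple[str, int, int]]:
    """Sub-pieces (kind, mic_start, length) covering fragment offsets [lo, lo+n)."""
    out = []
    off = 0
    for kind, mic_start, plen, _seq in pieces:
        a = max(lo, off)
        b = min(lo + n, off + plen)
        if a < b:
            out.append((kind, mic_start + (a - off), b - a))
        off += plen
        if off >= lo + n:
            break
    return out


def _merge_blocks(blocks: list[tuple[str, int, int]]) -> list[tuple[int, int]]:
    """Merge adjacent MIC blocks; retained-IES pieces are MIC-contiguous."""
    merged: list[list[int]] = []
    for _kind, s, n in blocks:
        if merged and merged[-1][0] + merged[-1][1] == s:
            merged[-1][1] += n
        else:
            merged.append([s, n])
    return [(s, n) for s, n in merged]


def _mac_blocks(
    blocks: list[tuple[str, int, int]],
    junctions: list[int],
    cum: list[int],
) -> list[tuple[int, int]] | None:
    """MAC-space single block for reads with no retained-IES bases.

    Pure MAC-destined reads are contiguous in MAC space even across excised
    junctions, so the lift is a single matched block.
    """
    if any(kind == "ies" for kind, _s, _n in blocks):
        return None
    total = sum(n for _k, _s, n in blocks)
    mac_start = _mic_to_mac_fast(junctions, cum, blocks[0][1])
    return [(mac_start, total)]


def _mic_to_mac_fast(junctions: list[int], cum: list[int], mic_pos: int) -> int:
    """MAC coordinate of a MAC-destined MAC+IES position (inverse of p -> p + cum[k])."""
    lo, hi = 0, len(cum) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        cand = mic_pos - cum[mid]
        if mid < len(junctions) and cand > junctions[mid]:
            lo = mid + 1
        else:
            hi = mid
    return mic_pos - cum[lo]


# ---------------------------------------------------------------------------
# Planted excision errors
# ---------------------------------------------------------------------------

def _canonical_ta_placement(seq: str, s: int, e: int) -> tuple[int, int, bool]:
    """Leftmost shift-equivalent placement whose span starts and ends with TA."""
    ss, ee = s, e
    while ss > 0 and seq[ss - 1] == seq[ee - 1]:
        ss -= 1
        ee -= 1
    best = None
    while True:
        if seq[ss:ss + 2] == "TA" and seq[ee - 2:ee] == "TA":
            best = (ss, ee)
            break
        if ee < len(seq) and seq[ss] == seq[ee]:
            ss += 1
            ee += 1
        else:
            break
    if best is None:
        return s, e, False
    return best[0], best[1], True


def _left_shift(seq: str, s: int, e: int) -> tuple[int, int]:
    while s > 0 and seq[s - 1] == seq[e - 1]:
        s -= 1
        e -= 1
    return s, e


def plant_excision_errors(
    mac: dict[str, str],
    annotations: Sequence[IesAnnotation],
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Emit extra read pairs carrying planted TA-bounded deletions on MAC.

    Cryptic deletions remove TA-bounded MAC segments away from IES
    junctions; alternative-boundary deletions extend from an annotated IES
    junction TA to a nearby downstream TA.  Reads report the deletion with
    aligner-style left-shifted placement; the truth records canonical
    coordinates.  With zero error counts the read stream is unchanged.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    em = config.errors
    reads: list[SimRead] = []
    if em.n_cryptic == 0 and em.n_alt_boundary == 0:
        return reads
    rl = config.read_len
    junctions_by_scaffold = {
        name: sorted(a.mac_junction for a in annotations if a.mac_scaffold == name)
        for name in mac
    }

    def emit(scaffold: str, s: int, e: int, klass: str, tag: int) -> None:
        seq = mac[scaffold]
        cs, ce, ok = _canonical_ta_placement(seq, s, e)
        if not ok:
            raise GenerationError(f"planted deletion [{s},{e}) on {scaffold} not TA-bounded")
        rs, re_ = _left_shift(seq, cs, ce)
        truth.planted.append(
            PlantedDeletion(scaffold, cs, ce, klass, reported_start=rs, reported_end=re_)
        )
        for ri in range(em.reads_per_error):
            a = int(rng.integers(10, rl - 10))  # left anchor length
            b = rl - a
            if rs - a < 0 or re_ + b > len(seq):
                continue
            qname = f"err:{klass}:{scaffold}:{tag}:{ri}"
            read_seq = seq[rs - a:rs] + seq[re_:re_ + b]
            reads.append(
                SimRead(
                    name=qname,
                    mate=1,
                    scaffold=scaffold,
                    seq=read_seq,
                    mic_blocks=None,
                    mac_blocks=[(rs - a, a), (re_, b)],
                    is_reverse=False,
                )
            )
            # plain downstream mate to keep the pair well-formed
            m_start = min(re_ + b + 20, len(seq) - rl)
            reads.append(
                SimRead(
                    name=qname,
                    mate=2,
                    scaffold=scaffold,
                    seq=seq[m_start:m_start + rl],
                    mic_blocks=None,
                    mac_blocks=[(m_start, rl)],
                    is_reverse=True,
                )
            )

    scaffolds = list(mac)
    planted = 0
    attempts = 0
    while planted < em.n_cryptic:
        attempts += 1
        if attempts > 200 * max(1, em.n_cryptic):
            raise GenerationError(
                f"no eligible TA pair in length range {em.length_min}-{em.length_max}"
            )
        name = scaffolds[int(rng.integers(len(scaffolds)))]
        seq = mac[name]
        s = int(rng.integers(rl, len(seq) - rl - em.length_max))
        if seq[s:s + 2] != "TA":
            continue
        ok_e = [
            e
            for e in range(s + em.length_min, s + em.length_max + 1)
            if seq[e - 2:e] == "TA"
        ]
        if not ok_e:
            continue
        e = ok_e[int(rng.integers(len(ok_e)))]
        js = junctions_by_scaffold[name]
        if any(abs(s - j) < 5 or abs(e - j) < 5 for j in js):
            continue  # keep cryptic deletions away from real junctions
        emit(name, s, e, "cryptic", planted)
        planted += 1

    planted = 0
    attempts = 0
    all_junctions = [
        (a.mac_scaffold, a.mac_junction) for a in annotations
    ]
    while planted < em.n_alt_boundary and all_junctions:
        attempts += 1
        if attempts > 200 * max(1, em.n_alt_boundary):
            raise GenerationError("no alternative-boundary TA found near junctions")
        name, j = all_junctions[int(rng.integers(len(all_junctions)))]
        seq = mac[name]
        # deletion from the junction TA to a downstream TA (one-TA span)
        ok_e = [
            e
            for e in range(j + em.length_min, min(j + em.search_window, len(seq) - rl))
            if seq[e - 2:e] == "TA"
        ]
        if not ok_e:
            continue
        e = ok_e[int(rng.integers(len(ok_e)))]
        emit(name, j, e, "alternative_boundary", planted)
        planted += 1
    return reads


# ---------------------------------------------------------------------------
# sRNA simulation
# ---------------------------------------------------------------------------

@dataclass
class SrnaRead:
    name: str
    scaffold: str
    start: int        # MAC+IES coordinate
    length: int
    seq: str
    kind: str         # scn | ies
    unique: bool


def simulate_srna_reads(
    mic: dict[str, str],
    annotations: Sequence[IesAnnotation],
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SrnaRead]:
    """Simulate scnRNA and iesRNA reads with ground-truth placements.

    scnRNAs: fixed-length (default 25 nt) windows uniform over MAC+IES
    scaffolds.  iesRNAs: lengths over 21-31 nt (mode 27), strictly within
    IES intervals (a length longer than the host IES is resampled from the
    truncated distribution), with starts drawn near the IES ends with
    probability ``end_weight``; per-IES counts follow a multinomial over
    weights ``length * (floor + (1-floor) * rho)``.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    sm = config.srna
    reads: list[SrnaRead] = []

    names = list(mic)
    lens = np.array([len(mic[n]) for n in names], dtype=float)
    scaffold_p = lens / lens.sum()
    picks = rng.choice(len(names), size=sm.n_scn, p=scaffold_p)
    for i, si in enumerate(picks):
        name = names[si]
        seq = mic[name]
        start = int(rng.integers(0, len(seq) - sm.scn_len))
        reads.append(
            SrnaRead(
                name=f"scn:{i}",
                scaffold=name,
                start=start,
                length=sm.scn_len,
                seq=seq[start:start + sm.scn_len],
                kind="scn",
                unique=True,
            )
        )

    anns = list(annotations)
    if anns and sm.n_ies_reads > 0:
        seq_counts: dict[str, int] = {}
        for a in anns:
            seq_counts[a.sequence] = seq_counts.get(a.sequence, 0) + 1
        weights = np.array(
            [
                a.length * (sm.abundance_floor + (1 - sm.abundance_floor) * truth.rho[a.ies_id])
                for a in anns
            ]
        )
        counts = rng.multinomial(sm.n_ies_reads, weights / weights.sum())
        lengths_all, pmf = sm.length_pmf()
        for a, n_reads in zip(anns, counts):
            truth.srna_expected[a.ies_id] = float(n_reads)
            span = a.length + 2  # full IES incl. both TAs
            mask = lengths_all <= span
            p = pmf * mask
            if p.sum() == 0:
                continue
            p = p / p.sum()
            ls = rng.choice(lengths_all, size=n_reads, p=p)
            for ri, l in enumerate(ls):
                l = int(l)
                max_start = span - l
                if rng.random() < sm.end_weight:
                    w = min(sm.end_window, max_start)
                    rel = int(rng.integers(0, w + 1))
                    if rng.random() < 0.5:
                        rel = max_start - rel
                else:
                    rel = int(rng.integers(0, max_start + 1))
                start = a.start + rel
                reads.append(
                    SrnaRead(
                        name=f"ies:{a.ies_id}:{ri}",
                        scaffold=a.scaffold,
                        start=start,
                        length=l,
                        seq=mic[a.scaffold][start:start + l],
                        kind="ies",
                        unique=seq_counts[a.sequence] == 1,
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[SimRead], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in sorted(reads, key=lambda r: (r.name, r.mate)):
            fh = f1 if r.mate == 1 else f2
            seq = revcomp(r.seq) if r.mate == 2 else r.seq
            fh.write(f"@{r.name}/{r.mate}\n{seq}\n+\n{'I' * len(seq)}\n")


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (s, n) in enumerate(blocks):
        if i > 0:
            gap = s - (blocks[i - 1][0] + blocks[i - 1][1])
            cig.append((2, gap))  # D
        cig.append((0, n))  # M
    return cig


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    scaffold: str,
    blocks: list[tuple[int, int]],
    seq: str,
    mate: int,
    is_reverse: bool,
    paired: bool = True,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.query_sequence = seq
    seg.reference_id = header.get_tid(scaffold)
    seg.reference_start = blocks[0][0]
    seg.cigartuples = _blocks_to_cigar(blocks)
    seg.mapping_quality = 60
    flag = 0
    if paired:
        flag |= 0x1 | 0x2
        flag |= 0x40 if mate == 1 else 0x80
        if is_reverse:
            flag |= 0x10
        else:
            flag |= 0x20
    seg.flag = flag
    seg.next_reference_id = seg.reference_id if paired else -1
    seg.next_reference_start = seg.reference_start if paired else -1
    return seg


def write_dna_truth_sams(
    reads: Sequence[SimRead],
    mic: dict[str, str],
    mac: dict[str, str],
    mic_path: str | Path,
    mac_path: str | Path,
) -> dict[str, int]:
    """Write ground-truth alignments against both references (sorted SAM).

    The MAC+IES SAM carries every regular read (excised junction-spanning
    reads expressed as deletions); the MAC SAM carries reads composed purely
    of MAC-destined bases plus planted-error reads.  Returns mapped-read
    counts per output for downstream normalization.
    """
    mic_header = pysam.AlignmentHeader.from_dict(sam_header(mic))
    mac_header = pysam.AlignmentHeader.from_dict(sam_header(mac))
    mic_recs, mac_recs = [], []
    for r in reads:
        if r.mic_blocks is not None:
            mic_recs.append(
                _make_segment(mic_header, r.name, r.scaffold, r.mic_blocks, r.seq, r.mate, r.is_reverse)
            )
        if r.mac_blocks is not None:
            mac_recs.append(
                _make_segment(mac_header, r.name, r.scaffold, r.mac_blocks, r.seq, r.mate, r.is_reverse)
            )
    for recs, header, path in ((mic_recs, mic_header, mic_path), (mac_recs, mac_header, mac_path)):
        recs.sort(key=lambda s: (s.reference_id, s.reference_start, s.query_name))
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for s in recs:
                out.write(s)
    return {"mic_mapped": len(mic_recs), "mac_mapped": len(mac_recs)}


def write_srna_truth_sams(
    reads: Sequence[SrnaRead],
    mic: dict[str, str],
    mac: dict[str, str],
    annotations: Sequence[IesAnnotation],
    mac_path: str | Path,
    mic_path: str | Path,
) -> dict[str, int]:
    """Write idealized exact-match sRNA alignments for two-stage assignment.

    Reads whose interval touches no IES base also exist in the MAC genome
    and are written (lifted) to the MAC SAM; all other reads are written to
    the MAC+IES SAM.  Reads from IESs whose full sequence occurs at several
    loci are flagged non-unique (mapping quality 0).
    """
    from .genome_io import CoordinateMap

    cmap = CoordinateMap(annotations)
    ies_intervals: dict[str, list[tuple[int, int]]] = {}
    for a in annotations:
        ies_intervals.setdefault(a.scaffold, []).append((a.start, a.end))
    for v in ies_intervals.values():
        v.sort()
    mic_header = pysam.AlignmentHeader.from_dict(sam_header(mic))
    mac_header = pysam.AlignmentHeader.from_dict(sam_header(mac))
    mac_recs, mic_recs = [], []
    for r in reads:
        touches_ies = _touches_interval(ies_intervals.get(r.scaffold, []), r.start, r.start + r.length)
        if not touches_ies:
            mac_start = cmap.mic_to_mac(r.scaffold, r.start)
            seg = _make_segment(
                mac_header, r.name, r.scaffold, [(mac_start, r.length)], r.seq, 1, False, paired=False
            )
            seg.mapping_quality = 60 if r.unique else 0
            mac_recs.append(seg)
        else:
            seg = _make_segment(
                mic_header, r.name, r.scaffold, [(r.start, r.length)], r.seq, 1, False, paired=False
            )
            seg.mapping_quality = 60 if r.unique else 0
            mic_recs.append(seg)
    for recs, path in ((mac_recs, mac_path), (mic_recs, mic_path)):
        recs.sort(key=lambda s: (s.reference_id, s.reference_start, s.query_name))
    with pysam.AlignmentFile(str(mac_path), "w", header=mac_header) as out:
        for s in mac_recs:
            out.write(s)
    with pysam.AlignmentFile(str(mic_path), "w", header=mic_header) as out:
        for s in mic_recs:
            out.write(s)
    return {"mac": len(mac_recs), "mic": len(mic_recs)}


def _touches_interval(intervals: list[tuple[int, int]], s: int, e: int) -> bool:
    import bisect

    i = bisect.bisect_right(intervals, (s, 10**18))
    for j in (i - 1, i):
        if 0 <= j < len(intervals):
            a, b = intervals[j]
            if s < b and a < e:
                return True
    return False


def write_truth_tables(
    annotations: Sequence[IesAnnotation], truth: SimulationTruth, path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ies_id\tscaffold\tstart\tlength\tmac_junction\trho\n")
        for a in annotations:
            fh.write(
                f"{a.ies_id}\t{a.scaffold}\t{a.start}\t{a.length}\t"
                f"{a.mac_junction}\t{truth.rho[a.ies_id]:.6g}\n"
            )
    return path


def write_planted_table(truth: SimulationTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tlength\tklass\treported_start\treported_end\n")
        for p in truth.planted:
            fh.write(
                f"{p.scaffold}\t{p.start}\t{p.end}\t{p.length}\t{p.klass}\t"
                f"{p.reported_start}\t{p.reported_end}\n"
            )
    return path


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> dict[str, object]:
    """Run the full simulation and write all artifacts to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mac, mic, annotations, truth = build_genomes(config)
    rng_reads = np.random.default_rng(config.seed + 1)
    reads = simulate_dna_reads(mac, mic, annotations, truth, config, rng_reads)
    reads += plant_excision_errors(mac, annotations, truth, config)
    srna = simulate_srna_reads(mic, annotations, truth, config)

    write_fasta(mac, out / "mac.fa")
    write_fasta(mic, out / "mac_with_ies.fa")
    write_gff3(annotations, out / "ies.gff3")
    write_fastq(reads, out / "dna_R1.fastq", out / "dna_R2.fastq")
    counts = write_dna_truth_sams(
        reads, mic, mac, out / "dna_mic_truth.sam", out / "dna_mac_truth.sam"
    )
    srna_counts = write_srna_truth_sams(
        srna, mic, mac, annotations, out / "srna_mac_truth.sam", out / "srna_mic_truth.sam"
    )
    write_truth_tables(annotations, truth, out / "truth_ies.tsv")
    write_planted_table(truth, out / "truth_planted.tsv")
    return {
        "mac": mac,
        "mic": mic,
        "annotations": annotations,
        "truth": truth,
        "reads": reads,
        "srna": srna,
        "mapped_counts": {**counts, **{f"srna_{k}": v for k, v in srna_counts.items()}},
        "paths": {
            "mac_fasta": out / "mac.fa",
            "mic_fasta": out / "mac_with_ies.fa",
            "gff3": out / "ies.gff3",
            "dna_mic_sam": out / "dna_mic_truth.sam",
            "dna_mac_sam": out / "dna_mac_truth.sam",
            "srna_mac_sam": out / "srna_mac_truth.sam",
            "srna_mic_sam": out / "srna_mic_truth.sam",
        },
    }
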
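"""Quasi-IES scanning: MAC segments flanked by perfect terminal inverted repeats.

A quasi-IES is a somatic-genome segment that looks like an IES substrate:
it starts with a 5-bp IES end motif (e.g. TATAG) and ends with the motif's
reverse complement (e.g. CTATA), a perfect terminal inverted repeat.  Such
segments are potential targets for erroneous (cryptic) excision, and their
depletion relative to expectation in the real genome is a signature of
evolutionary counter-selection.

Lengths follow the one-TA convention used for IESs: for a motif at
``[i, i+5)`` and its reverse complement at ``[j-5, j)``, the length is
``j - 2 - i``, so that the right flanking TA (the last two bases of the
reverse-complement motif) plays the role of the retained junction TA and a
26 bp quasi-IES has the same extremes as a 26 bp IES.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp


@dataclass
class QuasiIes:
    scaffold: str
    start: int      # first base of the left TA (= motif start)
    length: int     # one-TA convention: j - 2 - start
    motif: str


def _find_all(seq: str, pattern: str) -> list[int]:
    out = []
    i = seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def scan_quasi_ies(
    genome: dict[str, str],
    motif: str,
    min_len: int = 26,
    max_len: int = 150,
) -> list[QuasiIes]:
    """Report every perfectly inverted-repeat-flanked segment of the motif.

    Overlapping and nested occurrences are all reported.  The scan is
    strand-asymmetric by design (motif at the 5' end, reverse complement at
    the 3' end); scanning the reverse complement of the genome yields the
    mirrored set.  Runtime is linear in genome length plus motif-hit pairs
    within the length window.
    """
    if len(motif) != 5 or not motif.startswith("TA"):
        raise ValueError("motif must be 5 bp and start with TA")
    rc = revcomp(motif)
    out: list[QuasiIes] = []
    for name, seq in genome.items():
        lefts = _find_all(seq, motif)
        rights = np.array(_find_all(seq, rc), dtype=int)  # start of rc occurrence
        if len(lefts) == 0 or len(rights) == 0:
            continue
        ends = rights + 5  # exclusive end j of the rc occurrence
        for i in lefts:
            # one-TA length j - 2 - i within [min_len, max_len]
            lo = np.searchsorted(ends, i + min_len + 2, side="left")
            hi = np.searchsorted(ends, i + max_len + 2, side="right")
            for j in ends[lo:hi]:
                out.append(QuasiIes(name, i, int(j) - 2 - i, motif))
    out.sort(key=lambda q: (q.scaffold, q.start, q.length))
    return out


def quasi_length_profile(quasis: Sequence[QuasiIes]) -> pd.Series:
    """Exact tally of quasi-IES counts per one-TA length."""
    if not quasis:
        return pd.Series(dtype=int, name="count")
    lengths = pd.Series([q.length for q in quasis])
    prof = lengths.value_counts().sort_index()
    prof.name = "count"
    prof.index.name = "length"
    return prof


def _base_composition(genome: dict[str, str]) -> dict[str, float]:
    counts = {b: 0 for b in "ACGT"}
    total = 0
    for seq in genome.values():
        for b in "ACGT":
            counts[b] += seq.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("genome has no unambiguous bases")
    return {b: c / total for b, c in counts.items()}


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian walk on the
    de Bruijn graph of order 1, Altschul-Erickson style)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    # pick a random last-exit edge per vertex (except the final vertex) that
    # forms an arborescence toward the final vertex, by random trial
    last = seq[-1]
    vertices = list(edges)
    for _attempt in range(1000):
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last}
        # connectivity check: following last-exit edges must reach `last`
        ok = True
        for v in last_exit:
            cur, seen = v, set()
            while cur != last:
                if cur in seen or cur not in last_exit:
                    ok = False
                    break
                seen.add(cur)
                cur = last_exit[cur]
            if not ok:
                break
        if ok:
            break
    else:
        return seq
    remaining: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v != last:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        if v != last:
            pool.append(last_exit[v])
        remaining[v] = pool
    out = [seq[0]]
    cur = seq[0]
    idx = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        nxt = remaining[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def expected_quasi_counts(
    genome: dict[str, str],
    motif: str,
    lengths: Sequence[int],
    method: str = "closed_form",
    n_shuffles: int = 20,
    seed: int | None = None,
) -> pd.Series:
    """Expected quasi-IES counts per length under a null genome model.

    closed_form: independent-site expectation from the genome base
    composition -- for each length L, (positions) x P(motif) x P(revcomp).
    shuffle: mean observed count over dinucleotide-preserving shuffles of
    each scaffold (seeded).
    """
    lengths = list(lengths)
    if method == "closed_form":
        comp = _base_composition(genome)
        p_left = float(np.prod([comp[b] for b in motif]))
        p_right = float(np.prod([comp[b] for b in revcomp(motif)]))
        values = []
        for L in lengths:
            positions = sum(max(0, len(seq) - L - 1) for seq in genome.values())
            values.append(positions * p_left * p_right)
        return pd.Series(values, index=pd.Index(lengths, name="length"), name="expected")
    if method == "shuffle":
        if n_shuffles <= 0:
            raise ValueError("n_shuffles must be > 0")
        rng = np.random.default_rng(seed)
        totals = np.zeros(len(lengths))
        lmin, lmax = min(lengths), max(lengths)
        for _ in range(n_shuffles):
            shuffled = {k: _dinucleotide_shuffle(v, rng) for k, v in genome.items()}
            prof = quasi_length_profile(
                scan_quasi_ies(shuffled, motif, min_len=lmin, max_len=lmax)
            )
            for i, L in enumerate(lengths):
                totals[i] += prof.get(L, 0)
        return pd.Series(
            totals / n_shuffles, index=pd.Index(lengths, name="length"), name="expected"
        )
    raise ValueError(f"unknown method {method!r}")
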
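"""Detection and canonical realignment of TA-bounded deletions (TA-indels).

Low-frequency excision errors leave deletions relative to the MAC reference
that are bounded by TA dinucleotides, like IES excision itself.  Aligners
place a deletion arbitrarily within its shift-equivalence class (usually
left-shifted), so each reported deletion is realigned to a canonical
placement before TA-boundedness is decided.

Two classes are distinguished: *cryptic* excision removes MAC-destined DNA
away from any annotated IES junction, while an *alternative-boundary*
deletion has an endpoint at an annotated junction (an IES excised beyond
its usual boundary).  Residual IES retention is an insertion relative to
the MAC reference and is measured by the retention module, not here.

Rates are normalized as reads with TA-indels per million mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .genome_io import IesAnnotation


@dataclass
class RawDeletion:
    scaffold: str
    start: int
    end: int
    query_name: str


@dataclass
class TaIndel:
    scaffold: str
    del_start: int
    del_end: int
    klass: str            # cryptic | alternative_boundary
    read_count: int
    contains_n: bool = False

    @property
    def length(self) -> int:
        """Deletion length (one-TA convention: del_end - del_start)."""
        return self.del_end - self.del_start


def extract_deletions(
    records: Iterable[pysam.AlignedSegment],
    min_len: int = 5,
    max_len: int = 10000,
) -> list[RawDeletion]:
    """One raw deletion per read per within-read deletion operation in bounds."""
    out: list[RawDeletion] = []
    for read in records:
        if read.is_unmapped or not read.cigartuples:
            continue
        pos = read.reference_start
        for op, n in read.cigartuples:
            if op in (0, 7, 8):
                pos += n
            elif op in (2, 3):  # D / N
                if min_len <= n <= max_len:
                    out.append(RawDeletion(read.reference_name, pos, pos + n, read.query_name))
                pos += n
    return out


def _equivalent_placements(seq: str, s: int, e: int) -> list[tuple[int, int]]:
    """All shift-equivalent placements of deleting [s, e) from ``seq``."""
    placements = [(s, e)]
    ss, ee = s, e
    while ss > 0 and seq[ss - 1] == seq[ee - 1]:
        ss -= 1
        ee -= 1
        placements.append((ss, ee))
    ss, ee = s, e
    while ee < len(seq) and seq[ss] == seq[ee]:
        ss += 1
        ee += 1
        placements.append((ss, ee))
    placements.sort()
    return placements


def realign_deletion(
    mac_genome: dict[str, str] | str,
    scaffold: str | None,
    del_start: int,
    del_end: int,
    rule: str = "span",
) -> tuple[int, int, bool]:
    """Canonically realign a reported deletion against the reference.

    Enumerates every sequence-equivalent placement of the deletion (shifting
    while the base entering one end equals the base leaving the other) and
    returns the leftmost placement that is TA-bounded, together with a flag.

    rule="span" (default): the deleted span itself starts with TA and ends
    with TA, the literal reading of TA-bounded deletions.  rule="junction":
    stricter IES-excision chemistry -- the span starts with TA and the two
    reference bases immediately after the span are TA, so a single TA is
    retained at the junction.
    """
    seq = mac_genome if isinstance(mac_genome, str) else mac_genome[scaffold]
    for ss, ee in _equivalent_placements(seq, del_start, del_end):
        if seq[ss:ss + 2] != "TA":
            continue
        if rule == "span" and seq[ee - 2:ee] == "TA":
            return ss, ee, True
        if rule == "junction" and seq[ee:ee + 2] == "TA":
            return ss, ee, True
    # no TA-bounded placement: canonicalize to the leftmost equivalent
    # placement so the result is a pure function of the equivalence class
    ss, ee = _equivalent_placements(seq, del_start, del_end)[0]
    return ss, ee, False


def classify_taindel(
    del_start: int,
    del_end: int,
    junctions: Sequence[int],
    tol: int = 0,
) -> str:
    """alternative_boundary iff an endpoint lies within ``tol`` of a junction.

    ``junctions`` are MAC positions of annotated junction TAs (the T).  The
    deletion start is compared to the junction TA start and the deletion end
    to the junction TA end (a TA...TA span eating the junction TA at either
    extremity).
    """
    for j in junctions:
        if min(abs(del_start - j), abs(del_end - (j + 2))) <= tol:
            return "alternative_boundary"
    return "cryptic"


def catalog_taindels(
    records: Iterable[pysam.AlignedSegment],
    mac_genome: dict[str, str],
    annotations: Sequence[IesAnnotation] = (),
    min_len: int = 5,
    max_len: int = 10000,
    rule: str = "span",
    tol: int = 0,
) -> tuple[list[TaIndel], dict[str, int]]:
    """Extract, realign, filter and classify TA-indels from MAC alignments.

    Deletions whose deleted reference span contains 'N' are flagged and
    excluded from counting.  Deletions supported by multiple reads are
    merged by canonical coordinates; ``read_count`` accumulates and the
    per-read total is reported in the stats for normalization.
    """
    raw = extract_deletions(records, min_len=min_len, max_len=max_len)
    junctions_by_scaffold: dict[str, list[int]] = {}
    for a in annotations:
        junctions_by_scaffold.setdefault(a.mac_scaffold, []).append(a.mac_junction)
    merged: dict[tuple[str, int, int], TaIndel] = {}
    stats = {
        "raw_deletions": len(raw),
        "ta_bounded_reads": 0,
        "non_ta": 0,
        "contains_n": 0,
    }
    reads_with_taindel: set[str] = set()
    for d in raw:
        seq = mac_genome[d.scaffold]
        cs, ce, ok = realign_deletion(seq, None, d.start, d.end, rule=rule)
        if not ok:
            stats["non_ta"] += 1
            continue
        if "N" in seq[cs:ce]:
            stats["contains_n"] += 1
            continue
        stats["ta_bounded_reads"] += 1
        reads_with_taindel.add(d.query_name)
        key = (d.scaffold, cs, ce)
        if key not in merged:
            klass = classify_taindel(cs, ce, junctions_by_scaffold.get(d.scaffold, []), tol=tol)
            merged[key] = TaIndel(d.scaffold, cs, ce, klass, read_count=0)
        merged[key].read_count += 1
    stats["reads_with_taindel"] = len(reads_with_taindel)
    out = sorted(merged.values(), key=lambda t: (t.scaffold, t.del_start, t.del_end))
    return out, stats


def normalize_taindels(taindel_read_count: int, mapped_read_count: int) -> float:
    """Reads with TA-indels per million mapped reads."""
    if mapped_read_count <= 0:
        raise ValueError("mapped read count must be > 0")
    return 1e6 * taindel_read_count / mapped_read_count


def taindel_length_histogram(taindels: Sequence[TaIndel]) -> pd.DataFrame:
    """Per-class counts by deletion length (one-TA convention)."""
    rows = [(t.length, t.klass, t.read_count) for t in taindels]
    if not rows:
        return pd.DataFrame(columns=["length", "klass", "count"])
    df = pd.DataFrame(rows, columns=["length", "klass", "count"])
    return (
        df.groupby(["length", "klass"], as_index=False)["count"].sum()
        .sort_values(["length", "klass"])
        .reset_index(drop=True)
    )
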
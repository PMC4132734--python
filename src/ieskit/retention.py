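"""Per-IES retention scores from split-junction read counting.

For every IES and every sample, reads that contain the IES sequence across
an IES end (IES+) and reads that span the macronuclear junction TA (IES-)
are counted, and the retention score is

    IRS = IES+ / (IES+ + IES-)

so a completely excised IES scores 0 and a completely retained IES scores
1.  Reads are only counted at IES ends/junctions (never by interior
coverage), avoiding length biases, and each read contributes at most one
count per IES.

The classifier operates on alignments against the MAC+IES reference by
default, where an excised-form junction read appears as a deletion spanning
the IES; it can also count IES- reads on MAC-space alignments where the
junction is a plain matched crossing.  ``compute_irs`` defaults to counting
retained-form reads at the *left* IES end only: the fragments that witness
the left end of a retained molecule are exactly the fragments that would
witness the junction had the molecule been excised, so the informative
reads of an IES are i.i.d. Bernoulli(rho) trials and IRS is an unbiased
estimator of the true retention fraction.  Counting both ends
(``end_policy="both"``) uses more reads but overweights the retained form
for long, well-covered IESs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome_io import IesAnnotation

IES_PLUS = "IES_plus"
IES_MINUS = "IES_minus"
UNINFORMATIVE = "uninformative"


@dataclass
class RetentionRecord:
    ies_id: str
    ies_plus: int
    ies_minus: int
    sample: str = ""

    @property
    def irs(self) -> float:
        n = self.ies_plus + self.ies_minus
        return self.ies_plus / n if n > 0 else float("nan")


def _matched_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    return [(s, e) for s, e in read.get_blocks()]


def _deletions(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    out = []
    pos = read.reference_start
    for op, n in read.cigartuples or []:
        if op in (0, 7, 8):  # M/=/X
            pos += n
        elif op == 2:  # D
            out.append((pos, pos + n))
            pos += n
        elif op == 3:  # N
            pos += n
    return out


def _covers(blocks: list[tuple[int, int]], lo: int, hi: int) -> bool:
    """True if one contiguous matched block covers [lo, hi)."""
    return any(s <= lo and e >= hi for s, e in blocks)


def _is_equivalent_deletion(
    seq: str | None, ds: int, de: int, start: int, end: int
) -> bool:
    """Whether deletion [ds, de) is shift-equivalent to [start, end)."""
    if de - ds != end - start:
        return False
    if (ds, de) == (start, end):
        return True
    if seq is None:
        return False
    s, e = ds, de
    step = 1 if start > ds else -1
    while (s, e) != (start, end):
        if step == 1:
            if e >= len(seq) or seq[s] != seq[e]:
                return False
            s += 1
            e += 1
        else:
            if s <= 0 or seq[s - 1] != seq[e - 1]:
                return False
            s -= 1
            e -= 1
    return True


def classify_read(
    read: pysam.AlignedSegment,
    annotation: IesAnnotation,
    min_anchor: int = 5,
    end_policy: str = "both",
    space: str = "mic",
    genome_seq: str | None = None,
) -> str:
    """Classify one read for one IES as IES+, IES- or uninformative.

    In MAC+IES space a read is IES+ if a contiguous matched block crosses an
    IES end with at least ``min_anchor`` aligned bases on both sides of the
    end (the inner bases lying in IES-exclusive sequence), and IES- if it
    carries a deletion shift-equivalent to the IES excision with at least
    ``min_anchor`` matched bases flanking the deletion.  In MAC space a read
    is IES- if a matched block crosses the junction TA with ``min_anchor``
    bases on both sides.  Reads wholly inside the IES interior, or not
    reaching any end, are uninformative.  ``min_anchor`` must be >= 3 so
    that the two shared junction-TA bases can never satisfy an inner anchor
    on their own.
    """
    if min_anchor < 3:
        raise ValueError("min_anchor must be >= 3")
    if end_policy not in ("both", "left", "right"):
        raise ValueError(f"unknown end_policy {end_policy!r}")
    a = annotation
    if space == "mac":
        if read.reference_name != a.mac_scaffold:
            return UNINFORMATIVE
        j = a.mac_junction
        blocks = _matched_blocks(read)
        if _covers(blocks, j - min_anchor, j + 2 + min_anchor):
            return IES_MINUS
        return UNINFORMATIVE
    if read.reference_name != a.scaffold:
        return UNINFORMATIVE
    blocks = _matched_blocks(read)
    # excised form: a deletion equivalent to removing [start, start+length)
    for ds, de in _deletions(read):
        if _is_equivalent_deletion(genome_seq, ds, de, a.start, a.start + a.length):
            left_ok = any(e == ds and e - s >= min_anchor for s, e in blocks)
            right_ok = any(s == de and e - s >= min_anchor for s, e in blocks)
            if left_ok and right_ok:
                return IES_MINUS
    # retained form: contiguous matched crossing of an IES end
    left = _covers(blocks, a.start - min_anchor, a.start + min_anchor)
    right = _covers(blocks, a.end - min_anchor, a.end + min_anchor)
    if end_policy == "left" and left:
        return IES_PLUS
    if end_policy == "right" and right:
        return IES_PLUS
    if end_policy == "both" and (left or right):
        return IES_PLUS
    return UNINFORMATIVE


def compute_irs(
    records: Iterable[pysam.AlignedSegment],
    annotations: Sequence[IesAnnotation],
    min_anchor: int = 5,
    end_policy: str = "left",
    space: str = "mic",
    genome: dict[str, str] | None = None,
    sample: str = "",
) -> pd.DataFrame:
    """Accumulate IES+/IES- counts over reads and compute per-IES IRS.

    Each read contributes at most one count per IES (a read crossing both
    ends of a short IES is a single IES+ count); a read informative for
    several distinct IESs counts once for each.  IESs with no informative
    reads get an undefined (NaN) score.

    Returns a DataFrame with columns ies_id, ies_plus, ies_minus, irs,
    coverage, sample.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    key = (lambda a: a.scaffold) if space == "mic" else (lambda a: a.mac_scaffold)
    for idx, a in enumerate(annotations):
        lo = a.start if space == "mic" else a.mac_junction
        hi = a.end if space == "mic" else a.mac_junction + 2
        trees.setdefault(key(a), IntervalTree()).addi(lo - 1, hi + 1, idx)

    plus = np.zeros(len(annotations), dtype=int)
    minus = np.zeros(len(annotations), dtype=int)
    for read in records:
        if read.is_unmapped or read.reference_name not in trees:
            continue
        seq = genome.get(read.reference_name) if genome else None
        span_lo, span_hi = read.reference_start, read.reference_end
        for hit in trees[read.reference_name].overlap(span_lo, span_hi):
            a = annotations[hit.data]
            label = classify_read(
                read, a, min_anchor=min_anchor, end_policy=end_policy,
                space=space, genome_seq=seq,
            )
            if label == IES_PLUS:
                plus[hit.data] += 1
            elif label == IES_MINUS:
                minus[hit.data] += 1

    n = plus + minus
    with np.errstate(invalid="ignore"):
        irs = np.where(n > 0, plus / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {
            "ies_id": [a.ies_id for a in annotations],
            "ies_plus": plus,
            "ies_minus": minus,
            "irs": irs,
            "coverage": n,
            "sample": sample,
        }
    )


def irs_histogram(
    records: pd.DataFrame | Sequence[float], bin_width: float = 0.02
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of defined IRS values over [0, 1].

    ``bin_width`` must divide 1 evenly; bins are left-closed with a
    right-closed final bin.  Returns (counts, bin_edges, n_undefined).
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 1 evenly")
    if isinstance(records, pd.DataFrame):
        values = records["irs"].to_numpy(dtype=float)
    else:
        values = np.asarray(list(records), dtype=float)
    undefined = int(np.isnan(values).sum())
    values = values[~np.isnan(values)]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return counts, edges, undefined
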
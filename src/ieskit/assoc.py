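"""Correlation analyses among IES retention scores.

Three pair families are analysed: scores of the same IESs across
knockdown samples, scores of sequence-identical IESs at distinct loci
(a handle on the genetic component of retention), and scores of adjacent
IESs on the same scaffold (a handle on regional effects).  Pairs of
identical IESs are only usable when their flanking sequences differ within
a read length of the boundaries, otherwise their boundary-crossing reads
are indistinguishable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import IesAnnotation


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson"):
    """Correlation coefficient with two-tailed p-value; returns (r, p, n)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), int(x.size)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), int(x.size)


def find_identical_pairs(
    annotations: Sequence[IesAnnotation],
    mic_genome: dict[str, str],
    scores: pd.DataFrame | None = None,
    flank_window: int = 100,
    min_scaffold_len: int = 0,
    exclude_zero: bool = True,
    control_scores: pd.DataFrame | None = None,
    min_score_vs_control: float | None = None,
) -> pd.DataFrame:
    """All unordered pairs of sequence-identical IESs at distinct loci.

    Pairs whose flanking sequence (``flank_window`` bp on each side, about a
    read length) is also identical are excluded as indistinguishable.
    Optional filters mirror common practice: scaffolds must be at least
    ``min_scaffold_len`` long, IESs with score 0 may be excluded, and a
    score-versus-control ratio filter (score >= ratio * control score) can
    be applied when control scores are given.

    Returns a DataFrame (ies_a, ies_b, score_a, score_b, same_scaffold,
    distance) where distance is the MAC+IES gap for same-scaffold pairs and
    NaN otherwise.
    """
    score_map = None
    if scores is not None:
        score_map = scores.set_index("ies_id")["irs"]
    control_map = None
    if control_scores is not None:
        control_map = control_scores.set_index("ies_id")["irs"]

    def usable(a: IesAnnotation) -> bool:
        if len(mic_genome.get(a.scaffold, "")) < min_scaffold_len:
            return False
        if score_map is not None:
            s = score_map.get(a.ies_id, np.nan)
            if np.isnan(s):
                return False
            if exclude_zero and s == 0:
                return False
            if (
                min_score_vs_control is not None
                and control_map is not None
                and not (s >= min_score_vs_control * control_map.get(a.ies_id, 0.0))
            ):
                return False
        return True

    groups: dict[str, list[IesAnnotation]] = {}
    for a in annotations:
        if usable(a):
            groups.setdefault(a.sequence, []).append(a)

    def flanks(a: IesAnnotation) -> tuple[str, str]:
        seq = mic_genome[a.scaffold]
        return (
            seq[max(0, a.start - flank_window):a.start],
            seq[a.end:a.end + flank_window],
        )

    rows = []
    for members in groups.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if flanks(a) == flanks(b):
                    continue  # indistinguishable IES+ reads
                same = a.scaffold == b.scaffold
                dist = abs(a.start - b.start) - (a.length + 2) if same else np.nan
                rows.append(
                    (
                        a.ies_id,
                        b.ies_id,
                        score_map.get(a.ies_id, np.nan) if score_map is not None else np.nan,
                        score_map.get(b.ies_id, np.nan) if score_map is not None else np.nan,
                        same,
                        dist,
                    )
                )
    return pd.DataFrame(
        rows, columns=["ies_a", "ies_b", "score_a", "score_b", "same_scaffold", "distance"]
    )


def adjacent_pairs(
    annotations: Sequence[IesAnnotation],
    scores: pd.DataFrame,
    max_gap: float = np.inf,
    n_intervening: int = 0,
) -> pd.DataFrame:
    """Pairs of IESs separated by exactly ``n_intervening`` IESs.

    ``n_intervening`` 0 means immediate neighbors.  The genomic distance is
    the MAC+IES gap between the two IES intervals and must be <= max_gap.
    Undefined scores drop the pair.
    """
    score_map = scores.set_index("ies_id")["irs"]
    by_scaffold: dict[str, list[IesAnnotation]] = {}
    for a in annotations:
        by_scaffold.setdefault(a.scaffold, []).append(a)
    rows = []
    step = n_intervening + 1
    for scaffold, anns in by_scaffold.items():
        anns.sort(key=lambda a: a.start)
        for i in range(len(anns) - step):
            a, b = anns[i], anns[i + step]
            gap = b.start - a.end
            if gap > max_gap:
                continue
            sa = score_map.get(a.ies_id, np.nan)
            sb = score_map.get(b.ies_id, np.nan)
            if np.isnan(sa) or np.isnan(sb):
                continue
            rows.append((a.ies_id, b.ies_id, sa, sb, scaffold, gap, n_intervening))
    return pd.DataFrame(
        rows,
        columns=["ies_a", "ies_b", "score_a", "score_b", "scaffold", "distance", "n_intervening"],
    )


def random_pairs(
    annotations: Sequence[IesAnnotation],
    scores: pd.DataFrame,
    n_pairs: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-IES pair baseline for the null of no spatial association."""
    rng = np.random.default_rng(seed)
    score_map = scores.dropna(subset=["irs"]).set_index("ies_id")["irs"]
    ids = [a.ies_id for a in annotations if a.ies_id in score_map.index]
    rows = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(ids), size=2, replace=False)
        rows.append((ids[i], ids[j], score_map[ids[i]], score_map[ids[j]]))
    return pd.DataFrame(rows, columns=["ies_a", "ies_b", "score_a", "score_b"])
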
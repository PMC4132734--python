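"""Per-IES small-RNA densities by size class, versus retention scores.

scnRNAs (25 nt) are produced genome-wide and overlap IES boundaries;
iesRNAs (mode 27 nt) match strictly within IESs.  Densities are reads per
base of IES, normalized per million 15-35 nt sRNAs mapped to either
reference.  Binned-median profiles over retention-score intervals of 0.01,
EWMA-smoothed and trimmed to two standard deviations of the mean IRS,
reproduce the characteristic flat scnRNA and retention-increasing iesRNA
shapes.
"""

from __future__ import annotations

import bisect
from typing import Sequence

import numpy as np
import pandas as pd

from .end_bases import ewma
from .genome_io import IesAnnotation


def per_ies_density(
    assigned: pd.DataFrame,
    annotations: Sequence[IesAnnotation],
    size_class: int,
    normalization_total: int,
    policy: str | None = None,
) -> pd.DataFrame:
    """Count assigned MAC+IES-space sRNA reads of one size class per IES.

    ``assigned`` is the output of two-stage assignment (columns read,
    space, scaffold, start, length).  A read counts toward an IES either if
    its span is fully contained in the IES interval (policy "contained",
    the iesRNA-like default for classes != 25 nt) or if it overlaps the
    interval by at least one base (policy "overlap", the boundary-spanning
    scnRNA-like default for the 25 nt class).

    Density is count / IES length (one-TA bp); normalized density divides
    by (normalization_total / 1e6).
    """
    if policy is None:
        policy = "overlap" if size_class == 25 else "contained"
    if policy not in ("overlap", "contained"):
        raise ValueError(f"unknown policy {policy!r}")
    if normalization_total <= 0:
        raise ValueError("normalization_total must be > 0")
    sub = assigned[(assigned["space"] == "mic") & (assigned["length"] == size_class)]
    by_scaffold: dict[str, list[IesAnnotation]] = {}
    for a in annotations:
        by_scaffold.setdefault(a.scaffold, []).append(a)
    for v in by_scaffold.values():
        v.sort(key=lambda a: a.start)
    starts = {k: [a.start for a in v] for k, v in by_scaffold.items()}

    counts = {a.ies_id: 0 for a in annotations}
    for scaffold, grp in sub.groupby("scaffold"):
        anns = by_scaffold.get(scaffold)
        if not anns:
            continue
        st = starts[scaffold]
        for s, ln in zip(grp["start"].to_numpy(), grp["length"].to_numpy()):
            e = s + ln
            i = bisect.bisect_right(st, s) - 1
            for k in (i, i + 1):
                if 0 <= k < len(anns):
                    a = anns[k]
                    if policy == "contained":
                        hit = a.start <= s and e <= a.end
                    else:
                        hit = s < a.end and a.start < e
                    if hit:
                        counts[a.ies_id] += 1
                        break
    scale = normalization_total / 1e6
    rows = []
    for a in annotations:
        c = counts[a.ies_id]
        density = c / a.length
        rows.append((a.ies_id, size_class, c, density, density / scale))
    return pd.DataFrame(
        rows, columns=["ies_id", "size_class", "count", "density", "norm_density"]
    )


def density_vs_irs(
    densities: pd.DataFrame,
    irs: pd.DataFrame,
    bin_width: float = 0.01,
    stat: str = "median",
    ewma_span: float = 5,
    sd_trim: float = 2.0,
    outlier_cap: float | None = 0.4,
    value_col: str = "density",
) -> pd.DataFrame:
    """Binned statistic of per-IES density over retention-score intervals.

    The per-bin statistic (median by default) is EWMA-smoothed over bins;
    ``in_trim`` marks bins within ``sd_trim`` standard deviations of the
    mean IRS.  Densities above ``outlier_cap`` are excluded from the binned
    profile (they remain in the per-IES table upstream).  Empty bins are
    absent from the output.
    """
    if densities.empty or irs.empty:
        return pd.DataFrame(columns=["bin", "bin_center", "value", "smoothed", "n", "in_trim"])
    merged = densities.merge(irs[["ies_id", "irs"]], on="ies_id").dropna(subset=["irs"])
    if merged.empty:
        return pd.DataFrame(columns=["bin", "bin_center", "value", "smoothed", "n", "in_trim"])
    if outlier_cap is not None:
        merged = merged[merged[value_col] <= outlier_cap]
    vals = merged["irs"].to_numpy()
    mean, sd = vals.mean(), vals.std()
    n_bins = int(round(1 / bin_width))
    merged = merged.assign(bin=np.minimum((vals / bin_width).astype(int), n_bins - 1))
    agg = merged.groupby("bin")[value_col].agg(stat)
    n = merged.groupby("bin")[value_col].size()
    out = pd.DataFrame(
        {
            "bin": agg.index,
            "bin_center": (agg.index.astype(float) + 0.5) * bin_width,
            "value": agg.to_numpy(),
            "n": n.to_numpy(),
        }
    ).reset_index(drop=True)
    out["smoothed"] = ewma(out["value"].to_numpy(), ewma_span)
    out["in_trim"] = (out["bin_center"] >= mean - sd_trim * sd) & (
        out["bin_center"] <= mean + sd_trim * sd
    )
    return out[["bin", "bin_center", "value", "smoothed", "n", "in_trim"]]
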
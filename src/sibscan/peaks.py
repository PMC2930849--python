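"""Linkage peaks and -1/-2 LOD support intervals."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class Peak:
    chrom: object
    cm: float
    marker: str
    lod: float
    index: int                      # row in the scan frame
    support_1lod: tuple             # (left cm, right cm, left marker, right marker)
    support_2lod: tuple


def _support(cm, lod, markers, i, drop):
    """Walk outward until the LOD falls ``drop`` below the peak (or the
    chromosome ends); returns the first positions at or past the drop."""
    target = lod[i] - drop
    left = i
    while left > 0 and lod[left] > target:
        left -= 1
    right = i
    while right < len(lod) - 1 and lod[right] > target:
        right += 1
    return (float(cm[left]), float(cm[right]), markers[left], markers[right])


def find_peaks(curve: pd.DataFrame, min_lod: float = 3.0,
               lod_col: str = "lod") -> list:
    """Local maxima of a per-position scan frame with support intervals.

    A peak is a position whose LOD is >= both neighbours (ties broken by
    keeping the first of a flat run) and >= ``min_lod``.  The -1 and -2
    LOD support intervals are found by walking outward until the score
    drops by 1 (resp. 2) or the chromosome ends; the -1 interval is
    nested inside the -2 interval by construction.
    """
    out = []
    for chrom, grp in curve.groupby("chrom", sort=False):
        lod = grp[lod_col].to_numpy(dtype=float)
        cm = grp["cm"].to_numpy(dtype=float)
        markers = grp["marker"].to_numpy()
        rows = grp.index.to_numpy()
        for i in range(len(lod)):
            if lod[i] < min_lod:
                continue
            if i > 0 and lod[i - 1] >= lod[i]:
                continue
            if i < len(lod) - 1 and lod[i + 1] > lod[i]:
                continue
            out.append(Peak(
                chrom=chrom, cm=float(cm[i]), marker=str(markers[i]),
                lod=float(lod[i]), index=int(rows[i]),
                support_1lod=_support(cm, lod, markers, i, 1.0),
                support_2lod=_support(cm, lod, markers, i, 2.0),
            ))
    out.sort(key=lambda p: -p.lod)
    return out


def local_maxima_above(curve: pd.DataFrame, floor: float,
                       lod_col: str = "lod") -> pd.DataFrame:
    """All local maxima with LOD >= floor; used for null-replicate peaks."""
    rows = []
    for p in find_peaks(curve, min_lod=floor, lod_col=lod_col):
        rows.append({"chrom": p.chrom, "cm": p.cm, "lod": p.lod,
                     "marker": p.marker})
    return pd.DataFrame(rows, columns=["chrom", "cm", "lod", "marker"])
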
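"""Pooled allele-frequency LOD scan and QTL support-interval calling.

The association statistic is the absolute log10 odds ratio of a marker's
allele frequencies in two segregant pools, computed from read counts with the
Haldane-Anscombe 1/2 continuity correction:

    LOD = | log10( ((a_alt + 1/2) / (a_ref + 1/2)) /
                   ((b_alt + 1/2) / (b_ref + 1/2)) ) |

The correction keeps every site finite (complete selection gives extreme but
finite scores) and the absolute value makes the statistic symmetric in the
two pools and under a simultaneous ref/alt swap. Peaks above a fixed LOD
cutoff (default 3) are reported with 1-LOD support intervals: the interval
ends at the first flanking marker on each side whose LOD has dropped at
least ``drop`` units below the peak, clamped to the chromosome's marker span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QtlInterval",
    "lod_score",
    "scan",
    "call_qtl",
    "common_region",
    "compare_all_pools",
    "intervals_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QtlInterval:
    """A called QTL peak with its 1-LOD support interval (1-based closed)."""

    chrom: str
    peak_pos: int
    peak_lod: float
    start: int
    end: int
    pools: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if not self.start <= self.peak_pos <= self.end:
            raise ValueError("peak position must lie inside the interval")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "QtlInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def lod_score(a_ref, a_alt, b_ref, b_alt):
    """Absolute log10 continuity-corrected odds ratio of two pools' counts.

    Accepts scalars or arrays; all depths must be >= 0 with positive total
    depth per pool (zero-depth sites are the scan's job to skip).
    """
    a_ref = np.asarray(a_ref, dtype=float)
    a_alt = np.asarray(a_alt, dtype=float)
    b_ref = np.asarray(b_ref, dtype=float)
    b_alt = np.asarray(b_alt, dtype=float)
    if np.any(a_ref + a_alt <= 0) or np.any(b_ref + b_alt <= 0):
        raise ValueError("each pool needs positive total depth")
    odds_a = (a_alt + 0.5) / (a_ref + 0.5)
    odds_b = (b_alt + 0.5) / (b_ref + 0.5)
    out = np.abs(np.log10(odds_a / odds_b))
    return float(out) if out.ndim == 0 else out


def scan(
    het_sites: pd.DataFrame,
    pool_a: pd.DataFrame,
    pool_b: pd.DataFrame,
    smooth_window: int = 0,
) -> pd.DataFrame:
    """Per-site LOD track for one pool pair over the heterozygous marker map.

    The three tables are inner-joined on (chrom, pos); sites with zero total
    depth in either pool are skipped (count in ``attrs["n_skipped"]``).
    ``smooth_window`` > 1 applies a per-chromosome rolling median over that
    many sites (off by default: the statistic is reported per variant).

    Returns a DataFrame ``chrom, pos, freq_a, freq_b, lod``.
    """
    base = het_sites[["chrom", "pos"]]
    a = pool_a[["chrom", "pos", "ref_depth", "alt_depth"]].rename(
        columns={"ref_depth": "a_ref", "alt_depth": "a_alt"}
    )
    b = pool_b[["chrom", "pos", "ref_depth", "alt_depth"]].rename(
        columns={"ref_depth": "b_ref", "alt_depth": "b_alt"}
    )
    merged = base.merge(a, on=["chrom", "pos"]).merge(b, on=["chrom", "pos"])
    if len(merged) == 0:
        raise ValueError("no shared sites between pools and marker set")
    dp_a = merged["a_ref"] + merged["a_alt"]
    dp_b = merged["b_ref"] + merged["b_alt"]
    ok = (dp_a > 0) & (dp_b > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("skipped %d zero-depth sites", n_skipped)
    merged = merged.loc[ok].reset_index(drop=True)
    out = merged[["chrom", "pos"]].copy()
    out["freq_a"] = merged["a_alt"] / (merged["a_ref"] + merged["a_alt"])
    out["freq_b"] = merged["b_alt"] / (merged["b_ref"] + merged["b_alt"])
    out["lod"] = lod_score(merged["a_ref"], merged["a_alt"], merged["b_ref"], merged["b_alt"])
    if smooth_window and smooth_window > 1:
        out["lod"] = (
            out.groupby("chrom", sort=False)["lod"]
            .transform(lambda s: s.rolling(smooth_window, center=True, min_periods=1).median())
        )
    out.attrs["pools"] = (
        pool_a.attrs.get("pool", "A"),
        pool_b.attrs.get("pool", "B"),
    )
    out.attrs["n_skipped"] = n_skipped
    return out


def call_qtl(track: pd.DataFrame, threshold: float = 3.0, drop: float = 1.0) -> list[QtlInterval]:
    """Call QTL peaks above ``threshold`` with ``drop``-LOD support intervals.

    Peaks are local maxima of the per-site LOD exceeding the threshold
    (leftmost marker wins among ties). The support interval runs to the first
    marker on each side whose LOD is at least ``drop`` units below the peak;
    if the score never drops, the interval extends to the chromosome's
    terminal marker. Overlapping intervals on one chromosome are merged,
    keeping the higher peak.
    """
    if len(track) == 0:
        raise ValueError("empty LOD track")
    pools = tuple(track.attrs.get("pools", ("A", "B")))
    intervals: list[QtlInterval] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy()
        lod = sub["lod"].to_numpy(dtype=float)
        # candidate peaks, highest first; leftmost first among equals
        cand = [i for i in np.argsort(-lod, kind="stable") if lod[i] > threshold]
        claimed: list[tuple[int, int, QtlInterval]] = []
        for i in cand:
            if any(lo <= i <= hi for lo, hi, _ in claimed):
                continue
            lo = i
            while lo > 0 and lod[lo] > lod[i] - drop:
                lo -= 1
            if lod[lo] > lod[i] - drop:  # hit chromosome start without dropping
                lo = 0
            hi = i
            while hi < len(lod) - 1 and lod[hi] > lod[i] - drop:
                hi += 1
            merged = False
            itv = QtlInterval(
                chrom=str(chrom),
                peak_pos=int(pos[i]),
                peak_lod=float(lod[i]),
                start=int(pos[lo]),
                end=int(pos[hi]),
                pools=pools,
            )
            # merge with any overlapping, already-claimed (higher-peak) interval
            for lo2, hi2, other in claimed:
                if not (hi < lo2 or hi2 < lo):
                    merged = True
                    break
            if not merged:
                claimed.append((lo, hi, itv))
        intervals.extend(itv for _, _, itv in claimed)
    intervals.sort(key=lambda q: (track["chrom"].drop_duplicates().tolist().index(q.chrom), q.start))
    return intervals


def common_region(
    intervals_a: list[QtlInterval], intervals_b: list[QtlInterval]
) -> pd.DataFrame:
    """Pairwise intersections of overlapping intervals from two comparisons.

    Commutative; each intersection is contained in both inputs; disjoint
    pairs contribute nothing. Returns a DataFrame ``chrom, start, end``.
    """
    rows = []
    for a in intervals_a:
        for b in intervals_b:
            if a.overlaps(b):
                rows.append(
                    {
                        "chrom": a.chrom,
                        "start": max(a.start, b.start),
                        "end": min(a.end, b.end),
                    }
                )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out.drop_duplicates().reset_index(drop=True)


def intervals_to_frame(intervals: list[QtlInterval]) -> pd.DataFrame:
    """Tabulate called intervals (1-based closed) for TSV/BED output."""
    return pd.DataFrame(
        [
            {
                "chrom": q.chrom,
                "start": q.start,
                "end": q.end,
                "peak_pos": q.peak_pos,
                "peak_lod": round(q.peak_lod, 4),
                "name": f"{q.pools[0]}_vs_{q.pools[1]}",
            }
            for q in intervals
        ],
        columns=["chrom", "start", "end", "peak_pos", "peak_lod", "name"],
    )


def compare_all_pools(
    het_sites: pd.DataFrame,
    pools: dict[str, pd.DataFrame],
    threshold: float = 3.0,
    drop: float = 1.0,
    sensitive: str = "Sensitive",
    resistant: tuple[str, str] = ("ResistantParental", "ResistantEvolved"),
) -> dict:
    """All three pairwise scans plus the cross-comparison common region.

    ``pools`` maps phenotype-class name to its pooled counts; the three
    expected classes are the sensitive pool and the two resistant pools. The
    common region is the intersection of the QTL intervals called in the two
    sensitive-vs-resistant comparisons.

    Returns ``{"tracks": {pair: track}, "intervals": {pair: [QtlInterval]},
    "common": DataFrame}`` with pair keys like ``"Sensitive|ResistantParental"``.
    """
    required = [sensitive, *resistant]
    for name in required:
        if name not in pools:
            raise ValueError(f"missing pool: {name!r}")
    pairs = [
        (sensitive, resistant[0]),
        (sensitive, resistant[1]),
        (resistant[0], resistant[1]),
    ]
    tracks: dict[str, pd.DataFrame] = {}
    intervals: dict[str, list[QtlInterval]] = {}
    for a, b in pairs:
        key = f"{a}|{b}"
        tr = scan(het_sites, pools[a], pools[b])
        tr.attrs["pools"] = (a, b)
        tracks[key] = tr
        intervals[key] = call_qtl(tr, threshold=threshold, drop=drop)
    common = common_region(
        intervals[f"{sensitive}|{resistant[0]}"],
        intervals[f"{sensitive}|{resistant[1]}"],
    )
    return {"tracks": tracks, "intervals": intervals, "common": common}
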
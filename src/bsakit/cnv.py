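"""Read-depth copy-number analysis.

Averages sequencing coverage in fixed 1000-bp tiling windows, normalizes each
chromosome's median window depth by the genome-wide median (medians, not
means: robust to local CNV), and flags chromosomes whose depth ratio sits on
a non-baseline copy-number grid point. In a diploid, a trisomic chromosome
shows a 3:2 = 1.5-fold depth ratio; a monosomic one 0.5.

Windows are non-overlapping tiles by default; a smaller ``stride`` gives
sliding windows. Chromosome-level calls are the primary output; runs of
consecutive outlier windows are additionally reported as putative segmental
CNVs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AneuploidyCall",
    "read_depth_table",
    "window_depth",
    "chromosome_ratios",
    "call_aneuploidy",
    "segmental_calls",
]


@dataclass(frozen=True)
class AneuploidyCall:
    """Per-chromosome copy-number assessment.

    ``depth_ratio`` is chromosome median window depth over the genome-wide
    median; ``copy_estimate`` is the nearest integer copy number on the
    baseline-ploidy grid; ``flagged`` marks a call different from baseline.
    """

    chrom: str
    depth_ratio: float
    copy_estimate: int
    flagged: bool


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Read a depth track: bedGraph (chrom, start, end, depth; 0-based half-open)
    or 3-column per-base TSV (chrom, pos, depth; 1-based).

    Returns per-base records normalized to columns ``chrom, pos, depth``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 4:
        rows = []
        for chrom, start, end, depth in df.iloc[:, :4].itertuples(index=False):
            pos = np.arange(int(start) + 1, int(end) + 1)
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "depth": float(depth)}))
        return pd.concat(rows, ignore_index=True)
    df = df.iloc[:, :3]
    df.columns = ["chrom", "pos", "depth"]
    return df


def window_depth(depth: pd.DataFrame, window: int = 1000, stride: int | None = None) -> pd.DataFrame:
    """Average per-base depth in windows of ``window`` bp.

    ``depth`` has columns ``chrom, pos, depth`` (1-based, sorted by position
    within chromosome; unsorted input raises). Positions absent from the
    table count as zero coverage. Each window mean is the summed depth over
    the window divided by the window's true length; the final partial window
    is normalized by its actual length (to the last covered base). The
    default ``stride`` equals ``window`` (non-overlapping tiles); a smaller
    stride gives sliding windows.

    Returns ``chrom, start, end, mean_depth`` (1-based closed).
    """
    required = {"chrom", "pos", "depth"}
    if not required.issubset(depth.columns):
        raise ValueError(f"depth table needs columns {sorted(required)}")
    stride = window if stride is None else stride
    if stride < 1 or window < 1:
        raise ValueError("window and stride must be >= 1")
    rows = []
    for chrom, sub in depth.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"depth records not sorted by position on {chrom}")
        d = sub["depth"].to_numpy(dtype=float)
        chrom_len = int(pos[-1])
        per_base = np.zeros(chrom_len)
        per_base[pos - 1] = d
        csum = np.concatenate([[0.0], np.cumsum(per_base)])
        starts = np.arange(1, chrom_len + 1, stride)
        ends = np.minimum(starts + window - 1, chrom_len)
        sums = csum[ends] - csum[starts - 1]
        lens = ends - starts + 1
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "mean_depth": sums / lens}
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["window"] = window
    return out


def chromosome_ratios(windows: pd.DataFrame) -> pd.Series:
    """Median window depth per chromosome over the genome-wide median.

    Scale-invariant: multiplying all depths by a constant leaves ratios
    unchanged. Raises when the genome-wide median is zero.
    """
    genome_median = float(windows["mean_depth"].median())
    if genome_median == 0:
        raise ValueError("genome-wide median window depth is zero")
    ratios = windows.groupby("chrom", sort=False)["mean_depth"].median() / genome_median
    ratios.name = "depth_ratio"
    return ratios


def call_aneuploidy(
    ratios: pd.Series, baseline_ploidy: int = 2, tolerance: float = 0.15
) -> list[AneuploidyCall]:
    """Flag chromosomes whose depth ratio matches a non-baseline copy number.

    A chromosome is flagged when its ratio lies within ``tolerance`` of
    k / baseline_ploidy for the nearest integer k != baseline_ploidy
    (e.g. ratio 1.48 in a diploid -> trisomy, copy 3; 0.55 -> monosomy).
    Unflagged chromosomes are reported with the baseline copy number.
    """
    calls = []
    for chrom, ratio in ratios.items():
        k = int(round(ratio * baseline_ploidy))
        flagged = k != baseline_ploidy and abs(ratio - k / baseline_ploidy) <= tolerance
        calls.append(
            AneuploidyCall(
                chrom=str(chrom),
                depth_ratio=float(ratio),
                copy_estimate=k if flagged else baseline_ploidy,
                flagged=flagged,
            )
        )
    return calls


def segmental_calls(
    windows: pd.DataFrame,
    baseline_ploidy: int = 2,
    tolerance: float = 0.15,
    min_windows: int = 10,
) -> pd.DataFrame:
    """Runs of >= ``min_windows`` consecutive windows off the baseline band.

    A coarse segmental-CNV report complementing the chromosome-level calls:
    windows whose depth / genome-median falls outside 1 +/- tolerance are
    grouped into maximal consecutive runs per chromosome.

    Returns ``chrom, start, end, n_windows, mean_ratio``.
    """
    genome_median = float(windows["mean_depth"].median())
    if genome_median == 0:
        raise ValueError("genome-wide median window depth is zero")
    rows = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        ratio = sub["mean_depth"].to_numpy() / genome_median
        off = np.abs(ratio - 1.0) > tolerance
        start_idx = None
        for i, flag in enumerate(np.append(off, False)):
            if flag and start_idx is None:
                start_idx = i
            elif not flag and start_idx is not None:
                if i - start_idx >= min_windows:
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": int(sub["start"].iloc[start_idx]),
                            "end": int(sub["end"].iloc[i - 1]),
                            "n_windows": i - start_idx,
                            "mean_ratio": float(ratio[start_idx:i].mean()),
                        }
                    )
                start_idx = None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows", "mean_ratio"])
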
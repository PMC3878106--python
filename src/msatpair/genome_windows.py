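"""Genomic windows: tiling chromosomes, counting rMP / mSD midpoints per
window, and quantifying the "rich-gets-richer" co-aggregation of segmental
duplications with repetitive microsatellite pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .msd_call import MSDFamily
from .rmp_core import RMPFamily
from .rmp_stats import spearman


@dataclass(frozen=True)
class GenomicWindow:
    """Left-closed right-open interval [start, end) with feature counts."""

    seq_id: str
    start: int
    end: int
    rmp_count: int = 0
    msd_count: int = 0


@dataclass(frozen=True)
class WindowCorrelation:
    rho: float
    p: float
    r2: float


def make_windows(
    seq_lengths: Mapping[str, int],
    breakpoints: Sequence[int] | None = None,
    width: int | None = None,
) -> list[GenomicWindow]:
    """Tile each sequence into windows.

    Either ``breakpoints`` (strictly increasing interior edges, shared by all
    sequences; the last window absorbs the remainder and edges at or beyond
    the sequence length are dropped) or a uniform ``width`` (full tiles, the
    final partial tile merged into the last window) must be given.
    """
    if (breakpoints is None) == (width is None):
        raise ValueError("give exactly one of breakpoints or width")
    windows: list[GenomicWindow] = []
    for seq_id, length in seq_lengths.items():
        if breakpoints is not None:
            bps = [int(b) for b in breakpoints]
            if any(a >= b for a, b in zip(bps, bps[1:])) or (bps and bps[0] <= 0):
                raise ValueError("breakpoints must be strictly increasing and > 0")
            edges = [0] + [b for b in bps if b < length] + [length]
        else:
            if width <= 0:
                raise ValueError("width must be > 0")
            n_full = max(1, length // width)
            edges = [i * width for i in range(n_full)] + [length]
        for a, b in zip(edges, edges[1:]):
            windows.append(GenomicWindow(seq_id, a, b))
    return windows


def count_in_windows(
    midpoints: Iterable[tuple[str, int]], windows: Sequence[GenomicWindow]
) -> np.ndarray:
    """Counts aligned with ``windows``; each midpoint lands in exactly one
    window by the half-open rule (a point on a boundary goes right)."""
    by_seq: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_seq.setdefault(w.seq_id, []).append(i)
    counts = np.zeros(len(windows), dtype=np.int64)
    starts: dict[str, tuple[np.ndarray, list[int]]] = {}
    for seq_id, idxs in by_seq.items():
        idxs.sort(key=lambda i: windows[i].start)
        starts[seq_id] = (np.array([windows[i].start for i in idxs]), idxs)
    for seq_id, pos in midpoints:
        if seq_id not in starts:
            continue
        arr, idxs = starts[seq_id]
        j = int(np.searchsorted(arr, pos, side="right")) - 1
        if j < 0 or pos >= windows[idxs[j]].end:
            raise ValueError(f"midpoint {seq_id}:{pos} outside window range")
        counts[idxs[j]] += 1
    return counts


def family_midpoints(families: Sequence[RMPFamily]) -> list[tuple[str, int]]:
    return [(m.seq_id, m.midpoint) for f in families for m in f.members]


def msd_midpoints(msds: Sequence[MSDFamily]) -> list[tuple[str, int]]:
    return [(m.seq_id, m.midpoint) for f in msds for m in f.members]


def tabulate_windows(
    seq_lengths: Mapping[str, int],
    families: Sequence[RMPFamily],
    msds: Sequence[MSDFamily],
    breakpoints: Sequence[int] | None = None,
    width: int | None = None,
) -> list[GenomicWindow]:
    """Windows with rMP and mSD member-midpoint counts filled in."""
    windows = make_windows(seq_lengths, breakpoints, width)
    rmp = count_in_windows(family_midpoints(families), windows)
    msd = count_in_windows(msd_midpoints(msds), windows)
    return [
        replace(w, rmp_count=int(r), msd_count=int(s))
        for w, r, s in zip(windows, rmp, msd)
    ]


def window_correlation(
    windows: Sequence[GenomicWindow], drop_empty: bool = False
) -> WindowCorrelation:
    """Spearman rho/p of mSD vs rMP counts across windows, plus the squared
    Pearson correlation (r^2 of the least-squares linear fit).

    Windows with zero rMPs are retained by default; ``drop_empty`` removes
    them before the test.  Degenerate constant vectors give r2 = 0 and
    rho = nan.
    """
    x = np.array([w.rmp_count for w in windows], dtype=float)
    y = np.array([w.msd_count for w in windows], dtype=float)
    if drop_empty:
        keep = x > 0
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 windows")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return WindowCorrelation(float("nan"), float("nan"), 0.0)
    rho, p = spearman(x, y)
    r, _ = stats.pearsonr(x, y)
    return WindowCorrelation(rho, p, float(r * r))


def write_window_table(windows: Sequence[GenomicWindow], path: str | Path) -> None:
    pd.DataFrame(
        [(w.seq_id, w.start, w.end, w.rmp_count, w.msd_count) for w in windows],
        columns=["seq_id", "start", "end", "rmp", "msd"],
    ).to_csv(path, sep="\t", index=False)
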
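"""Sliding-window grid and per-window aggregation.

Windows are 0-based half-open intervals of fixed size (default 100 kb)
anchored at coordinate 0 on a fixed step grid (default 25 kb), so
consecutive windows overlap. The final window of a chromosome may extend
past its end; SNPs beyond the end cannot exist, so no padding is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

WINDOW_SIZE = 100_000
STEP = 25_000
MIN_SNPS = 30


@dataclass(frozen=True)
class GenomicWindow:
    """One window: 0-based half-open [start, start + window_size)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ConfigError(f"invalid window {self.chrom}:{self.start}-{self.end}")

    def contains(self, pos: int) -> bool:
        """Whether a 1-based position falls in this window."""
        return self.start <= pos - 1 < self.end


def make_windows(
    chrom_lengths: Mapping[str, int],
    window_size: int = WINDOW_SIZE,
    step: int = STEP,
) -> pd.DataFrame:
    """Enumerate the window grid as a DataFrame (chrom, start, end).

    Windows start at 0, step, 2*step, ... while start < chromosome length.
    ``window_size`` must be a positive multiple of ``step``.
    """
    if step <= 0 or window_size <= 0:
        raise ConfigError("window_size and step must be > 0")
    if window_size % step != 0:
        raise ConfigError(
            f"window_size {window_size} is not a multiple of step {step}"
        )
    frames = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ConfigError(f"chromosome {chrom}: length must be > 0")
        starts = np.arange(0, length, step, dtype=np.int64)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + window_size}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def window_aggregate(
    windows: pd.DataFrame,
    site_chrom: np.ndarray,
    site_pos: np.ndarray,
    site_values: np.ndarray,
    window_size: int = WINDOW_SIZE,
    step: int = STEP,
) -> tuple[np.ndarray, np.ndarray]:
    """Count and sum per-SNP values over every window.

    ``windows`` must come from :func:`make_windows` with the same
    ``window_size``/``step`` (rows contiguous and in grid order per
    chromosome). A SNP at 1-based position p belongs to every window whose
    0-based start s satisfies s <= p-1 < s + window_size — at most
    window_size/step of them. Returns (n_snps, value_sum) aligned to
    ``windows`` rows.
    """
    n_snps = np.zeros(len(windows), dtype=np.int64)
    sums = np.zeros(len(windows), dtype=np.float64)
    if len(windows) == 0 or len(site_pos) == 0:
        return n_snps, sums
    k_max = window_size // step
    values = np.asarray(site_values, dtype=float)
    row0 = 0
    for chrom, grp in windows.groupby("chrom", sort=False):
        n_win = len(grp)
        sel = site_chrom == chrom
        if sel.any():
            p0 = site_pos[sel] - 1
            v = values[sel]
            w_last = p0 // step
            for off in range(k_max):
                w = w_last - off
                ok = (w >= 0) & (w < n_win)
                np.add.at(n_snps, row0 + w[ok], 1)
                np.add.at(sums, row0 + w[ok], v[ok])
        row0 += n_win
    return n_snps, sums


def window_mean(
    windows: pd.DataFrame,
    site_chrom: np.ndarray,
    site_pos: np.ndarray,
    site_values: np.ndarray,
    window_size: int = WINDOW_SIZE,
    step: int = STEP,
    min_snps: int = MIN_SNPS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window arithmetic mean of per-SNP values.

    Windows holding fewer than ``min_snps`` SNPs are masked (NaN value);
    masked windows are excluded from any later Z-transformation. Returns
    (n_snps, mean) aligned to ``windows`` rows.
    """
    n, s = window_aggregate(
        windows, site_chrom, site_pos, site_values, window_size, step
    )
    with np.errstate(invalid="ignore"):
        mean = np.where(n >= min_snps, s / np.maximum(n, 1), np.nan)
    return n, mean
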
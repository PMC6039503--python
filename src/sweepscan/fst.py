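"""Per-SNP pairwise F_ST and its sliding-window aggregation.

The statistic is the two-population "weighted" F_ST computed per SNP from
pooled allele read frequencies p1 and p2:

    p_bar = (p1 + p2) / 2
    s2    = ((p1 - p_bar)^2 + (p2 - p_bar)^2) / (r - 1)   with r = 2
          = (p1 - p2)^2 / 2
    F_ST  = s2 / (p_bar * (1 - p_bar) + s2 / r)

s2 is the sample variance (denominator r-1) of the two allele frequencies,
which calibrates the statistic so fixed differences give F_ST(0,1) = 1;
when both populations are fixed for the same allele the denominator is 0
and F_ST is defined as 0. Per-SNP values are averaged in 100-kb windows on
a 25-kb grid; windows with fewer than 30 SNPs are masked. A focal breed's
track is the per-window mean over its comparisons against every other
breed (five, in a six-breed panel), masked wherever any single comparison
is masked so every breed value averages the same number of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .filtering import FilterResult
from .io import CountsTable
from .windows import MIN_SNPS, STEP, WINDOW_SIZE, window_mean


@dataclass(frozen=True)
class PairwiseFstResult:
    """One per-SNP pairwise F_ST evaluation with its intermediates."""

    p1: float
    p2: float
    p_bar: float
    s2: float
    fst: float
    r: int = 2


def snp_fst_values(p1, p2) -> np.ndarray:
    """Vectorized per-SNP pairwise F_ST from two allele-frequency arrays."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ConfigError("allele frequencies must lie in [0, 1]")
    p_bar = (p1 + p2) / 2.0
    s2 = (p1 - p2) ** 2 / 2.0
    denom = p_bar * (1.0 - p_bar) + s2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0, s2 / np.maximum(denom, np.finfo(float).tiny), 0.0)
    return fst


def snp_fst(p1: float, p2: float) -> PairwiseFstResult:
    """Per-SNP pairwise F_ST for a single frequency pair, with intermediates."""
    fst = float(snp_fst_values(p1, p2))
    p_bar = (p1 + p2) / 2.0
    s2 = (p1 - p2) ** 2 / 2.0
    return PairwiseFstResult(p1=p1, p2=p2, p_bar=p_bar, s2=s2, fst=fst)


def pair_eligible(filt: FilterResult, i: int, j: int) -> np.ndarray:
    """Sites entering the F_ST track of breed pair (i, j).

    A SNP is eligible iff it meets the coverage and quality rules in BOTH
    pools and is a retained SNP (all rules) in AT LEAST ONE of them — a
    site fixed in one breed but polymorphic in the other is informative.
    """
    return (
        filt.depth_qual_ok[:, i]
        & filt.depth_qual_ok[:, j]
        & (filt.passed[:, i] | filt.passed[:, j])
    )


def window_mean_fst(
    windows: pd.DataFrame,
    site_chrom: np.ndarray,
    site_pos: np.ndarray,
    fst_values: np.ndarray,
    window_size: int = WINDOW_SIZE,
    step: int = STEP,
    min_snps: int = MIN_SNPS,
) -> pd.DataFrame:
    """Average per-SNP F_ST in sliding windows for one breed pair.

    Returns ``windows`` with ``n_snps`` and ``fst`` columns; windows with
    fewer than ``min_snps`` contributing SNPs carry NaN.
    """
    n, mean = window_mean(
        windows, site_chrom, site_pos, fst_values, window_size, step, min_snps
    )
    out = windows.copy()
    out["n_snps"] = n
    out["fst"] = mean
    return out


def pair_fst_tracks(
    counts: CountsTable,
    filt: FilterResult,
    windows: pd.DataFrame,
    window_size: int = WINDOW_SIZE,
    step: int = STEP,
    min_snps: int = MIN_SNPS,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Window F_ST tracks for every unordered breed pair."""
    depth = counts.depth
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, counts.n_alt / np.maximum(depth, 1), np.nan)
    tracks: dict[tuple[str, str], pd.DataFrame] = {}
    nb = counts.n_breeds
    for i in range(nb):
        for j in range(i + 1, nb):
            sel = pair_eligible(filt, i, j)
            fst = snp_fst_values(freq[sel, i], freq[sel, j])
            tracks[(counts.breeds[i], counts.breeds[j])] = window_mean_fst(
                windows,
                counts.chrom[sel],
                counts.pos[sel],
                fst,
                window_size,
                step,
                min_snps,
            )
    return tracks


def breed_mean_fst(
    pair_tracks: Mapping[tuple[str, str], pd.DataFrame],
    focal_breed: str,
    breeds: list[str],
) -> pd.DataFrame:
    """Average a focal breed's pairwise window tracks into one breed track.

    Per window, the value is the mean of the focal breed's pairwise F_ST
    values across all its comparisons (five in a six-breed panel); the
    window is masked for the breed if it is masked in ANY comparison.
    ``n_snps`` carries the minimum SNP count across the comparisons (the
    binding constraint for the mask).
    """
    others = [b for b in breeds if b != focal_breed]
    if not others:
        raise ConfigError("breed averaging needs at least two breeds")
    cols = []
    ns = []
    template = None
    for other in others:
        key = (focal_breed, other) if (focal_breed, other) in pair_tracks else (other, focal_breed)
        if key not in pair_tracks:
            raise ConfigError(
                f"missing pairwise track for {focal_breed} vs {other}: expected "
                f"{len(others)} comparisons"
            )
        track = pair_tracks[key]
        template = track if template is None else template
        cols.append(track["fst"].to_numpy())
        ns.append(track["n_snps"].to_numpy())
    values = np.column_stack(cols)
    out = template[["chrom", "start", "end"]].copy()
    out["n_snps"] = np.column_stack(ns).min(axis=1)
    masked = np.isnan(values).any(axis=1)
    mean = values.mean(axis=1)
    mean[masked] = np.nan
    out["fst"] = mean
    return out
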
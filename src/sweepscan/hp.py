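"""Pooled expected heterozygosity H_p per SNP and per window.

For one breed at one site, with n_maj and n_min the read counts of the
major and minor allele in that breed's pool,

    H_p = 2 * n_maj * n_min / (n_maj + n_min)^2

the pooled analogue of expected heterozygosity 2p(1-p), bounded in
[0, 0.5] and invariant under swapping which allele is labelled ref or alt.
It is depressed toward 0 inside selective sweeps, where one allele
approaches fixation.

Per-SNP values are averaged along 100-kb sliding windows with a 25-kb
step (``hp_mode="per_snp_mean"``). The alternative used in some of the
genome-scan literature — pooling the major/minor read counts over the
whole window before forming the ratio — is available as
``hp_mode="window_pooled"``. The >= 30 SNP window mask is applied in both
modes, mirroring the F_ST scan so the two tracks share one grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .filtering import FilterResult
from .io import CountsTable
from .windows import MIN_SNPS, STEP, WINDOW_SIZE, window_aggregate, window_mean

HP_MODES = ("per_snp_mean", "window_pooled")


@dataclass(frozen=True)
class HpResult:
    """Per-SNP pooled heterozygosity with its inputs."""

    n_maj: int
    n_min: int
    hp: float


def snp_hp_values(n_maj, n_min) -> np.ndarray:
    """Vectorized per-SNP H_p from major/minor allele read counts."""
    n_maj = np.asarray(n_maj, dtype=float)
    n_min = np.asarray(n_min, dtype=float)
    if np.any(n_min > n_maj):
        raise ConfigError("n_min exceeds n_maj: order alleles before calling")
    if np.any(n_min < 0):
        raise ConfigError("negative read counts")
    total = n_maj + n_min
    if np.any(total < 1):
        raise DataError("snp_hp undefined at zero total reads")
    return 2.0 * n_maj * n_min / total**2


def snp_hp(n_maj: int, n_min: int) -> HpResult:
    """Per-SNP pooled heterozygosity for a single site."""
    return HpResult(n_maj=n_maj, n_min=n_min, hp=float(snp_hp_values(n_maj, n_min)))


def window_mean_hp(
    windows: pd.DataFrame,
    site_chrom: np.ndarray,
    site_pos: np.ndarray,
    n_maj: np.ndarray,
    n_min: np.ndarray,
    window_size: int = WINDOW_SIZE,
    step: int = STEP,
    min_snps: int = MIN_SNPS,
    hp_mode: str = "per_snp_mean",
) -> pd.DataFrame:
    """Window H_p track for one breed from its filtered SNP set.

    Returns ``windows`` plus ``n_snps`` and ``hp`` columns; windows with
    fewer than ``min_snps`` SNPs carry NaN.
    """
    if hp_mode not in HP_MODES:
        raise ConfigError(f"hp_mode must be one of {HP_MODES}, got {hp_mode!r}")
    out = windows.copy()
    if hp_mode == "per_snp_mean":
        hp = snp_hp_values(n_maj, n_min)
        n, mean = window_mean(
            windows, site_chrom, site_pos, hp, window_size, step, min_snps
        )
        out["n_snps"] = n
        out["hp"] = mean
    else:
        n, sum_maj = window_aggregate(
            windows, site_chrom, site_pos, np.asarray(n_maj, float), window_size, step
        )
        _, sum_min = window_aggregate(
            windows, site_chrom, site_pos, np.asarray(n_min, float), window_size, step
        )
        total = sum_maj + sum_min
        with np.errstate(invalid="ignore", divide="ignore"):
            hp_w = 2.0 * sum_maj * sum_min / np.maximum(total, 1) ** 2
        hp_w[(n < min_snps) | (total == 0)] = np.nan
        out["n_snps"] = n
        out["hp"] = hp_w
    return out


def breed_hp_track(
    counts: CountsTable,
    filt: FilterResult,
    breed: str,
    windows: pd.DataFrame,
    window_size: int = WINDOW_SIZE,
    step: int = STEP,
    min_snps: int = MIN_SNPS,
    hp_mode: str = "per_snp_mean",
) -> pd.DataFrame:
    """Window H_p track for one breed of a filtered counts table."""
    j = counts.breeds.index(breed)
    sel = filt.passed[:, j]
    n_maj = np.maximum(counts.n_ref[sel, j], counts.n_alt[sel, j])
    n_min = np.minimum(counts.n_ref[sel, j], counts.n_alt[sel, j])
    return window_mean_hp(
        windows,
        counts.chrom[sel],
        counts.pos[sel],
        n_maj,
        n_min,
        window_size,
        step,
        min_snps,
        hp_mode,
    )
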
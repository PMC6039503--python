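"""Z-transformation, empirical-tail outlier calling, and sharing.

Each breed's genome-wide window tracks are standardized,

    ZF_ST = (F_ST - mu_FST) / sigma_FST,   ZH_p = (H_p - mu_Hp) / sigma_Hp,

with mu and sigma computed over that breed's unmasked windows genome-wide
(sample standard deviation, n-1 denominator). Outliers are empirical
tails: the floor(q*N) windows with the largest ZF_ST and the floor(q*N)
windows with the smallest ZH_p (q = 0.005, i.e. the top/bottom 0.5%),
ties broken deterministically by genomic order. Windows present in BOTH
tails — identical coordinates, since both tracks share one grid — are the
putative selection signatures. Across breeds, a putative window is
``shared`` when it overlaps (>= 1 bp) a putative window of any other
breed, else ``breed-specific``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

STATUS_FST = "fst_outlier"
STATUS_HP = "hp_outlier"
STATUS_BOTH = "putative_selection"

CALL_COLUMNS = [
    "breed", "chrom", "start", "end",
    "n_snps", "fst", "zfst", "hp", "zhp", "status",
]


@dataclass
class ZScoreSet:
    """A Z-transformed statistic track.

    ``values`` and ``z`` are aligned; masked entries (NaN) do not enter
    ``mu``/``sigma`` and stay NaN in ``z``.
    """

    values: np.ndarray
    mu: float
    sigma: float
    z: np.ndarray


def z_transform(window_values) -> ZScoreSet:
    """Standardize a window-statistic track to mean 0, sd 1.

    NaN entries are masked windows and are ignored. Raises ``DataError``
    for fewer than two unmasked windows or a constant track.
    """
    values = np.asarray(window_values, dtype=float)
    ok = ~np.isnan(values)
    n = int(ok.sum())
    if n < 2:
        raise DataError(f"z_transform needs >= 2 unmasked windows, got {n}")
    mu = float(values[ok].mean())
    sigma = float(values[ok].std(ddof=1))
    if sigma == 0.0:
        raise DataError("z_transform: constant track (zero variance)")
    return ZScoreSet(values=values, mu=mu, sigma=sigma, z=(values - mu) / sigma)


def _tail_indices(z: np.ndarray, q: float, largest: bool) -> np.ndarray:
    """Row indices of the floor(q*N) most extreme unmasked windows.

    N counts unmasked windows of the track. Ties are broken by genomic
    order (the row order of the track): the earlier window wins.
    """
    ok = np.flatnonzero(~np.isnan(z))
    k = int(np.floor(q * len(ok)))
    if k == 0:
        return np.empty(0, dtype=np.int64)
    key = -z[ok] if largest else z[ok]
    order = np.lexsort((ok, key))  # primary: extremity; secondary: genomic order
    return ok[order[:k]]


def select_outliers(track: pd.DataFrame, q: float = 0.005) -> pd.DataFrame:
    """Call empirical-tail outlier windows for one breed.

    ``track`` must carry columns chrom, start, end, breed, n_snps, fst,
    zfst, hp, zhp in genomic order. Returns the called windows with a
    ``status`` column: ``fst_outlier`` (top ZF_ST tail), ``hp_outlier``
    (bottom ZH_p tail), or ``putative_selection`` for windows in both
    tails.
    """
    if not (0.0 < q < 0.5):
        raise ConfigError(f"q must be in (0, 0.5), got {q}")
    zf = track["zfst"].to_numpy(dtype=float)
    zh = track["zhp"].to_numpy(dtype=float)
    fst_idx = _tail_indices(zf, q, largest=True)
    hp_idx = _tail_indices(zh, q, largest=False)
    both = np.intersect1d(fst_idx, hp_idx)
    status = {}
    for i in fst_idx:
        status[int(i)] = STATUS_FST
    for i in hp_idx:
        status[int(i)] = STATUS_HP
    for i in both:
        status[int(i)] = STATUS_BOTH
    rows = sorted(status)
    calls = track.iloc[rows].copy()
    calls["status"] = [status[i] for i in rows]
    return calls.reset_index(drop=True)


def classify_shared(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label putative-selection windows as shared or breed-specific.

    A putative window is ``shared`` iff its interval overlaps (>= 1 bp,
    same chromosome) a putative window of ANY other breed. Also returns
    the pairwise overlap-count matrix M (Venn input): M[a, b] is the
    number of breed a's putative windows overlapping at least one of breed
    b's; the diagonal holds each breed's putative window count.
    """
    calls = calls.copy()
    calls["sharing"] = pd.NA
    put = calls[calls["status"] == STATUS_BOTH]
    breeds = sorted(calls["breed"].unique())
    matrix = pd.DataFrame(0, index=breeds, columns=breeds, dtype=int)
    if len(put) == 0:
        return calls, matrix
    merged = put.merge(put, on="chrom", suffixes=("_a", "_b"))
    merged = merged[
        (merged["breed_a"] != merged["breed_b"])
        & (merged["start_a"] < merged["end_b"])
        & (merged["start_b"] < merged["end_a"])
    ]
    shared_keys = set(
        zip(merged["breed_a"], merged["chrom"], merged["start_a"])
    )
    is_put = calls["status"] == STATUS_BOTH
    keys = list(zip(calls["breed"], calls["chrom"], calls["start"]))
    calls.loc[is_put, "sharing"] = [
        "shared" if k in shared_keys else "breed-specific"
        for k, p in zip(keys, is_put)
        if p
    ]
    for b in breeds:
        matrix.loc[b, b] = int((put["breed"] == b).sum())
    pair_counts = (
        merged.drop_duplicates(["breed_a", "chrom", "start_a", "breed_b"])
        .groupby(["breed_a", "breed_b"])
        .size()
    )
    for (a, b), cnt in pair_counts.items():
        matrix.loc[a, b] = int(cnt)
    return calls, matrix
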
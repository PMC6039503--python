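"""Count-based SNP retention filters, applied per breed and per site.

A site enters a breed's SNP set iff, in that breed's pool:

1. read depth >= ``min_coverage`` (default 15),
2. reads supporting the minor allele >= ``min_reads2`` (default 2),
3. mean base quality >= ``min_avg_qual`` (default 30),
4. the one-sided exact binomial tail P(X >= k | n, error_rate) — the
   probability of seeing at least k minor-allele reads out of n from
   sequencing error alone — is below ``p_threshold`` (default 0.05), and
5. the minor-allele read frequency >= ``maf_min`` (default 0.025, one
   chromosome in a pool of 20 diploids).

Membership is a conjunction, so it does not depend on rule order; the
order above is fixed only to attribute each removed site to the first rule
it fails in the removal report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import ConfigError, DataError
from .io import CountsTable

#: rule names in attribution order
FILTER_RULES = ("min_coverage", "min_reads2", "min_avg_qual", "significance", "maf")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the per-breed SNP retention rules."""

    min_coverage: int = 15
    min_reads2: int = 2
    min_avg_qual: float = 30.0
    p_threshold: float = 0.05
    maf_min: float = 0.025
    error_rate: float = 0.01

    def __post_init__(self) -> None:
        if min(self.min_coverage, self.min_reads2, self.min_avg_qual, self.maf_min) < 0:
            raise ConfigError("filter thresholds must be >= 0")
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigError(f"error_rate must be in [0,1), got {self.error_rate}")


def allele_significance_p(n_ref, n_alt, error_rate: float = 0.01):
    """One-sided exact binomial tail for minor-allele support.

    With k = min(n_ref, n_alt) and n = n_ref + n_alt, returns
    P(X >= k | n, error_rate): the probability that sequencing error alone
    produces at least k minor-allele reads. k = 0 gives 1.0. Accepts
    scalars or arrays.
    """
    n_ref = np.asarray(n_ref)
    n_alt = np.asarray(n_alt)
    n = n_ref + n_alt
    if np.any(n < 1):
        raise DataError("allele_significance_p undefined at zero total reads")
    k = np.minimum(n_ref, n_alt)
    p = binom.sf(k - 1, n, error_rate)
    return float(p) if p.ndim == 0 else p


def breed_maf(n_ref, n_alt):
    """Minor-allele read frequency min(f, 1-f) with f = n_alt / depth."""
    n_ref = np.asarray(n_ref, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    n = n_ref + n_alt
    if np.any(n < 1):
        raise DataError("breed_maf undefined at zero coverage")
    f = n_alt / n
    maf = np.minimum(f, 1.0 - f)
    return float(maf) if maf.ndim == 0 else maf


@dataclass
class FilterResult:
    """Per-breed filter masks and the removal report.

    ``passed[i, j]`` is True iff site i is in breed j's SNP set.
    ``depth_qual_ok`` marks sites meeting only the coverage and quality
    rules in a breed (used for pair eligibility in the F_ST scan).
    ``report`` has one row per (breed, rule) with the number of sites the
    rule removed (first-failing attribution) plus the breed's retained
    total.
    """

    breeds: list[str]
    passed: np.ndarray
    depth_qual_ok: np.ndarray
    report: pd.DataFrame
    params: FilterParams

    def n_retained(self) -> dict[str, int]:
        return {b: int(self.passed[:, j].sum()) for j, b in enumerate(self.breeds)}


def apply_filters(counts: CountsTable, params: FilterParams | None = None) -> FilterResult:
    """Apply the SNP retention rules to every breed of a counts table."""
    if params is None:
        params = FilterParams()
    depth = counts.depth
    minor = np.minimum(counts.n_ref, counts.n_alt)
    r_cov = depth >= params.min_coverage
    r_reads2 = minor >= params.min_reads2
    r_qual = counts.mean_qual >= params.min_avg_qual
    safe_n = np.maximum(depth, 1)
    pvals = binom.sf(minor - 1, safe_n, params.error_rate)
    pvals = np.where(depth > 0, pvals, 1.0)
    r_sig = pvals < params.p_threshold
    maf = np.where(depth > 0, minor / safe_n, 0.0)
    r_maf = maf >= params.maf_min

    rules = [r_cov, r_reads2, r_qual, r_sig, r_maf]
    passed = np.logical_and.reduce(rules)

    rows = []
    for j, breed in enumerate(counts.breeds):
        surviving = np.ones(len(counts), dtype=bool)
        retained = int(passed[:, j].sum())
        for name, rule in zip(FILTER_RULES, rules):
            removed = surviving & ~rule[:, j]
            rows.append((breed, name, int(removed.sum()), retained))
            surviving &= rule[:, j]
    report = pd.DataFrame(rows, columns=["breed", "rule", "n_removed", "n_retained"])
    return FilterResult(
        breeds=list(counts.breeds),
        passed=passed,
        depth_qual_ok=r_cov & r_qual,
        report=report,
        params=params,
    )
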
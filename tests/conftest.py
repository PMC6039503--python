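import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sweepscan import CountsTable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_counts(rows, breeds):
    """Build a CountsTable from (chrom, pos, ref, alt, [(n_ref, n_alt, qual), ...]) rows."""
    return CountsTable(
        chrom=np.array([r[0] for r in rows], dtype=object),
        pos=np.array([r[1] for r in rows], dtype=np.int64),
        ref=np.array([r[2] for r in rows], dtype=object),
        alt=np.array([r[3] for r in rows], dtype=object),
        breeds=list(breeds),
        n_ref=np.array(
            [[c[0] for c in r[4]] for r in rows], dtype=np.int64
        ).reshape(len(rows), len(breeds)),
        n_alt=np.array(
            [[c[1] for c in r[4]] for r in rows], dtype=np.int64
        ).reshape(len(rows), len(breeds)),
        mean_qual=np.array(
            [[c[2] for c in r[4]] for r in rows], dtype=float
        ).reshape(len(rows), len(breeds)),
    )


@pytest.fixture
def six_site_counts():
    """One breed, six sites, each engineered to fail exactly one retention
    rule in attribution order (coverage, minor reads, quality, significance,
    MAF) plus one site passing all five."""
    rows = [
        ("chr1", 100, "A", "C", [(12, 2, 35.0)]),    # depth 14 < 15
        ("chr1", 200, "A", "C", [(38, 1, 35.0)]),    # minor reads 1 < 2
        ("chr1", 300, "A", "C", [(30, 10, 25.0)]),   # mean qual 25 < 30
        ("chr1", 400, "A", "C", [(198, 2, 35.0)]),   # P(X>=2 | 200, 0.01) ~ 0.60
        ("chr1", 500, "A", "C", [(391, 9, 35.0)]),   # MAF 9/400 = 0.0225 < 0.025
        ("chr1", 600, "A", "C", [(30, 10, 35.0)]),   # passes everything
    ]
    return build_counts(rows, ["B1"])
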
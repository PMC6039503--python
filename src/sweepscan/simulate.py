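"""Synthetic multi-breed Pool-seq data with drift structure and sweeps.

The generator emulates the study design the scan is built for: several
breed pools (default six) of 20 diploids each, sequenced to a mean depth of
about 26x, at a SNP density of a few SNPs per kb. Neutral differentiation
between breeds follows the Balding-Nichols model: each breed's allele
frequency at a site is a Beta draw around the ancestral frequency p with
variance F*p*(1-p), where F is the per-breed drift coefficient. Selective
sweeps are implanted by pushing the focal breed's frequencies in a region
to (near-)fixation of the locally common allele, which produces the
high-F_ST / low-H_p signature the scan targets.

Reads are then sampled directly from the breed frequency (Poisson depth,
binomial allele sampling with a symmetric per-read error rate). This skips
the two-stage individual-then-read sampling of a real pool; with 40
chromosomes per pool the extra variance is second-order for testing the
scan, and the simplification is deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, PlacementError
from .io import BASES, CountsTable, GeneFeature

DEFAULT_BETA_SHAPE = (0.7, 0.7)
DEFAULT_FREQ_BOUNDS = (0.05, 0.95)


@dataclass(frozen=True)
class BreedModel:
    """Population/pool model for one breed.

    ``F_drift`` is the Balding-Nichols differentiation coefficient in (0,1);
    ``n_individuals`` is the number of diploid animals in the DNA pool;
    ``mean_depth`` is the expected read depth per site.
    """

    name: str
    n_individuals: int = 20
    F_drift: float = 0.1
    mean_depth: float = 26.0

    def __post_init__(self) -> None:
        if not (0.0 < self.F_drift < 1.0):
            raise ConfigError(
                f"breed {self.name}: F_drift must be in (0,1), got {self.F_drift}"
            )
        if self.n_individuals < 1:
            raise ConfigError(f"breed {self.name}: n_individuals must be >= 1")
        if self.mean_depth <= 0:
            raise ConfigError(f"breed {self.name}: mean_depth must be > 0")


@dataclass(frozen=True)
class SweepTruth:
    """Ground truth for one implanted sweep (0-based half-open region)."""

    breed: str
    chrom: str
    start: int
    end: int
    target_freq: float = 0.98

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigError(
                f"sweep {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if not (0.0 <= self.target_freq <= 1.0):
            raise ConfigError("target_freq must be in [0,1]")


@dataclass
class SimulatedFrequencies:
    """Per-site ancestral and per-breed allele frequencies.

    ``pos`` is 1-based; ``freqs`` has shape (n_sites, n_breeds) and holds
    the alternate-allele frequency in each breed.
    """

    chrom_lengths: dict[str, int]
    breeds: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    p_anc: np.ndarray
    freqs: np.ndarray


def _unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Draw n distinct 1-based positions uniformly on [1, length]."""
    if n > length:
        raise ConfigError(f"cannot place {n} SNPs on a {length}-bp chromosome")
    seen = np.unique(rng.integers(1, length + 1, size=n))
    while len(seen) < n:
        extra = rng.integers(1, length + 1, size=2 * (n - len(seen)) + 16)
        seen = np.unique(np.concatenate([seen, extra]))
    if len(seen) > n:
        keep = rng.choice(len(seen), size=n, replace=False)
        seen = np.sort(seen[keep])
    return seen.astype(np.int64)


def simulate_frequencies(
    chrom_lengths: Mapping[str, int],
    breed_models: Sequence[BreedModel],
    snp_per_kb: float = 2.5,
    seed: int = 0,
    beta_shape: tuple[float, float] = DEFAULT_BETA_SHAPE,
    freq_bounds: tuple[float, float] = DEFAULT_FREQ_BOUNDS,
) -> SimulatedFrequencies:
    """Simulate neutral Balding-Nichols allele frequencies.

    SNP positions are placed uniformly at ``snp_per_kb`` per chromosome.
    The ancestral frequency of each site is drawn from a symmetric
    Beta(0.7, 0.7) truncated (by rejection) to [0.05, 0.95], so most sites
    stay polymorphic enough to survive the MAF filter in at least one
    breed; each breed's frequency is an independent
    Beta(p(1-F)/F, (1-p)(1-F)/F) draw.
    """
    if snp_per_kb <= 0:
        raise ConfigError("snp_per_kb must be > 0")
    for name, length in chrom_lengths.items():
        if length <= 0:
            raise ConfigError(f"chromosome {name}: length must be > 0")
    rng = np.random.default_rng(seed)
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for name, length in chrom_lengths.items():
        n = int(round(length / 1000.0 * snp_per_kb))
        pos = _unique_positions(rng, length, n)
        chroms.append(np.full(n, name, dtype=object))
        positions.append(pos)
    chrom = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
    pos = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    n_sites = len(pos)

    a, b = beta_shape
    lo, hi = freq_bounds
    p = rng.beta(a, b, size=n_sites)
    bad = (p < lo) | (p > hi)
    while bad.any():
        p[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (p < lo) | (p > hi)

    freqs = np.empty((n_sites, len(breed_models)))
    for j, model in enumerate(breed_models):
        F = model.F_drift
        scale = (1.0 - F) / F
        freqs[:, j] = rng.beta(p * scale, (1.0 - p) * scale)
    return SimulatedFrequencies(
        chrom_lengths=dict(chrom_lengths),
        breeds=[m.name for m in breed_models],
        chrom=chrom,
        pos=pos,
        p_anc=p,
        freqs=freqs,
    )


def implant_sweep(sim: SimulatedFrequencies, sweep: SweepTruth) -> SimulatedFrequencies:
    """Return a copy of ``sim`` with one sweep implanted.

    Inside the region, the focal breed's frequency is set to
    ``target_freq`` or ``1 - target_freq``, whichever is closer to the
    site's current frequency, so the sweep fixes the locally common allele.
    Other breeds are untouched.
    """
    if sweep.breed not in sim.breeds:
        raise ConfigError(f"unknown breed {sweep.breed!r}")
    if sweep.chrom not in sim.chrom_lengths:
        raise DataError(f"sweep chromosome {sweep.chrom!r} not in simulated genome")
    if sweep.start < 0 or sweep.end > sim.chrom_lengths[sweep.chrom]:
        raise DataError(
            f"sweep {sweep.chrom}:{sweep.start}-{sweep.end} extends outside "
            f"the {sim.chrom_lengths[sweep.chrom]}-bp chromosome"
        )
    j = sim.breeds.index(sweep.breed)
    p0 = sim.pos - 1  # 0-based
    mask = (sim.chrom == sweep.chrom) & (p0 >= sweep.start) & (p0 < sweep.end)
    freqs = sim.freqs.copy()
    cur = freqs[mask, j]
    t = sweep.target_freq
    freqs[mask, j] = np.where(np.abs(cur - t) <= np.abs(cur - (1.0 - t)), t, 1.0 - t)
    return replace(sim, freqs=freqs)


def sample_pool_reads(
    sim: SimulatedFrequencies,
    breed_models: Sequence[BreedModel],
    error_rate: float = 0.01,
    mean_qual: float = 35.0,
    seed: int = 0,
) -> CountsTable:
    """Sample pooled read counts from simulated frequencies.

    Per site and breed, depth ~ Poisson(mean_depth) and the alternate-read
    count ~ Binomial(depth, p') with p' = p(1-e) + (1-p)e, where e is the
    symmetric per-read error rate. Sites covered by no breed are dropped.
    Reference/alternate bases are assigned at random (they carry no signal).
    """
    if not (0.0 <= error_rate < 0.5):
        raise ConfigError(f"error_rate must be in [0, 0.5), got {error_rate}")
    names = [m.name for m in breed_models]
    if names != sim.breeds:
        raise ConfigError(
            f"breed_models {names} do not match simulated breeds {sim.breeds}"
        )
    rng = np.random.default_rng(seed)
    n, b = sim.freqs.shape
    depth = np.empty((n, b), dtype=np.int64)
    for j, model in enumerate(breed_models):
        depth[:, j] = rng.poisson(model.mean_depth, size=n)
    p_read = sim.freqs * (1.0 - error_rate) + (1.0 - sim.freqs) * error_rate
    n_alt = rng.binomial(depth, p_read)
    n_ref = depth - n_alt

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    base_arr = np.array(list(BASES), dtype=object)

    covered = depth.sum(axis=1) > 0
    table = CountsTable(
        chrom=sim.chrom[covered],
        pos=sim.pos[covered],
        ref=base_arr[ref_idx[covered]],
        alt=base_arr[alt_idx[covered]],
        breeds=list(names),
        n_ref=n_ref[covered],
        n_alt=n_alt[covered],
        mean_qual=np.full((int(covered.sum()), b), float(mean_qual)),
        meta={"n_dropped_uncovered": int((~covered).sum()), "seed": seed},
    )
    table.validate()
    return table


def emit_toy_annotation(
    chrom_lengths: Mapping[str, int],
    n_genes: int,
    seed: int = 0,
    path=None,
    min_len: int = 5_000,
    max_len: int = 50_000,
    max_attempts_per_gene: int = 200,
) -> list[GeneFeature]:
    """Place non-overlapping synthetic gene intervals and (optionally) write GFF3.

    Genes are 5-50 kb, placed uniformly (chromosome chosen proportional to
    length) with rejection of overlaps. IDs are assigned in genomic order,
    so output bytes are a pure function of the inputs and seed.
    """
    if n_genes < 0:
        raise ConfigError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    for _ in range(n_genes):
        for _attempt in range(max_attempts_per_gene):
            c = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
            glen = int(rng.integers(min_len, max_len + 1))
            if chrom_lengths[c] < glen:
                continue
            start = int(rng.integers(1, chrom_lengths[c] - glen + 2))  # 1-based
            end = start + glen - 1  # inclusive
            if all(e < start or s > end for s, e in placed[c]):
                placed[c].append((start, end))
                break
        else:
            raise PlacementError(
                f"could not place {n_genes} non-overlapping genes in a "
                f"{int(lengths.sum())}-bp genome"
            )
    genes: list[GeneFeature] = []
    i = 0
    for c in names:
        for start, end in sorted(placed[c]):
            i += 1
            genes.append(GeneFeature(f"G{i:05d}", c, start, end, "+"))
    if path is not None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c in names:
                fh.write(f"##sequence-region {c} 1 {chrom_lengths[c]}\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\ttoysim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID=gene:{g.gene_id};Name={g.gene_id}\n"
                )
    return genes


def write_sweep_truth(sweeps: Sequence[SweepTruth], path) -> None:
    pd.DataFrame(
        [(s.breed, s.chrom, s.start, s.end, s.target_freq) for s in sweeps],
        columns=["breed", "chrom", "start", "end", "target_freq"],
    ).to_csv(path, sep="\t", index=False)


def read_sweep_truth(path) -> list[SweepTruth]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SweepTruth(r.breed, r.chrom, int(r.start), int(r.end), float(r.target_freq))
        for r in df.itertuples()
    ]
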
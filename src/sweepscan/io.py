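"""Readers and writers for pooled allele-count data and interval formats.

On-disk currency is tab-separated text: popoolation2-style ``.sync`` files
for interchange with Pool-seq tooling, a native counts table that
additionally carries per-pool mean base qualities (which sync lacks), GFF3
for gene models, and TSV/BED for window statistics and outlier calls.

In memory, bulk count data lives in a columnar :class:`CountsTable` (numpy
arrays, one row per biallelic site, one column block per breed pool);
:class:`PooledSite` is the per-row record view.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.iterators import DataIterator

from .errors import DataError, ParseError, SchemaError

BASES = "ACGT"
# column order of the count sextet in sync files: A:T:C:G:N:del
SYNC_BASE_ORDER = "ATCG"
DEFAULT_MEAN_QUAL = 35.0

#: columns of the window-statistics TSV, in order
WINDOW_STAT_COLUMNS = [
    "chrom", "start", "end", "breed", "n_snps", "fst", "zfst", "hp", "zhp",
]


@dataclass(frozen=True)
class BreedCounts:
    """Read counts and mean base quality for one breed pool at one site."""

    n_ref: int
    n_alt: int
    mean_qual: float

    @property
    def depth(self) -> int:
        return self.n_ref + self.n_alt


@dataclass(frozen=True)
class PooledSite:
    """One biallelic site with per-breed pooled read counts.

    ``pos`` is 1-based. ``counts`` maps breed name to :class:`BreedCounts`.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    counts: Mapping[str, BreedCounts]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise DataError(
                f"ref and alt allele identical ({self.ref_allele}) at "
                f"{self.chrom}:{self.pos}"
            )
        for base in (self.ref_allele, self.alt_allele):
            if base not in BASES:
                raise DataError(f"allele {base!r} not one of {BASES}")
        if all(c.depth == 0 for c in self.counts.values()):
            raise DataError(f"no breed covers {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval from GFF3 (1-based, inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise DataError("gene_id must be non-empty")
        if self.end < self.start:
            raise DataError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )


@dataclass
class CountsTable:
    """Columnar container for pooled counts at biallelic sites.

    Arrays are aligned by row (site): ``chrom``/``pos``/``ref``/``alt`` have
    shape ``(n_sites,)``; ``n_ref``/``n_alt``/``mean_qual`` have shape
    ``(n_sites, n_breeds)`` with columns ordered as ``breeds``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    breeds: list[str]
    n_ref: np.ndarray
    n_alt: np.ndarray
    mean_qual: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_breeds(self) -> int:
        return len(self.breeds)

    @property
    def depth(self) -> np.ndarray:
        """Per-site, per-breed total read depth, shape (n_sites, n_breeds)."""
        return self.n_ref + self.n_alt

    def maf(self) -> np.ndarray:
        """Per-site, per-breed minor-allele read frequency (NaN at depth 0)."""
        depth = self.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(depth > 0, self.n_alt / np.maximum(depth, 1), np.nan)
        return np.minimum(f, 1.0 - f)

    def __getitem__(self, i: int) -> PooledSite:
        return PooledSite(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref_allele=str(self.ref[i]),
            alt_allele=str(self.alt[i]),
            counts={
                b: BreedCounts(
                    int(self.n_ref[i, j]),
                    int(self.n_alt[i, j]),
                    float(self.mean_qual[i, j]),
                )
                for j, b in enumerate(self.breeds)
            },
        )

    def validate(self) -> None:
        """Check the PooledSite invariants over the whole table."""
        if len(self) == 0:
            return
        if self.pos.min() < 1:
            raise DataError("positions must be 1-based (>= 1)")
        if (self.n_ref < 0).any() or (self.n_alt < 0).any():
            raise DataError("negative read counts")
        if (self.ref == self.alt).any():
            i = int(np.argmax(self.ref == self.alt))
            raise DataError(
                f"ref == alt at {self.chrom[i]}:{self.pos[i]}"
            )
        uncovered = self.depth.sum(axis=1) == 0
        if uncovered.any():
            i = int(np.argmax(uncovered))
            raise DataError(f"no breed covers {self.chrom[i]}:{self.pos[i]}")

    def to_frame(self) -> pd.DataFrame:
        cols: dict = {
            "chrom": self.chrom,
            "pos": self.pos,
            "ref": self.ref,
            "alt": self.alt,
        }
        for j, b in enumerate(self.breeds):
            cols[f"{b}_n_ref"] = self.n_ref[:, j]
            cols[f"{b}_n_alt"] = self.n_alt[:, j]
            cols[f"{b}_mean_qual"] = self.mean_qual[:, j]
        return pd.DataFrame(cols)


def _empty_counts(breeds: Sequence[str]) -> CountsTable:
    b = len(breeds)
    return CountsTable(
        chrom=np.empty(0, dtype=object),
        pos=np.empty(0, dtype=np.int64),
        ref=np.empty(0, dtype=object),
        alt=np.empty(0, dtype=object),
        breeds=list(breeds),
        n_ref=np.empty((0, b), dtype=np.int64),
        n_alt=np.empty((0, b), dtype=np.int64),
        mean_qual=np.empty((0, b), dtype=np.float64),
    )


def read_sync(
    path,
    pool_names: Sequence[str] | None = None,
    default_qual: float = DEFAULT_MEAN_QUAL,
    max_third_allele_frac: float = 0.10,
) -> CountsTable:
    """Read a popoolation2 sync file into a :class:`CountsTable`.

    Each line is ``chrom  pos  ref`` followed by one ``A:T:C:G:N:del``
    count sextet per pool. The two alleles of a site are the two most
    abundant bases summed across pools (ties broken in A<C<G<T order); N
    and deletion counts are ignored. A site is dropped when a third allele
    carries more than ``max_third_allele_frac`` of its A/C/G/T reads, or
    when no pool covers it; drop tallies are reported in ``meta``.

    Sync files carry no base qualities, so ``mean_qual`` is filled with
    ``default_qual`` everywhere.
    """
    rows: list[tuple] = []
    n_pools: int | None = None
    n_multi = 0
    n_uncovered = 0
    n_ref_mismatch = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected chrom, pos, ref and at "
                    f"least one count sextet, got {len(fields)} fields"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: position {pos_s!r} is not an integer"
                ) from None
            if ref not in BASES:
                raise ParseError(
                    f"{path}: line {lineno}: reference base {ref!r} not one of {BASES}"
                )
            sextets = fields[3:]
            if n_pools is None:
                n_pools = len(sextets)
            elif len(sextets) != n_pools:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_pools} pools, got {len(sextets)}"
                )
            counts = np.zeros((n_pools, 4), dtype=np.int64)
            for p, sx in enumerate(sextets):
                parts = sx.split(":")
                if len(parts) != 6:
                    raise ParseError(
                        f"{path}: line {lineno}: malformed count sextet {sx!r}"
                    )
                try:
                    vals = [int(x) for x in parts]
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer count in {sx!r}"
                    ) from None
                if any(v < 0 for v in vals):
                    raise ParseError(
                        f"{path}: line {lineno}: negative count in {sx!r}"
                    )
                # remap A:T:C:G to internal A,C,G,T order; drop N and del
                for b_sync, v in zip(SYNC_BASE_ORDER, vals[:4]):
                    counts[p, BASES.index(b_sync)] = v
            totals = counts.sum(axis=0)
            total = int(totals.sum())
            if total == 0:
                n_uncovered += 1
                continue
            order = np.argsort(-totals, kind="stable")  # ties: A<C<G<T
            if totals[order[2]] > max_third_allele_frac * total:
                n_multi += 1
                continue
            top1, top2 = int(order[0]), int(order[1])
            ref_idx = BASES.index(ref)
            if ref_idx == top1:
                a, b = top1, top2
            elif ref_idx == top2:
                a, b = top2, top1
            else:
                # observed alleles do not include the file's reference base;
                # keep the site with the major allele in the ref slot
                n_ref_mismatch += 1
                a, b = top1, top2
            rows.append((chrom, pos, BASES[a], BASES[b], counts[:, a], counts[:, b]))

    if n_pools is None:
        n_pools = len(pool_names) if pool_names else 0
    breeds = list(pool_names) if pool_names else [f"pool{i+1}" for i in range(n_pools)]
    if len(breeds) != n_pools:
        raise SchemaError(
            f"{path}: file has {n_pools} pools but {len(breeds)} pool names given"
        )
    if not rows:
        table = _empty_counts(breeds)
    else:
        table = CountsTable(
            chrom=np.array([r[0] for r in rows], dtype=object),
            pos=np.array([r[1] for r in rows], dtype=np.int64),
            ref=np.array([r[2] for r in rows], dtype=object),
            alt=np.array([r[3] for r in rows], dtype=object),
            breeds=breeds,
            n_ref=np.stack([r[4] for r in rows]),
            n_alt=np.stack([r[5] for r in rows]),
            mean_qual=np.full((len(rows), n_pools), float(default_qual)),
        )
    table.meta.update(
        n_dropped_multiallelic=n_multi,
        n_dropped_uncovered=n_uncovered,
        n_ref_mismatch=n_ref_mismatch,
    )
    table.validate()
    return table


def write_sync(counts: CountsTable, path) -> None:
    """Write a :class:`CountsTable` as a sync file (base qualities dropped)."""
    with open(path, "w") as fh:
        for i in range(len(counts)):
            ref_col = BASES.index(counts.ref[i])
            alt_col = BASES.index(counts.alt[i])
            pools = []
            for j in range(counts.n_breeds):
                per_base = [0, 0, 0, 0, 0, 0]  # A,T,C,G,N,del
                per_base[SYNC_BASE_ORDER.index(BASES[ref_col])] = int(counts.n_ref[i, j])
                per_base[SYNC_BASE_ORDER.index(BASES[alt_col])] = int(counts.n_alt[i, j])
                pools.append(":".join(str(v) for v in per_base))
            fh.write(
                f"{counts.chrom[i]}\t{counts.pos[i]}\t{counts.ref[i]}\t"
                + "\t".join(pools)
                + "\n"
            )


def read_pooled_counts(
    path,
    breed_names: Sequence[str],
    default_qual: float = DEFAULT_MEAN_QUAL,
) -> CountsTable:
    """Read the native tab-separated counts dialect.

    The file must have columns ``chrom, pos, ref, alt`` plus, per breed B,
    ``B_n_ref`` and ``B_n_alt``; ``B_mean_qual`` is optional and defaults to
    ``default_qual`` when absent. Rows must be unique on (chrom, pos).
    """
    breed_names = list(breed_names)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = ["chrom", "pos", "ref", "alt"]
    for b in breed_names:
        required += [f"{b}_n_ref", f"{b}_n_alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")
    dup = df.duplicated(["chrom", "pos"])
    if dup.any():
        i = int(np.argmax(dup.values))
        raise DataError(
            f"{path}: duplicate site {df['chrom'].iloc[i]}:{df['pos'].iloc[i]}"
        )
    n = len(df)
    b = len(breed_names)
    qual = np.full((n, b), float(default_qual))
    for j, name in enumerate(breed_names):
        col = f"{name}_mean_qual"
        if col in df.columns:
            qual[:, j] = df[col].to_numpy(dtype=float)
    table = CountsTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        ref=df["ref"].str.upper().to_numpy(dtype=object),
        alt=df["alt"].str.upper().to_numpy(dtype=object),
        breeds=breed_names,
        n_ref=np.column_stack(
            [df[f"{x}_n_ref"].to_numpy(dtype=np.int64) for x in breed_names]
        ) if n else np.empty((0, b), dtype=np.int64),
        n_alt=np.column_stack(
            [df[f"{x}_n_alt"].to_numpy(dtype=np.int64) for x in breed_names]
        ) if n else np.empty((0, b), dtype=np.int64),
        mean_qual=qual,
    )
    table.validate()
    return table


def write_pooled_counts(counts: CountsTable, path) -> None:
    """Write a :class:`CountsTable` in the native counts dialect."""
    counts.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_gff3_genes(path) -> list[GeneFeature]:
    """Extract gene records from a GFF3 file (gzipped input accepted).

    Only features of type ``gene`` are used. ``gene_id`` is taken from the
    ``ID`` attribute (falling back to ``Name``); an Ensembl-style ``gene:``
    prefix is stripped.
    """
    with _open_text(path) as fh:
        text = fh.read()
    genes: list[GeneFeature] = []
    if not any(
        line and not line.startswith("#") for line in text.splitlines()
    ):
        return genes
    for feat in DataIterator(text, from_string=True):
        if feat.featuretype != "gene":
            continue
        if feat.end < feat.start:
            raise ParseError(
                f"{path}: gene at {feat.seqid}:{feat.start} has end < start"
            )
        ids = feat.attributes.get("ID") or feat.attributes.get("Name")
        if not ids:
            raise ParseError(
                f"{path}: gene at {feat.seqid}:{feat.start}-{feat.end} has "
                "neither ID nor Name attribute"
            )
        gene_id = ids[0]
        if gene_id.startswith("gene:"):
            gene_id = gene_id[len("gene:"):]
        genes.append(
            GeneFeature(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand if feat.strand in "+-" else ".",
            )
        )
    return genes


def write_window_stats(stats: pd.DataFrame, path) -> None:
    """Write per-window statistics as TSV, sorted by (chrom, start, breed).

    Columns are fixed (see ``WINDOW_STAT_COLUMNS``); masked values are
    written as ``NA``. Floats are printed with 12 significant digits so a
    write/read round trip preserves values at that precision.
    """
    df = stats.copy()
    for col in WINDOW_STAT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[WINDOW_STAT_COLUMNS].sort_values(
        ["chrom", "start", "breed"], kind="stable"
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def read_window_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])


def write_outlier_bed(windows: pd.DataFrame, path) -> None:
    """Write outlier windows as BED (0-based half-open), breed in the name column."""
    df = windows[["chrom", "start", "end", "breed"]].sort_values(
        ["chrom", "start", "breed"], kind="stable"
    )
    df.to_csv(path, sep="\t", index=False, header=False)
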
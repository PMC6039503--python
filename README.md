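# sweepscan

Selection-signature scans from pooled whole-genome resequencing allele
counts.

## The problem

When a livestock breed is selected — for coat color, growth, altitude
tolerance — the favoured haplotype rises toward fixation and drags a
genomic region with it. That selective sweep leaves two complementary
footprints in population data: the region becomes unusually
*differentiated* from other breeds (high F_ST) and unusually *monomorphic*
within the selected breed (low heterozygosity). Pool-seq designs — one
sequencing library per population, made from the pooled DNA of many
individuals — detect both footprints cheaply, because the statistics need
only allele read counts per population, not genotypes.

`sweepscan` implements the complete count-based scan for multi-breed
Pool-seq panels (the design it emulates: six breed pools of 20 diploids at
~26× depth), plus a synthetic-data generator so the whole chain is testable
without any raw sequencing data. It is aimed at population-genomics
practitioners who have per-pool allele counts (popoolation2 `sync` files or
a simple TSV) and want candidate sweep regions and genes out the other end.

## The method

1. **SNP retention, per breed** — a site enters a breed's SNP set iff
   depth ≥ 15, minor-allele reads ≥ 2, mean base quality ≥ 30, the exact
   binomial tail P(X ≥ k | n, e=0.01) — the chance of k minor reads from
   sequencing error alone — is < 0.05, and the minor-allele read frequency
   is ≥ 0.025 (one chromosome in a pool of 20 diploids).
2. **Per-SNP statistics** — for each breed pair, with pool allele
   frequencies p₁, p₂:

       p̄ = (p₁+p₂)/2,  s² = (p₁−p₂)²/2,  F_ST = s² / (p̄(1−p̄) + s²/2)

   and within each breed, from major/minor allele read counts:

       H_p = 2·n_maj·n_min / (n_maj+n_min)²

3. **Windows** — statistics are averaged along 100-kb sliding windows with
   a 25-kb step; windows with < 30 SNPs are masked. A breed's F_ST track is
   the per-window mean over its comparisons against every other breed.
4. **Outliers** — each track is Z-transformed genome-wide
   (ZF_ST = (F_ST − μ)/σ, likewise ZH_p); the top 0.5 % of ZF_ST and the
   bottom 0.5 % of ZH_p are empirical outliers, and windows in **both**
   tails are the putative selection signatures. Cross-breed overlap labels
   each as breed-specific or shared.
5. **Annotation** — genes (GFF3) overlapping a putative window by ≥ 1 bp
   are reported as candidates; windows without genes are flagged too.

The generator gives the scan something honest to chew on: Balding–Nichols
drift (each breed's frequency ~ Beta around the ancestral frequency with
variance F·p(1−p)), Poisson depth, binomial read sampling with sequencing
error, and sweeps implanted by driving a region's focal-breed frequencies
to near-fixation of the locally common allele.

## Worked example

`examples/03_genome_scan.py` simulates a six-breed panel on one 10-Mb
chromosome with a single 200-kb sweep at 4.0–4.2 Mb in `breed_1`, then runs
the full scan (`q` widened to 0.02 because one chromosome has only 400
windows):

```
  breed  n_snps  snps_per_kb  mean_maf  mean_hp  n_fst_outliers  n_hp_outliers  n_putative  n_genes
breed_1   20203        2.020     0.274    0.365               8              8           7        6
breed_2   20524        2.052     0.276    0.367               8              8           0        0
...

putative selection windows (high ZF_ST and low ZH_p):
  breed chrom   start     end  zfst   zhp        sharing
breed_1  chr1 3975000 4075000  5.44 -4.04 breed-specific
breed_1  chr1 4000000 4100000  6.81 -8.09 breed-specific
breed_1  chr1 4025000 4125000  7.01 -8.17 breed-specific
breed_1  chr1 4050000 4150000  7.81 -8.24 breed-specific
breed_1  chr1 4075000 4175000  7.61 -7.84 breed-specific
breed_1  chr1 4100000 4200000  7.74 -7.95 breed-specific
breed_1  chr1 4125000 4225000  5.77 -2.87 breed-specific
```

Each breed retains ~2 SNPs/kb with mean minor-allele frequency ≈ 0.27 and
mean pooled heterozygosity ≈ 0.37 — the moderate-diversity regime the scan
assumes. Every putative window lands on the implanted sweep, only in the
focal breed, with strongly positive ZF_ST and strongly negative ZH_p; the
six candidate genes are the toy-annotation genes inside those windows. The
other examples show the raw simulated counts (`01`), the per-SNP statistics
on hand-picked inputs (`02`), and sweep-recovery power over replicates
(`04`).

The same scan is available from the shell:

```bash
sweepscan run -c config.yaml        # or: simulate / filter / scan / outliers / annotate
sweepscan report <out_dir>
```

writing counts, window tracks, outlier calls (TSV/BED), gene annotations
and a per-breed report into the configured output directory,
byte-reproducibly for a given config and seed.

## Layout

- `src/sweepscan/` — `io` (sync/TSV/GFF3/BED), `simulate` (generator),
  `filtering`, `windows`, `fst`, `hp`, `outliers`, `annotate`, `pipeline`,
  `presets`, `cli`
- `examples/` — four narrative scripts, one per capability
- `docs/methods.md` — model, assumptions, parameter choices, limitations
- `tests/` — pytest suite, including end-to-end property checks
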
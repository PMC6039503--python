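# Methods

## Statistical model and procedure

The scan treats each breed pool as a sample of allele read counts from an
unobserved population allele frequency. All inference is per biallelic
site and count-based; no genotypes, haplotypes or linkage information are
used.

**SNP retention.** A site is a SNP *in a breed* when its pool shows enough
coverage and enough minor-allele evidence: depth ≥ `min_coverage` (15
reads), minor-allele reads ≥ `min_reads2` (2), mean base quality ≥
`min_avg_qual` (30), exact one-sided binomial tail
P(X ≥ k | n, `error_rate`) < `p_threshold` (0.05), and minor-allele read
frequency ≥ `maf_min` (0.025). The binomial test asks whether the k minor
reads among n could plausibly all be sequencing errors; `error_rate` is
fixed at 0.01, a typical short-read per-base error after quality
filtering. The null is the same "sequencing error alone" hypothesis a
pooled SNP caller uses, restated as a fully specified exact test so it is
reproducible from counts. MAF 0.025 corresponds to a single chromosome in
a pool of 20 diploids, the smallest real signal the design can carry.
Membership is a conjunction — rule order only attributes removals in the
report. Filters are deliberately per-breed: a site can be a SNP in one
pool and invisible in another, and the union over breeds is the panel's
unique-SNP set.

**Pairwise F_ST.** For pool alternate-allele frequencies p₁, p₂ (read
proportions), with r = 2 populations:

    p̄ = (p₁ + p₂)/2
    s² = ((p₁ − p̄)² + (p₂ − p̄)²)/(r − 1) = (p₁ − p₂)²/2
    F_ST = s² / (p̄(1 − p̄) + s²/r)

s² uses the sample variance (r − 1 denominator); this is the calibration
for which a fixed difference gives exactly F_ST(0, 1) = 1, and
F_ST(p, p) = 0. When both pools are fixed for the same allele the
denominator vanishes and F_ST is defined as 0. The estimator applies no
pool-size correction, so read-sampling noise inflates it slightly and
uniformly; the Z-transformation downstream removes any constant
inflation.

A SNP enters a pair's F_ST track iff it passes the coverage and quality
rules in *both* pools and is a fully retained SNP in *at least one* —
a site fixed in one breed but polymorphic in the other is exactly the
differentiated case the scan looks for, while a site failing depth or
quality in either pool has no trustworthy frequency in that pair. The
minor-read, significance and MAF rules are all polymorphism evidence, so
"retained in at least one pool" is the coherent one-sided requirement.

**Pooled heterozygosity.** Within a breed, from major/minor allele read
counts at a retained SNP:

    H_p = 2·n_maj·n_min / (n_maj + n_min)²

the plug-in pooled analogue of expected heterozygosity 2p(1−p), bounded
in [0, 0.5], maximal at balanced counts and 0 at fixation — the sweep
signature. The major/minor ordering makes it invariant to which allele
was labelled reference. At depth n its expectation is 2p(1−p)(1−1/n), a
small uniform downward bias that the Z-transformation again absorbs.

**Windows.** Statistics are averaged over 100-kb windows advanced by
25 kb, anchored at coordinate 0, 0-based half-open (BED-compatible);
windows with fewer than `min_snps` = 30 SNPs are masked. The final window
of a chromosome may extend past its end — positions beyond the end simply
cannot occur. A breed's F_ST track is the per-window mean of its pairwise
tracks against every other breed (five comparisons in a six-breed panel),
masked wherever *any* single comparison is masked, so every unmasked
breed value averages the same number of comparisons. The mask threshold
is applied to H_p windows as well for comparability of the two tracks.

**Outliers.** Each breed's track is standardized genome-wide with the
sample standard deviation (n − 1) over unmasked windows. Tails are
count-based: the floor(q·N) windows with the largest ZF_ST and the
floor(q·N) with the smallest ZH_p, q = 0.005, N the breed's unmasked
window count per track. A count rule (rather than a value threshold) is
used because empirical-quantile scans report near-constant outlier counts
across breeds; ties are broken by genomic order (earlier chromosome/start
wins) so results are deterministic. Putative selection signatures are the
windows present in both tails at identical coordinates — both tracks live
on one grid, so exact-coordinate intersection is well-defined within a
breed. Across breeds, masked windows differ, so sharing uses any-overlap
(≥ 1 bp): a putative window overlapping any other breed's putative window
is `shared`, else `breed-specific`.

**Annotation.** GFF3 gene records (1-based inclusive) are converted to
0-based half-open intervals; a gene overlapping a putative window by
≥ 1 bp is a candidate for that breed. Strand is ignored. Windows without
genes are reported as unannotated rather than dropped. A run with
annotation and window chromosome-name sets that are fully disjoint fails
loudly — that is a naming-scheme mismatch ("1" vs "chr1"), not biology.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the scan consumes, at
the design point of a six-breed pooled study: pools of `n_individuals` =
20 diploids, `mean_depth` = 26 reads/site, SNP density `snp_per_kb` = 2.5
(within the 2–4/kb range typical of diverged livestock panels).

- **Ancestral frequencies** ~ Beta(0.7, 0.7) truncated by rejection to
  [0.05, 0.95]: a U-shaped but bounded spectrum so most sites survive the
  MAF filter somewhere in the panel.
- **Drift**: per breed, Balding–Nichols — frequency ~
  Beta(p(1−F)/F, (1−p)(1−F)/F), i.e. mean p and variance F·p(1−p), with
  `F_drift` = 0.1 per breed. This directly controls the differentiation
  level the scan consumes and runs at desk scale; haplotype structure,
  which frequency-based statistics never see, is not modelled.
- **Reads**: depth ~ Poisson(mean_depth); alternate reads ~
  Binomial(depth, p′) with p′ = p(1−e) + (1−p)e and `error_rate` e = 0.01.
  Reads are drawn directly from the breed frequency, skipping the
  individual-sampling stage of a real pool; with 40 chromosomes per pool
  the neglected variance is second-order for testing purposes.
- **Sweeps**: within a region, the focal breed's frequency is set to
  `target_freq` or 1 − `target_freq`, whichever is nearer its current
  value, fixing the locally common allele (default 0.98 — near-fixation
  with residual polymorphism, the realistic end state of strong recent
  selection).

Measured at these defaults (not tuned to them): post-filter mean MAF
≈ 0.27, mean per-SNP H_p ≈ 0.37, genome-wide mean window F_ST ≈ 0.11 —
the moderate-differentiation regime of a multi-breed livestock panel.

What passing tests on this generator shows: the pipeline's bookkeeping is
exact, its statistics match their definitions, and sweeps of the modelled
kind are recovered with high power at realistic depth and density. What
it does not show: behaviour under linkage disequilibrium, demographic
history (bottlenecks, admixture), uneven pooling, reference bias, or
quality miscalibration — none of which the generator emulates. Real-data
outlier sets should be treated as candidate regions, not calibrated
hypothesis tests.

## Numerical and degenerate-case choices

- F_ST with a zero denominator (both pools fixed, same allele) is 0; all
  frequencies validated to [0, 1].
- H_p demands ordered inputs (n_maj ≥ n_min) and ≥ 1 read; callers that
  hold ref/alt counts take max/min first.
- The significance tail at k = 0 is exactly 1.0, so monomorphic sites can
  never pass the significance rule regardless of depth.
- Z-transformation refuses tracks with < 2 unmasked windows or zero
  variance rather than emitting NaNs/infinities.
- floor(q·N) can be 0 on small genomes (N < 200 windows at q = 0.005);
  the scan then calls nothing, by design — small fixtures should widen q.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical config + seed reproduces every
  output byte-for-byte (logs carry no timestamps).
- Sync parsing: the two site alleles are the two most abundant bases
  summed across pools (ties broken A<C<G<T); sites whose third allele
  exceeds 10 % of A/C/G/T reads are dropped and counted, keeping the
  biallelic statistics well-defined. Sync carries no base qualities, so
  `mean_qual` defaults to 35 (comfortably above the 30 filter — the
  format's absence of quality should not silently discard data).

## Problem sizes

The test suite and acceptance script run the power study at full design
scale — six breeds, five 20-Mb chromosomes (≈ 250,000 sites, 4,000
windows), three 200-kb sweeps, 20 seeded replicates — which completes in
well under a minute on one core thanks to the columnar (numpy) data path.
Calibration checks use a 16-Mb two-chromosome genome; unit fixtures are
hand-built tables of a few sites.

## Known limitations

- Two-population F_ST only; no multi-population (e.g. variance-components)
  estimator, no haplotype statistics (iHS, XP-EHH), no composite-likelihood
  sweep tests.
- Empirical quantile outliers carry no p-values or FDR control; the 0.5 %
  tail is a ranking device, and its yield scales with genome size.
- No Pool-seq unbiased correction for H_p or nucleotide diversity; the
  plug-in estimator is used, relying on standardization to absorb bias.
- The pipeline starts from allele counts; alignment, duplicate removal and
  variant calling from raw reads are upstream of its scope.
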
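"""The three per-SNP quantities the scan is built on.

Evaluates the pairwise F_ST estimator, pooled heterozygosity H_p, and the
exact binomial allele-significance test on hand-picked inputs, printing
each with the interpretation a practitioner would give it.
"""

from sweepscan import allele_significance_p, snp_fst, snp_hp

print("pairwise F_ST from two pool allele frequencies")
for p1, p2 in [(0.5, 0.5), (0.2, 0.8), (0.0, 1.0)]:
    r = snp_fst(p1, p2)
    print(f"  p1={p1:.1f} p2={p2:.1f} -> p_bar={r.p_bar:.2f} s2={r.s2:.2f} F_ST={r.fst:.4f}")
print("  0 = identical frequencies, 1 = fixed difference\n")

print("pooled heterozygosity H_p from major/minor read counts")
for n_maj, n_min in [(50, 50), (30, 10), (100, 0)]:
    print(f"  n_maj={n_maj:3d} n_min={n_min:2d} -> H_p={snp_hp(n_maj, n_min).hp:.3f}")
print("  0.5 = balanced alleles, 0 = monomorphic (the sweep signature)\n")

print("allele significance: P(>= k minor reads | n reads, 1% error)")
for n_ref, n_alt in [(13, 2), (14, 1), (30, 10)]:
    p = allele_significance_p(n_ref, n_alt, 0.01)
    verdict = "SNP retained" if p < 0.05 else "rejected as possible error"
    print(f"  {n_ref}/{n_alt} reads -> P={p:.2e}  ({verdict} at P<0.05)")
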
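"""A complete selection scan on a synthetic six-breed panel.

Simulates the full study design scaled to one 10-Mb chromosome — six
pools, F = 0.1 drift, one 200-kb sweep driven to frequency 0.98 in
breed_1 — then runs filtering, the window F_ST and H_p scans, outlier
calling and annotation, and prints the per-breed report and the putative
selection windows. The tail fraction is widened to q=0.02 because a
single 10-Mb chromosome has only 400 windows.
"""

from sweepscan import RunConfig, SweepTruth, run_pipeline
from sweepscan.presets import pool_panel

config = RunConfig(
    breeds=pool_panel(),
    chrom_lengths={"chr1": 10_000_000},
    out_dir="scan_example_out",
    seed=5,
    sweeps=[SweepTruth("breed_1", "chr1", 4_000_000, 4_200_000, 0.98)],
    n_toy_genes=200,
    q=0.02,
)
result = run_pipeline(config)

print("per-breed run report:")
print(result.report.round(3).to_string(index=False))

put = result.calls[result.calls["status"] == "putative_selection"]
print("\nputative selection windows (high ZF_ST and low ZH_p):")
cols = ["breed", "chrom", "start", "end", "zfst", "zhp", "sharing"]
print(put[cols].round(2).to_string(index=False))

genes = result.gene_table
print(f"\ncandidate genes overlapping those windows: {genes['gene_id'].nunique()}")
print("the implanted sweep spans 4.0-4.2 Mb; windows listed there for breed_1")
print("are true recoveries, anything elsewhere would be an empirical-tail")
print("false positive. full tables were written to scan_example_out/.")
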
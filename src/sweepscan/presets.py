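"""Ready-made study configurations.

``pool_panel`` builds the default six-pool design the generator emulates
(20 diploids per pool, ~26x depth, drift coefficient F = 0.1 per breed).
``sweep_study_config`` is the standard power-evaluation setup: five 20-Mb
chromosomes at 2.5 SNPs/kb with three 200-kb sweeps driven to allele
frequency 0.98 in the first breed — large enough that 100-kb windows hold
~250 SNPs and sweeps span several fully-contained windows, small enough to
run on a desktop.
"""

from __future__ import annotations

from .pipeline import RunConfig
from .simulate import BreedModel, SweepTruth


def pool_panel(
    n_breeds: int = 6,
    f_drift: float = 0.1,
    n_individuals: int = 20,
    mean_depth: float = 26.0,
) -> list[BreedModel]:
    """A panel of identically parameterized breed pools."""
    return [
        BreedModel(
            name=f"breed_{i + 1}",
            n_individuals=n_individuals,
            F_drift=f_drift,
            mean_depth=mean_depth,
        )
        for i in range(n_breeds)
    ]


def default_sweeps(focal_breed: str = "breed_1") -> list[SweepTruth]:
    """Three 200-kb sweeps at target frequency 0.98, on distinct chromosomes."""
    return [
        SweepTruth(focal_breed, "chr1", 5_000_000, 5_200_000, 0.98),
        SweepTruth(focal_breed, "chr3", 10_000_000, 10_200_000, 0.98),
        SweepTruth(focal_breed, "chr5", 15_000_000, 15_200_000, 0.98),
    ]


def sweep_study_config(
    out_dir: str = "sweepscan_out",
    seed: int = 0,
    n_chroms: int = 5,
    chrom_length: int = 20_000_000,
    snp_per_kb: float = 2.5,
    with_sweeps: bool = True,
    f_drift: float = 0.1,
) -> RunConfig:
    """The standard synthetic study: six pools, 100 Mb, three sweeps."""
    breeds = pool_panel(f_drift=f_drift)
    return RunConfig(
        breeds=breeds,
        chrom_lengths={f"chr{i + 1}": chrom_length for i in range(n_chroms)},
        out_dir=out_dir,
        seed=seed,
        snp_per_kb=snp_per_kb,
        sweeps=default_sweeps(breeds[0].name) if with_sweeps else [],
    )
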
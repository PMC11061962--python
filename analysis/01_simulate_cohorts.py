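"""Simulate the two synthetic chicken-like cohorts used by the analysis.

Emits a neutral cohort (background divergence only) and a swept cohort
(three planted 150 kb sweeps in group G1) as VCF + population map +
truth BED under scratch/cohorts/, and records per-cohort site counts in
results/01_cohort_summary.tsv.

Both cohorts: two groups of 25 diploids, a 2 Mb chromosome, ~6,000 SNPs,
background divergence F = 0.05; 2% of sites get one filter-failing INFO
metric so the filtering stage has work to do.
"""

import os

import pandas as pd

from sweepscan.simdata import SimulationConfig, SweepSpec, emit_dataset

OUT_DATA = "scratch/cohorts"
OUT_RESULTS = "results"
SEED = 20240430

SWEEPS = (
    SweepSpec("chr1", 300_000, 450_000, 1, f_sweep=0.6, s=0.9),
    SweepSpec("chr1", 900_000, 1_050_000, 1, f_sweep=0.6, s=0.9),
    SweepSpec("chr1", 1_500_000, 1_650_000, 1, f_sweep=0.6, s=0.9),
)

BASE = dict(chrom_lengths={"chr1": 2_000_000}, snp_density=0.003,
            f_bg=0.05, individuals_per_group=25, info_failure_rate=0.02)


def main() -> None:
    os.makedirs(OUT_RESULTS, exist_ok=True)
    rows = []
    for label, sweeps in (("neutral", ()), ("swept", SWEEPS)):
        cfg = SimulationConfig(seed=SEED, sweeps=sweeps, **BASE)
        paths = emit_dataset(cfg, os.path.join(OUT_DATA, label), prefix=label)
        n_sites = sum(1 for line in open(paths["vcf"]) if not line.startswith("#"))
        rows.append({"cohort": label, "n_sites": n_sites,
                     "n_sweeps": len(sweeps), "vcf": paths["vcf"],
                     "pop_map": paths["pop_map"], "truth": paths["truth"]})
        print(f"{label}: {n_sites} sites, {len(sweeps)} planted sweeps "
              f"-> {paths['vcf']}")
    pd.DataFrame(rows).to_csv(
        os.path.join(OUT_RESULTS, "01_cohort_summary.tsv"), sep="\t",
        index=False)


if __name__ == "__main__":
    main()
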
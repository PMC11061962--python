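"""Diversity summaries on the swept cohort: mean π, MAF spectra, LD decay.

Mean windowed nucleotide diversity per group (the swept group G1 should
show the deficit), folded minor-allele-frequency spectra with the rare
(< 0.005) / low ([0.005, 0.01]) / common (> 0.01) bins, and the
composite-LD decay curve with the distance at which mean r² first
reaches 0.2.  Since sites are simulated without linkage, LD should decay
within the very first distance bin.

Outputs: results/05_mean_pi.tsv, results/05_maf_spectrum.tsv,
results/05_ld_decay.tsv.
"""

import os

import numpy as np
import pandas as pd

from sweepscan.summaries import group_mean_pi, ld_decay, maf_spectrum
from sweepscan.windows import make_windows, window_table

VCF = "scratch/cohorts/swept/swept.vcf"
POP_MAP = "scratch/cohorts/swept/swept.popmap.tsv"


def main() -> None:
    os.makedirs("results", exist_ok=True)
    sites = pd.read_csv("scratch/cohorts/swept_sites.tsv", sep="\t")
    grid = make_windows({"chr1": 2_000_000})
    win = window_table(sites, grid, "G0", "G1")
    rows = [{"group": g, "mean_window_pi": group_mean_pi(win[col])}
            for g, col in (("G0", "pi_A"), ("G1", "pi_B"))]
    pd.DataFrame(rows).to_csv("results/05_mean_pi.tsv", sep="\t", index=False)
    for r in rows:
        print(f"mean window pi [{r['group']}]: {r['mean_window_pi']:.6g}")

    specs = []
    for g in ("G0", "G1"):
        p = sites[f"p_{g}"].to_numpy(dtype=float)
        spec = maf_spectrum(p[~np.isnan(p)]).table
        spec.insert(0, "group", g)
        specs.append(spec)
    pd.concat(specs).to_csv("results/05_maf_spectrum.tsv", sep="\t",
                            index=False)

    # LD from the first 400 scan sites' dosages in group G0
    from cyvcf2 import VCF as CyVCF
    vcf = CyVCF(VCF, gts012=True)
    g0_idx = [i for i, s in enumerate(vcf.samples) if s.startswith("G0")]
    dosages, positions = [], []
    for var in vcf:
        if len(positions) >= 400:
            break
        gt = np.asarray(var.gt_types)[g0_idx].astype(float)
        gt[gt == 3] = -1
        dosages.append(gt)
        positions.append(var.POS)
    res = ld_decay(np.array(dosages), np.array(positions),
                   max_distance=50_000, bin_width=2_000)
    res.table.to_csv("results/05_ld_decay.tsv", sep="\t", index=False)
    print(f"LD decay rate (first bin with mean r2 <= 0.2): "
          f"{res.decay_rate_bp:.0f} bp")


if __name__ == "__main__":
    main()
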
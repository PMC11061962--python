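"""Hard-filter the swept cohort and select the scan sites.

Reads the VCF from step 01, applies the GATK-style hard filters
(strict-inequality thresholds, per variant class), then restricts to
bi-allelic polymorphic SNPs.  Writes the stage counts to
results/02_filter_summary.tsv and the per-site summary to
scratch/cohorts/swept_sites.tsv.
"""

import os

import pandas as pd

from sweepscan.variants import (apply_hard_filters, read_sites,
                                select_scan_sites)

VCF = "scratch/cohorts/swept/swept.vcf"
POP_MAP = "scratch/cohorts/swept/swept.popmap.tsv"


def main() -> None:
    table = read_sites(VCF, POP_MAP)
    kept, removed = apply_hard_filters(table)
    scan = select_scan_sites(kept)
    print(f"input sites:        {len(table)}")
    print(f"hard-filter failed: {len(removed)} "
          f"({100 * len(removed) / len(table):.2f}%)")
    print(f"scan sites (bi-allelic polymorphic SNPs): {len(scan)}")

    os.makedirs("results", exist_ok=True)
    pd.DataFrame([{
        "n_input": len(table),
        "n_removed_hard_filter": len(removed),
        "n_kept": len(kept),
        "n_scan_sites": len(scan),
    }]).to_csv("results/02_filter_summary.tsv", sep="\t", index=False)
    scan.to_csv("scratch/cohorts/swept_sites.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
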
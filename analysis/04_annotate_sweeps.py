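"""Annotate the swept cohort: SNP categories, DSS x QTL overlap, specific SNPs.

A deterministic toy gene annotation (40 genes tiled over the 2 Mb
chromosome, one in ten non-coding) and a synthetic QTL interval set are
generated in code; scan SNPs are classified into the seven location
categories, category fractions are compared against the annotation's
genome composition, DSSs from step 03 are intersected with the QTLs, and
group-specific / nearly-fixed SNPs are counted.

Outputs: results/04_categories.tsv, results/04_enrichment.tsv,
results/04_overlap.tsv.
"""

import os

import numpy as np
import pandas as pd

from sweepscan.annotate import (GenomeAnnotation, Transcript,
                                category_enrichment, classify_location,
                                group_specific_snps, interval_overlap)

CHROM_LEN = 2_000_000
SEED = 20240430


def toy_genes() -> GenomeAnnotation:
    """40 evenly spaced 20 kb genes; every tenth is a ncRNA gene."""
    transcripts = []
    for i in range(40):
        start = 10_000 + i * 50_000
        coding = (i % 10) != 0
        exons = [(start, start + 8_000), (start + 14_000, start + 20_000)]
        # CDS length 7000 + 5000 = 12,000, a multiple of 3
        cds = [(start + 1_000, start + 8_000), (start + 14_000, start + 19_000)]
        transcripts.append(Transcript(
            f"g{i:02d}.t1", "chr1", "+", start, start + 20_000,
            exons=exons, cds=cds if coding else [],
            utr5=[(start, start + 1_000)] if coding else [],
            utr3=[(start + 19_000, start + 20_000)] if coding else [],
            coding=coding))
    return GenomeAnnotation(transcripts)


def toy_qtls(rng: np.random.Generator, n: int = 30) -> list:
    starts = np.sort(rng.integers(0, CHROM_LEN - 100_000, size=n))
    return [("chr1", int(s), int(s + rng.integers(20_000, 100_000)), f"qtl{i}")
            for i, s in enumerate(starts)]


def main() -> None:
    sites = pd.read_csv("scratch/cohorts/swept_sites.tsv", sep="\t")
    ann = toy_genes()

    cats = [classify_location(c, p, ann)
            for c, p in zip(sites["chrom"], sites["pos"])]
    counts = pd.Series(cats).value_counts()
    frac = counts / counts.sum()
    os.makedirs("results", exist_ok=True)
    frac.rename("fraction").to_frame().assign(count=counts).to_csv(
        "results/04_categories.tsv", sep="\t")
    print("SNP location categories:")
    print(frac.to_string())

    # genome composition of the toy annotation, by the same precedence
    probe = np.arange(1, CHROM_LEN, 200)
    genome_cats = pd.Series([classify_location("chr1", int(p), ann)
                             for p in probe]).value_counts(normalize=True)
    ratios = category_enrichment(frac.to_dict(), genome_cats.to_dict())
    pd.Series(ratios, name="obs_over_expected").to_csv(
        "results/04_enrichment.tsv", sep="\t")

    dss = pd.read_csv("results/03_scan_swept/dss.tsv", sep="\t")
    rng = np.random.default_rng(SEED)
    qtls = toy_qtls(rng)
    d_frac, q_frac, _ = interval_overlap(
        [(r.chrom, int(r.start), int(r.end)) for r in dss.itertuples()], qtls)
    print(f"DSSs overlapping >=1 QTL: {100 * d_frac:.1f}%; "
          f"QTLs overlapping >=1 DSS: {100 * q_frac:.1f}%")
    pd.DataFrame([{"dss_with_qtl_frac": d_frac,
                   "qtl_with_dss_frac": q_frac}]).to_csv(
        "results/04_overlap.tsv", sep="\t", index=False)

    spec, fixed = group_specific_snps(sites, "G1")
    print(f"G1-specific SNPs: {len(spec)}; nearly fixed (p > 0.9): "
          f"{len(fixed)} ({100 * len(fixed) / max(len(spec), 1):.2f}%)")


if __name__ == "__main__":
    main()
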
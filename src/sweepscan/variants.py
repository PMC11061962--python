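"""Per-site, per-group variant summaries and hard filtering.

A *site table* is a pandas DataFrame with one row per VCF record and, for
every population group ``g``:

    n_g    diploid individuals with a called genotype
    ac_g   alternate-allele count among called alleles
    het_g  heterozygous individuals
    p_g    alternate-allele frequency  ac_g / (2 n_g)
    h_g    observed heterozygote fraction  het_g / n_g
    pi_g   per-site nucleotide diversity  2 c_ref c_alt / (n (n - 1)),
           with n the number of called alleles (defined for n >= 2, else 0
           with usable_g = False)

plus ``chrom``, ``pos`` (1-based), ``ref``, ``alt``, ``is_snp``,
``biallelic`` and the raw GATK INFO metrics used by the hard filters.

Hard filtering follows the conventional GATK threshold set: a site is
removed iff ANY threshold condition of its class (SNP or indel) holds,
with strict inequalities, and an absent INFO metric never triggers
removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FilterPolicy",
    "read_pop_map",
    "read_sites",
    "site_table_from_counts",
    "apply_hard_filters",
    "select_scan_sites",
    "group_names",
]

INFO_KEYS = ("QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum", "InbreedingCoeff")


@dataclass(frozen=True)
class FilterPolicy:
    """Hard-filter thresholds; a condition key maps to (comparison, value).

    Comparisons are strict: ``lt`` removes when metric < value, ``gt``
    removes when metric > value.  Defaults are the standard short-read
    caller recommendations for SNPs and indels.
    """

    snp: dict[str, tuple[str, float]] = field(default_factory=lambda: {
        "QD": ("lt", 2.0),
        "FS": ("gt", 60.0),
        "MQ": ("lt", 40.0),
        "SOR": ("gt", 3.0),
        "MQRankSum": ("lt", -12.5),
        "ReadPosRankSum": ("lt", -8.0),
    })
    indel: dict[str, tuple[str, float]] = field(default_factory=lambda: {
        "QD": ("lt", 2.0),
        "FS": ("gt", 200.0),
        "SOR": ("gt", 10.0),
        "InbreedingCoeff": ("lt", -0.8),
        "ReadPosRankSum": ("lt", -20.0),
    })


def read_pop_map(path: str) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample, group = line.split()[:2]
            out[sample] = group
    return out


def group_names(table: pd.DataFrame) -> list[str]:
    """The population groups present in a site table."""
    return [c[2:] for c in table.columns if c.startswith("n_")]


def site_table_from_counts(base_cols: dict, counts: dict[str, dict]) -> pd.DataFrame:
    """Assemble a site table from raw per-group integer counts."""
    cols = dict(base_cols)
    for g, c in counts.items():
        n = np.asarray(c["n"], dtype=np.int64)
        ac = np.asarray(c["ac"], dtype=np.int64)
        het = np.asarray(c["het"], dtype=np.int64)
        n_al = 2 * n
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, ac / np.maximum(n_al, 1), np.nan)
            h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
            pi = np.where(
                n_al >= 2,
                2.0 * (n_al - ac) * ac / (np.maximum(n_al, 2) * np.maximum(n_al - 1, 1)),
                0.0,
            )
        cols[f"n_{g}"] = n
        cols[f"ac_{g}"] = ac
        cols[f"het_{g}"] = het
        cols[f"p_{g}"] = p
        cols[f"h_{g}"] = h
        cols[f"pi_{g}"] = pi
        cols[f"usable_{g}"] = n_al >= 2
    return pd.DataFrame(cols)


def read_sites(vcf_path: str, pop_map: dict[str, str] | str,
               groups: list[str] | None = None) -> pd.DataFrame:
    """Parse a VCF into a site table with per-group summaries.

    ``pop_map`` maps sample id to group (or is a path to such a TSV).
    VCF samples absent from the map are ignored with a warning.  Missing
    genotypes are excluded from all per-group counts.  Multi-allelic
    records are kept in the table (``biallelic`` False) so that the
    selection step can exclude them explicitly.
    """
    from cyvcf2 import VCF

    if isinstance(pop_map, str):
        pop_map = read_pop_map(pop_map)

    vcf = VCF(vcf_path, gts012=True)
    samples = vcf.samples
    unmapped = [s for s in samples if s not in pop_map]
    if unmapped:
        logger.warning("ignoring %d VCF samples absent from the population map",
                       len(unmapped))
    if groups is None:
        seen = []
        for s in samples:
            g = pop_map.get(s)
            if g is not None and g not in seen:
                seen.append(g)
        groups = seen
    sample_idx = {
        g: np.array([i for i, s in enumerate(samples) if pop_map.get(s) == g],
                    dtype=np.int64)
        for g in groups
    }
    for g, idx in sample_idx.items():
        if idx.size == 0:
            raise ValueError(f"group {g!r} has no samples in this VCF")

    rows: dict[str, list] = {k: [] for k in
                             ("chrom", "pos", "ref", "alt", "is_snp", "biallelic")}
    info_rows: dict[str, list] = {k: [] for k in INFO_KEYS}
    counts: dict[str, dict[str, list]] = {
        g: {"n": [], "ac": [], "het": []} for g in groups
    }

    for var in vcf:
        alts = var.ALT
        biallelic = len(alts) == 1
        alt = alts[0] if alts else "."
        is_snp = len(var.REF) == 1 and all(len(a) == 1 for a in alts) and bool(alts)
        rows["chrom"].append(var.CHROM)
        rows["pos"].append(var.POS)
        rows["ref"].append(var.REF)
        rows["alt"].append(alt)
        rows["is_snp"].append(is_snp)
        rows["biallelic"].append(biallelic)
        for k in INFO_KEYS:
            v = var.INFO.get(k)
            info_rows[k].append(np.nan if v is None else float(v))
        # gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types)
        for g, idx in sample_idx.items():
            sub = gt[idx]
            called = sub < 3
            counts[g]["n"].append(int(called.sum()))
            counts[g]["ac"].append(int(sub[called].sum()))
            counts[g]["het"].append(int((sub == 1).sum()))

    base = dict(rows)
    for k in INFO_KEYS:
        base[k] = np.array(info_rows[k], dtype=float)
    table = site_table_from_counts(base, counts)
    # contig lengths from the header, when declared
    lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
    table.attrs["chrom_lengths"] = lengths
    return table


def _removal_mask(table: pd.DataFrame, rules: dict[str, tuple[str, float]]) -> np.ndarray:
    mask = np.zeros(len(table), dtype=bool)
    for key, (op, thr) in rules.items():
        if key not in table.columns:
            continue
        vals = table[key].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            hit = vals < thr if op == "lt" else vals > thr
        mask |= np.where(np.isnan(vals), False, hit)
    return mask


def apply_hard_filters(table: pd.DataFrame,
                       policy: FilterPolicy | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a site table into (kept, removed) by the hard filters.

    SNP rows are tested against the SNP thresholds, all other rows
    against the indel thresholds; removal requires ANY strict-inequality
    condition to hold.  Rows with an absent metric are never removed on
    that metric.
    """
    policy = policy or FilterPolicy()
    is_snp = table["is_snp"].to_numpy(dtype=bool)
    removed = np.where(
        is_snp,
        _removal_mask(table, policy.snp),
        _removal_mask(table, policy.indel),
    )
    kept_t = table.loc[~removed].reset_index(drop=True)
    removed_t = table.loc[removed].reset_index(drop=True)
    kept_t.attrs.update(table.attrs)
    return kept_t, removed_t


def select_scan_sites(table: pd.DataFrame,
                      chromosomes: list[str] | None = None) -> pd.DataFrame:
    """Restrict to bi-allelic SNPs that are polymorphic overall.

    A site is monomorphic when the pooled alternate-allele count over all
    groups is 0 or equals the pooled called-allele count.  An optional
    chromosome include-list restricts the scan (e.g. to autosomes).
    """
    groups = group_names(table)
    keep = table["is_snp"].to_numpy(dtype=bool) & table["biallelic"].to_numpy(dtype=bool)
    total_ac = sum(table[f"ac_{g}"].to_numpy() for g in groups)
    total_al = sum(2 * table[f"n_{g}"].to_numpy() for g in groups)
    keep &= (total_ac > 0) & (total_ac < total_al)
    if chromosomes is not None:
        keep &= table["chrom"].isin(chromosomes).to_numpy()
    out = table.loc[keep].reset_index(drop=True)
    out.attrs.update(table.attrs)
    if out.empty:
        logger.warning("no scan sites remain after bi-allelic/polymorphic selection")
    return out
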
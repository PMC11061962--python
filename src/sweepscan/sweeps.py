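"""Calling, merging and summarising discrete selective sweeps (DSSs).

A window is a putative selective sweep when its Z-scored statistic
exceeds the cutoff — strictly: Z_FST(i) > 6 or Z|Δπ|(i) > 3.09 (the
one-sided standard-normal 0.001 quantile).  Significant windows that
overlap by at least one nucleotide are merged transitively into discrete
selective sweeps; abutting half-open intervals (end == start) are not
merged.  The per-statistic DSS sets are complementary in practice, so
the final call is their interval union, re-merged, with provenance flags
recording which statistic(s) contributed.

``run_comparison`` orchestrates one full scan — VCF → site table → hard
filters → scan sites → windows → permutation null → Z-scores → DSSs —
and writes every stage's table plus a run manifest.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import variants
from .nullmodel import build_null, compute_zscores
from .windows import make_windows

logger = logging.getLogger(__name__)

__all__ = ["SweepParams", "Comparison", "call_windows", "merge_to_dss",
           "union_dss", "dss_summary", "run_comparison"]


@dataclass(frozen=True)
class SweepParams:
    """Scan parameters: window geometry, replicate count and Z cutoffs."""

    window_size: int = 40_000
    step: int = 20_000
    n_permutations: int = 100
    z_fst_cutoff: float = 6.0
    z_dpi_cutoff: float = 3.09


@dataclass(frozen=True)
class Comparison:
    """One two-sided comparison: each side pools one or more map groups."""

    label: str
    groups_a: tuple[str, ...]
    groups_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.groups_a or not self.groups_b:
            raise ValueError("both comparison sides must be non-empty")
        if set(self.groups_a) & set(self.groups_b):
            raise ValueError("comparison sides must be disjoint")


def call_windows(scores: pd.DataFrame, params: SweepParams | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Significant windows per statistic (strict '>' at each cutoff)."""
    params = params or SweepParams()
    z_fst = scores["z_fst"].to_numpy(dtype=float)
    z_dpi = scores["z_dpi"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        sig_fst = np.where(np.isnan(z_fst), False, z_fst > params.z_fst_cutoff)
        sig_dpi = np.where(np.isnan(z_dpi), False, z_dpi > params.z_dpi_cutoff)
    return {
        "fst": scores.loc[sig_fst].reset_index(drop=True),
        "dpi": scores.loc[sig_dpi].reset_index(drop=True),
    }


def _merge_intervals(df: pd.DataFrame, method: str | None = None) -> pd.DataFrame:
    """Transitive ≥1-bp-overlap merge of half-open intervals.

    Expects columns chrom/start/end and optionally z_fst/z_dpi (their
    maxima are aggregated) and method flags.
    """
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows",
                                     "max_z_fst", "max_z_dpi", "method"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    cur = None
    for rec in df.itertuples(index=False):
        r = rec._asdict()
        if method is not None:
            r.setdefault("method", method)
        if (cur is not None and r["chrom"] == cur["chrom"]
                and r["start"] < cur["end"]):  # >=1 bp shared span
            cur["end"] = max(cur["end"], r["end"])
            cur["n_windows"] += r.get("n_windows", 1)
            cur["max_z_fst"] = np.nanmax([cur["max_z_fst"],
                                          r.get("max_z_fst", r.get("z_fst", np.nan))])
            cur["max_z_dpi"] = np.nanmax([cur["max_z_dpi"],
                                          r.get("max_z_dpi", r.get("z_dpi", np.nan))])
            cur["methods"] |= set(r.get("method", "").split("+")) - {""}
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": r["chrom"],
                "start": int(r["start"]),
                "end": int(r["end"]),
                "n_windows": int(r.get("n_windows", 1)),
                "max_z_fst": float(r.get("max_z_fst", r.get("z_fst", np.nan))),
                "max_z_dpi": float(r.get("max_z_dpi", r.get("z_dpi", np.nan))),
                "methods": set(r.get("method", "").split("+")) - {""},
            }
    rows.append(cur)
    out = pd.DataFrame([{**r, "method": "+".join(sorted(r.pop("methods")))}
                        for r in rows])
    return out[["chrom", "start", "end", "n_windows", "max_z_fst",
                "max_z_dpi", "method"]].reset_index(drop=True)


def merge_to_dss(sig_windows: pd.DataFrame, method: str = "") -> pd.DataFrame:
    """Merge significant windows sharing ≥1 bp into discrete sweeps."""
    return _merge_intervals(sig_windows, method=method)


def union_dss(dss_fst: pd.DataFrame, dss_dpi: pd.DataFrame
              ) -> tuple[pd.DataFrame, dict]:
    """Final DSS call: union of both statistics' DSSs, re-merged.

    Also reports the pairwise overlap between the two input sets (the
    fraction of each set's intervals touched by the other), since the
    two statistics are largely complementary.
    """
    fst = dss_fst.copy()
    dpi = dss_dpi.copy()
    if "method" not in fst.columns or fst.get("method", pd.Series(dtype=str)).eq("").all():
        fst["method"] = "fst"
    if "method" not in dpi.columns or dpi.get("method", pd.Series(dtype=str)).eq("").all():
        dpi["method"] = "dpi"
    nonempty = [d for d in (fst, dpi) if not d.empty]
    if nonempty:
        final = _merge_intervals(pd.concat(nonempty, ignore_index=True))
    else:
        final = _merge_intervals(fst)

    overlap = {
        "fst_overlapped_by_dpi": _overlap_fraction(fst, dpi),
        "dpi_overlapped_by_fst": _overlap_fraction(dpi, fst),
    }
    return final, overlap


def _overlap_fraction(queries: pd.DataFrame, targets: pd.DataFrame) -> float:
    if queries.empty:
        return 0.0
    from .annotate import interval_overlap
    frac, _, _ = interval_overlap(
        list(zip(queries["chrom"], queries["start"], queries["end"])),
        [(c, int(s), int(e), i) for i, (c, s, e) in
         enumerate(zip(targets["chrom"], targets["start"], targets["end"]))],
    )
    return frac


def dss_summary(dss: pd.DataFrame, genome_size: int,
                short_threshold: int = 140_000) -> dict:
    """Count, length distribution and genome fraction of a DSS set."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if dss.empty:
        return {"n_dss": 0, "n_windows": 0, "min_length": 0, "median_length": 0,
                "max_length": 0, "frac_shorter_than_threshold": float("nan"),
                "genome_fraction": 0.0}
    lengths = (dss["end"] - dss["start"]).to_numpy()
    return {
        "n_dss": int(len(dss)),
        "n_windows": int(dss["n_windows"].sum()),
        "min_length": int(lengths.min()),
        "median_length": float(np.median(lengths)),
        "max_length": int(lengths.max()),
        "frac_shorter_than_threshold": float((lengths < short_threshold).mean()),
        "genome_fraction": float(lengths.sum() / genome_size),
    }


def scan_sites_table(sites: pd.DataFrame, chrom_lengths: dict[str, int],
                     group_a: str, group_b: str,
                     params: SweepParams | None = None, seed: int = 0) -> dict:
    """Scan an in-memory site table: windows → null → Z → DSSs.

    The table must already be restricted to scan sites (bi-allelic,
    polymorphic).  Shared by :func:`run_comparison` and the simulation
    drivers, which skip VCF round-tripping.
    """
    params = params or SweepParams()
    from .windows import window_table

    grid = make_windows(chrom_lengths, params.window_size, params.step)
    win = window_table(sites, grid, group_a, group_b)
    nulls = build_null(sites, grid, group_a, group_b,
                       n_replicates=params.n_permutations, seed=seed)
    scores = compute_zscores(win, nulls)
    sig = call_windows(scores, params)
    dss_fst = merge_to_dss(sig["fst"], method="fst")
    dss_dpi = merge_to_dss(sig["dpi"], method="dpi")
    final, overlap = union_dss(dss_fst, dss_dpi)
    summary = dss_summary(final, int(sum(chrom_lengths.values())))
    summary["n_significant_windows_fst"] = int(len(sig["fst"]))
    summary["n_significant_windows_dpi"] = int(len(sig["dpi"]))
    return {"windows": scores, "nulls": nulls, "dss_fst": dss_fst,
            "dss_dpi": dss_dpi, "dss": final, "overlap": overlap,
            "summary": summary}


def simulate_and_scan(config, params: SweepParams | None = None,
                      seed: int | None = None) -> dict:
    """Simulate a cohort and scan group G0 against G1, all in memory.

    ``seed`` defaults to the simulation seed; it drives the permutation
    null.  Returns the scan artifact dict plus ``truth`` and
    ``scan_sites``.
    """
    from .simdata import (sample_genotypes, simulate_site_frequencies,
                          sites_from_genotypes)

    params = params or SweepParams()
    seed = config.seed if seed is None else seed
    freqs = simulate_site_frequencies(config)
    geno = sample_genotypes(freqs, config.individuals_per_group, config.seed,
                            config.missing_rate)
    sites = sites_from_genotypes(freqs, geno, config.group_names,
                                 config.individuals_per_group)
    scan_sites = variants.select_scan_sites(
        sites.assign(is_snp=True, biallelic=True))
    res = scan_sites_table(scan_sites, config.chrom_lengths,
                           config.group_names[0], config.group_names[1],
                           params, seed=seed)
    res["truth"] = config.truth()
    res["scan_sites"] = scan_sites
    return res


def run_comparison(vcf_path: str, pop_map: dict[str, str] | str,
                   comparison: Comparison, params: SweepParams | None = None,
                   seed: int = 0, out_dir: str | None = None,
                   chrom_lengths: dict[str, int] | None = None,
                   chromosomes: list[str] | None = None) -> dict:
    """Run one full sweep scan for a comparison; optionally write outputs.

    Returns a dict with the stage artifacts: ``sites``, ``scan_sites``,
    ``windows`` (scored), ``nulls``, ``dss_fst``, ``dss_dpi``, ``dss``
    (final), ``overlap`` and ``summary``.
    """
    params = params or SweepParams()
    if isinstance(pop_map, str):
        pop_map = variants.read_pop_map(pop_map)

    # pool each side's map groups under one label
    relabel = {}
    for g in comparison.groups_a:
        relabel[g] = "A"
    for g in comparison.groups_b:
        relabel[g] = "B"
    pooled_map = {s: relabel[g] for s, g in pop_map.items() if g in relabel}

    sites = variants.read_sites(vcf_path, pooled_map, groups=["A", "B"])
    kept, removed = variants.apply_hard_filters(sites)
    scan_sites = variants.select_scan_sites(kept, chromosomes=chromosomes)

    lengths = chrom_lengths or sites.attrs.get("chrom_lengths") or {}
    if not lengths:
        raise ValueError("chromosome lengths unavailable: pass chrom_lengths "
                         "or use a VCF with ##contig headers")
    result = scan_sites_table(scan_sites, lengths, "A", "B", params, seed=seed)
    scores = result["windows"]
    final = result["dss"]
    nulls = result["nulls"]
    summary = result["summary"]
    overlap = result["overlap"]
    result.update({"sites": sites, "kept": kept, "removed": removed,
                   "scan_sites": scan_sites})

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        scores.to_csv(os.path.join(out_dir, "windows.tsv"), sep="\t", index=False)
        final.to_csv(os.path.join(out_dir, "dss.tsv"), sep="\t", index=False)
        final[["chrom", "start", "end"]].to_csv(
            os.path.join(out_dir, "dss.bed"), sep="\t", index=False, header=False)
        null_rows = [{"statistic": m.statistic, "K": m.n_replicates,
                      "seed": m.seed, "mu": m.mu, "sigma": m.sigma,
                      "n_pooled": m.n_pooled} for m in nulls.values()]
        pd.DataFrame(null_rows).to_csv(
            os.path.join(out_dir, "null_summary.tsv"), sep="\t", index=False)
        manifest = {
            "comparison": comparison.label,
            "groups_a": list(comparison.groups_a),
            "groups_b": list(comparison.groups_b),
            "params": {"window_size": params.window_size, "step": params.step,
                       "n_permutations": params.n_permutations,
                       "z_fst_cutoff": params.z_fst_cutoff,
                       "z_dpi_cutoff": params.z_dpi_cutoff},
            "seed": seed,
            "summary": summary,
            "overlap": overlap,
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    return result
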
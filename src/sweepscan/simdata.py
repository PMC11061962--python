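"""Synthetic two-group diploid genotype data with planted selective sweeps.

The generator draws per-group allele frequencies under the Balding–Nichols
model: given an ancestral frequency ``p`` and a drift parameter ``F`` in
(0, 1), each group's frequency is Beta-distributed with

    p_i ~ Beta(p (1 - F) / F,  (1 - p)(1 - F) / F),

which has mean ``p`` and variance ``F p (1 - p)``.  Groups and sites are
independent; no linkage is simulated.

A planted sweep modifies the *target* group inside a genomic interval: its
frequency is drawn with an elevated drift parameter ``F_sweep`` and then
pushed deterministically toward the nearer allele-frequency boundary with
strength ``s``:

    p' = p (1 - s)        if p < 0.5
    p' = p + s (1 - p)    otherwise.

This produces both elevated between-group differentiation and reduced
within-group diversity in the sweep interval — the two signals the window
scan looks for.

Genotypes are sampled as diploid dosages ``g ~ Binomial(2, p_i)`` per
individual, and the dataset is emitted as a VCF v4.2 file with GT fields
and GATK-style INFO metrics, a two-column population map, and a BED file
of the true sweep intervals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SweepSpec",
    "SimulationConfig",
    "SweepTruth",
    "simulate_site_frequencies",
    "sample_genotypes",
    "sites_from_genotypes",
    "emit_dataset",
]

# INFO values written for sites that pass every hard filter.
PASSING_INFO = {
    "QD": 25.0,
    "FS": 1.0,
    "MQ": 60.0,
    "SOR": 1.0,
    "MQRankSum": 0.0,
    "ReadPosRankSum": 0.0,
    "InbreedingCoeff": 0.0,
}

# Single-metric values that trip the SNP hard filters.
FAILING_INFO = {
    "QD": 1.0,
    "FS": 100.0,
    "MQ": 30.0,
    "SOR": 5.0,
    "MQRankSum": -20.0,
    "ReadPosRankSum": -10.0,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: interval on one chromosome, acting on one group.

    ``start``/``end`` are 0-based half-open base-pair coordinates.
    ``f_sweep`` is the elevated Balding–Nichols drift parameter used for
    the target group inside the interval; ``s`` is the boundary-push
    strength in [0, 1].
    """

    chrom: str
    start: int
    end: int
    target_group: int
    f_sweep: float = 0.6
    s: float = 0.9

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"sweep interval empty: [{self.start}, {self.end})")
        if not 0.0 < self.f_sweep < 1.0:
            raise ValueError("f_sweep must lie in (0, 1)")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("push strength s must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``snp_density`` is the expected number of variant sites per bp
    (0.005 corresponds to ~50,000 sites on a 10 Mb chromosome).
    ``f_bg`` is the neutral background divergence between the groups.
    ``info_failure_rate`` is the fraction of emitted sites given exactly
    one filter-failing INFO metric.
    """

    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 10_000_000})
    snp_density: float = 0.005
    n_groups: int = 2
    individuals_per_group: int = 25
    f_bg: float = 0.05
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    sweeps: tuple[SweepSpec, ...] = ()
    info_failure_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.f_bg < 1.0:
            raise ValueError("f_bg must lie in (0, 1)")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")
        if self.n_groups < 2:
            raise ValueError("need at least two groups")
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {sw.chrom!r}")
            if sw.end > self.chrom_lengths[sw.chrom]:
                raise ValueError("sweep interval extends past chromosome end")
            if sw.target_group >= self.n_groups:
                raise ValueError("sweep target group out of range")

    @property
    def group_names(self) -> list[str]:
        return [f"G{i}" for i in range(self.n_groups)]

    def truth(self) -> "SweepTruth":
        return SweepTruth(
            [(sw.chrom, sw.start, sw.end, sw.target_group) for sw in self.sweeps]
        )


@dataclass(frozen=True)
class SweepTruth:
    """The planted sweep intervals, for recovery scoring."""

    intervals: list[tuple[str, int, int, int]]

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, grp in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\tsweep_G{grp}\n")

    @classmethod
    def from_bed(cls, path: str) -> "SweepTruth":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, start, end, name = line.split()[:4]
                rows.append((chrom, int(start), int(end), int(name.rsplit("G", 1)[1])))
        return cls(rows)


def _bn_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols Beta draw with mean p and variance f*p*(1-p)."""
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))


def sweep_push(p: np.ndarray, s: float) -> np.ndarray:
    """Push frequencies toward the nearer boundary with strength s."""
    p = np.asarray(p, dtype=float)
    return np.where(p < 0.5, p * (1.0 - s), p + s * (1.0 - p))


def simulate_site_frequencies(config: SimulationConfig) -> pd.DataFrame:
    """Draw site positions and per-group allele frequencies.

    Returns a DataFrame with columns ``chrom``, ``pos`` (1-based),
    ``p_anc`` and one ``p_{group}`` column per group.  Positions are
    strictly increasing within each chromosome.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5175]))
    frames = []
    lo, hi = config.ancestral_range
    for chrom, length in config.chrom_lengths.items():
        n_sites = rng.poisson(length * config.snp_density)
        pos0 = np.unique(rng.integers(0, length, size=n_sites))
        p_anc = rng.uniform(lo, hi, size=pos0.size)
        cols = {"chrom": chrom, "pos": pos0 + 1, "p_anc": p_anc}
        for gi, gname in enumerate(config.group_names):
            p_g = _bn_draw(rng, p_anc, config.f_bg)
            for sw in config.sweeps:
                if sw.chrom != chrom or sw.target_group != gi:
                    continue
                mask = (pos0 >= sw.start) & (pos0 < sw.end)
                if mask.any():
                    swept = _bn_draw(rng, p_anc[mask], sw.f_sweep)
                    p_g[mask] = sweep_push(swept, sw.s)
            cols[f"p_{gname}"] = p_g
        frames.append(pd.DataFrame(cols))
    out = pd.concat(frames, ignore_index=True)
    return out


def sample_genotypes(
    freqs: pd.DataFrame,
    individuals_per_group: int,
    seed: int,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Sample diploid dosages, one Binomial(2, p_i) draw per individual.

    Returns an int8 matrix of shape (n_sites, n_groups * individuals_per
    _group) with dosages in {0, 1, 2}; missing genotypes are coded -1.
    Column blocks follow the group order of the frequency table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E07]))
    group_cols = [c for c in freqs.columns if c.startswith("p_") and c != "p_anc"]
    n_sites = len(freqs)
    geno = np.empty((n_sites, len(group_cols) * individuals_per_group), dtype=np.int8)
    for gi, col in enumerate(group_cols):
        p = freqs[col].to_numpy()[:, None]
        block = rng.binomial(2, p, size=(n_sites, individuals_per_group))
        geno[:, gi * individuals_per_group : (gi + 1) * individuals_per_group] = block
    if missing_rate > 0:
        miss = rng.random(geno.shape) < missing_rate
        geno[miss] = -1
    return geno


def sites_from_genotypes(freqs: pd.DataFrame, geno: np.ndarray,
                         group_names: list[str],
                         individuals_per_group: int) -> pd.DataFrame:
    """Build a per-site summary table straight from simulated genotypes.

    The columns match what :func:`sweepscan.variants.read_sites` produces
    from a VCF, so downstream stages can run without file I/O.
    """
    from .variants import site_table_from_counts

    cols = {"chrom": freqs["chrom"].to_numpy(), "pos": freqs["pos"].to_numpy()}
    counts = {}
    for gi, g in enumerate(group_names):
        block = geno[:, gi * individuals_per_group : (gi + 1) * individuals_per_group]
        called = block >= 0
        counts[g] = {
            "n": called.sum(axis=1),
            "ac": np.where(block > 0, block, 0).sum(axis=1),
            "het": (block == 1).sum(axis=1),
        }
    return site_table_from_counts(cols, counts)


def _ref_alt(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def emit_dataset(config: SimulationConfig, out_dir: str,
                 prefix: str = "cohort") -> dict[str, str]:
    """Simulate and write VCF + population map + truth BED.

    Returns a dict of file paths (``vcf``, ``pop_map``, ``truth``).
    All randomness is driven by ``config.seed``; repeated calls produce
    byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    freqs = simulate_site_frequencies(config)
    geno = sample_genotypes(freqs, config.individuals_per_group, config.seed,
                            config.missing_rate)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xEB17]))
    n_sites = len(freqs)
    ref, alt = _ref_alt(rng, n_sites)

    info_keys = list(PASSING_INFO)
    info_vals = np.tile(
        np.array([PASSING_INFO[k] for k in info_keys]), (n_sites, 1)
    )
    if config.info_failure_rate > 0:
        fail = rng.random(n_sites) < config.info_failure_rate
        fail_keys = list(FAILING_INFO)
        which = rng.integers(0, len(fail_keys), size=n_sites)
        for j, key in enumerate(fail_keys):
            col = info_keys.index(key)
            rows = fail & (which == j)
            info_vals[rows, col] = FAILING_INFO[key]

    sample_names = [
        f"{g}_s{i:03d}"
        for g in config.group_names
        for i in range(config.individuals_per_group)
    ]

    vcf_path = os.path.join(out_dir, f"{prefix}.vcf")
    gt_codes = np.array(["0/0", "0/1", "1/1", "./."])
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan-simdata\n")
        for chrom, length in config.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for key in info_keys:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        chroms = freqs["chrom"].to_numpy()
        positions = freqs["pos"].to_numpy()
        gt_idx = np.where(geno < 0, 3, geno)
        for i in range(n_sites):
            info = ";".join(
                f"{k}={info_vals[i, j]:g}" for j, k in enumerate(info_keys)
            )
            gts = "\t".join(gt_codes[gt_idx[i]])
            fh.write(
                f"{chroms[i]}\t{positions[i]}\t.\t{ref[i]}\t{alt[i]}\t100\t.\t"
                f"{info}\tGT\t{gts}\n"
            )

    map_path = os.path.join(out_dir, f"{prefix}.popmap.tsv")
    with open(map_path, "w") as fh:
        for g in config.group_names:
            for i in range(config.individuals_per_group):
                fh.write(f"{g}_s{i:03d}\t{g}\n")

    truth_path = os.path.join(out_dir, f"{prefix}.truth.bed")
    config.truth().to_bed(truth_path)

    return {"vcf": vcf_path, "pop_map": map_path, "truth": truth_path}
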
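"""Descriptive population-genetic summaries: mean π, MAF spectra, LD decay.

The minor-allele-frequency spectrum folds frequencies to
MAF = min(p, 1 - p) and bins them into rare (< 0.005), low-frequency
([0.005, 0.01]) and common (> 0.01) classes — the three thresholds
partition [0, 0.5].

Linkage disequilibrium is measured as composite r²: the squared Pearson
correlation of unphased genotype dosages between two sites, over
individuals called at both.  The LD decay rate is the smallest
distance-bin midpoint at which mean r² first falls to 0.2 or below
(undefined when it never does within the maximum distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MAFSpectrum", "LDResult", "group_mean_pi", "maf_spectrum",
           "ld_decay"]

MAF_RARE = 0.005
MAF_COMMON = 0.01
LD_DECAY_R2 = 0.2


@dataclass(frozen=True)
class MAFSpectrum:
    """Folded site-frequency spectrum in the three named bins, per class."""

    table: pd.DataFrame  # columns: class, bin, count, density


@dataclass(frozen=True)
class LDResult:
    """Binned mean r² versus distance and the first-crossing decay rate."""

    table: pd.DataFrame  # columns: bin_midpoint_bp, mean_r2, n_pairs
    decay_rate_bp: float  # NaN when r² never reaches 0.2


def group_mean_pi(window_pi: np.ndarray) -> float:
    """Arithmetic mean of window π over windows with data (NaN-excluded)."""
    vals = np.asarray(window_pi, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def _maf_bin(maf: np.ndarray, rare: float, common: float) -> np.ndarray:
    out = np.where(maf < rare, "rare",
                   np.where(maf <= common, "low", "common"))
    return out


def maf_spectrum(freqs: np.ndarray, classes: np.ndarray | None = None,
                 rare: float = MAF_RARE, common: float = MAF_COMMON
                 ) -> MAFSpectrum:
    """Fold frequencies to MAF and bin per SNP class.

    ``classes`` optionally labels each site (e.g. synonymous /
    nonsynonymous); densities are normalised within class.
    """
    p = np.asarray(freqs, dtype=float)
    maf = np.minimum(p, 1.0 - p)
    if classes is None:
        classes = np.full(p.shape, "all")
    classes = np.asarray(classes)
    bins = _maf_bin(maf, rare, common)
    rows = []
    for cls in pd.unique(classes):
        sel = classes == cls
        total = int(sel.sum())
        for b in ("rare", "low", "common"):
            count = int((bins[sel] == b).sum())
            rows.append({"class": cls, "bin": b, "count": count,
                         "density": count / total if total else float("nan")})
    return MAFSpectrum(pd.DataFrame(rows))


def ld_decay(dosages: np.ndarray, positions: np.ndarray,
             max_distance: int = 300_000, bin_width: int = 100,
             r2_threshold: float = LD_DECAY_R2) -> LDResult:
    """Composite-LD decay: mean r² per distance bin and the decay rate.

    ``dosages`` is sites × individuals with values in {0, 1, 2} and -1
    for missing; ``positions`` are bp coordinates on one chromosome.
    Pairs with zero dosage variance (monomorphic in the called subset)
    are excluded.
    """
    geno = np.asarray(dosages, dtype=float)
    pos = np.asarray(positions, dtype=np.int64)
    order = np.argsort(pos, kind="mergesort")
    geno = geno[order]
    pos = pos[order]
    geno[geno < 0] = np.nan

    n_sites = geno.shape[0]
    n_bins = int(np.ceil(max_distance / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    for i in range(n_sites):
        j = i + 1
        while j < n_sites and pos[j] - pos[i] <= max_distance:
            d = pos[j] - pos[i]
            if d > 0:
                both = ~np.isnan(geno[i]) & ~np.isnan(geno[j])
                if both.sum() >= 2:
                    x, y = geno[i, both], geno[j, both]
                    vx, vy = x.var(), y.var()
                    if vx > 0 and vy > 0:
                        r = np.corrcoef(x, y)[0, 1]
                        b = min(int((d - 1) // bin_width), n_bins - 1)
                        sums[b] += r * r
                        counts[b] += 1
            j += 1

    midpoints = (np.arange(n_bins) + 0.5) * bin_width
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame({"bin_midpoint_bp": midpoints, "mean_r2": mean_r2,
                          "n_pairs": counts})
    decay = float("nan")
    for mid, r2, n in zip(midpoints, mean_r2, counts):
        if n > 0 and r2 <= r2_threshold:
            decay = float(mid)
            break
    return LDResult(table, decay)
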
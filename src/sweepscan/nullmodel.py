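"""Permutation null model and Z-scoring for the window scan.

The null distribution of each window statistic is obtained by shuffling
the per-site allele-frequency records across the fixed genomic positions:
each site's complete payload (both groups' sample sizes, frequencies,
heterozygosities and per-site π, as one tuple) is reassigned to a
position by a uniform random permutation over all sites genome-wide.
This preserves every site's internal consistency and the genome-wide
multiset of payloads exactly; what it destroys is the spatial clustering
of unusual sites, which is what the windows detect.

Window statistics are recomputed for each of K permutation replicates
(default 100) and pooled over all scored windows of all replicates into a
single null mean and sample standard deviation per statistic (N - 1
denominator).  Observed windows are then Z-scored:

    Z_FST(i)  = (F_ST(i)  - mu_FST_null)  / sigma_FST_null
    Z_dpi(i)  = (|Δπ(i)|  - mu_dpi_null)  / sigma_dpi_null

Because the payload permutation does not change which positions carry
sites, window site counts are invariant across replicates; only the
payload-to-position assignment varies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import WindowGrid, site_fst_components, window_fst, window_pi

__all__ = ["NullModel", "DegenerateNullError", "permute_sites", "build_null",
           "compute_zscores"]

PAYLOAD_PREFIXES = ("n_", "ac_", "het_", "p_", "h_", "pi_", "usable_")


class DegenerateNullError(RuntimeError):
    """All permuted windows identical: the null SD is zero, no scan possible."""


@dataclass(frozen=True)
class NullModel:
    """Pooled permutation-null moments for one window statistic."""

    statistic: str          # "fst" or "abs_delta_pi"
    n_replicates: int
    seed: int
    mu: float
    sigma: float
    n_pooled: int

    def zscore(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mu) / self.sigma


def _payload_columns(sites: pd.DataFrame) -> list[str]:
    return [c for c in sites.columns
            if any(c.startswith(p) for p in PAYLOAD_PREFIXES)]


def permute_sites(sites: pd.DataFrame, seed: int | np.random.Generator
                  ) -> pd.DataFrame:
    """Reassign per-site payload tuples to positions uniformly at random.

    Genomic coordinates (and any other non-payload columns) stay in
    place; the per-group summary columns are permuted jointly as rows.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    perm = rng.permutation(len(sites))
    out = sites.copy()
    cols = _payload_columns(sites)
    out[cols] = sites[cols].to_numpy()[perm]
    return out


def build_null(sites: pd.DataFrame, grid: WindowGrid, group_a: str,
               group_b: str, n_replicates: int = 100, seed: int = 0,
               keep_replicates: bool = False
               ) -> dict[str, NullModel] | tuple[dict[str, NullModel], dict]:
    """Permutation null models for window F_ST and |Δπ|.

    Per replicate the payload permutation is applied and all window
    statistics recomputed; window values are pooled over replicates.
    Since the per-site variance components and π depend on the payload
    only, permuting the payload is equivalent to permuting the
    precomputed per-site arrays, which is what this function does.

    Raises :class:`DegenerateNullError` when a pooled SD is zero.
    """
    if n_replicates < 2:
        raise ValueError("need at least two permutation replicates")
    rng = np.random.default_rng(seed)

    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    site_idx, win_idx, n_windows = grid.site_window_map(chrom, pos)
    lengths = grid.windows()["length"].to_numpy()
    scored = np.bincount(win_idx, minlength=n_windows) > 0

    a, b, c = site_fst_components(
        sites[f"n_{group_a}"], sites[f"p_{group_a}"], sites[f"h_{group_a}"],
        sites[f"n_{group_b}"], sites[f"p_{group_b}"], sites[f"h_{group_b}"],
    )
    a = np.asarray(a)
    abc = np.asarray(a) + b + c
    pi_a = np.where(sites[f"usable_{group_a}"].to_numpy(),
                    sites[f"pi_{group_a}"].to_numpy(dtype=float), 0.0)
    pi_b = np.where(sites[f"usable_{group_b}"].to_numpy(),
                    sites[f"pi_{group_b}"].to_numpy(dtype=float), 0.0)

    fst_pool, dpi_pool = [], []
    archive = {"fst": [], "abs_delta_pi": []}
    for _ in range(n_replicates):
        perm = rng.permutation(len(sites))
        fst = window_fst(a[perm], abc[perm] - a[perm], np.zeros_like(a),
                         site_idx, win_idx, n_windows)
        wa = window_pi(pi_a[perm], np.ones(len(sites), bool), site_idx, win_idx,
                       n_windows, lengths)
        wb = window_pi(pi_b[perm], np.ones(len(sites), bool), site_idx, win_idx,
                       n_windows, lengths)
        dpi = np.abs(wa - wb)[scored]
        fst_pool.append(fst[np.isfinite(fst)])
        dpi_pool.append(dpi)
        if keep_replicates:
            archive["fst"].append(fst)
            archive["abs_delta_pi"].append(
                np.where(scored, np.abs(wa - wb), np.nan))

    models: dict[str, NullModel] = {}
    for name, pool in (("fst", fst_pool), ("abs_delta_pi", dpi_pool)):
        pooled = np.concatenate(pool)
        mu = float(pooled.mean())
        sigma = float(pooled.std(ddof=1))
        if sigma == 0.0:
            raise DegenerateNullError(
                f"permutation null for {name} is degenerate (sigma = 0); "
                "all windows are identical under permutation")
        models[name] = NullModel(name, n_replicates, seed, mu, sigma,
                                 int(pooled.size))
    if keep_replicates:
        return models, archive
    return models


def compute_zscores(windows: pd.DataFrame,
                    nulls: dict[str, NullModel]) -> pd.DataFrame:
    """Attach Z-scores for each window statistic (affine transform).

    Undefined statistics (NaN) propagate as NaN Z-scores.
    """
    out = windows.copy()
    out["z_fst"] = nulls["fst"].zscore(out["fst"].to_numpy())
    out["z_dpi"] = nulls["abs_delta_pi"].zscore(out["abs_delta_pi"].to_numpy())
    return out
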
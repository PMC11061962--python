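"""Sliding windows and per-window Weir–Cockerham F_ST, π and |Δπ|.

The two-population Weir–Cockerham (1984) variance components are computed
per site from sample sizes ``n_i``, alternate-allele frequencies ``p_i``
and observed heterozygote fractions ``h_i`` (r = 2 groups):

    n_bar = (n_1 + n_2) / 2
    n_c   = (2 n_bar - (n_1^2 + n_2^2) / (2 n_bar))
    p_bar = (n_1 p_1 + n_2 p_2) / (2 n_bar)
    s2    = (n_1 (p_1 - p_bar)^2 + n_2 (p_2 - p_bar)^2) / n_bar
    h_bar = (n_1 h_1 + n_2 h_2) / (2 n_bar)

    a = (n_bar / n_c) [ s2 - (p_bar (1-p_bar) - s2/2 - h_bar/4) / (n_bar - 1) ]
    b = (n_bar / (n_bar - 1)) [ p_bar (1-p_bar) - s2/2 - h_bar (2 n_bar - 1)/(4 n_bar) ]
    c = h_bar / 2

A window's F_ST is the ratio of sums Σa / Σ(a+b+c) over its usable sites
(the standard window weighting); windows whose denominator is zero are
undefined and excluded from scoring.  Negative window F_ST values are
retained — the downstream Z-transform handles location and scale, and
flooring would bias the permutation null.

Window π divides the summed per-site π by the window length in bp (the
convention of the common windowed-π tools), so |Δπ| is comparable across
windows; truncated terminal windows use their true length.

All interval arithmetic is 0-based half-open; VCF positions are converted
on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowGrid",
    "make_windows",
    "site_fst_components",
    "window_fst",
    "window_pi",
    "window_table",
]


@dataclass(frozen=True)
class WindowGrid:
    """A genome-wide sliding-window grid (0-based half-open intervals)."""

    chrom_lengths: dict[str, int]
    size: int = 40_000
    step: int = 20_000

    def __post_init__(self) -> None:
        if self.size <= 0 or self.step <= 0:
            raise ValueError("window size and step must be positive")
        if self.step > self.size:
            raise ValueError("step must not exceed window size")

    def windows(self) -> pd.DataFrame:
        """All windows as a DataFrame (chrom, start, end, length)."""
        chroms, starts, ends = [], [], []
        for chrom, length in self.chrom_lengths.items():
            start = 0
            while start < length:
                chroms.append(chrom)
                starts.append(start)
                ends.append(min(start + self.size, length))
                start += self.step
        starts_a = np.array(starts, dtype=np.int64)
        ends_a = np.array(ends, dtype=np.int64)
        return pd.DataFrame({
            "chrom": chroms,
            "start": starts_a,
            "end": ends_a,
            "length": ends_a - starts_a,
        })

    def site_window_map(self, chrom: np.ndarray, pos: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, int]:
        """Map sites (1-based pos) to the global window ids containing them.

        Returns (site_index, window_index, n_windows): parallel arrays
        with one entry per (site, window) incidence.
        """
        win = self.windows()
        n_windows = len(win)
        offsets: dict[str, tuple[int, int]] = {}
        for c in win["chrom"].unique():
            idx = np.flatnonzero((win["chrom"] == c).to_numpy())
            offsets[c] = (int(idx[0]), int(idx[-1]))
        pos0 = np.asarray(pos, dtype=np.int64) - 1
        site_idx_parts, win_idx_parts = [], []
        chrom = np.asarray(chrom)
        for c, (off_lo, off_hi) in offsets.items():
            in_c = np.flatnonzero(chrom == c)
            if in_c.size == 0:
                continue
            p0 = pos0[in_c]
            m_hi = p0 // self.step
            m_lo = np.maximum((p0 - self.size) // self.step + 1, 0)
            n_per = (m_hi - m_lo + 1).astype(np.int64)
            site_idx = np.repeat(in_c, n_per)
            # enumerate m_lo..m_hi per site
            cum = np.concatenate([[0], np.cumsum(n_per)])
            local = np.arange(cum[-1]) - np.repeat(cum[:-1], n_per)
            m = np.repeat(m_lo, n_per) + local
            keep = m <= (off_hi - off_lo)
            site_idx_parts.append(site_idx[keep])
            win_idx_parts.append(m[keep] + off_lo)
        if site_idx_parts:
            return (np.concatenate(site_idx_parts),
                    np.concatenate(win_idx_parts), n_windows)
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), n_windows)


def make_windows(chrom_lengths: dict[str, int], size: int = 40_000,
                 step: int = 20_000) -> WindowGrid:
    """Build the sliding-window grid (defaults 40 kb windows, 20 kb step)."""
    return WindowGrid(dict(chrom_lengths), size, step)


def site_fst_components(n1, p1, h1, n2, p2, h2):
    """Per-site Weir–Cockerham variance components (a, b, c) for r = 2.

    Vectorized over sites.  Sites where either group has fewer than two
    called individuals, or where n_c = 0, yield NaN components (callers
    treat those sites as unusable).  Sites monomorphic in both groups
    yield exact zeros.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        inner = p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0

    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(n_c) | (n_c == 0) | (n_bar <= 1)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def _window_sums(values: np.ndarray, site_idx: np.ndarray, win_idx: np.ndarray,
                 n_windows: int) -> np.ndarray:
    v = values[site_idx]
    ok = np.isfinite(v)
    return np.bincount(win_idx[ok], weights=v[ok], minlength=n_windows)


def window_fst(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               site_idx: np.ndarray, win_idx: np.ndarray,
               n_windows: int) -> np.ndarray:
    """Ratio-of-sums window F_ST; NaN where the denominator is zero."""
    num = _window_sums(np.asarray(a, dtype=float), site_idx, win_idx, n_windows)
    den = _window_sums(np.asarray(a, dtype=float) + b + c, site_idx, win_idx,
                       n_windows)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = num / den
    return np.where(den == 0.0, np.nan, fst)


def window_pi(pi_site: np.ndarray, usable: np.ndarray,
              site_idx: np.ndarray, win_idx: np.ndarray,
              n_windows: int, window_lengths: np.ndarray) -> np.ndarray:
    """Window π = (Σ per-site π) / window length in bp.

    Windows without usable sites for the group report π = 0 (absence of
    observed diversity is itself signal); callers drop windows that are
    empty for every statistic.
    """
    vals = np.where(np.asarray(usable, dtype=bool),
                    np.asarray(pi_site, dtype=float), 0.0)
    sums = _window_sums(vals, site_idx, win_idx, n_windows)
    return sums / np.asarray(window_lengths, dtype=float)


def window_table(sites: pd.DataFrame, grid: WindowGrid,
                 group_a: str, group_b: str) -> pd.DataFrame:
    """Per-window scan statistics for one comparison.

    Returns the grid's window frame with columns ``n_sites``, ``fst``,
    ``pi_A``, ``pi_B`` and ``abs_delta_pi``.  Windows with no usable
    site for either statistic are dropped.
    """
    win = grid.windows()
    site_idx, win_idx, n_windows = grid.site_window_map(
        sites["chrom"].to_numpy(), sites["pos"].to_numpy())

    a, b, c = site_fst_components(
        sites[f"n_{group_a}"], sites[f"p_{group_a}"], sites[f"h_{group_a}"],
        sites[f"n_{group_b}"], sites[f"p_{group_b}"], sites[f"h_{group_b}"],
    )
    fst = window_fst(a, b, c, site_idx, win_idx, n_windows)

    lengths = win["length"].to_numpy()
    pi_a = window_pi(sites[f"pi_{group_a}"].to_numpy(),
                     sites[f"usable_{group_a}"].to_numpy(),
                     site_idx, win_idx, n_windows, lengths)
    pi_b = window_pi(sites[f"pi_{group_b}"].to_numpy(),
                     sites[f"usable_{group_b}"].to_numpy(),
                     site_idx, win_idx, n_windows, lengths)

    n_sites = np.bincount(win_idx, minlength=n_windows).astype(np.int64)

    out = win.copy()
    out["n_sites"] = n_sites
    out["fst"] = fst
    out["pi_A"] = pi_a
    out["pi_B"] = pi_b
    out["abs_delta_pi"] = np.abs(pi_a - pi_b)
    # no usable site at all -> no information for either statistic
    out.loc[n_sites == 0, ["pi_A", "pi_B", "abs_delta_pi"]] = np.nan
    out = out[n_sites > 0].reset_index(drop=True)
    return out
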
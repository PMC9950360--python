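"""Diversity statistics, Tajima's D and the sliding-window selection scan.

Balancing selection maintains both clades at intermediate frequency, which
inflates mean pairwise diversity (pi) relative to the number of segregating
sites and drives Tajima's D strongly positive.  The scan slides a 1.5 kb
window in 100 bp steps across the region, computes S, pi, Watterson's
theta and D per window, and ranks windows jointly by pi and D to localise
the candidate functional segment.

Conventions: window length L is the physical span in bp (a callable-site
mask may be supplied to override it); D uses total (not per-site) S and pi
in Tajima's (1989) normalisation; windows with S < 3 report D as undefined
and are excluded from ranking; missing haplotypes are deleted pairwise per
site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import MISSING, DataError, HaplotypeMatrix


@dataclass
class DiversityStats:
    n: int
    L: float
    S: int
    pi_total: float
    pi_per_site: float
    theta_w_per_site: float
    tajima_d: float | None  # None when undefined (S too small)


def _site_components(matrix: HaplotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant (pairwise-difference sum, polymorphic flag).

    For a site with n_v non-missing haplotypes of which k carry the
    alternate allele, the sum of pairwise differences over all C(n_v, 2)
    haplotype pairs is k (n_v - k); averaging over pairs uses C(n_v, 2)
    per site (pairwise deletion).
    """
    A = matrix.alleles
    miss = A == MISSING
    nv = A.shape[1] - miss.sum(axis=1)
    k = np.where(miss, 0, A).sum(axis=1)
    poly = (k > 0) & (k < nv)
    pairs = nv * (nv - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_diff = np.where(pairs > 0, k * (nv - k) / pairs, 0.0)
    return mean_diff, poly


def seg_sites(matrix: HaplotypeMatrix, interval: tuple[int, int] | None = None) -> int:
    """Number of sites polymorphic among the non-missing haplotypes."""
    sub = matrix if interval is None else matrix.subset_positions(*interval)
    _, poly = _site_components(sub)
    return int(poly.sum())


def nucleotide_diversity(
    matrix: HaplotypeMatrix,
    interval: tuple[int, int] | None = None,
    L: float | None = None,
) -> tuple[float, float]:
    """Mean pairwise differences: (pi_per_site, pi_total).

    pi_total averages Hamming distances over all haplotype pairs with
    pairwise deletion per site; pi_per_site divides by the physical length
    ``L`` (defaults to the interval span).
    """
    sub = matrix if interval is None else matrix.subset_positions(*interval)
    if sub.n_haplotypes < 2:
        raise DataError("nucleotide diversity needs at least 2 haplotypes")
    mean_diff, _ = _site_components(sub)
    pi_total = float(mean_diff.sum())
    if L is None:
        if interval is not None:
            L = interval[1] - interval[0] + 1
        else:
            pos = sub.positions
            L = float(pos[-1] - pos[0] + 1) if len(pos) else 1.0
    return pi_total / L, pi_total


def harmonic_a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's estimator per site: S / (a1 * L) with a1 = sum_{i<n} 1/i."""
    if n < 2:
        raise DataError("Watterson's theta needs n >= 2")
    return S / harmonic_a1(n) / L


def tajima_constants(n: int) -> tuple[float, float]:
    """The (e1, e2) normalising constants of Tajima's D for sample size n."""
    a1 = harmonic_a1(n)
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def tajimas_d_from_parts(S: int, pi_total: float, n: int) -> float | None:
    """D = (pi_total - S/a1) / sqrt(e1 S + e2 S (S-1)); None when S = 0."""
    if S == 0:
        return None
    e1, e2 = tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return (pi_total - S / harmonic_a1(n)) / math.sqrt(var)


def tajimas_d(matrix: HaplotypeMatrix, interval: tuple[int, int] | None = None) -> float | None:
    sub = matrix if interval is None else matrix.subset_positions(*interval)
    mean_diff, poly = _site_components(sub)
    return tajimas_d_from_parts(int(poly.sum()), float(mean_diff.sum()), sub.n_haplotypes)


def diversity_stats(
    matrix: HaplotypeMatrix, interval: tuple[int, int], L: float | None = None
) -> DiversityStats:
    sub = matrix.subset_positions(*interval)
    n = matrix.n_haplotypes
    if L is None:
        L = interval[1] - interval[0] + 1
    mean_diff, poly = _site_components(sub)
    S = int(poly.sum())
    pi_total = float(mean_diff.sum())
    d = tajimas_d_from_parts(S, pi_total, n)
    return DiversityStats(
        n=n,
        L=L,
        S=S,
        pi_total=pi_total,
        pi_per_site=pi_total / L,
        theta_w_per_site=watterson_theta(S, n, L) if n >= 2 else float("nan"),
        tajima_d=d,
    )


# ---------------------------------------------------------------------------
# Sliding scan
# ---------------------------------------------------------------------------


@dataclass
class WindowScan:
    windows: pd.DataFrame  # start, end, n, S, pi_total, pi_per_site, theta_w_per_site, tajima_d
    window_size: int
    step: int

    #: windows with S < this report D as undefined and are excluded from ranking
    MIN_S_FOR_D = 3


def sliding_scan(
    matrix: HaplotypeMatrix,
    region: tuple[int, int],
    window_size: int = 1500,
    step: int = 100,
) -> WindowScan:
    """Windowed S / pi / theta_w / Tajima's D over ``region``.

    Windows start at region_start, region_start + step, ... while the full
    window fits inside the region; each window is [start, start + size - 1].
    """
    start, end = region
    span = end - start + 1
    if span < window_size:
        raise DataError(f"region span {span} bp shorter than one {window_size} bp window")
    mean_diff, poly = _site_components(matrix)
    pos = matrix.positions
    n = matrix.n_haplotypes
    # cumulative sums over variants sorted by position for O(1) window queries
    cum_diff = np.concatenate([[0.0], np.cumsum(mean_diff)])
    cum_poly = np.concatenate([[0], np.cumsum(poly.astype(np.int64))])
    starts = np.arange(start, end - window_size + 2, step, dtype=np.int64)
    rows = []
    a1 = harmonic_a1(n) if n >= 2 else float("nan")
    for ws in starts:
        we = ws + window_size - 1
        lo = np.searchsorted(pos, ws, side="left")
        hi = np.searchsorted(pos, we, side="right")
        S = int(cum_poly[hi] - cum_poly[lo])
        pi_total = float(cum_diff[hi] - cum_diff[lo])
        if S >= WindowScan.MIN_S_FOR_D:
            d = tajimas_d_from_parts(S, pi_total, n)
        else:
            d = None
        rows.append(
            {
                "start": int(ws),
                "end": int(we),
                "n": n,
                "S": S,
                "pi_total": pi_total,
                "pi_per_site": pi_total / window_size,
                "theta_w_per_site": S / a1 / window_size,
                "tajima_d": np.nan if d is None else d,
            }
        )
    return WindowScan(pd.DataFrame(rows), window_size, step)


@dataclass
class RankedWindows:
    ranked: pd.DataFrame  # scan columns + rank_pi, rank_d, rank_sum
    top_segment: tuple[int, int]  # merged span of contiguous rank-1 windows
    tied: bool


def rank_windows(scan: WindowScan) -> RankedWindows:
    """Rank windows jointly by pi and Tajima's D (sum of the two ranks).

    Windows with undefined D are excluded.  The top window(s) — ties on the
    joint rank are all reported and flagged — are merged into a single
    candidate segment when contiguous or overlapping.
    """
    df = scan.windows.dropna(subset=["tajima_d"]).copy()
    if df.empty:
        raise DataError("no window has a defined Tajima's D")
    df["rank_pi"] = df["pi_total"].rank(ascending=False, method="min")
    df["rank_d"] = df["tajima_d"].rank(ascending=False, method="min")
    df["rank_sum"] = df["rank_pi"] + df["rank_d"]
    best = df["rank_sum"].min()
    top = df[df["rank_sum"] == best].sort_values("start")
    tied = len(top) > 1
    seg_start = int(top["start"].iloc[0])
    seg_end = int(top["end"].iloc[0])
    for _, w in top.iloc[1:].iterrows():
        if w["start"] <= seg_end + scan.step:
            seg_end = max(seg_end, int(w["end"]))
    return RankedWindows(df.sort_values("rank_sum"), (seg_start, seg_end), tied)


def empirical_p(observed_d: float, null_d: Sequence[float]) -> float:
    """One-tailed add-one empirical p-value for a positive-D test:
    p = (1 + #{null >= observed}) / (1 + n_null)."""
    null = np.asarray([x for x in null_d if x is not None and not np.isnan(x)])
    if null.size == 0:
        raise DataError("empty null distribution")
    return float((1 + np.sum(null >= observed_d)) / (1 + null.size))
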
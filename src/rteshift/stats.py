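"""Group-comparison statistics.

Self-contained implementations of the tests used for tumour/normal and
stratum comparisons: two-sided Mann-Whitney U (exact by enumeration or
tie-corrected normal approximation with continuity correction),
Kruskal-Wallis H with tie correction, Dunn's pairwise z post hoc,
Student/Welch t (paired and unpaired) and simple linear regression with a
slope t-test. Mid-ranks are used for ties throughout.

These are authored rather than delegated so that exactness and calibration
can be asserted against independent oracles; scipy is used only for the
reference distributions (normal, t, chi-square) themselves.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .intervals import ValidationError


@dataclass
class GroupComparison:
    """Result of a group-comparison test."""

    statistic_name: str
    statistic_value: float
    p: float
    pairwise: list[tuple[int, int, float, float]] | None = None  # (i, j, z, p_adj)


def _rankdata(values: np.ndarray) -> np.ndarray:
    """Mid-ranks (average ranks for ties)."""
    return _sps.rankdata(values, method="average")


def _tie_counts(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts[counts > 1]


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> GroupComparison:
    """Two-sided Mann-Whitney U rank-sum test.

    ``mode``: "exact" enumerates all C(n_x+n_y, n_x) group assignments of
    the (mid-)ranks and computes P(|U - n_x n_y/2| >= observed); it is used
    by "auto" when the number of combinations is <= 20000 and there are no
    ties. Otherwise a tie-corrected normal approximation with continuity
    correction is used. Reports the smaller of U_x and U_y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney requires two non-empty groups")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    rx = ranks[:nx].sum()
    ux = rx - nx * (nx + 1) / 2.0
    uy = nx * ny - ux
    u = min(ux, uy)
    mu = nx * ny / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    n_comb = math.comb(nx + ny, nx)

    if mode not in ("exact", "normal_approx", "auto"):
        raise ValidationError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n_comb <= 20000 and not has_ties)

    if use_exact:
        # enumerate all assignments of nx ranks to group x
        obs_dev = abs(ux - mu)
        count = 0
        idx = range(nx + ny)
        for subset in combinations(idx, nx):
            r = ranks[list(subset)].sum()
            u_sub = r - nx * (nx + 1) / 2.0
            if abs(u_sub - mu) >= obs_dev - 1e-12:
                count += 1
        p = count / n_comb
    else:
        n = nx + ny
        ties = _tie_counts(pooled)
        tie_term = (ties**3 - ties).sum() / (n * (n - 1)) if ties.size else 0.0
        sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            dev = ux - mu
            cc = 0.5 * np.sign(dev)  # continuity correction toward the mean
            z = (dev - cc) / math.sqrt(sigma2) if dev != 0 else 0.0
            p = min(1.0, 2.0 * _sps.norm.sf(abs(z)))
    return GroupComparison("mann_whitney_U", float(u), float(p))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis H test with tie correction, chi-square p on k-1 df."""
    if len(groups) < 3:
        raise ValidationError("kruskal_wallis requires >= 3 groups (use mann_whitney)")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = _rankdata(pooled)
    h = 0.0
    offset = 0
    for a in arrays:
        r = ranks[offset : offset + a.size].sum()
        h += r * r / a.size
        offset += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    ties = _tie_counts(pooled)
    c = 1.0 - (ties**3 - ties).sum() / (n**3 - n) if ties.size else 1.0
    if c <= 0:  # all observations identical
        return GroupComparison("kruskal_wallis_H", 0.0, 1.0)
    h /= c
    p = float(_sps.chi2.sf(h, df=len(arrays) - 1))
    return GroupComparison("kruskal_wallis_H", float(h), p)


def dunn_pairwise(
    groups: Sequence[Sequence[float]], adjust: str = "holm"
) -> list[tuple[int, int, float, float]]:
    """Dunn's pairwise z comparisons after Kruskal-Wallis.

    z_ij = (meanrank_i - meanrank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p,
    adjusted across all pairs (default Holm).
    """
    if adjust not in ("holm", "bonferroni", "none"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    if len(groups) < 3:
        raise ValidationError("dunn_pairwise requires >= 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = _rankdata(pooled)
    meanranks = []
    offset = 0
    for a in arrays:
        meanranks.append(ranks[offset : offset + a.size].mean())
        offset += a.size
    ties = _tie_counts(pooled)
    tie_term = (ties**3 - ties).sum() / (12.0 * (n - 1)) if ties.size else 0.0
    base = n * (n + 1) / 12.0 - tie_term
    pairs: list[tuple[int, int, float]] = []
    raw_p: list[float] = []
    for i, j in combinations(range(len(arrays)), 2):
        se = math.sqrt(base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = (meanranks[i] - meanranks[j]) / se if se > 0 else 0.0
        pairs.append((i, j, z))
        raw_p.append(min(1.0, 2.0 * float(_sps.norm.sf(abs(z)))))
    if adjust == "holm":
        from .enrichment import holm_adjust

        adj = holm_adjust(raw_p)
    elif adjust == "bonferroni":
        adj = [min(1.0, p * len(raw_p)) for p in raw_p]
    else:
        adj = raw_p
    return [(i, j, z, p) for (i, j, z), p in zip(pairs, adj)]


def t_test(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    equal_var: bool = False,
    two_sided: bool = True,
) -> GroupComparison:
    """Student/Welch t-test (default Welch); ``paired`` tests the differences.

    Degenerate zero-variance inputs give p=1 when means are equal and p=0
    (with a warning) when they differ — the data admit no sampling noise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValidationError("paired t-test requires equal lengths")
        d = x - y
        n = d.size
        sd = d.std(ddof=1) if n > 1 else 0.0
        if sd == 0:
            if d.mean() == 0:
                return GroupComparison("t_paired", 0.0, 1.0)
            warnings.warn("zero variance with nonzero mean difference; p=0")
            return GroupComparison("t_paired", math.inf, 0.0)
        t = d.mean() / (sd / math.sqrt(n))
        df = n - 1
        name = "t_paired"
    else:
        nx, ny = x.size, y.size
        if nx < 2 or ny < 2:
            raise ValidationError("t-test requires >= 2 observations per group")
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if vx == 0 and vy == 0:
            if x.mean() == y.mean():
                return GroupComparison("t_welch", 0.0, 1.0)
            warnings.warn("zero variance in both groups with different means; p=0")
            return GroupComparison("t_welch", math.inf, 0.0)
        if equal_var:
            sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
            se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
            df = nx + ny - 2
            name = "t_student"
        else:
            se = math.sqrt(vx / nx + vy / ny)
            df = (vx / nx + vy / ny) ** 2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
            name = "t_welch"
        t = (x.mean() - y.mean()) / se
    p = float(_sps.t.sf(abs(t), df))
    p = min(1.0, (2.0 if two_sided else 1.0) * p)
    return GroupComparison(name, float(t), p)


def linregress(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float, float]:
    """Ordinary least squares y = a + b x.

    Returns (slope, intercept, r2, p_slope) with the slope tested by
    t = b / SE(b) on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or n != y.size:
        raise ValidationError("linregress requires >= 3 paired points")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0:
        warnings.warn("degenerate x variance; slope undefined")
        return math.nan, math.nan, math.nan, math.nan
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    rss = (resid**2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    if rss <= 0:  # perfect fit
        return float(slope), float(intercept), float(r2), 0.0
    se = math.sqrt(rss / (n - 2) / sxx)
    t = slope / se
    p = min(1.0, 2.0 * float(_sps.t.sf(abs(t), n - 2)))
    return float(slope), float(intercept), float(r2), p
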
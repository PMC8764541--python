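"""Rank-based statistical battery used throughout the pipeline.

Implements the Mann-Whitney U test (exact enumeration for small untied
samples, tie- and continuity-corrected normal approximation otherwise), the
Kruskal-Wallis test with the eta-squared effect size, Benjamini-Hochberg
step-up FDR adjustment, and the Steel-Dwass all-pairs comparison using the
large-sample studentized-range approximation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import ndtr
from scipy.stats import chi2, norm, rankdata

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 8


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" | "normal"


@dataclass(frozen=True)
class PairwiseTestResult:
    level_a: str
    level_b: str
    statistic: float
    p: float


@dataclass
class FactorTestResult:
    factor: str
    group_sizes: tuple[int, ...]
    h: float
    eta_squared: float
    eta_squared_raw: float
    p_raw: float
    p_fdr: float | None = None
    followup: list[PairwiseTestResult] = field(default_factory=list)


def _tie_term(pooled: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"empty sample: {name}")
    if np.any(np.isnan(arr)):
        raise ValueError(f"NaN in sample: {name}")
    return arr


def mann_whitney(
    x, y, *, continuity: bool = True, method: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``method="auto"`` enumerates the exact permutation distribution of U when
    both samples have at most 8 observations and the pooled data are tie-free;
    otherwise it uses the normal approximation with tie correction and
    (optionally) continuity correction.
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = (
            "exact"
            if (n1 <= _EXACT_MAX_N and n2 <= _EXACT_MAX_N and not has_ties)
            else "normal"
        )
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires tie-free data")
        return _mann_whitney_exact(x, y)
    if method != "normal":
        raise ValueError(f"unknown method {method!r}")
    return _mann_whitney_normal(x, y, continuity=continuity)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    n1 = len(x)
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> MannWhitneyResult:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    offset = n1 * (n1 + 1) / 2.0
    hits = 0
    for ranks_x in combinations(range(1, n + 1), n1):
        u = sum(ranks_x) - offset
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    p = hits / comb(n, n1)
    return MannWhitneyResult(u=u_obs, p=p, method="exact")


def _mann_whitney_normal(
    x: np.ndarray, y: np.ndarray, *, continuity: bool
) -> MannWhitneyResult:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        warnings.warn("degenerate all-tied input; p set to 1", stacklevel=2)
        return MannWhitneyResult(u=u, p=1.0, method="normal")
    z = (abs(u - mu) - (0.5 if continuity else 0.0)) / sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(ndtr(-z)))
    return MannWhitneyResult(u=u, p=p, method="normal")


def kruskal_wallis_eta2(
    groups: Sequence, factor: str = ""
) -> FactorTestResult:
    """Kruskal-Wallis H (tie-corrected) with the eta-squared effect size.

    eta^2 = (H - k + 1) / (n - k); the raw value is retained and the reported
    value is clipped to [0, 1].  The p-value comes from the chi-squared
    distribution with k - 1 degrees of freedom.
    """
    arrays = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = tuple(len(a) for a in arrays)
    n = sum(sizes)
    if n <= k:
        raise ValueError("total sample size must exceed the number of groups")
    pooled = np.concatenate(arrays)
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for size in sizes:
        r = ranks[start : start + size].sum()
        h += r * r / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    h = 0.0 if correction <= 0 else h / correction
    eta_raw = (h - k + 1) / (n - k)
    eta = float(np.clip(eta_raw, 0.0, 1.0))
    p = float(chi2.sf(h, k - 1))
    return FactorTestResult(
        factor=factor,
        group_sizes=sizes,
        h=float(h),
        eta_squared=eta,
        eta_squared_raw=float(eta_raw),
        p_raw=p,
    )


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def studentized_range_sf(q: float, k: int) -> float:
    """P(range of k iid standard normals > q); the infinite-df studentized range.

    P(Q <= q) = k * Int phi(z) [Phi(z) - Phi(z - q)]^(k-1) dz.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if q <= 0:
        return 1.0

    def integrand(z: float) -> float:
        return k * norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - q)) ** (k - 1)

    cdf, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=1e-12, limit=200)
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def steel_dwass(
    groups: Sequence, labels: Sequence[str] | None = None
) -> list[PairwiseTestResult]:
    """All-pairs rank comparison with familywise control via the studentized range.

    For each pair of groups, ranks are computed within the pair only; the
    standardized (tie-corrected) rank sum t is referred to the studentized
    range with k groups and infinite df through q = t * sqrt(2).
    """
    arrays = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    for i, a in enumerate(arrays):
        if len(a) < 2:
            raise ValueError(f"group {i} has fewer than two observations")
    if labels is None:
        labels = [str(i) for i in range(k)]
    results: list[PairwiseTestResult] = []
    for i, j in combinations(range(k), 2):
        xi, xj = arrays[i], arrays[j]
        ni, nj = len(xi), len(xj)
        n = ni + nj
        ranks = rankdata(np.concatenate([xi, xj]))
        w = ranks[:ni].sum()
        expect = ni * (n + 1) / 2.0
        var = ni * nj / (n * (n - 1.0)) * (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0)
        if var <= 0:
            warnings.warn("degenerate all-tied pair; p set to 1", stacklevel=2)
            results.append(
                PairwiseTestResult(labels[i], labels[j], statistic=0.0, p=1.0)
            )
            continue
        t = abs(w - expect) / sqrt(var)
        p = studentized_range_sf(t * sqrt(2.0), k)
        results.append(PairwiseTestResult(labels[i], labels[j], statistic=t, p=p))
    return results


def factor_screen(
    values: Mapping[str, float] | pd.Series,
    factors: pd.DataFrame,
    factor_names: Sequence[str] | None = None,
    *,
    followup: bool = True,
    min_level_size: int = 2,
) -> list[FactorTestResult]:
    """Kruskal-Wallis screen of one response across categorical factors.

    ``values`` maps sample id -> response (e.g. per-infant shared abundance);
    ``factors`` is a DataFrame of categorical columns indexed by sample id.
    Missing values are dropped per factor.  BH-FDR is applied across the
    screened factors; follow-up is Mann-Whitney for two-level factors and
    Steel-Dwass for three or more levels (levels with fewer than
    ``min_level_size`` observations are excluded from Steel-Dwass).
    """
    series = pd.Series(values, dtype=float)
    if factor_names is None:
        factor_names = list(factors.columns)
    results: list[FactorTestResult] = []
    for name in factor_names:
        if name not in factors.columns:
            raise KeyError(f"unknown factor {name!r}")
        levels = factors[name].reindex(series.index)
        mask = levels.notna() & (levels.astype(str) != "")
        usable = series[mask]
        usable_levels = levels[mask].astype(str)
        uniq = sorted(usable_levels.unique())
        if len(uniq) < 2:
            logger.warning("factor %r has <2 non-missing levels; skipped", name)
            continue
        groups = [usable[usable_levels == lv].to_numpy() for lv in uniq]
        result = kruskal_wallis_eta2(groups, factor=name)
        if followup:
            if len(uniq) == 2:
                mw = mann_whitney(groups[0], groups[1])
                result.followup = [
                    PairwiseTestResult(uniq[0], uniq[1], statistic=mw.u, p=mw.p)
                ]
            else:
                big = [
                    (lv, g) for lv, g in zip(uniq, groups) if len(g) >= min_level_size
                ]
                if len(big) >= 2:
                    result.followup = steel_dwass(
                        [g for _, g in big], labels=[lv for lv, _ in big]
                    )
                else:
                    logger.warning(
                        "factor %r: too few sufficiently large levels for "
                        "all-pairs follow-up",
                        name,
                    )
        results.append(result)
    if results:
        adjusted = benjamini_hochberg([r.p_raw for r in results])
        for r, q in zip(results, adjusted):
            r.p_fdr = float(q)
    return results


def factor_screen_frame(results: Sequence[FactorTestResult]) -> pd.DataFrame:
    """Tabular view of a factor screen (one row per factor)."""
    return pd.DataFrame(
        {
            "factor": [r.factor for r in results],
            "levels": [len(r.group_sizes) for r in results],
            "n": [sum(r.group_sizes) for r in results],
            "H": [r.h for r in results],
            "eta_squared": [r.eta_squared for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_fdr": [r.p_fdr for r in results],
        }
    )
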
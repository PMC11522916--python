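"""Hill-number diversity, sample coverage and rarefaction/extrapolation.

Hill numbers of order q are effective species numbers: q = 0 is species
richness, q = 1 the exponential of Shannon entropy, q = 2 the inverse
Simpson concentration.  Sample coverage — the estimated fraction of the
community's individuals belonging to species seen in the sample — is
estimated from singleton and doubleton counts.  Rarefaction interpolates
the expected diversity at sub-sample sizes via exact hypergeometric
expectations of the abundance frequency counts; extrapolation beyond the
reference sample uses the Chao1-style asymptotic estimators and is capped
at twice the reference size, where the estimators remain stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "hill_number",
    "sample_coverage",
    "coverage_at",
    "rarefaction_curve",
    "cover_to_pseudocounts",
    "DiversityEstimate",
]


@dataclass(frozen=True)
class DiversityEstimate:
    """One point of a rarefaction/extrapolation curve."""

    q: int
    m: int
    estimate: float
    coverage: float
    method: str  # interpolated | observed | extrapolated


def hill_number(p: np.ndarray, q: float) -> float:
    """Hill number of order ``q`` for a relative-abundance vector.

    ``(sum p_i^q)^(1/(1-q))`` for q != 1 and ``exp(-sum p_i ln p_i)`` at
    q = 1 (the analytic limit, not a numerical one).  Zero entries are
    ignored; ``p`` must sum to one.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0 or np.all(p == 0):
        raise ValueError("empty or all-zero abundance vector")
    if np.any(p < 0):
        raise ValueError("negative relative abundances")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"relative abundances sum to {p.sum()}, not 1")
    p = p[p > 0]
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def _validate_counts(counts) -> np.ndarray:
    x = np.asarray(counts)
    if x.size == 0:
        raise ValueError("empty count vector")
    if np.any(x < 0):
        raise ValueError("negative counts")
    if not np.issubdtype(x.dtype, np.integer):
        if not np.allclose(x, np.round(x)):
            raise ValueError(
                "coverage and rarefaction are defined on integer counts; "
                "convert percent cover with cover_to_pseudocounts first"
            )
        x = np.round(x).astype(np.int64)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all counts are zero")
    return x.astype(np.int64)


def sample_coverage(counts) -> float:
    """Chao–Jost estimate of sample coverage from a count vector.

    ``1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)]`` with f1, f2 the
    singleton and doubleton counts; equals 1 when there are no singletons.
    """
    x = _validate_counts(counts)
    n = int(x.sum())
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    denom = (n - 1) * f1 + 2 * f2
    return float(1.0 - (f1 / n) * ((n - 1) * f1 / denom))


def _lchoose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def _A_chao(n: int, f1: int, f2: int) -> float:
    if f1 == 0:
        return 1.0
    if f2 > 0:
        return 2 * f2 / ((n - 1) * f1 + 2 * f2)
    if f1 > 1:
        return 2 / ((n - 1) * (f1 - 1) + 2)
    return 1.0


def _f0_chao1(n: int, f1: int, f2: int) -> float:
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2


def coverage_at(counts, m: int) -> float:
    """Expected sample coverage at sample size ``m`` (interpolated for
    m < n, reference estimate at m = n, extrapolated beyond)."""
    x = _validate_counts(counts)
    n = int(x.sum())
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if m < n:
        # 1 - sum_i (x_i/n) C(n - x_i, m) / C(n - 1, m)
        terms = np.exp(_lchoose(n - x, m) - _lchoose(n - 1, m))
        return float(1.0 - np.sum((x / n) * terms))
    A = _A_chao(n, f1, f2)
    return float(1.0 - (f1 / n) * (1.0 - A) ** (m - n + 1))


def _shannon_obs(x: np.ndarray, n: int) -> float:
    p = x / n
    return float(-np.sum(p * np.log(p)))


def _shannon_chao_jost(x: np.ndarray, n: int) -> float:
    """Chao–Jost nearly unbiased entropy estimator (asymptotic Shannon)."""
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    part = 0.0
    for xi in x:
        if xi <= n - 1:
            part += (xi / n) * np.sum(1.0 / np.arange(xi, n))
    A = _A_chao(n, f1, f2)
    if f1 > 0 and A < 1:
        r = np.arange(1, n)
        tail = -np.log(A) - np.sum((1.0 / r) * (1 - A) ** r)
        part += (f1 / n) * (1 - A) ** (1 - n) * tail
    return float(part)


def _interp_richness(x: np.ndarray, n: int, m: int) -> float:
    return float(np.sum(1.0 - np.exp(_lchoose(n - x, m) - _lchoose(n, m))))


def _interp_shannon(x: np.ndarray, n: int, m: int) -> float:
    # exact E[f_k(m)] under hypergeometric subsampling
    k = np.arange(1, m + 1)
    log_denom = _lchoose(n, m)
    lw = _lchoose(x[:, None], k[None, :]) + _lchoose(
        n - x[:, None], m - k[None, :]
    ) - log_denom
    efk = np.exp(lw).sum(axis=0)
    frac = k / m
    return float(np.exp(-np.sum(frac * np.log(frac) * efk)))


def _simpson_estimate(x: np.ndarray, n: int, m: int) -> float:
    s = np.sum(x * (x - 1.0)) / (n * (n - 1.0)) if n > 1 else 1.0
    return float(1.0 / (1.0 / m + (m - 1.0) / m * s))


def _extrap_richness(x: np.ndarray, n: int, m: int) -> float:
    s_obs = float(x.size)
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    f0 = _f0_chao1(n, f1, f2)
    if f0 == 0:
        return s_obs
    return s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** (m - n))


def _extrap_shannon(x: np.ndarray, n: int, m: int) -> float:
    h_obs = _shannon_obs(x, n)
    h_inf = _shannon_chao_jost(x, n)
    w = n / m
    return float(np.exp(w * h_obs + (1 - w) * max(h_inf, h_obs)))


def rarefaction_curve(counts, q: int, grid=None) -> list[DiversityEstimate]:
    """Rarefaction/extrapolation curve of the order-``q`` Hill number.

    ``grid`` is a sequence of sample sizes; sizes above ``2n`` are
    rejected.  Defaults to 40 knots from 1 to 2n including the reference
    size n, where the curve equals the observed Hill number exactly.
    """
    if q not in (0, 1, 2):
        raise ValueError("q must be 0, 1 or 2")
    x = _validate_counts(counts)
    n = int(x.sum())
    if grid is None:
        grid = np.unique(
            np.concatenate(
                [np.linspace(1, 2 * n, 40).astype(int), [n]]
            )
        )
    grid = np.asarray(grid, dtype=int)
    if np.any(grid <= 0):
        raise ValueError("grid sample sizes must be positive")
    if np.any(grid > 2 * n):
        raise ValueError("extrapolation capped at twice the reference sample size")

    out = []
    for m in grid:
        m = int(m)
        if m <= n:
            if q == 0:
                est = _interp_richness(x, n, m)
            elif q == 1:
                est = _interp_shannon(x, n, m)
            else:
                est = _simpson_estimate(x, n, m)
            method = "observed" if m == n else "interpolated"
        else:
            if q == 0:
                est = _extrap_richness(x, n, m)
            elif q == 1:
                est = _extrap_shannon(x, n, m)
            else:
                est = _simpson_estimate(x, n, m)
            method = "extrapolated"
        out.append(DiversityEstimate(q, m, est, coverage_at(x, m), method))
    return out


def curve_frame(estimates: list[DiversityEstimate], unit: str = "") -> pd.DataFrame:
    """Long-format table of a rarefaction curve."""
    return pd.DataFrame(
        {
            "unit": unit,
            "q": [e.q for e in estimates],
            "m": [e.m for e in estimates],
            "method": [e.method for e in estimates],
            "estimate": [e.estimate for e in estimates],
            "coverage": [e.coverage for e in estimates],
        }
    )


def cover_to_pseudocounts(
    cover_pct, total_length_m: float, resolution_cm: float = 1.0
):
    """Convert line-intercept percent cover to integer pseudo-counts.

    Cover from a tape is a length ratio, not a count, but coverage and
    rarefaction need discrete individuals.  Each taxon's intercepted
    length is discretised at ``resolution_cm`` (default 1 cm of tape =
    one pseudo-individual), a declared, configurable convention.
    """
    cover = np.asarray(cover_pct, dtype=float)
    if total_length_m <= 0:
        raise ValueError("total_length_m must be positive")
    if resolution_cm <= 0:
        raise ValueError("resolution_cm must be positive")
    length_cm = cover / 100.0 * total_length_m * 100.0
    return np.round(length_cm / resolution_cm).astype(np.int64)
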
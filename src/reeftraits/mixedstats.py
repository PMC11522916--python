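"""Random-intercept linear mixed models and ANOVA with LSD letters.

The mixed model is ``y = X b + sum_g Z_g u_g + e`` with independent
random intercepts ``u_g ~ N(0, s2_g I)`` for one or two crossed grouping
factors and residual ``e ~ N(0, s2_e I)``.  Variance components are
estimated by REML, profiling the residual variance and optimising the
variance ratios on the log scale (positivity without constrained
optimisers), with an explicit check of the zero boundary.  Fixed-effect
Wald t-tests use Satterthwaite's approximation: the denominator degrees
of freedom are ``2 g^2 / (grad g' A grad g)`` where ``g`` is the
coefficient variance as a function of the variance components and ``A``
their asymptotic (inverse observed REML information) covariance.

One-way ANOVA with Fisher's LSD post hoc is provided for the per-year
comparisons of assemblage metrics; LSD is deliberately uncorrected for
multiplicity — that is what the method is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LmmFit", "fit_lmm", "satterthwaite_test", "AnovaLsdResult", "anova_lsd"]


def _indicator(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(str)
    levels = sorted(pd.unique(labels))
    z = np.zeros((labels.size, len(levels)))
    for j, lv in enumerate(levels):
        z[:, j] = labels == lv
    return z


@dataclass
class LmmFit:
    """Fitted random-intercept linear mixed model (REML)."""

    params: pd.Series  # fixed-effect estimates
    bse: pd.Series  # standard errors at the REML variance estimates
    vcomp: dict[str, float]  # per random factor + "residual"
    loglik: float  # REML log-likelihood (up to an additive constant)
    converged: bool
    boundary: list[str]  # variance components estimated at zero
    n_obs: int
    n_fixed: int
    # internals needed by the Satterthwaite approximation
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _Z: dict[str, np.ndarray] = field(repr=False, default=None)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        for name in self.params.index:
            t, df, p = satterthwaite_test(self, name)
            rows.append([name, self.params[name], self.bse[name], t, df, p])
        return pd.DataFrame(
            rows, columns=["term", "estimate", "se", "t", "df", "p"]
        ).set_index("term")


def _reml_pieces(theta: np.ndarray, y, X, Zs):
    """Profiled REML for variance ratios theta = s2_g / s2_e."""
    n, p = X.shape
    v0 = np.eye(n)
    for th, z in zip(theta, Zs):
        if th > 0:
            v0 += th * (z @ z.T)
    try:
        L = np.linalg.cholesky(v0)
    except np.linalg.LinAlgError:
        return None
    logdet_v = 2.0 * np.log(np.diag(L)).sum()
    vi_y = np.linalg.solve(v0, y)
    vi_X = np.linalg.solve(v0, X)
    xtvx = X.T @ vi_X
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return None
    beta = np.linalg.solve(xtvx, X.T @ vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(v0, r))
    s2 = quad / (n - p)
    # -2 profiled REML log-likelihood, up to a constant
    dev = (n - p) * np.log(s2) + logdet_v + logdet_x
    return dev, beta, s2, xtvx


def fit_lmm(
    y,
    X: pd.DataFrame,
    groups: dict[str, np.ndarray],
) -> LmmFit:
    """REML fit of a linear mixed model with 1-2 crossed random intercepts.

    ``X`` is the fixed design (include the intercept column yourself or
    via :func:`design_matrix`), ``groups`` maps a factor name to its
    per-observation labels.  Boundary estimates (variance component = 0)
    are allowed and reported in ``boundary``.
    """
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed-effect columns")
    if not 1 <= len(groups) <= 2:
        raise ValueError("supports one or two random-intercept factors")
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < p:
        corr = np.corrcoef(Xv, rowvar=False)
        aliased = [
            (X.columns[i], X.columns[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-8
        ]
        raise ValueError(f"singular fixed design; aliased columns: {aliased}")
    Zs, names = [], []
    for name, labels in groups.items():
        z = _indicator(labels)
        if z.shape[1] < 2:
            raise ValueError(f"random factor {name!r} needs at least 2 levels")
        Zs.append(z)
        names.append(name)

    k = len(Zs)

    def objective(log_theta):
        pieces = _reml_pieces(np.exp(log_theta), yv, Xv, Zs)
        return np.inf if pieces is None else pieces[0]

    # multi-start over interior points plus every boundary configuration
    best = None
    starts = [np.zeros(k), np.full(k, np.log(0.1)), np.full(k, np.log(10.0))]
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    theta = np.exp(best.x)
    best_dev = float(best.fun)
    converged = bool(best.success)

    # explicit boundary check: every configuration with some components at 0
    for mask in itertools.product([False, True], repeat=k):
        mask = np.array(mask)
        if not mask.any():
            continue
        fixed = np.where(mask, 0.0, theta)
        free = ~mask
        if free.any():
            def obj_sub(lt, fixed=fixed, free=free):
                t = fixed.copy()
                t[free] = np.exp(lt)
                pieces = _reml_pieces(t, yv, Xv, Zs)
                return np.inf if pieces is None else pieces[0]

            res = optimize.minimize(
                obj_sub, np.log(np.maximum(theta[free], 1e-4)),
                method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10},
            )
            cand = fixed.copy()
            cand[free] = np.exp(res.x)
            cand_dev = float(res.fun)
        else:
            cand = fixed
            cand_dev = float(_reml_pieces(fixed, yv, Xv, Zs)[0])
        if cand_dev < best_dev - 1e-10:
            theta, best_dev = cand, cand_dev

    theta = np.where(theta < 1e-10, 0.0, theta)
    dev, beta, s2, xtvx = _reml_pieces(theta, yv, Xv, Zs)
    cov_beta = s2 * np.linalg.inv(xtvx)
    vcomp = {name: float(th * s2) for name, th in zip(names, theta)}
    vcomp["residual"] = float(s2)
    return LmmFit(
        params=pd.Series(beta, index=X.columns),
        bse=pd.Series(np.sqrt(np.diag(cov_beta)), index=X.columns),
        vcomp=vcomp,
        loglik=-0.5 * dev,
        converged=converged,
        boundary=[names[i] for i in range(k) if theta[i] == 0.0],
        n_obs=n,
        n_fixed=p,
        _X=Xv,
        _y=yv,
        _Z={name: z for name, z in zip(names, Zs)},
    )


def _coef_variance(gamma: np.ndarray, X, Zs, j: int) -> float:
    """Variance of beta_j at variance components gamma = (s2_g..., s2_e)."""
    n = X.shape[0]
    v = gamma[-1] * np.eye(n)
    for g, z in zip(gamma[:-1], Zs):
        v += g * (z @ z.T)
    xtvx = X.T @ np.linalg.solve(v, X)
    return float(np.linalg.inv(xtvx)[j, j])


def _reml_deviance_gamma(gamma: np.ndarray, y, X, Zs) -> float:
    """-2 REML log-likelihood on the natural variance scale."""
    n, p = X.shape
    if gamma[-1] <= 0 or np.any(gamma[:-1] < 0):
        return np.inf
    v = gamma[-1] * np.eye(n)
    for g, z in zip(gamma[:-1], Zs):
        v += g * (z @ z.T)
    sign_v, logdet_v = np.linalg.slogdet(v)
    vi_X = np.linalg.solve(v, X)
    xtvx = X.T @ vi_X
    sign_x, logdet_x = np.linalg.slogdet(xtvx)
    if sign_v <= 0 or sign_x <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, X.T @ np.linalg.solve(v, y))
    r = y - X @ beta
    return logdet_v + logdet_x + float(r @ np.linalg.solve(v, r))


def satterthwaite_test(fit: LmmFit, coefficient) -> tuple[float, float, float]:
    """Wald t-test of one fixed effect with Satterthwaite df.

    Returns ``(t, df, p)``.  The df come from matching the first two
    moments of the scaled coefficient variance to a chi-square:
    ``df = 2 g^2 / (grad g' A grad g)`` with ``A`` the inverse observed
    REML information of the variance components.  Components estimated
    at the zero boundary are held out of the gradient (their uncertainty
    does not propagate), which recovers the OLS df ``N - p`` in the
    zero-variance limit.
    """
    j = list(fit.params.index).index(coefficient)
    names = list(fit._Z.keys())
    Zs = [fit._Z[nm] for nm in names]
    gamma = np.array([fit.vcomp[nm] for nm in names] + [fit.vcomp["residual"]])
    est = fit.params.iloc[j]
    df_max = fit.n_obs - fit.n_fixed

    free = [i for i in range(len(gamma)) if gamma[i] > 0 or i == len(gamma) - 1]
    g0 = _coef_variance(gamma, fit._X, Zs, j)
    se = np.sqrt(g0)
    t = float(est / se)

    # gradient of the coefficient variance w.r.t. the free components
    h = np.maximum(1e-5 * np.abs(gamma[free]), 1e-10)
    grad = np.zeros(len(free))
    for a, idx in enumerate(free):
        gp = gamma.copy()
        gm = gamma.copy()
        gp[idx] += h[a]
        gm[idx] = max(gm[idx] - h[a], 0.0)
        grad[a] = (
            _coef_variance(gp, fit._X, Zs, j) - _coef_variance(gm, fit._X, Zs, j)
        ) / (gp[idx] - gm[idx])

    # observed information of the free variance components
    def dev_free(gf):
        g = gamma.copy()
        g[free] = gf
        return _reml_deviance_gamma(g, fit._y, fit._X, Zs)

    gf0 = gamma[free]
    hs = np.maximum(1e-4 * np.abs(gf0), 1e-8)
    m = len(free)
    hess = np.zeros((m, m))
    f0 = dev_free(gf0)
    for a in range(m):
        for b in range(a, m):
            ga = gf0.copy(); ga[a] += hs[a]; ga[b] += hs[b]
            gb = gf0.copy(); gb[a] += hs[a]
            gc = gf0.copy(); gc[b] += hs[b]
            hess[a, b] = hess[b, a] = (
                dev_free(ga) - dev_free(gb) - dev_free(gc) + f0
            ) / (hs[a] * hs[b])
    info = hess / 2.0  # information of -2 loglik is Hessian / 2
    try:
        A = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(info)
    denom = float(grad @ A @ grad)
    if denom <= 0:
        df = float(df_max)
    else:
        df = 2.0 * g0 * g0 / denom
    if df <= 0:
        raise ValueError("non-positive Satterthwaite df: numerical failure")
    df = min(df, float(df_max))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, float(df), float(p)


@dataclass
class AnovaLsdResult:
    """One-way ANOVA with Fisher's LSD letter display."""

    F: float
    df_between: int
    df_within: int
    p: float
    means: pd.Series  # group means, descending
    letters: dict[str, str]  # group -> letter string
    mse: float
    alpha: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.means, "letters": [self.letters[g] for g in self.means.index]}
        )


def _lsd_significant(means, ns, mse, df_within, alpha) -> np.ndarray:
    k = len(means)
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
            tt = abs(means[i] - means[j]) / se
            sig[i, j] = sig[j, i] = 2 * stats.t.sf(tt, df_within) < alpha
    return sig


def _letters_from_sig(sig: np.ndarray) -> list[str]:
    """Maximal-interval letter display on groups sorted by descending mean."""
    k = sig.shape[0]
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[i : j + 2, i : j + 2].any():
            j += 1
        if not any(a <= i and j <= b for a, b in intervals):
            intervals.append((i, j))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for letter_idx, (a, b) in enumerate(intervals):
        for g in range(a, b + 1):
            letters[g] += alphabet[letter_idx]
    return letters


def anova_lsd(values, groups, alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA followed by Fisher's LSD pairwise letters.

    All pairwise t-tests use the pooled within-group mean square with no
    multiplicity correction (that is what "least significant difference"
    means); when the overall F-test is not significant at ``alpha``, all
    groups share one letter.
    """
    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(groups)})
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    grouped = df.groupby("group")["value"]
    means = grouped.mean().sort_values(ascending=False)
    ns = grouped.size().reindex(means.index).to_numpy()
    n, k = len(df), len(means)
    if n <= k:
        raise ValueError("need within-group replication")
    ss_within = float(((df["value"] - grouped.transform("mean")) ** 2).sum())
    if ss_within == 0:
        raise ValueError("zero within-group variance everywhere: F undefined")
    df_b, df_w = k - 1, n - k
    grand = df["value"].mean()
    ss_between = float((ns * (means.to_numpy() - grand) ** 2).sum())
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    mse = ss_within / df_w
    if p < alpha:
        sig = _lsd_significant(means.to_numpy(), ns, mse, df_w, alpha)
    else:
        sig = np.zeros((k, k), dtype=bool)
    letters = dict(zip(means.index, _letters_from_sig(sig)))
    return AnovaLsdResult(float(F), df_b, df_w, p, means, letters, mse, alpha)


def design_matrix(
    data: pd.DataFrame,
    categorical: tuple[str, ...] = (),
    numeric: tuple[str, ...] = (),
    interactions: tuple[tuple[str, str], ...] = (),
) -> pd.DataFrame:
    """Treatment-coded fixed-effect design with an intercept column."""
    cols = {"Intercept": np.ones(len(data))}
    level_maps = {}
    for name in categorical:
        levels = sorted(data[name].astype(str).unique())
        level_maps[name] = levels[1:]
        for lv in levels[1:]:
            cols[f"{name}[{lv}]"] = (data[name].astype(str) == lv).astype(float)
    for name in numeric:
        cols[name] = data[name].astype(float).to_numpy()
    for a, b in interactions:
        for la in level_maps.get(a, [None]):
            ca = cols[f"{a}[{la}]"] if la is not None else data[a].astype(float)
            for lb in level_maps.get(b, [None]):
                cb = cols[f"{b}[{lb}]"] if lb is not None else data[b].astype(float)
                label_a = f"{a}[{la}]" if la is not None else a
                label_b = f"{b}[{lb}]" if lb is not None else b
                cols[f"{label_a}:{label_b}"] = np.asarray(ca) * np.asarray(cb)
    return pd.DataFrame(cols, index=data.index)
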
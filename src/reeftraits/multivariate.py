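"""Distance-based multivariate analysis of assemblage composition.

Implements the ordination and permutation machinery for community
matrices: Bray–Curtis dissimilarity, principal coordinates analysis
(classical scaling of a distance matrix), PERMANOVA with crossed fixed
factors and sequential (Type-I) sums of squares, and distance-based
redundancy analysis (db-RDA) with forward selection of constraints by
AIC.

PERMANOVA partitions the total sum of squared distances through the
Gower-centred inner-product matrix G = -1/2 J D^2 J: for a hat matrix H
of a model term, the term's sum of squares is tr((H_k - H_{k-1}) G), and
significance comes from freely permuting the rows/columns of G.  The
same G underlies PCoA and db-RDA, so the three analyses share one
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "bray_curtis",
    "pcoa",
    "Ordination",
    "permanova",
    "dbrda",
    "dbrda_forward_select",
    "DbRdaModel",
]


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between the rows of an abundance matrix.

    ``d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``; requires non-negative
    entries and at least one positive entry per row.
    """
    values = np.asarray(matrix, dtype=float)
    if np.any(values < 0):
        raise ValueError("abundance matrix has negative entries")
    zero_rows = np.where(values.sum(axis=1) == 0)[0]
    if zero_rows.size:
        labels = [str(matrix.index[i]) for i in zero_rows]
        raise ValueError(f"all-zero assemblage rows: {labels}")
    d = squareform(pdist(values, metric="braycurtis"))
    ids = [str(i) for i in matrix.index]
    return DistanceMatrix(d, ids=ids)


@dataclass
class Ordination:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame  # units x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    explained: np.ndarray  # fraction per retained axis, on positive eigenvalues
    correction: str = "none"

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues[self.eigenvalues > 0].sum())


def _as_distance(d) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, DistanceMatrix):
        return np.asarray(d.data, dtype=float), list(d.ids)
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(arr) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return arr, [str(i) for i in range(arr.shape[0])]


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making d + c Euclidean-embeddable."""
    n = d.shape[0]
    delta1 = _gower_center(d**2)
    delta2 = _gower_center(d)
    upper = np.hstack([np.zeros((n, n)), 2 * delta1])
    lower = np.hstack([-np.eye(n), -4 * delta2])
    eigs = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(np.max(eigs.real))


def pcoa(d, n_axes: int | None = None, correction: str = "none") -> Ordination:
    """Principal coordinates analysis (classical metric scaling).

    Double-centres -1/2 d^2, eigendecomposes, and scales eigenvectors by
    the square root of their eigenvalues.  Axes with non-positive
    eigenvalues carry no coordinates and are excluded from the
    explained-variance accounting; ``correction='cailliez'`` instead adds
    the smallest constant to the off-diagonal distances that removes the
    negative eigenvalues.
    """
    arr, ids = _as_distance(d)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 units")
    if correction not in {"none", "cailliez"}:
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "cailliez":
        c = _cailliez_constant(arr)
        if c > 1e-12:
            arr = arr + c * (1 - np.eye(n))
    g = _gower_center(arr**2)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-10 * abs(eigval[0]), 1e-12) if eigval[0] > 0 else eigval > 0

    total_pos = eigval[pos].sum()
    k = int(pos.sum()) if n_axes is None else min(n_axes, n - 1)
    coords = np.zeros((n, k))
    explained = np.zeros(k)
    for i in range(k):
        if i < eigval.size and pos[i]:
            coords[:, i] = eigvec[:, i] * np.sqrt(eigval[i])
            explained[i] = eigval[i] / total_pos if total_pos > 0 else 0.0
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"PCoA{i + 1}" for i in range(k)]
    )
    return Ordination(frame, eigval, explained, correction)


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column space of x, and its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def _dummy(values: pd.Series) -> np.ndarray:
    levels = sorted(pd.unique(values.astype(str)))
    arr = np.zeros((len(values), len(levels)))
    for j, lv in enumerate(levels):
        arr[:, j] = (values.astype(str) == lv).to_numpy(dtype=float)
    return arr


def _term_matrix(design: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        parts = term.split(":")
        combined = design[parts[0]].astype(str)
        for p in parts[1:]:
            combined = combined + "␟" + design[p].astype(str)
        return _dummy(combined)
    return _dummy(design[term])


def permanova(
    d,
    design: pd.DataFrame,
    terms: tuple[str, ...] = ("year", "protected", "year:protected"),
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """PERMANOVA with crossed fixed factors and sequential sums of squares.

    ``design`` holds one factor column per main effect, aligned to the
    distance-matrix ids; ``terms`` are entered in order, interactions
    written ``a:b``.  Units are permuted freely (no strata); each term's
    p-value is ``(number of permuted pseudo-F >= observed + 1)/(n_perm+1)``.
    A seed is required: permutation tests must be reproducible.
    """
    if seed is None:
        raise ValueError("permanova requires an explicit seed")
    arr, ids = _as_distance(d)
    n = arr.shape[0]
    if len(design) != n:
        raise ValueError("design rows must match distance-matrix units")
    g = _gower_center(arr**2)
    ss_total = float(np.trace(g))

    cum = np.ones((n, 1))
    h_prev, rank_prev = _hat(cum)
    diffs, dfs = [], []
    for term in terms:
        cum = np.hstack([cum, _term_matrix(design, term)])
        h_cur, rank_cur = _hat(cum)
        df = rank_cur - rank_prev
        if df == 0:
            raise ValueError(
                f"term {term!r} is fully aliased with terms already in the model"
            )
        diffs.append(h_cur - h_prev)
        dfs.append(df)
        h_prev, rank_prev = h_cur, rank_cur
    resid_proj = np.eye(n) - h_prev
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    ss_terms = np.array([float(np.sum(p * g)) for p in diffs])
    ss_resid = float(np.sum(resid_proj * g))

    if ss_total <= 1e-12:  # all units identical: no variation to partition
        rows = [[t, df, 0.0, np.nan, 0.0, np.nan]
                for t, df in zip(terms, dfs)]
        rows.append(["Residual", df_resid, 0.0, np.nan, 1.0, np.nan])
        rows.append(["Total", n - 1, 0.0, np.nan, 1.0, np.nan])
        table = pd.DataFrame(
            rows, columns=["term", "df", "sum_sq", "pseudo_F", "R2", "p"]
        ).set_index("term")
        table.attrs["n_perm"] = n_perm
        table.attrs["seed"] = seed
        return table

    ms_resid = ss_resid / df_resid
    f_obs = (ss_terms / np.array(dfs)) / ms_resid

    rng = np.random.default_rng(seed)
    idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    g_perm = g[idx[:, :, None], idx[:, None, :]]  # (B, n, n)
    ss_resid_perm = np.einsum("bij,ij->b", g_perm, resid_proj)
    ms_resid_perm = ss_resid_perm / df_resid
    p_values = []
    for proj, df, f0 in zip(diffs, dfs, f_obs):
        ss_perm = np.einsum("bij,ij->b", g_perm, proj)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (ss_perm / df) / ms_resid_perm
        p = (np.sum(f_perm >= f0 - 1e-12) + 1) / (n_perm + 1)
        p_values.append(float(p))

    rows = []
    for term, df, ss, f0, p in zip(terms, dfs, ss_terms, f_obs, p_values):
        rows.append([term, df, ss, f0, ss / ss_total, p])
    rows.append(["Residual", df_resid, ss_resid, np.nan, ss_resid / ss_total, np.nan])
    rows.append(["Total", n - 1, ss_total, np.nan, 1.0, np.nan])
    table = pd.DataFrame(
        rows, columns=["term", "df", "sum_sq", "pseudo_F", "R2", "p"]
    ).set_index("term")
    table.attrs["n_perm"] = n_perm
    table.attrs["seed"] = seed
    return table


@dataclass
class DbRdaModel:
    """Result of a (forward-selected) distance-based redundancy analysis."""

    selected: list[str]
    constrained_eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    site_scores: pd.DataFrame | None
    predictor_scores: pd.DataFrame | None
    steps: pd.DataFrame = field(default_factory=pd.DataFrame)
    aic: float = np.nan

    @property
    def unconstrained_inertia(self) -> float:
        return self.total_inertia - self.constrained_inertia


def _aic(n: int, rss: float, k: int) -> float:
    # residual-deviance analogue used for ordination step selection
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + 2 * (k + 1)


def dbrda(d, predictors: pd.DataFrame) -> DbRdaModel:
    """Distance-based RDA: constrained ordination of a distance matrix.

    The distance matrix is embedded by PCoA (positive axes only) and the
    coordinates regressed on the centred predictors; constrained inertia
    is the sum of squares of the fitted values.
    """
    ord_full = pcoa(d)
    y = ord_full.coordinates.to_numpy()
    keep = ord_full.eigenvalues[: y.shape[1]] > 0
    y = y[:, keep]
    n = y.shape[0]
    total = float((y**2).sum())
    x = np.asarray(predictors, dtype=float)
    if np.isnan(x).any():
        raise ValueError("predictors contain missing values")
    xc = x - x.mean(axis=0)
    h, rank = _hat(xc) if xc.size else (np.zeros((n, n)), 0)
    fitted = h @ y
    constrained = float((fitted**2).sum())

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2
    n_axes = int(np.sum(eig > 1e-10 * max(eig[0], 1.0))) if eig.size else 0
    eig = eig[:n_axes]
    axes = [f"dbRDA{i + 1}" for i in range(n_axes)]
    site = pd.DataFrame(
        (y @ vt[:n_axes].T), index=predictors.index, columns=axes
    )
    if n_axes:
        with np.errstate(invalid="ignore", divide="ignore"):
            pred_scores = np.corrcoef(xc.T, site.to_numpy().T)[
                : xc.shape[1], xc.shape[1] :
            ]
        pred = pd.DataFrame(pred_scores, index=predictors.columns, columns=axes)
    else:
        pred = None
    return DbRdaModel(
        selected=list(predictors.columns),
        constrained_eigenvalues=eig,
        total_inertia=total,
        constrained_inertia=constrained,
        site_scores=site if n_axes else None,
        predictor_scores=pred,
        aic=_aic(n, total - constrained, rank),
    )


def dbrda_forward_select(d, candidates: pd.DataFrame) -> DbRdaModel:
    """Forward selection of db-RDA constraints by AIC.

    Starting from the unconstrained (null) model, each step adds the
    candidate column that minimises the model AIC
    ``n ln(residual inertia / n) + 2 (k + 1)`` and stops when no addition
    lowers it.  Candidates collinear with the selected set are skipped.
    """
    arr, _ = _as_distance(d)
    n = arr.shape[0]
    ord_full = pcoa(d)
    y = ord_full.coordinates.to_numpy()
    keep = ord_full.eigenvalues[: y.shape[1]] > 0
    y = y[:, keep]
    total = float((y**2).sum())

    log_rows = []
    if total <= 1e-12:
        steps = pd.DataFrame(log_rows, columns=["step", "candidate", "aic", "selected"])
        return DbRdaModel([], np.array([]), total, 0.0, None, None, steps,
                          aic=_aic(n, total, 0))

    selected: list[str] = []
    current_aic = _aic(n, total, 0)
    step = 0
    while True:
        step += 1
        best = None
        for cand in candidates.columns:
            if cand in selected:
                continue
            cols = selected + [cand]
            xc = candidates[cols].to_numpy(dtype=float)
            xc = xc - xc.mean(axis=0)
            h, rank = _hat(xc)
            if rank <= len(selected):  # collinear with already-selected set
                log_rows.append([step, cand, np.nan, False])
                continue
            rss = total - float(((h @ y) ** 2).sum())
            aic = _aic(n, rss, rank)
            log_rows.append([step, cand, aic, False])
            if best is None or aic < best[1]:
                best = (cand, aic)
        if best is None or best[1] >= current_aic:
            break
        selected.append(best[0])
        current_aic = best[1]
        log_rows.append([step, best[0], best[1], True])

    steps = pd.DataFrame(log_rows, columns=["step", "candidate", "aic", "selected"])
    if not selected:
        return DbRdaModel([], np.array([]), total, 0.0, None, None, steps,
                          aic=_aic(n, total, 0))
    model = dbrda(d, candidates[selected])
    model.steps = steps
    return model
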
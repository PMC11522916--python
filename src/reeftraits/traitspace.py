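"""Coral functional trait space and trait-based diversity metrics.

Seven habitat-forming traits (growth rate, skeletal density, colony
size, colony height, corallite width, intra-colony space size and
surface-area:volume ratio) are binned into ordinal 1-5 categories,
turned into a Gower distance matrix, and embedded by PCoA.  The first
four axes form the trait space in which three assemblage-level metrics
are computed:

* **trait volume fraction** — convex-hull volume of the taxa present in
  an assemblage divided by the hull volume of the pooled reference set;
* **5-NN functional redundancy** — mean over taxa of the summed
  Euclidean distances to the five nearest other taxa (smaller = more
  redundant, i.e. denser packing);
* **functional dispersion (FDis)** — abundance-weighted mean distance of
  taxa to the abundance-weighted centroid.

The pooled all-years taxon set is the fixed reference frame: per-year
subsets are measured inside it, which is what makes the yearly
percentages comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import gaussian_kde
from skbio import DistanceMatrix

from reeftraits.multivariate import pcoa

__all__ = [
    "TRAIT_NAMES",
    "impute_traits",
    "bin_traits",
    "gower_distance",
    "TraitSpace",
    "build_trait_space",
    "VolumeFraction",
    "trait_volume_fraction",
    "functional_redundancy_5nn",
    "functional_dispersion",
    "KdeOccupancy",
    "kde_occupancy",
]

#: The seven coral functional traits, in canonical column order.
TRAIT_NAMES: tuple[str, ...] = (
    "growth_rate",
    "skeletal_density",
    "colony_size",
    "colony_height",
    "corallite_width",
    "space_size",
    "sav_ratio",
)


def impute_traits(
    table: pd.DataFrame,
    trait_columns: tuple[str, ...] = TRAIT_NAMES,
) -> pd.DataFrame:
    """Fill missing trait values by hierarchical geometric means.

    Gaps are filled from the geometric mean of measured congeners
    (same ``genus``), falling back to the growth-form mean and finally
    the global mean.  Traits are positive and right-skewed, so means are
    taken on the log scale.  The returned frame carries boolean columns
    ``imputed_<trait>`` and, in ``attrs['imputation_level']``, the level
    used for each filled cell.
    """
    out = table.copy()
    levels: dict[tuple[str, str], str] = {}
    for trait in trait_columns:
        vals = pd.to_numeric(out[trait], errors="coerce")
        if vals.notna().sum() == 0:
            raise ValueError(f"trait {trait!r} is missing for all taxa")
        if (vals.dropna() <= 0).any():
            raise ValueError(f"trait {trait!r} has non-positive values")
        logv = np.log(vals)
        genus_mean = logv.groupby(out["genus"]).mean()
        form_mean = logv.groupby(out["growth_form"]).mean()
        global_mean = logv.mean()
        filled = vals.copy()
        flag = vals.isna()
        for taxon in out.index[flag]:
            g = out.loc[taxon, "genus"]
            f = out.loc[taxon, "growth_form"]
            if g in genus_mean.index and np.isfinite(genus_mean[g]):
                filled[taxon] = np.exp(genus_mean[g])
                levels[(taxon, trait)] = "genus"
            elif f in form_mean.index and np.isfinite(form_mean[f]):
                filled[taxon] = np.exp(form_mean[f])
                levels[(taxon, trait)] = "growth_form"
            else:
                filled[taxon] = np.exp(global_mean)
                levels[(taxon, trait)] = "global"
        out[trait] = filled
        out[f"imputed_{trait}"] = flag.to_numpy()
    out.attrs["imputation_level"] = levels
    return out


def bin_traits(
    raw: pd.DataFrame,
    breaks: dict[str, tuple[float, float, float, float]],
    trait_columns: tuple[str, ...] = TRAIT_NAMES,
) -> pd.DataFrame:
    """Bin raw trait values into ordinal 1-5 categories.

    The category is one plus the number of cut points strictly below the
    value, so a value equal to a cut point falls in the lower category.
    Values outside the declared global range are clamped with a warning.
    """
    cats = {}
    for trait in trait_columns:
        cuts = np.asarray(breaks[trait], dtype=float)
        if cuts.size != 4 or np.any(np.diff(cuts) <= 0):
            raise ValueError(f"breaks for {trait!r} must be 4 increasing cut points")
        vals = pd.to_numeric(raw[trait], errors="coerce")
        if vals.isna().any():
            missing = list(raw.index[vals.isna()])
            raise ValueError(f"trait {trait!r} has gaps (impute first): {missing}")
        lo, hi = cuts[0] / 10.0, cuts[-1] * 10.0
        if ((vals < lo) | (vals > hi)).any():
            warnings.warn(f"clamping out-of-range values for trait {trait!r}")
            vals = vals.clip(lo, hi)
        cats[trait] = np.searchsorted(cuts, vals.to_numpy(), side="left") + 1
    return pd.DataFrame(cats, index=raw.index, dtype=np.int64)


def gower_distance(ordinal: pd.DataFrame) -> DistanceMatrix:
    """Gower distance over ordinal trait categories.

    Per trait, distance is |x - y| divided by the trait's observed range
    in the table; the overall distance is the unweighted mean over
    traits.  A trait with zero range carries no information and is
    dropped from the mean with a warning.
    """
    vals = ordinal.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("ordinal trait table has gaps")
    ranges = vals.max(axis=0) - vals.min(axis=0)
    keep = ranges > 0
    if not np.all(keep):
        dropped = [ordinal.columns[i] for i in np.where(~keep)[0]]
        warnings.warn(f"zero-range traits dropped from Gower distance: {dropped}")
    if not np.any(keep):
        raise ValueError("all traits have zero range")
    v = vals[:, keep] / ranges[keep]
    diff = np.abs(v[:, None, :] - v[None, :, :])
    d = diff.mean(axis=2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(i) for i in ordinal.index])


@dataclass
class TraitSpace:
    """Taxon coordinates on the retained PCoA axes of the Gower matrix."""

    coordinates: pd.DataFrame  # taxa x n_axes
    eigenvalues: np.ndarray
    explained: np.ndarray

    @property
    def taxa(self) -> list[str]:
        return list(self.coordinates.index)

    def subset_coords(self, taxa) -> np.ndarray:
        missing = [t for t in taxa if t not in self.coordinates.index]
        if missing:
            raise KeyError(f"taxa outside the reference trait space: {missing}")
        return self.coordinates.loc[list(taxa)].to_numpy()


def build_trait_space(d: DistanceMatrix, n_axes: int = 4) -> TraitSpace:
    """Embed a pooled Gower matrix and retain the leading axes.

    The pooled (all years, all sites) taxon set defines the fixed
    reference frame; per-year assemblages are subsets measured inside it.
    """
    if len(d.ids) < 6:
        raise ValueError("trait space needs at least 6 taxa")
    ordn = pcoa(d, n_axes=n_axes)
    coords = ordn.coordinates
    if _affine_rank(coords.to_numpy()) < n_axes:
        raise ValueError(
            f"fewer than {n_axes + 1} affinely independent taxa: "
            f"{n_axes}-D hull volume undefined"
        )
    return TraitSpace(coords, ordn.eigenvalues, ordn.explained)


def _affine_rank(points: np.ndarray) -> int:
    centered = points - points.mean(axis=0)
    return int(np.linalg.matrix_rank(centered, tol=1e-9))


@dataclass(frozen=True)
class VolumeFraction:
    """Occupied fraction of the reference hull, with a degeneracy flag."""

    fraction: float
    degenerate: bool = False

    def __float__(self) -> float:
        return self.fraction


def _hull_volume(points: np.ndarray) -> float:
    dim = points.shape[1]
    if points.shape[0] < dim + 1 or _affine_rank(points) < dim:
        raise QhullError("degenerate point set")
    return float(ConvexHull(points).volume)


def trait_volume_fraction(space: TraitSpace, subset) -> VolumeFraction:
    """Convex-hull volume of a taxon subset relative to the pooled hull.

    Returns a value in [0, 1]; equals 1 when the subset is the full
    reference set and is monotone non-decreasing under supersets.  A
    subset that is degenerate in the space's dimension (too few taxa, or
    affinely dependent) yields 0 with ``degenerate=True`` rather than an
    error, so a sparse year does not abort a pipeline run.
    """
    ref_points = space.coordinates.to_numpy()
    ref_volume = _hull_volume(ref_points)
    pts = space.subset_coords(subset)
    try:
        vol = _hull_volume(pts)
    except QhullError:
        return VolumeFraction(0.0, degenerate=True)
    return VolumeFraction(min(vol / ref_volume, 1.0), degenerate=False)


def functional_redundancy_5nn(space: TraitSpace, subset, k: int = 5) -> float:
    """Mean over taxa of summed distances to the ``k`` nearest neighbours.

    Euclidean distances on the retained trait-space axes; ties in
    neighbour rank break by taxon-label order.  Lower values mean taxa
    are more densely packed, i.e. the assemblage is more functionally
    redundant.
    """
    taxa = sorted(subset)  # label order fixes tie-breaking
    if len(taxa) < k + 1:
        raise ValueError(f"need at least {k + 1} taxa, got {len(taxa)}")
    pts = space.subset_coords(taxa)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    nearest = np.sort(dist, axis=1)[:, :k]
    return float(nearest.sum(axis=1).mean())


def functional_dispersion(space: TraitSpace, abundances: pd.Series) -> float:
    """Abundance-weighted dispersion (FDis) on the trait-space axes.

    ``FDis = sum_i w_i ||z_i - c|| / sum_i w_i`` with the weighted
    centroid ``c = sum_i w_i z_i / sum_i w_i``; invariant to rescaling
    all weights by a constant, zero iff all positive-weight taxa
    coincide.
    """
    w = abundances[abundances > 0]
    if (abundances < 0).any():
        raise ValueError("negative abundances")
    if w.empty:
        raise ValueError("all abundance weights are zero")
    pts = space.subset_coords(w.index)
    wv = w.to_numpy(dtype=float)
    centroid = (wv[:, None] * pts).sum(axis=0) / wv.sum()
    dist = np.sqrt(((pts - centroid) ** 2).sum(axis=1))
    return float((wv * dist).sum() / wv.sum())


@dataclass
class KdeOccupancy:
    """Gaussian-KDE occupancy map on a pair of trait-space axes."""

    x: np.ndarray  # grid coordinates, axis 1
    y: np.ndarray  # grid coordinates, axis 2
    density: np.ndarray  # (len(y), len(x)) grid, integrates to ~1
    contour_levels: dict[float, float]  # probability mass -> density level
    axis_pair: tuple[int, int]


def kde_occupancy(
    space: TraitSpace,
    subset,
    axis_pair: tuple[int, int] = (1, 2),
    grid_size: int = 101,
    mass_levels: tuple[float, ...] = (0.5, 0.95),
    padding: float = 0.35,
) -> KdeOccupancy:
    """Kernel-density occupancy of an assemblage on two trait-space axes.

    Fits a Gaussian KDE (Scott bandwidth) to the subset's coordinates on
    the chosen 1-based axis pair and evaluates it on a regular grid that
    pads the reference-frame extent, so maps of different years share a
    canvas.  ``contour_levels`` maps each requested probability mass to
    the density value whose superlevel set encloses that mass.
    """
    taxa = list(subset)
    if len(taxa) < 3:
        raise ValueError("KDE occupancy needs at least 3 taxa")
    i, j = axis_pair[0] - 1, axis_pair[1] - 1
    pts = space.subset_coords(taxa)[:, [i, j]]
    if np.ptp(pts[:, 0]) < 1e-12 or np.ptp(pts[:, 1]) < 1e-12:
        raise ValueError("zero-variance axis: KDE bandwidth undefined")
    ref = space.coordinates.to_numpy()[:, [i, j]]
    span = ref.max(axis=0) - ref.min(axis=0)
    lo = ref.min(axis=0) - padding * span
    hi = ref.max(axis=0) + padding * span
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    kde = gaussian_kde(pts.T)
    xx, yy = np.meshgrid(xs, ys)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(yy.shape)
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    levels = {}
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * cell
    for mass in mass_levels:
        idx = np.searchsorted(cum, mass)
        idx = min(idx, flat.size - 1)
        levels[mass] = float(flat[idx])
    return KdeOccupancy(xs, ys, dens, levels, axis_pair)
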
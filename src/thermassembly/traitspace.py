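"""Assemblage-level trait-space analytics.

The central diversity metric is the two-dimensional *hypervolume*: the
area of the highest-density region (HDR) enclosing a stated probability
mass (default 95%) of a weighted Gaussian kernel density fitted to the
species' standardized (CTmin, CTmax) points, with species weighted by
their individual counts (abundance in simulations, specimens measured
in field tables).

To keep the metric comparable across assemblages of different richness,
the estimate follows a fixed-richness resampling protocol: repeatedly
subsample a fixed number of species (default 20, without replacement,
with sampling probability proportional to the species' weights so
common species anchor the estimate), compute the HDR area of the
weighted KDE of the subsample, and average over repeats.  Assemblages
at or below the subsample size are evaluated once on all their
species.

Standardization is *pooled*: one mean/SD per trait computed over all
species of all assemblages being compared, then applied uniformly.
Per-assemblage scaling would erase exactly the between-assemblage
volume differences the metric is meant to expose.

Bandwidths default to per-dimension Silverman rules over the distinct
subsampled points, and are injectable everywhere — sweep analyses pass
one fixed bandwidth so that level volumes stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "TraitScaler",
    "HypervolumeResult",
    "StrategyClassification",
    "DegenerateTraitsError",
    "standardize_traits",
    "hypervolume",
    "ttrange_stats",
    "classify_strategies",
    "kde2d_quantile_contour",
]

STRATEGY_LABELS = ("warm-adapted", "heat-tolerant", "cold-adapted", "heat-sensitive")

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


class DegenerateTraitsError(ValueError):
    """Raised when trait data carry no usable two-dimensional spread."""


@dataclass(frozen=True)
class TraitScaler:
    """Pooled z-score scaling record, retained so results can be inverted."""

    mean: np.ndarray  # (2,) CTmin, CTmax
    sd: np.ndarray  # (2,)

    def transform(self, ctmin, ctmax):
        return (np.asarray(ctmin) - self.mean[0]) / self.sd[0], (
            np.asarray(ctmax) - self.mean[1]
        ) / self.sd[1]

    def inverse(self, zmin, zmax):
        return (
            np.asarray(zmin) * self.sd[0] + self.mean[0],
            np.asarray(zmax) * self.sd[1] + self.mean[1],
        )


@dataclass(frozen=True)
class HypervolumeResult:
    volume: float
    n_subsample: int
    n_repeat: int
    quantile: float
    bandwidths: tuple
    degenerate: bool


@dataclass(frozen=True)
class StrategyClassification:
    labels: pd.Series  # per-species strategy label, aligned to the input index
    centroids: pd.DataFrame  # strategy x (ctmin_c, ctmax_c), original units
    ratios: dict  # strategy -> fraction of species

    @property
    def ratio_vector(self) -> np.ndarray:
        return np.array([self.ratios[k] for k in STRATEGY_LABELS])


def _trait_points(table: pd.DataFrame, standardized: bool) -> np.ndarray:
    cols = ("ctmin_z", "ctmax_z") if standardized else ("ctmin_c", "ctmax_c")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(
            f"trait table lacks column(s) {missing}; "
            "run standardize_traits first" if standardized else f"missing {missing}"
        )
    return table.loc[:, list(cols)].to_numpy(dtype=float)


def standardize_traits(
    tables: Sequence[pd.DataFrame] | pd.DataFrame,
) -> tuple[list[pd.DataFrame], TraitScaler]:
    """Z-score CTmin/CTmax using the pooled species set of all tables.

    Returns copies of the inputs with ``ctmin_z``/``ctmax_z`` columns
    added, plus the scaling record.  A single table may be passed; a
    one-element list is returned.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    tables = list(tables)
    if not tables:
        raise ValueError("no tables given")
    pooled = np.concatenate([_trait_points(t, standardized=False) for t in tables])
    if pooled.shape[0] < 2:
        raise ValueError("pooled standardization requires >= 2 species")
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateTraitsError("zero pooled SD in a trait; cannot standardize")
    out = []
    for t in tables:
        t = t.copy()
        t["ctmin_z"] = (t["ctmin_c"] - mean[0]) / sd[0]
        t["ctmax_z"] = (t["ctmax_c"] - mean[1]) / sd[1]
        out.append(t)
    return out, TraitScaler(mean=mean, sd=sd)


def _merge_duplicates(pts: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge exactly coincident trait points, summing their weights."""
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    if uniq.shape[0] == pts.shape[0]:
        return pts, w
    wsum = np.zeros(uniq.shape[0])
    np.add.at(wsum, inverse, w)
    return uniq, wsum


def _silverman_bandwidths(pts: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-dimension Silverman bandwidths for a 2-D point set.

    Bandwidths are computed from the distinct trait points themselves
    (unweighted), so they reflect the spatial extent of the sampled
    species cloud; the weights only shape the density on top of it.
    """
    n = pts.shape[0]
    sd = pts.std(axis=0, ddof=1)
    return sd * n ** (-1.0 / 6.0)  # Silverman factor for d=2


def _kde_grid(
    pts: np.ndarray,
    w: np.ndarray,
    bw: np.ndarray,
    grid_n: int = 256,
    pad_bw: float = 3.0,
):
    """Weighted separable-Gaussian KDE on a padded regular grid.

    Returns (x, y, density, cell_area).  Density integrates to ~1 over
    the padded box (the kernels' tails beyond 3 bandwidths are lost).
    """
    w = w / w.sum()
    lo = pts.min(axis=0) - pad_bw * bw
    hi = pts.max(axis=0) + pad_bw * bw
    x = np.linspace(lo[0], hi[0], grid_n)
    y = np.linspace(lo[1], hi[1], grid_n)
    gx = np.exp(-0.5 * ((x[None, :] - pts[:, 0:1]) / bw[0]) ** 2) / (bw[0] * _SQRT_2PI)
    gy = np.exp(-0.5 * ((y[None, :] - pts[:, 1:2]) / bw[1]) ** 2) / (bw[1] * _SQRT_2PI)
    density = (w[:, None] * gx).T @ gy
    cell = (x[1] - x[0]) * (y[1] - y[0])
    return x, y, density, cell


def _hdr_threshold(density: np.ndarray, cell: float, quantile: float):
    """Iso-density level whose superlevel set first holds >= quantile mass.

    Returns (level, n_cells) with density ties at the level included.
    """
    flat = np.sort(density.ravel())[::-1]
    mass = flat * cell
    cum = np.cumsum(mass)
    total = cum[-1]
    k = int(np.searchsorted(cum, quantile * total))
    k = min(k, flat.size - 1)
    level = flat[k]
    n_cells = int((density >= level).sum())
    return level, n_cells


def _single_hdr_area(
    pts: np.ndarray,
    w: np.ndarray,
    quantile: float,
    bandwidth: Optional[np.ndarray],
    grid_n: int,
    pad_bw: float,
) -> tuple[float, np.ndarray]:
    pts, w = _merge_duplicates(pts, w)
    bw = np.asarray(bandwidth, dtype=float) if bandwidth is not None else _silverman_bandwidths(pts, w)
    if np.any(bw <= 0) or not np.all(np.isfinite(bw)):
        raise DegenerateTraitsError("zero/invalid KDE bandwidth (no spread in a trait)")
    _, _, density, cell = _kde_grid(pts, w, bw, grid_n=grid_n, pad_bw=pad_bw)
    _, n_cells = _hdr_threshold(density, cell, quantile)
    return n_cells * cell, bw


def hypervolume(
    table: pd.DataFrame,
    n_subsample: int = 20,
    n_repeat: int = 100,
    quantile: float = 0.95,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    bandwidth: Optional[Sequence[float]] = None,
    grid_n: int = 256,
    pad_bw: float = 3.0,
    weight_col: str = "n",
) -> HypervolumeResult:
    """Fixed-richness resampled HDR area of the standardized trait KDE.

    ``table`` must carry ``ctmin_z``/``ctmax_z`` columns (see
    :func:`standardize_traits`) and a positive weight column.  Species
    are subsampled without replacement with probability proportional to
    their weights; weights are renormalized within each subsample.
    Tables with fewer than 3 distinct trait points are flagged
    degenerate with volume 0.
    """
    pts = _trait_points(table, standardized=True)
    w = table[weight_col].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("species weights must be > 0")
    merged_pts, _ = _merge_duplicates(pts, w)
    if merged_pts.shape[0] < 3:
        return HypervolumeResult(
            volume=0.0,
            n_subsample=n_subsample,
            n_repeat=n_repeat,
            quantile=quantile,
            bandwidths=(float("nan"), float("nan")),
            degenerate=True,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_species = pts.shape[0]
    if n_species <= n_subsample:
        repeats = 1
    else:
        repeats = n_repeat
    # abundance-weighted subsampling: common species anchor the estimate,
    # vagrant singletons are rarely drawn
    p_sample = w / w.sum()
    areas = []
    bws = []
    for _ in range(repeats):
        if n_species <= n_subsample:
            idx = np.arange(n_species)
        else:
            idx = rng.choice(n_species, size=n_subsample, replace=False, p=p_sample)
        sub_pts, sub_w = pts[idx], w[idx]
        merged, _ = _merge_duplicates(sub_pts, sub_w)
        if merged.shape[0] < 3 or np.any(merged.std(axis=0) == 0):
            continue  # degenerate subsample; skip this repeat
        try:
            area, bw = _single_hdr_area(sub_pts, sub_w, quantile, bandwidth, grid_n, pad_bw)
        except DegenerateTraitsError:
            continue
        areas.append(area)
        bws.append(bw)
    if not areas:
        return HypervolumeResult(
            volume=0.0,
            n_subsample=n_subsample,
            n_repeat=n_repeat,
            quantile=quantile,
            bandwidths=(float("nan"), float("nan")),
            degenerate=True,
        )
    mean_bw = np.mean(np.asarray(bws), axis=0)
    return HypervolumeResult(
        volume=float(np.mean(areas)),
        n_subsample=n_subsample,
        n_repeat=n_repeat,
        quantile=quantile,
        bandwidths=(float(mean_bw[0]), float(mean_bw[1])),
        degenerate=False,
    )


def ttrange_stats(table: pd.DataFrame) -> tuple[float, float]:
    """Unweighted mean and sample SD of per-species TTrange (CTmax - CTmin)."""
    if len(table) == 0:
        raise ValueError("empty trait table")
    tt = (table["ctmax_c"] - table["ctmin_c"]).to_numpy(dtype=float)
    mean = float(tt.mean())
    sd = float(tt.std(ddof=1)) if tt.size > 1 else float("nan")
    return mean, sd


def classify_strategies(
    table: pd.DataFrame,
    n_restarts: int = 50,
    seed: int | None = None,
    standardized: bool = False,
) -> StrategyClassification:
    """Partition species into four thermal strategies by k-means.

    Clustering runs on standardized traits (z-scored within the given
    table unless ``standardized=True``, in which case the existing
    ``ctmin_z``/``ctmax_z`` columns are used).  Cluster identities are
    assigned deterministically from the centroids: highest-CTmin
    centroid is warm-adapted, lowest is cold-adapted, and of the
    remaining two the higher-CTmax one is heat-tolerant, the lower
    heat-sensitive.
    """
    raw = _trait_points(table, standardized=False)
    if raw.shape[0] < 4:
        raise DegenerateTraitsError("need >= 4 species for 4 clusters")
    if standardized:
        X = _trait_points(table, standardized=True)
    else:
        sd = raw.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateTraitsError("zero trait SD; cannot classify")
        X = (raw - raw.mean(axis=0)) / sd
    if np.unique(X, axis=0).shape[0] < 4:
        raise DegenerateTraitsError("need >= 4 distinct trait points for 4 clusters")
    km = KMeans(n_clusters=4, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(X)
    # map cluster ids to strategy names via the centroids in original units
    cent = np.vstack([raw[assign == k].mean(axis=0) for k in range(4)])
    order = np.argsort(cent[:, 0])  # by centroid CTmin
    cold, warm = order[0], order[-1]
    mid = [k for k in range(4) if k not in (cold, warm)]
    heat_tol = mid[0] if cent[mid[0], 1] >= cent[mid[1], 1] else mid[1]
    heat_sen = mid[1] if heat_tol == mid[0] else mid[0]
    name_of = {warm: "warm-adapted", heat_tol: "heat-tolerant",
               cold: "cold-adapted", heat_sen: "heat-sensitive"}
    labels = pd.Series([name_of[k] for k in assign], index=table.index, name="strategy")
    centroids = pd.DataFrame(
        cent, columns=["ctmin_c", "ctmax_c"],
        index=[name_of[k] for k in range(4)],
    ).loc[list(STRATEGY_LABELS)]
    counts = labels.value_counts()
    n = float(len(labels))
    ratios = {lab: float(counts.get(lab, 0)) / n for lab in STRATEGY_LABELS}
    return StrategyClassification(labels=labels, centroids=centroids, ratios=ratios)


@dataclass(frozen=True)
class DensityContour:
    level: float
    polygons: list  # list of (k, 2) vertex arrays in standardized trait units
    x: np.ndarray
    y: np.ndarray
    density: np.ndarray
    area: float  # HDR area, same estimator as a full-richness single-repeat hypervolume


def kde2d_quantile_contour(
    table: pd.DataFrame,
    quantile: float = 0.95,
    bandwidth: Optional[Sequence[float]] = None,
    grid_n: int = 256,
    pad_bw: float = 3.0,
    weight_col: str = "n",
) -> DensityContour:
    """Iso-density contour enclosing >= ``quantile`` of the KDE mass.

    Shares the grid-KDE and threshold machinery with
    :func:`hypervolume`, so the enclosed area equals a single-repeat,
    full-richness hypervolume of the same table.
    """
    from skimage import measure

    pts = _trait_points(table, standardized=True)
    w = table[weight_col].to_numpy(dtype=float)
    pts, w = _merge_duplicates(pts, w)
    if pts.shape[0] < 3:
        raise DegenerateTraitsError("need >= 3 distinct trait points for a contour")
    bw = np.asarray(bandwidth, dtype=float) if bandwidth is not None else _silverman_bandwidths(pts, w)
    if np.any(bw <= 0) or not np.all(np.isfinite(bw)):
        raise DegenerateTraitsError("zero/invalid KDE bandwidth (no spread in a trait)")
    x, y, density, cell = _kde_grid(pts, w, bw, grid_n=grid_n, pad_bw=pad_bw)
    level, n_cells = _hdr_threshold(density, cell, quantile)
    polys = []
    for c in measure.find_contours(density, level):
        # grid indices -> data coordinates (rows index x, columns y)
        px = np.interp(c[:, 0], np.arange(x.size), x)
        py = np.interp(c[:, 1], np.arange(y.size), y)
        polys.append(np.column_stack([px, py]))
    return DensityContour(
        level=float(level), polygons=polys, x=x, y=y, density=density,
        area=float(n_cells * cell),
    )
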
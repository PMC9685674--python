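"""Region-level aggregation and Moran's I spatial autocorrelation.

Rankings are averaged over the distinct species present in each region and
the global Moran's I of those regional means is tested by permutation (the
analytic null expectation is -1/(n-1)).  The weighting scheme over regions —
row-standardized inverse great-circle distance with a median-distance cutoff
by default, or polygon contiguity — is recorded in the output because the
choice is consequential and there is no universal convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import EARTH_RADIUS_KM

logger = logging.getLogger("cladespec")

__all__ = [
    "RegionSummary",
    "summarize_regions",
    "SpatialWeights",
    "inverse_distance_weights",
    "contiguity_weights",
    "MoranResult",
    "morans_i",
]


def summarize_regions(
    assignments: pd.DataFrame,
    rankings: pd.DataFrame,
    region_ids=None,
    geometries=None,
) -> pd.DataFrame:
    """Per-region distinct-species count and mean specialization ranking.

    ``assignments`` is a (species, region[, count]) table; ``rankings`` the
    frame from :func:`cladespec.ranking.final_ranking` (or anything indexed
    by species with a ``final_ranking`` column).  A species occurring many
    times in a region counts once; assigned species without a ranking are
    excluded and logged.  When region geometries are given, centroid lon/lat
    columns are added.
    """
    if "final_ranking" not in rankings.columns:
        raise KeyError("rankings frame lacks 'final_ranking'")
    pairs = assignments[["species", "region"]].drop_duplicates()
    ranked = pairs["species"].isin(rankings.index)
    n_unranked = pairs.loc[~ranked, "species"].nunique()
    if n_unranked:
        logger.info("excluding %d assigned species without rankings", n_unranked)
    pairs = pairs[ranked]
    pairs = pairs.assign(final_ranking=rankings.loc[pairs["species"], "final_ranking"].to_numpy())
    out = (
        pairs.groupby("region", sort=True)
        .agg(n_species=("species", "nunique"), mean_ranking=("final_ranking", "mean"))
        .reset_index()
    )
    if region_ids is not None and geometries is not None:
        cent = {rid: g.centroid for rid, g in zip(region_ids, geometries)}
        out["lon"] = out["region"].map(lambda r: cent[r].x if r in cent else np.nan)
        out["lat"] = out["region"].map(lambda r: cent[r].y if r in cent else np.nan)
    return out


# ---------------------------------------------------------------------------
# Spatial weights


@dataclass
class SpatialWeights:
    matrix: np.ndarray  # n x n, non-negative, zero diagonal
    scheme: str
    row_standardized: bool
    region_ids: tuple[str, ...]

    def __post_init__(self):
        W = self.matrix
        if W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(W < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight diagonal must be zero")

    @property
    def islands(self) -> np.ndarray:
        """Indices of regions with zero total weight."""
        return np.flatnonzero(self.matrix.sum(axis=1) == 0)


def _great_circle_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def inverse_distance_weights(
    summaries: pd.DataFrame,
    cutoff: str | float = "median",
    row_standardize: bool = True,
) -> SpatialWeights:
    """Inverse great-circle-distance weights between region centroids.

    Pairs farther apart than the cutoff (the median pairwise distance by
    default) get zero weight; rows are standardized to sum to one unless
    disabled.  Regions left with no neighbor become islands (flagged by
    :func:`morans_i`).
    """
    lon = summaries["lon"].to_numpy(dtype=float)
    lat = summaries["lat"].to_numpy(dtype=float)
    D = _great_circle_km(lon, lat)
    n = len(D)
    iu = np.triu_indices(n, k=1)
    cut = float(np.median(D[iu])) if cutoff == "median" else float(cutoff)
    with np.errstate(divide="ignore"):
        W = 1.0 / D
    W[~np.isfinite(W)] = 0.0
    W[D > cut] = 0.0
    np.fill_diagonal(W, 0.0)
    if row_standardize:
        rs = W.sum(axis=1, keepdims=True)
        W = np.divide(W, rs, out=np.zeros_like(W), where=rs > 0)
    return SpatialWeights(
        matrix=W,
        scheme=f"inverse-distance(cutoff={cut:.1f}km)",
        row_standardized=row_standardize,
        region_ids=tuple(summaries["region"]),
    )


def contiguity_weights(
    summaries: pd.DataFrame,
    region_ids,
    geometries,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Binary shared-boundary (queen) contiguity weights between polygons."""
    geom = {rid: g for rid, g in zip(region_ids, geometries)}
    regions = list(summaries["region"])
    n = len(regions)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = geom.get(regions[i]), geom.get(regions[j])
            if gi is not None and gj is not None and gi.intersects(gj):
                W[i, j] = W[j, i] = 1.0
    if row_standardize:
        rs = W.sum(axis=1, keepdims=True)
        W = np.divide(W, rs, out=np.zeros_like(W), where=rs > 0)
    return SpatialWeights(
        matrix=W, scheme="contiguity", row_standardized=row_standardize,
        region_ids=tuple(regions),
    )


# ---------------------------------------------------------------------------
# Moran's I


@dataclass
class MoranResult:
    I: float
    expected: float  # -1/(n-1) under the null
    p: float  # two-sided permutation p
    n: int
    n_perm: int
    scheme: str
    n_islands: int


def morans_i(
    values: pd.Series | np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 9999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with two-sided permutation inference.

    I = (n/S0) * (z'Wz)/(z'z) for centered values z.  Island regions (zero
    row weight) are excluded with a warning; the permutation p shuffles
    values over the remaining regions (seeded) and doubles the smaller tail
    relative to the analytic expectation -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    if len(x) != len(weights.matrix):
        raise ValueError("values and weights disagree in length")
    islands = weights.islands
    if len(islands):
        logger.warning("excluding %d island region(s) with zero weight", len(islands))
    keep = np.setdiff1d(np.arange(len(x)), islands)
    x = x[keep]
    W = weights.matrix[np.ix_(keep, keep)]
    n = len(x)
    if n < 4:
        raise ValueError(f"Moran's I needs >= 4 regions, have {n}")
    if np.var(x) == 0:
        raise ValueError("zero variance of values")
    S0 = W.sum()
    if S0 <= 0:
        raise ValueError("zero total weight")

    def stat(v: np.ndarray) -> float:
        z = v - v.mean()
        return float(len(v) / S0 * (z @ W @ z) / (z @ z))

    obs = stat(x)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    ge = 1
    le = 1
    for _ in range(n_perm):
        s = stat(rng.permutation(x))
        if s >= obs:
            ge += 1
        if s <= obs:
            le += 1
    p = min(1.0, 2.0 * min(ge, le) / (n_perm + 1))
    return MoranResult(
        I=obs, expected=expected, p=float(p), n=n, n_perm=n_perm,
        scheme=weights.scheme, n_islands=int(len(islands)),
    )
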
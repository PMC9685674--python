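"""The five raw specialization metrics.

Each per-species metric is computed independently and is allowed to be
missing — a species with too few occurrence points still participates in the
ranking through whatever metrics it does have.  Nothing here is scored or
inverted; interpretation (small range = specialized, etc.) lives in
:mod:`cladespec.ranking`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, shape
from shapely.strtree import STRtree

from .io import TRAIT_COLUMNS, normalize_label

logger = logging.getLogger("cladespec")

__all__ = [
    "EARTH_RADIUS_KM",
    "laea_project",
    "compute_eoo",
    "load_regions",
    "assign_regions",
    "count_distinct_regions",
    "compute_plasticity",
    "score_domatia",
    "count_interactions",
    "build_metric_table",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

#: default leaf traits entering the total-plasticity sum (the four retained
#: by model selection); the full measured set is io.TRAIT_COLUMNS
DEFAULT_PLASTICITY_TRAITS = (
    "petiole_length",
    "leaf_length",
    "leaf_lobedness",
    "specific_leaf_area",
)


# ---------------------------------------------------------------------------
# Extent of occurrence


def laea_project(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Lambert azimuthal equal-area forward projection (spherical), in km.

    Centered at ``(lon0, lat0)``; areas of figures near the center are
    preserved, which is what an extent-of-occurrence polygon needs to be
    comparable across latitudes.
    """
    lam = np.radians(np.asarray(lon, dtype=float) - lon0)
    phi = np.radians(np.asarray(lat, dtype=float))
    phi0 = np.radians(lat0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    # the antipode maps to infinity; clip to avoid overflow on pathological input
    k = np.sqrt(2.0 / np.maximum(denom, 1e-12))
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam)
    )
    return x, y


@dataclass
class EooResult:
    area_km2: float | None
    n_points: int
    n_distinct: int
    degenerate: bool
    reason: str | None = None


def compute_eoo(lon: Sequence[float], lat: Sequence[float]) -> EooResult:
    """Minimum-convex-polygon extent of occurrence, km².

    Points are projected with an azimuthal equal-area projection centered on
    their centroid before the hull is taken, so the area is unbiased by
    latitude.  Fewer than 3 distinct points, or an all-collinear set, yields a
    missing area with a degenerate flag; the order and multiplicity of points
    never matter.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    pts = np.unique(np.column_stack([lon, lat]), axis=0)
    n, nd = len(lon), len(pts)
    if nd < 3:
        return EooResult(None, n, nd, True, f"only {nd} distinct point(s)")
    x, y = laea_project(pts[:, 0], pts[:, 1], float(np.mean(pts[:, 0])), float(np.mean(pts[:, 1])))
    xy = np.column_stack([x, y])
    # collinearity with tolerance: a great-circle-aligned cloud projects to a
    # sliver of tiny but nonzero width; judge thinness by the PCA aspect ratio
    sv = np.linalg.svd(xy - xy.mean(axis=0), compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < 1e-4:
        return EooResult(None, n, nd, True, "points are (nearly) collinear")
    hull = MultiPoint(xy).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0.0:
        return EooResult(None, n, nd, True, "points are collinear")
    return EooResult(float(hull.area), n, nd, False)


def eoo_by_species(occurrences: pd.DataFrame) -> pd.Series:
    """EOO per species from an occurrence table (species, lon, lat)."""
    out: dict[str, float] = {}
    for sp, grp in occurrences.groupby("species", sort=True):
        res = compute_eoo(grp["lon"].to_numpy(), grp["lat"].to_numpy())
        if res.degenerate:
            logger.info("EOO missing for %s: %s", sp, res.reason)
            out[sp] = np.nan
        else:
            out[sp] = res.area_km2
    return pd.Series(out, name="eoo_km2", dtype=float)


# ---------------------------------------------------------------------------
# Ecoregion assignment and DEL


def load_regions(path: str | Path) -> tuple[list[str], list]:
    """Read region polygons from a GeoJSON FeatureCollection.

    Returns (region ids, shapely geometries) in stable file order.  The id is
    the feature's ``id``, or its ``name``/``region`` property.
    """
    gj = json.loads(Path(path).read_text())
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    ids, geoms = [], []
    for i, feat in enumerate(gj["features"]):
        props = feat.get("properties") or {}
        rid = feat.get("id") or props.get("name") or props.get("region") or f"region_{i}"
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"{path}: invalid geometry for region {rid!r}")
        ids.append(str(rid))
        geoms.append(geom)
    return ids, geoms


def assign_regions(
    occurrences: pd.DataFrame, region_ids: Sequence[str], geometries: Sequence
) -> tuple[pd.DataFrame, int]:
    """Assign each occurrence point to the containing region polygon.

    Returns a (species, region, count) table plus the number of points that
    fell outside every polygon.  A point inside several (overlapping) polygons
    goes to the first by stable input order, with a warning.
    """
    pts = shapely.points(occurrences["lon"].to_numpy(), occurrences["lat"].to_numpy())
    tree = STRtree(list(geometries))
    # covered_by: boundary points count as inside
    pairs = tree.query(pts, predicate="covered_by")  # shape (2, m): [point idx, geom idx]
    assigned = np.full(len(pts), -1, dtype=int)
    n_overlap = 0
    for p, g in zip(pairs[0], pairs[1]):
        if assigned[p] == -1 or g < assigned[p]:
            if assigned[p] != -1:
                n_overlap += 1
            assigned[p] = g
    if n_overlap:
        logger.warning(
            "%d point(s) inside overlapping polygons; assigned to first by input order",
            n_overlap,
        )
    outside = int(np.sum(assigned < 0))
    if outside:
        logger.info("%d point(s) outside all region polygons", outside)
    ok = assigned >= 0
    table = (
        pd.DataFrame(
            {
                "species": occurrences["species"].to_numpy()[ok],
                "region": [region_ids[g] for g in assigned[ok]],
            }
        )
        .groupby(["species", "region"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return table, outside


def count_distinct_regions(assignments: pd.DataFrame) -> pd.Series:
    """Distinct inhabited regions per species (the DEL niche-breadth count)."""
    if assignments.empty:
        return pd.Series(name="del", dtype=float)
    out = assignments.groupby("species", sort=True)["region"].nunique().astype(float)
    out.name = "del"
    return out


# ---------------------------------------------------------------------------
# Plasticity


@dataclass
class PlasticityProfile:
    species: str
    per_trait: dict[str, float]  # CV per configured trait; NaN where below min_n
    n_specimens: int
    traits_used: tuple[str, ...]
    total: float  # NaN when no trait met min_n


def _cv(values: np.ndarray, ddof: int = 1) -> float:
    mean = float(np.mean(values))
    if mean == 0.0:
        return np.nan
    if len(values) <= ddof:
        return np.nan
    return float(np.std(values, ddof=ddof) / mean)


def compute_plasticity(
    specimens: pd.DataFrame,
    traits: Sequence[str] = DEFAULT_PLASTICITY_TRAITS,
    min_n: int = 3,
    aggregate: str = "sum",
    ddof: int = 1,
) -> PlasticityProfile:
    """Within-species trait plasticity for one species' specimen rows.

    Plasticity of a trait is the coefficient of variation (sample sd / mean
    by default) of the specimen values; the species total is the sum (or,
    optionally, mean) over the configured traits.  A trait with fewer than
    ``min_n`` usable specimens is missing; the total is missing only when
    every configured trait is.
    """
    if aggregate not in {"sum", "mean"}:
        raise ValueError(f"aggregate must be 'sum' or 'mean', got {aggregate!r}")
    sp = normalize_label(specimens["species"].iloc[0]) if len(specimens) else "?"
    per_trait: dict[str, float] = {}
    for trait in traits:
        if trait not in specimens.columns:
            per_trait[trait] = np.nan
            continue
        vals = pd.to_numeric(specimens[trait], errors="coerce").dropna().to_numpy()
        if len(vals) < min_n:
            per_trait[trait] = np.nan
            continue
        cv = _cv(vals, ddof=ddof)
        if np.isnan(cv):
            logger.info("plasticity undefined for %s/%s (zero mean)", sp, trait)
        per_trait[trait] = cv
    used = tuple(t for t, v in per_trait.items() if not np.isnan(v))
    if used:
        vals = np.array([per_trait[t] for t in used])
        total = float(np.sum(vals)) if aggregate == "sum" else float(np.mean(vals))
    else:
        total = np.nan
    return PlasticityProfile(
        species=sp,
        per_trait=per_trait,
        n_specimens=int(len(specimens)),
        traits_used=used,
        total=total,
    )


def plasticity_by_species(
    specimens: pd.DataFrame,
    traits: Sequence[str] = DEFAULT_PLASTICITY_TRAITS,
    min_n: int = 3,
    aggregate: str = "sum",
    ddof: int = 1,
) -> pd.Series:
    out: dict[str, float] = {}
    for sp, grp in specimens.groupby("species", sort=True):
        prof = compute_plasticity(grp, traits=traits, min_n=min_n, aggregate=aggregate, ddof=ddof)
        out[sp] = prof.total
    return pd.Series(out, name="plasticity", dtype=float)


# ---------------------------------------------------------------------------
# Domatia


def score_domatia(codes: Sequence[int]) -> int:
    """Total domatia score for one species from per-specimen codes.

    Each of (nominally) three specimens is coded 0 (no domatia), 1 (hairs,
    likely nonfunctional) or 2 (functional domatia); the species score is the
    sum, on a 0-6 scale.  Fewer than three specimens is tolerated — the mean
    code is rescaled onto 0-6 — and logged as a deficiency.
    """
    codes = [int(c) for c in codes]
    if not codes:
        raise ValueError("no domatia codes")
    if any(c not in (0, 1, 2) for c in codes):
        raise ValueError(f"domatia codes must be in {{0,1,2}}, got {codes}")
    if len(codes) == 3:
        return sum(codes)
    if len(codes) < 3:
        logger.info("domatia scored from %d specimen(s) (3 expected)", len(codes))
    return round(6.0 * float(np.mean(codes)) / 2.0)


def domatia_by_species(table: pd.DataFrame) -> pd.Series:
    """Per-species domatia totals from a long (species, code) table."""
    out: dict[str, float] = {}
    for sp, grp in table.groupby("species", sort=True):
        out[sp] = float(score_domatia(grp["code"].tolist()))
    return pd.Series(out, name="domatia_total", dtype=float)


# ---------------------------------------------------------------------------
# Interspecies interactions


def count_interactions(table: pd.DataFrame) -> pd.Series:
    """Distinct documented interaction partners per species.

    Species absent from the table get no value at all: an absent record means
    nobody looked, not that the species interacts with nothing.
    """
    if table.empty:
        return pd.Series(name="interactions", dtype=float)
    out = table.groupby("species", sort=True)["partner"].nunique().astype(float)
    out.name = "interactions"
    return out


# ---------------------------------------------------------------------------
# Assembly


def build_metric_table(
    occurrences: pd.DataFrame | None = None,
    assignments: pd.DataFrame | None = None,
    specimens: pd.DataFrame | None = None,
    domatia: pd.DataFrame | None = None,
    interactions: pd.DataFrame | None = None,
    regions: tuple[Sequence[str], Sequence] | None = None,
    plasticity_traits: Sequence[str] = DEFAULT_PLASTICITY_TRAITS,
    min_specimens: int = 3,
    plasticity_aggregate: str = "sum",
    interactions_absent_as_zero: bool = False,
) -> pd.DataFrame:
    """Assemble the per-species raw metric table from whatever inputs exist.

    Region assignment is taken from ``assignments`` when given, otherwise
    computed from ``occurrences`` x ``regions``.  Species with no metric at
    all are dropped (logged).  Index: species; columns: eoo_km2, del,
    plasticity, interactions, domatia_total (NaN = missing).
    """
    parts: list[pd.Series] = []
    if occurrences is not None and len(occurrences):
        parts.append(eoo_by_species(occurrences))
    if assignments is None and regions is not None and occurrences is not None:
        assignments, _ = assign_regions(occurrences, *regions)
    if assignments is not None and len(assignments):
        parts.append(count_distinct_regions(assignments))
    if specimens is not None and len(specimens):
        parts.append(
            plasticity_by_species(
                specimens,
                traits=plasticity_traits,
                min_n=min_specimens,
                aggregate=plasticity_aggregate,
            )
        )
    if interactions is not None and len(interactions):
        parts.append(count_interactions(interactions))
    if domatia is not None and len(domatia):
        parts.append(domatia_by_species(domatia))
    if not parts:
        raise ValueError("no metric inputs provided")
    table = pd.concat(parts, axis=1).sort_index()
    table.index.name = "species"
    for col in ("eoo_km2", "del", "plasticity", "interactions", "domatia_total"):
        if col not in table.columns:
            table[col] = np.nan
    table = table[["eoo_km2", "del", "plasticity", "interactions", "domatia_total"]]
    if interactions_absent_as_zero:
        table["interactions"] = table["interactions"].fillna(0.0)
    empty = table.index[table.isna().all(axis=1)]
    if len(empty):
        logger.info("dropping %d species with no metric at all", len(empty))
        table = table.drop(index=empty)
    logger.info("metric table: %d species", len(table))
    return table
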
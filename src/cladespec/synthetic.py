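"""Synthetic study generator with known ground truth.

Produces a complete input bundle — a Yule clade with a latent specialization
value evolving on it, occurrence points, specimen trait tables, interaction
and domatia records, a rectangular ecoregion grid, and validation labels —
shaped like the data a clade-wide specialization study consumes.  The latent
value drives every metric in the direction the scoring scheme assumes
(specialists: small ranges, few regions, low plasticity, many documented
interactions, more domatia), so the whole pipeline can be tested end-to-end
against a stored truth table without any external download.

Expert survey scores are modeled as the composite metric-based ranking the
species actually has (computed from the generated noise-free metric table
with the package's own scoring code) plus a configurable additive expert
bias and noise — which makes the bias a directly recoverable parameter of a
paired t-test between survey and pipeline rankings.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import metrics as m
from . import ranking as rk
from .io import TRAIT_COLUMNS, write_newick

logger = logging.getLogger("cladespec")

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_trait",
    "simulate_clade",
    "simulate_inputs",
    "SyntheticStudy",
    "recompute_rankings",
    "write_bundle",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror a 141-species oak-like clade."""

    n_species: int = 141
    # latent specialization model on the (unit-height) tree
    latent_model: str = "BM"  # or "OU"
    sigma2: float = 1.0
    ou_alpha: float = 2.0  # used when latent_model == "OU"
    ou_theta: float = 0.0
    # geography: study window and ecoregion grid
    lon_range: tuple[float, float] = (-115.0, -65.0)
    lat_range: tuple[float, float] = (5.0, 45.0)
    grid_shape: tuple[int, int] = (8, 8)
    # extent-of-occurrence link: log10 area from generalists to specialists
    log10_eoo_range: tuple[float, float] = (6.7, 3.2)
    eoo_noise_sd: float = 0.0  # sd on log10 area
    median_points: int = 150  # occurrence records per species (heavy-tailed)
    # specimens / plasticity link: CV from generalists to specialists
    cv_range: tuple[float, float] = (0.45, 0.07)
    mean_specimens: int = 14
    # interactions link (count, specialists high)
    interaction_range: tuple[float, float] = (2.0, 60.0)
    interaction_dispersion: float = 0.0  # 0 = deterministic counts, 1 = Poisson
    # survey
    survey_bias: float = 13.6  # additive expert bias, points
    survey_noise_sd: float = 0.0
    # IUCN thresholds on noisy latent percentile
    frac_threatened: float = 0.106
    frac_nt: float = 0.10
    iucn_noise_sd: float = 0.0
    # climate covariate
    bio15_range: tuple[float, float] = (10.0, 120.0)
    bio15_noise_sd: float = 0.0
    # per-metric missingness rates (species-level), applied preferentially
    # to high-latent species
    missing_eoo: float = 0.0
    missing_del: float = 0.0
    missing_plasticity: float = 0.0
    missing_interactions: float = 0.0
    missing_domatia: float = 0.0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        for r in (
            self.missing_eoo, self.missing_del, self.missing_plasticity,
            self.missing_interactions, self.missing_domatia,
        ):
            if not 0.0 <= r < 1.0:
                raise ValueError("missingness rates must be in [0, 1)")

    def zero_noise(self) -> "SimulationConfig":
        """Copy with every noise source and missingness rate set to zero."""
        return replace(
            self,
            eoo_noise_sd=0.0, interaction_dispersion=0.0, survey_noise_sd=0.0,
            iucn_noise_sd=0.0, bio15_noise_sd=0.0,
            missing_eoo=0.0, missing_del=0.0, missing_plasticity=0.0,
            missing_interactions=0.0, missing_domatia=0.0,
        )


# ---------------------------------------------------------------------------
# Clade and trait simulation


def simulate_yule_tree(n: int, rng: np.random.Generator) -> dendropy.Tree:
    """Pure-birth tree with ``n`` tips, rescaled to unit height.

    Tips are named Species_001..Species_n in preorder, so the same seed gives
    a byte-identical Newick string.
    """
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    root.t_birth = 0.0
    active = []
    for _ in range(2):
        child = root.new_child()
        child.t_birth = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.edge.length = t - node.t_birth
        for _ in range(2):
            child = node.new_child()
            child.t_birth = t
            active.append(child)
    present = t + rng.exponential(1.0 / n)
    for node in active:
        node.edge.length = present - node.t_birth
    scale = 1.0 / present if present > 0 else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    tns = tree.taxon_namespace
    width = len(str(n))
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            k += 1
            node.taxon = tns.new_taxon(f"Species_{k:0{width}d}")
    return tree


def simulate_trait(
    tree: dendropy.Tree,
    rng: np.random.Generator,
    model: str = "BM",
    sigma2: float = 1.0,
    root_state: float = 0.0,
    alpha: float = 2.0,
    theta: float = 0.0,
) -> pd.Series:
    """Simulate a continuous trait along the tree (BM or OU), per-tip values."""
    if model not in {"BM", "OU"}:
        raise ValueError(f"unknown trait model {model!r}")
    values: dict[int, float] = {id(tree.seed_node): root_state}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        v0 = values[id(node.parent_node)]
        bl = float(node.edge.length or 0.0)
        if model == "BM" or alpha <= 0:
            mean, var = v0, sigma2 * bl
        else:
            decay = math.exp(-alpha * bl)
            mean = v0 * decay + theta * (1.0 - decay)
            var = sigma2 * (-math.expm1(-2.0 * alpha * bl)) / (2.0 * alpha)
        values[id(node)] = mean + (rng.normal(0.0, math.sqrt(var)) if var > 0 else 0.0)
    out = {
        leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()
    }
    return pd.Series(out, name="latent").sort_index()


def simulate_clade(
    config: SimulationConfig, seed: int | None = None
) -> tuple[dendropy.Tree, pd.Series]:
    """Yule tree plus latent specialization values at the tips."""
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(config.n_species, rng)
    latent = simulate_trait(
        tree, rng,
        model=config.latent_model, sigma2=config.sigma2,
        alpha=config.ou_alpha, theta=config.ou_theta,
    )
    return tree, latent


# ---------------------------------------------------------------------------
# Input bundle


@dataclass
class SyntheticStudy:
    tree: dendropy.Tree
    config: SimulationConfig
    truth: pd.DataFrame  # species, latent, latent01, targets per metric
    occurrences: pd.DataFrame
    specimens: pd.DataFrame
    interactions: pd.DataFrame
    domatia: pd.DataFrame
    validation: pd.DataFrame
    regions_geojson: dict
    region_ids: list[str] = field(default_factory=list)
    region_geometries: list = field(default_factory=list)
    metric_table: pd.DataFrame | None = None  # generator-side recomputation
    anchor_rankings: pd.DataFrame | None = None


def _grid_geojson(config: SimulationConfig) -> dict:
    (lon0, lon1), (lat0, lat1) = config.lon_range, config.lat_range
    nx, ny = config.grid_shape
    dx, dy = (lon1 - lon0) / nx, (lat1 - lat0) / ny
    feats = []
    for j in range(ny):
        for i in range(nx):
            x0, y0 = lon0 + i * dx, lat0 + j * dy
            feats.append(
                {
                    "type": "Feature",
                    "id": f"r{j:02d}_{i:02d}",
                    "properties": {"name": f"r{j:02d}_{i:02d}"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[
                            [x0, y0], [x0 + dx, y0], [x0 + dx, y0 + dy],
                            [x0, y0 + dy], [x0, y0],
                        ]],
                    },
                }
            )
    return {"type": "FeatureCollection", "features": feats}


def _lerp(rng01: float, pair: tuple[float, float]) -> float:
    lo, hi = pair
    return lo + (hi - lo) * rng01


def _point_cloud(
    rng: np.random.Generator,
    center: tuple[float, float],
    target_km2: float,
    n_points: int,
    lon_range: tuple[float, float],
    lat_range: tuple[float, float],
) -> np.ndarray:
    """Gaussian occurrence cloud whose convex hull matches the target area.

    The cloud is rescaled about its centroid until the projected hull area is
    within 2% of the target (two iterations suffice), then clipped to the
    study window.
    """
    s_km = math.sqrt(target_km2 / (2.0 * math.pi * math.log(max(n_points, 4))))
    km_per_deg = 2.0 * math.pi * m.EARTH_RADIUS_KM / 360.0
    s_lat = s_km / km_per_deg
    s_lon = s_km / (km_per_deg * max(math.cos(math.radians(center[1])), 0.2))
    lon = center[0] + rng.normal(0.0, s_lon, n_points)
    lat = center[1] + rng.normal(0.0, s_lat, n_points)
    for _ in range(3):
        res = m.compute_eoo(lon, lat)
        if res.degenerate or res.area_km2 is None:
            break
        ratio = res.area_km2 / target_km2
        if abs(ratio - 1.0) < 0.02:
            break
        f = 1.0 / math.sqrt(ratio)
        lon = lon.mean() + (lon - lon.mean()) * f
        lat = lat.mean() + (lat - lat.mean()) * f
    lon = np.clip(lon, *lon_range)
    lat = np.clip(lat, *lat_range)
    return np.column_stack([lon, lat])


_TRAIT_MEANS = {
    "petiole_length": 12.0,       # mm
    "leaf_length": 80.0,          # mm
    "leaf_lobedness": 1.5,
    "specific_leaf_area": 12.0,   # mm^2/mg
    "perimeter_per_area": 0.8,    # 1/mm
    "venation": 6.0,              # veins per cm
}


def simulate_inputs(
    tree: dendropy.Tree,
    latent: pd.Series,
    config: SimulationConfig,
    seed: int | None = None,
) -> SyntheticStudy:
    """Generate the full input bundle from a clade and its latent values."""
    rng = np.random.default_rng(seed)
    species = list(latent.index)
    n = len(species)
    lo, hi = float(latent.min()), float(latent.max())
    latent01 = (latent - lo) / (hi - lo) if hi > lo else latent * 0.0 + 0.5

    # --- per-species metric targets (monotone links in latent01)
    log_eoo = np.array([_lerp(l, config.log10_eoo_range) for l in latent01])
    log_eoo = log_eoo + rng.normal(0.0, config.eoo_noise_sd, n)
    eoo_target = 10.0 ** log_eoo
    cv_target = np.array([_lerp(l, config.cv_range) for l in latent01])
    inter_mu = np.exp(
        [
            _lerp(l, (math.log(config.interaction_range[0]), math.log(config.interaction_range[1])))
            for l in latent01
        ]
    )

    # --- occurrences
    (lon0, lon1), (lat0, lat1) = config.lon_range, config.lat_range
    occ_rows = []
    n_points_all = {}
    for i, sp in enumerate(species):
        npts = int(np.clip(
            round(rng.lognormal(math.log(config.median_points) + 0.6 * (1 - latent01[sp]), 0.7)),
            10, 3000,
        ))
        n_points_all[sp] = npts
        # specialists cluster toward the low-latitude edge of the window
        c_lat = lat0 + (lat1 - lat0) * (
            0.15 + 0.7 * (1.0 - latent01[sp])
        ) + rng.normal(0.0, 2.0)
        c_lon = rng.uniform(lon0 + 5.0, lon1 - 5.0)
        c_lat = float(np.clip(c_lat, lat0 + 1.0, lat1 - 1.0))
        pts = _point_cloud(rng, (c_lon, c_lat), eoo_target[i], npts,
                           config.lon_range, config.lat_range)
        occ_rows.append(pd.DataFrame({"species": sp, "lon": pts[:, 0], "lat": pts[:, 1]}))
    occurrences = pd.concat(occ_rows, ignore_index=True)

    # --- specimens (all six measured traits; CV declines with latent)
    spec_rows = []
    for i, sp in enumerate(species):
        ns = int(np.clip(round(rng.normal(config.mean_specimens, 5.0)), 5, 60))
        row = {"species": [sp] * ns, "specimen_id": [f"{sp}_s{j:02d}" for j in range(ns)]}
        for t_i, trait in enumerate(TRAIT_COLUMNS):
            cv = cv_target[i] * (0.85 + 0.1 * t_i)  # slight per-trait spread
            sig = math.sqrt(math.log1p(cv * cv))
            mu = math.log(_TRAIT_MEANS[trait]) - 0.5 * sig * sig
            row[trait] = np.round(rng.lognormal(mu, sig, ns), 4)
        spec_rows.append(pd.DataFrame(row))
    specimens = pd.concat(spec_rows, ignore_index=True)

    # --- interactions (distinct partner records)
    inter_rows = []
    for i, sp in enumerate(species):
        if config.interaction_dispersion > 0:
            cnt = int(rng.poisson(inter_mu[i]))
        else:
            cnt = int(round(inter_mu[i]))
        for j in range(max(cnt, 1)):
            inter_rows.append((sp, f"partner_{j:03d}"))
    interactions = pd.DataFrame(inter_rows, columns=["species", "partner"])

    # --- domatia (three specimens, functional domatia more likely in specialists)
    dom_rows = []
    for i, sp in enumerate(species):
        p2 = 0.8 * latent01[sp]
        p1 = 0.15
        codes = rng.choice([0, 1, 2], size=3, p=[1.0 - p1 - p2, p1, p2])
        for c in codes:
            dom_rows.append((sp, int(c)))
    domatia = pd.DataFrame(dom_rows, columns=["species", "code"])

    # --- region grid
    gj = _grid_geojson(config)
    region_ids = [f["id"] for f in gj["features"]]
    from shapely.geometry import shape as _shape

    region_geoms = [_shape(f["geometry"]) for f in gj["features"]]

    # --- missingness, biased toward high-latent species
    def drop_species(rate: float) -> set[str]:
        if rate <= 0:
            return set()
        w = 0.25 + latent01.to_numpy()
        p = np.clip(rate * w / w.mean(), 0.0, 0.95)
        return {sp for sp, pi in zip(species, p) if rng.random() < pi}

    miss = {
        "eoo": drop_species(config.missing_eoo),
        "del": drop_species(config.missing_del),
        "plasticity": drop_species(config.missing_plasticity),
        "interactions": drop_species(config.missing_interactions),
        "domatia": drop_species(config.missing_domatia),
    }
    # occurrence-based metrics share the occurrence file: species missing EOO
    # and DEL lose their occurrence records entirely
    drop_occ = miss["eoo"] & miss["del"]
    occurrences = occurrences[~occurrences["species"].isin(drop_occ)].reset_index(drop=True)
    specimens = specimens[~specimens["species"].isin(miss["plasticity"])].reset_index(drop=True)
    interactions = interactions[~interactions["species"].isin(miss["interactions"])].reset_index(drop=True)
    domatia = domatia[~domatia["species"].isin(miss["domatia"])].reset_index(drop=True)

    # --- generator-side metric table and anchor rankings
    metric_table = m.build_metric_table(
        occurrences=occurrences,
        specimens=specimens,
        interactions=interactions,
        domatia=domatia,
        regions=(region_ids, region_geoms),
    )
    # species that kept occurrences but were drawn missing for exactly one of
    # the two occurrence metrics
    for sp in miss["eoo"] - drop_occ:
        if sp in metric_table.index:
            metric_table.loc[sp, "eoo_km2"] = np.nan
    for sp in miss["del"] - drop_occ:
        if sp in metric_table.index:
            metric_table.loc[sp, "del"] = np.nan
    anchor = rk.final_ranking(metric_table, rk.ScoringConfig())

    # --- validation: survey, IUCN, climate
    survey = anchor["final_ranking"].reindex(pd.Index(species)) + config.survey_bias
    survey = survey + rng.normal(0.0, config.survey_noise_sd, n)
    survey = survey.clip(0.0, 100.0).round(2)

    noisy = latent01 + rng.normal(0.0, config.iucn_noise_sd, n)
    q_thr = np.quantile(noisy, 1.0 - config.frac_threatened)
    q_nt = np.quantile(noisy, 1.0 - config.frac_threatened - config.frac_nt)
    iucn = []
    thr_sorted = np.sort(noisy[noisy >= q_thr])[::-1]
    n_thr = len(thr_sorted)
    for sp, v in zip(species, noisy):
        if v >= q_thr:
            r = 1.0 - (np.searchsorted(-thr_sorted, -v) / max(n_thr - 1, 1))
            iucn.append("CR" if r >= 0.9 else ("EN" if r >= 0.6 else "VU"))
        elif v >= q_nt:
            iucn.append("NT")
        else:
            iucn.append("LC")
    # species stripped of nearly everything are data deficient
    n_missing = pd.Series(
        {sp: sum(sp in s for s in miss.values()) for sp in species}
    )
    iucn = [
        "DD" if n_missing[sp] >= 3 else cat for sp, cat in zip(species, iucn)
    ]

    bio15 = np.array([_lerp(l, config.bio15_range) for l in latent01])
    bio15 = np.round(bio15 + rng.normal(0.0, config.bio15_noise_sd, n), 3)
    validation = pd.DataFrame(
        {"species": species, "iucn": iucn, "survey_score": survey.to_numpy(), "bio15": bio15}
    )

    truth = pd.DataFrame(
        {
            "species": species,
            "latent": latent.to_numpy(),
            "latent01": latent01.to_numpy(),
            "eoo_target_km2": eoo_target,
            "cv_target": cv_target,
            "interaction_target": inter_mu,
            "n_points": [n_points_all[sp] for sp in species],
        }
    )
    return SyntheticStudy(
        tree=tree,
        config=config,
        truth=truth,
        occurrences=occurrences,
        specimens=specimens,
        interactions=interactions,
        domatia=domatia,
        validation=validation,
        regions_geojson=gj,
        region_ids=region_ids,
        region_geometries=region_geoms,
        metric_table=metric_table,
        anchor_rankings=anchor,
    )


def recompute_rankings(
    study: SyntheticStudy, config: rk.ScoringConfig | None = None
) -> pd.DataFrame:
    """Run the metric + ranking pipeline on the generated inputs from scratch."""
    table = m.build_metric_table(
        occurrences=study.occurrences,
        specimens=study.specimens,
        interactions=study.interactions,
        domatia=study.domatia,
        regions=(study.region_ids, study.region_geometries),
    )
    return rk.final_ranking(table, config or rk.ScoringConfig())


def write_bundle(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as CSV/GeoJSON/Newick files; same seed, same bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(df: pd.DataFrame, name: str, float_fmt="%.6f"):
        p = out / name
        df.to_csv(p, index=False, float_format=float_fmt, lineterminator="\n")
        paths[name] = p

    save(study.occurrences, "occurrences.csv")
    save(study.specimens, "specimens.csv", float_fmt="%.4f")
    save(study.interactions, "interactions.csv")
    save(study.domatia, "domatia.csv")
    save(study.validation, "validation.csv")
    save(study.truth, "truth.csv")
    p = out / "regions.geojson"
    p.write_text(json.dumps(study.regions_geojson, sort_keys=True) + "\n")
    paths["regions.geojson"] = p
    p = out / "tree.nwk"
    write_newick(study.tree, p)
    paths["tree.nwk"] = p
    logger.info("synthetic bundle written to %s (%d files)", out, len(paths))
    return paths
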
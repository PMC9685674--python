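"""Range-relative scoring and the final 0-100 specialization ranking.

Raw metric values are mapped onto 0-100 points relative to the range observed
across the clade (linear min-max by default, rank-percentile optionally).
Metrics whose small values indicate specialization (extent of occurrence,
distinct-region count, plasticity) are inverted so that 100 always means
"most specialized".  Extent of occurrence gets special treatment: the upper
tail of its heavily right-skewed distribution is capped at zero points before
the remaining species are rescaled.  A species' final ranking is the
equal-weight mean of whatever metric scores it has — a species with three of
four metrics has each weighted 1/3, keeping data-deficient species on the
same 0-100 scale as fully represented ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cladespec")

__all__ = [
    "ScoringConfig",
    "range_score",
    "apply_eoo_cap",
    "final_ranking",
    "classify",
]

METRICS_5 = ("eoo_km2", "del", "plasticity", "interactions", "domatia_total")
METRICS_4 = ("eoo_km2", "del", "plasticity", "interactions")


@dataclass(frozen=True)
class ScoringConfig:
    """Options of the scoring scheme.

    ``inverted`` metrics score high when their raw value is low.  The default
    metric set is the four-metric model retained by model selection; set
    ``metrics=METRICS_5`` for the a-priori five-metric model (domatia
    included, each metric then worth 20%).
    """

    metrics: tuple[str, ...] = METRICS_4
    inverted: frozenset = frozenset({"eoo_km2", "del", "plasticity"})
    cap_percentile: float = 0.20
    score_mode: str = "linear"  # or "rank"

    def __post_init__(self):
        if not 0.0 <= self.cap_percentile < 1.0:
            raise ValueError("cap_percentile must be in [0, 1)")
        if self.score_mode not in {"linear", "rank"}:
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        bad = self.inverted - set(METRICS_5)
        if bad:
            raise ValueError(f"unknown inverted metrics {sorted(bad)}")

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "ScoringConfig":
        kwargs = {}
        if "metrics" in cfg:
            m = cfg["metrics"]
            kwargs["metrics"] = tuple(m) if isinstance(m, (tuple, list)) else (m,)
        if "inverted" in cfg:
            m = cfg["inverted"]
            kwargs["inverted"] = frozenset(m if isinstance(m, (tuple, list)) else (m,))
        if "cap_percentile" in cfg:
            kwargs["cap_percentile"] = float(cfg["cap_percentile"])
        if "score_mode" in cfg:
            kwargs["score_mode"] = str(cfg["score_mode"])
        return cls(**kwargs)


def range_score(values: pd.Series, invert: bool, mode: str = "linear") -> pd.Series:
    """Map raw metric values onto 0-100 points relative to the clade's range.

    ``linear``: 100*(x-min)/(max-min), flipped when ``invert``.  ``rank``:
    percentile of the mid-rank among non-missing values.  Missing stays
    missing.  If every present value is identical the metric cannot
    discriminate: every species gets 50 and a warning is logged.
    """
    values = pd.Series(values, dtype=float)
    present = values.dropna()
    if len(present) < 2:
        raise ValueError(f"need >= 2 non-missing values, have {len(present)}")
    lo, hi = float(present.min()), float(present.max())
    if lo == hi:
        logger.warning("degenerate metric: all %d values equal %g; scoring 50", len(present), lo)
        return values.where(values.isna(), 50.0)
    if mode == "linear":
        scaled = 100.0 * (values - lo) / (hi - lo)
    elif mode == "rank":
        ranks = present.rank(method="average")
        scaled = 100.0 * (ranks - 1.0) / (len(present) - 1.0)
        scaled = scaled.reindex(values.index)
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return (100.0 - scaled) if invert else scaled


def apply_eoo_cap(
    eoo: pd.Series, cap_percentile: float = 0.20, mode: str = "linear"
) -> tuple[pd.Series, pd.Index]:
    """Score extent of occurrence with the widest-ranging tail capped at zero.

    The ``ceil(cap_percentile * n)`` species with the largest EOO are assigned
    zero specialization points outright (their log-distributed areas would
    otherwise compress everyone else's scores); the rest are range-scored,
    inverted, over the remaining values only.  Ties straddling the boundary
    are all capped.  Returns (scores, capped species index).
    """
    eoo = pd.Series(eoo, dtype=float)
    present = eoo.dropna()
    n = len(present)
    if n < 5:
        raise ValueError(f"EOO cap needs >= 5 species with EOO, have {n}")
    k = math.ceil(cap_percentile * n)
    scores = pd.Series(np.nan, index=eoo.index, dtype=float)
    if k == 0:
        scores.loc[present.index] = range_score(present, invert=True, mode=mode)
        return scores, pd.Index([])
    order = present.sort_values(ascending=False)
    threshold = float(order.iloc[k - 1])
    capped = present.index[present >= threshold]
    if len(capped) > k:
        logger.info("EOO cap: %d species tied at the boundary; capping all %d",
                    len(capped) - k, len(capped))
    scores.loc[capped] = 0.0
    rest = present.drop(capped)
    if len(rest) >= 2:
        scores.loc[rest.index] = range_score(rest, invert=True, mode=mode)
    elif len(rest) == 1:
        scores.loc[rest.index] = 100.0
    logger.info("EOO cap: %d of %d species capped at zero points", len(capped), n)
    return scores, capped


def final_ranking(
    metric_table: pd.DataFrame, config: ScoringConfig | None = None
) -> pd.DataFrame:
    """Score every metric and combine into the final specialization ranking.

    Output frame indexed by species, with per-metric raw values,
    ``score_<metric>`` and ``weight_<metric>`` columns, the number of metrics
    available, the final 0-100 ranking (the weighted mean of available
    scores, equal weights), and the specialized/generalized class.
    """
    config = config or ScoringConfig()
    table = metric_table.copy()
    scores = pd.DataFrame(index=table.index, dtype=float)
    for metric in config.metrics:
        if metric not in table.columns:
            raise KeyError(f"metric column {metric!r} missing from table")
        col = table[metric]
        if col.notna().sum() < 2:
            logger.warning("metric %s has <2 values; skipped entirely", metric)
            scores[metric] = np.nan
            continue
        if metric == "eoo_km2" and config.cap_percentile > 0:
            scores[metric], _ = apply_eoo_cap(col, config.cap_percentile, config.score_mode)
        else:
            scores[metric] = range_score(
                col, invert=metric in config.inverted, mode=config.score_mode
            )
    available = scores.notna()
    n_avail = available.sum(axis=1)
    weights = available.astype(float).div(n_avail.replace(0, np.nan), axis=0)
    final = (scores * weights).sum(axis=1, min_count=1)

    out = table.loc[:, [m for m in config.metrics]].copy()
    for metric in config.metrics:
        out[f"score_{metric}"] = scores[metric]
        out[f"weight_{metric}"] = weights[metric].fillna(0.0)
    out["n_metrics_available"] = n_avail.astype(int)
    out["final_ranking"] = final
    dropped = out.index[out["n_metrics_available"] == 0]
    if len(dropped):
        logger.info("excluding %d species with zero scored metrics", len(dropped))
        out = out.drop(index=dropped)
    out["class"] = out["final_ranking"].map(classify)
    logger.info(
        "rankings: %d species (%d fully represented)",
        len(out), int((out["n_metrics_available"] == len(config.metrics)).sum()),
    )
    return out


def classify(ranking: float) -> str:
    """Specialized (>50) / generalized (<50) / boundary (=50) label."""
    if not 0.0 <= ranking <= 100.0:
        raise ValueError(f"ranking {ranking} outside [0, 100]")
    if ranking > 50.0:
        return "specialized"
    if ranking < 50.0:
        return "generalized"
    return "boundary"
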
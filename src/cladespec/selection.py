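"""Model selection and validation statistics.

Small-sample AICc all-subsets selection of which candidate metrics predict an
external designation (an ordinal threat code or a mean expert score), plus the
statistics used to compare the three designation systems with one another:
paired t-test, one-way ANOVA with Tukey-Kramer pairwise comparisons and a
compact letter display, and simple OLS regression.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import IUCN_CATEGORIES, THREATENED

logger = logging.getLogger("cladespec")

__all__ = [
    "ModelFit",
    "PairedTestResult",
    "GroupComparison",
    "aicc_correction",
    "aicc_subset_select",
    "paired_t",
    "anova_tukey_letters",
    "compact_letter_display",
    "simple_regression",
    "iucn_codes",
    "pool_threatened",
]

#: ordinal codes for least-squares fits on threat categories; DD is excluded
IUCN_ORDINAL = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}


def iucn_codes(iucn: pd.Series) -> pd.Series:
    """Map threat categories onto 0-4 ordinal codes (DD -> missing)."""
    return iucn.map(IUCN_ORDINAL).astype(float)


def pool_threatened(iucn: pd.Series) -> pd.Series:
    """Pool grades more severe than NT into one 'threatened' group (DD dropped)."""
    out = iucn.where(~iucn.isin(THREATENED), "threatened")
    return out.where(out != "DD")


# ---------------------------------------------------------------------------
# AICc subset selection


@dataclass(frozen=True)
class ModelFit:
    predictors: tuple[str, ...]
    n: int
    k: int  # parameters: coefficients (incl. intercept) + error variance
    loglik: float
    aic: float
    aicc: float
    r2: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ModelFit({'+'.join(self.predictors) or '1'}: n={self.n}, k={self.k}, "
            f"AICc={self.aicc:.2f}, R2={self.r2:.3f})"
        )


def aicc_correction(k: int, n: int) -> float:
    """Small-sample AIC correction term 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _ols_fit(y: np.ndarray, X: np.ndarray, names: tuple[str, ...]) -> ModelFit | None:
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        logger.warning("collinear predictor subset %s dropped", names)
        return None
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)  # ML variance
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    k = p + 1  # + error variance
    aic = -2.0 * loglik + 2.0 * k
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    if n <= k + 1:
        return None
    return ModelFit(
        predictors=names, n=n, k=k, loglik=loglik, aic=aic,
        aicc=aic + aicc_correction(k, n), r2=r2,
    )


def aicc_subset_select(
    response: pd.Series,
    candidates: pd.DataFrame,
    max_predictors: int | None = None,
) -> list[ModelFit]:
    """Exhaustive OLS subset selection ranked by AICc (ascending).

    Every non-empty subset of the candidate columns is fitted by ordinary
    least squares on its complete cases (intercept always included); subsets
    that are collinear or leave too few observations are dropped with a
    warning.  The first element of the returned list is the AICc-best model.
    """
    cols = list(candidates.columns)
    if not cols:
        raise ValueError("no candidate predictors")
    if len(cols) > 8:
        raise ValueError(f"{len(cols)} candidates exceed the exhaustive-search bound (8)")
    max_predictors = max_predictors or len(cols)
    fits: list[ModelFit] = []
    for r in range(1, max_predictors + 1):
        for subset in itertools.combinations(cols, r):
            data = pd.concat([response.rename("__y"), candidates[list(subset)]], axis=1).dropna()
            if len(data) < len(subset) + 4:  # n > k+2 with k = len(subset)+2
                logger.warning("subset %s: too few complete cases (%d)", subset, len(data))
                continue
            y = data["__y"].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in subset])
            fit = _ols_fit(y, X, subset)
            if fit is not None:
                fits.append(fit)
    if not fits:
        raise ValueError("no fittable predictor subset")
    fits.sort(key=lambda f: f.aicc)
    return fits


def selected_metric_union(
    fits_per_response: Mapping[str, Sequence[ModelFit]]
) -> tuple[str, ...]:
    """Union of predictors in the AICc-best model for each response."""
    union: set[str] = set()
    for name, fits in fits_per_response.items():
        best = fits[0]
        logger.info("best model for %s: %s", name, best)
        union |= set(best.predictors)
    return tuple(sorted(union))


# ---------------------------------------------------------------------------
# Paired t


@dataclass(frozen=True)
class PairedTestResult:
    mean_difference: float
    t_ratio: float
    df: int
    p: float
    n: int


def paired_t(a: pd.Series, b: pd.Series) -> PairedTestResult:
    """Classical paired t-test on complete pairs, two-sided.

    ``mean_difference`` is mean(a - b): positive when the first system scores
    higher on average than the second.
    """
    data = pd.concat([pd.Series(a).rename("a"), pd.Series(b).rename("b")], axis=1).dropna()
    if len(data) < 2:
        raise ValueError(f"need >= 2 complete pairs, have {len(data)}")
    d = data["a"].to_numpy(dtype=float) - data["b"].to_numpy(dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return PairedTestResult(0.0, 0.0, len(d) - 1, 1.0, len(d))
        raise ValueError("zero variance of nonzero differences")
    t = d.mean() / (sd / math.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), df=len(d) - 1)
    return PairedTestResult(float(d.mean()), float(t), len(d) - 1, float(p), len(d))


# ---------------------------------------------------------------------------
# ANOVA + Tukey-Kramer + compact letter display


@dataclass
class GroupComparison:
    groups: tuple[str, ...]
    means: dict[str, float]
    sizes: dict[str, int]
    F: float
    p: float
    pairwise_p: pd.DataFrame  # symmetric matrix of Tukey-Kramer p-values
    letters: dict[str, str]  # compact letter display
    alpha: float


def compact_letter_display(
    groups: Sequence[str], significant: Sequence[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter exactly when their pairwise comparison is NOT in
    ``significant``.  Starts from one column holding every group; each
    significant pair splits every column containing both; columns that become
    subsets of another are absorbed.
    """
    columns: list[set[str]] = [set(groups)]
    for g1, g2 in significant:
        for col in [c for c in columns if g1 in c and g2 in c]:
            columns.remove(col)
            columns.append(col - {g1})
            columns.append(col - {g2})
        # absorb: drop columns contained in another
        columns = [
            c for i, c in enumerate(columns)
            if c and not any(c < other or (c == other and i > j)
                             for j, other in enumerate(columns) if j != i)
        ]
    letters = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, col in enumerate(columns):
        tag = alphabet[idx] if idx < 26 else f"l{idx}"
        for g in groups:
            if g in col:
                letters[g] += tag
    return letters


def anova_tukey_letters(
    values: pd.Series, groups: pd.Series, alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA with Tukey-Kramer pairwise comparisons and letters.

    Pairwise p-values come from the studentized-range distribution with the
    Kramer adjustment for unequal group sizes; two groups share a letter iff
    their comparison is non-significant at ``alpha``.  Groups with fewer than
    2 members are excluded (log note) — pool threat grades beforehand with
    :func:`pool_threatened` if that is the intended design.
    """
    data = pd.concat([pd.Series(values).rename("v"), pd.Series(groups).rename("g")], axis=1).dropna()
    counts = data.groupby("g").size()
    small = counts.index[counts < 2]
    if len(small):
        logger.info("excluding group(s) with <2 members: %s", list(small))
        data = data[~data["g"].isin(small)]
        counts = counts.drop(index=small)
    names = tuple(sorted(counts.index))
    if len(names) < 2:
        raise ValueError(f"need >= 2 groups with >= 2 members, have {len(names)}")
    samples = [data.loc[data["g"] == g, "v"].to_numpy(dtype=float) for g in names]
    F, p = stats.f_oneway(*samples)
    tk = stats.tukey_hsd(*samples)
    pw = pd.DataFrame(np.asarray(tk.pvalue), index=names, columns=names)
    significant = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if pw.iloc[i, j] < alpha
    ]
    letters = compact_letter_display(names, significant)
    return GroupComparison(
        groups=names,
        means={g: float(np.mean(s)) for g, s in zip(names, samples)},
        sizes={g: int(len(s)) for g, s in zip(names, samples)},
        F=float(F),
        p=float(p),
        pairwise_p=pw,
        letters=letters,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Simple regression


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def simple_regression(y: pd.Series, x: pd.Series) -> RegressionResult:
    """OLS of y on x (complete cases), with the two-sided slope test."""
    data = pd.concat([pd.Series(y).rename("y"), pd.Series(x).rename("x")], axis=1).dropna()
    if len(data) < 3:
        raise ValueError(f"need >= 3 complete cases, have {len(data)}")
    if data["x"].nunique() < 2:
        raise ValueError("zero variance in x")
    res = stats.linregress(data["x"], data["y"])
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=len(data),
    )
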
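"""Shared data model and file I/O.

Every table and tree entering the pipeline passes through this module, so
species labels are normalized once, identically, everywhere: tree tips written
in the underscored Newick convention join exactly against CSV rows written
with spaces.  Validation is row-wise and forgiving — offending rows are
rejected with a numbered diagnostic while the rest of the file loads.
"""

from __future__ import annotations

import difflib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger("cladespec")

__all__ = [
    "normalize_label",
    "TableResult",
    "SCHEMAS",
    "read_table",
    "read_newick",
    "write_newick",
    "prune_to_common",
    "load_config",
    "SchemaError",
    "NewickError",
    "PruneError",
]

IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "DD")
#: IUCN grades pooled as "threatened" (anything more severe than NT)
THREATENED = ("VU", "EN", "CR")

_WS_RUN = re.compile(r"[\s_]+")


class SchemaError(ValueError):
    """Header of a CSV does not match the requested schema."""


class NewickError(ValueError):
    """Tree file violates the single-rooted-tree-with-branch-lengths contract."""


class PruneError(ValueError):
    """Tree and table share no species."""


def normalize_label(label: str) -> str:
    """Canonicalize a species label.

    Trims, collapses every run of whitespace and/or underscores to a single
    underscore, and preserves case.  Idempotent:
    ``normalize_label(normalize_label(s)) == normalize_label(s)``.
    """
    return _WS_RUN.sub("_", str(label).strip())


# ---------------------------------------------------------------------------
# Tabular schemas


def _check_lon(v: float) -> str | None:
    return None if -180.0 <= v <= 180.0 else f"lon {v} outside [-180, 180]"


def _check_lat(v: float) -> str | None:
    return None if -90.0 <= v <= 90.0 else f"lat {v} outside [-90, 90]"


def _check_positive(name: str) -> Callable[[float], str | None]:
    def check(v: float) -> str | None:
        return None if v > 0 else f"{name} {v} not strictly positive"

    return check


def _check_nonneg(name: str) -> Callable[[float], str | None]:
    def check(v: float) -> str | None:
        return None if v >= 0 else f"{name} {v} negative"

    return check


def _check_range(name: str, lo: float, hi: float) -> Callable[[float], str | None]:
    def check(v: float) -> str | None:
        return None if lo <= v <= hi else f"{name} {v} outside [{lo}, {hi}]"

    return check


def _check_int(name: str) -> Callable[[float], str | None]:
    def check(v: float) -> str | None:
        return None if float(v).is_integer() else f"{name} {v} not an integer"

    return check


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    numeric: tuple[str, ...] = ()
    #: per-column value checks, applied to present (non-missing) cells
    checks: dict[str, tuple[Callable[[float], str | None], ...]] = field(
        default_factory=dict
    )
    categorical: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: extra numeric columns are accepted (specimen trait tables vary)
    open_numeric: bool = False


TRAIT_COLUMNS = (
    "petiole_length",
    "leaf_length",
    "leaf_lobedness",
    "specific_leaf_area",
    "perimeter_per_area",
    "venation",
)

SCHEMAS: dict[str, TableSchema] = {
    "occurrences": TableSchema(
        name="occurrences",
        required=("species", "lon", "lat"),
        numeric=("lon", "lat"),
        checks={"lon": (_check_lon,), "lat": (_check_lat,)},
    ),
    "specimens": TableSchema(
        name="specimens",
        required=("species", "specimen_id"),
        numeric=(),
        checks={t: (_check_positive(t),) for t in TRAIT_COLUMNS},
        open_numeric=True,
    ),
    "metrics": TableSchema(
        name="metrics",
        required=("species",),
        numeric=("eoo_km2", "del", "plasticity", "interactions", "domatia_total"),
        checks={
            "eoo_km2": (_check_nonneg("eoo_km2"),),
            "del": (_check_int("del"), _check_range("del", 1, float("inf"))),
            "plasticity": (_check_nonneg("plasticity"),),
            "interactions": (
                _check_int("interactions"),
                _check_nonneg("interactions"),
            ),
            "domatia_total": (
                _check_int("domatia_total"),
                _check_range("domatia_total", 0, 6),
            ),
        },
    ),
    "validation": TableSchema(
        name="validation",
        required=("species",),
        numeric=("survey_score", "bio15"),
        checks={"survey_score": (_check_range("survey_score", 0, 100),)},
        categorical={"iucn": IUCN_CATEGORIES},
    ),
    "assignments": TableSchema(
        name="assignments",
        required=("species", "region"),
        numeric=("count",),
        checks={"count": (_check_int("count"), _check_range("count", 1, float("inf")))},
    ),
    "domatia": TableSchema(
        name="domatia",
        required=("species", "code"),
        numeric=("code",),
        checks={"code": (_check_int("code"), _check_range("code", 0, 2))},
    ),
    "interactions": TableSchema(
        name="interactions",
        required=("species", "partner"),
    ),
    "rankings": TableSchema(
        name="rankings",
        required=("species", "final_ranking"),
        numeric=("final_ranking",),
        checks={"final_ranking": (_check_range("final_ranking", 0, 100),)},
    ),
}


@dataclass
class TableResult:
    """A validated table plus the rows it rejected."""

    frame: pd.DataFrame
    rejected: pd.DataFrame  # columns: row (1-based data row), reason

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.frame)


def read_table(path: str | Path, schema: str | TableSchema) -> TableResult:
    """Read and validate a CSV against a named schema.

    Missing values are an empty cell or the literal ``NA`` — nothing else.
    Rows violating a column invariant are dropped and reported in
    ``TableResult.rejected`` with their 1-based data-row number.
    """
    sch = SCHEMAS[schema] if isinstance(schema, str) else schema
    raw = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=["", "NA"], skipinitialspace=True
    )
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing_cols = [c for c in sch.required if c not in raw.columns]
    if missing_cols:
        raise SchemaError(
            f"{path}: schema '{sch.name}' requires columns {missing_cols}; "
            f"found {list(raw.columns)}"
        )
    if raw.empty:
        logger.warning("%s: header only, empty %s table", path, sch.name)

    frame = raw.copy()
    if "species" in frame.columns:
        frame["species"] = frame["species"].map(
            lambda s: normalize_label(s) if pd.notna(s) else s
        )

    numeric_cols = set(sch.numeric)
    if sch.open_numeric:
        numeric_cols |= {
            c for c in frame.columns if c not in sch.required and c not in sch.categorical
        }
    reasons: dict[int, str] = {}
    for col in sorted(numeric_cols):
        if col not in frame.columns:
            continue
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = frame[col].notna() & converted.isna()
        for i in frame.index[bad]:
            reasons.setdefault(i, f"column '{col}': unparseable value {frame.at[i, col]!r}")
        frame[col] = converted
    for col, checks in sch.checks.items():
        if col not in frame.columns:
            continue
        for i in frame.index[frame[col].notna()]:
            if i in reasons:
                continue
            for check in checks:
                msg = check(frame.at[i, col])
                if msg is not None:
                    reasons[i] = f"column '{col}': {msg}"
                    break
    for col, allowed in sch.categorical.items():
        if col not in frame.columns:
            continue
        frame[col] = frame[col].str.strip().str.upper().where(frame[col].notna())
        for i in frame.index[frame[col].notna()]:
            if i not in reasons and frame.at[i, col] not in allowed:
                reasons[i] = f"column '{col}': {frame.at[i, col]!r} not in {allowed}"
    if "species" in frame.columns:
        for i in frame.index:
            if i not in reasons and (pd.isna(frame.at[i, "species"]) or frame.at[i, "species"] == ""):
                reasons[i] = "column 'species': empty label"

    rejected = pd.DataFrame(
        {"row": [i + 1 for i in sorted(reasons)], "reason": [reasons[i] for i in sorted(reasons)]}
    )
    kept = frame.drop(index=list(reasons)).reset_index(drop=True)
    if len(rejected):
        logger.info(
            "%s: %d of %d rows rejected (%s)", path, len(rejected), len(frame), sch.name
        )
        for _, r in rejected.iterrows():
            logger.debug("  row %d: %s", r["row"], r["reason"])
    return TableResult(frame=kept, rejected=rejected)


# ---------------------------------------------------------------------------
# Trees


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths on all non-root edges.

    Tip labels are normalized like every other species label.  Zero-length
    terminal branches are permitted but logged; a missing branch length on any
    non-root edge is an error naming the edge.
    """
    trees = dendropy.TreeList.get(path=str(path), schema="newick", preserve_underscores=True)
    if len(trees) != 1:
        raise NewickError(f"{path}: expected exactly one tree, found {len(trees)}")
    tree = trees[0]
    tree.is_rooted = True
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not str(leaf.taxon.label).strip():
            raise NewickError(f"{path}: unlabeled tip")
        leaf.taxon.label = normalize_label(leaf.taxon.label)
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in seen:
            raise NewickError(f"{path}: duplicate tip label {leaf.taxon.label!r}")
        seen.add(leaf.taxon.label)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else "internal edge above " + _describe(node)
            raise NewickError(f"{path}: missing branch length for {name}")
        if node.edge.length < 0:
            raise NewickError(f"{path}: negative branch length on {_describe(node)}")
        if node.is_leaf() and node.edge.length == 0:
            logger.warning("%s: zero-length terminal branch at %s", path, node.taxon.label)
    return tree


def _describe(node: dendropy.Node) -> str:
    tips = sorted(l.taxon.label for l in node.leaf_iter() if l.taxon)
    return "{" + ",".join(tips[:4]) + ("...}" if len(tips) > 4 else "}")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_to_common(
    tree: dendropy.Tree, species: Iterable[str] | pd.DataFrame
) -> tuple[dendropy.Tree, list[str]]:
    """Restrict a tree to the species shared with a table.

    Returns a pruned deep copy (unary interior nodes suppressed, branch
    lengths summed so patristic distances among survivors are untouched) and
    the sorted list of shared species.  Raises :class:`PruneError`, with
    nearest-label suggestions, when the intersection is empty.
    """
    if isinstance(species, pd.DataFrame):
        species = species["species"].tolist()
    wanted = {normalize_label(s) for s in species}
    tips = set(tip_labels(tree))
    common = sorted(tips & wanted)
    if not common:
        hints = {
            s: difflib.get_close_matches(s, sorted(tips), n=1)
            for s in sorted(wanted)[:10]
        }
        hint_txt = "; ".join(f"{s!r} ~ {m[0]!r}" if m else f"{s!r} ~ ?" for s, m in hints.items())
        raise PruneError(f"no species shared between tree and table (nearest: {hint_txt})")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(common)
    pruned.purge_taxon_namespace()
    logger.info(
        "pruned tree: %d tips in, %d retained (%d table species)",
        len(tips), len(common), len(wanted),
    )
    return pruned, common


# ---------------------------------------------------------------------------
# Flat key=value configuration


def _parse_value(text: str):
    text = text.strip()
    low = text.lower()
    if low in {"true", "yes", "on"}:
        return True
    if low in {"false", "no", "off"}:
        return False
    if "," in text:
        return tuple(_parse_value(t) for t in text.split(",") if t.strip())
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    return text


def load_config(path: str | Path) -> dict:
    """Read a flat ``key = value`` config file (# comments, comma lists)."""
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip().lower()] = _parse_value(value)
    return out
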
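"""Individual- and region-level data containers and cross-level mappings.

The model works on two linked tables.  The individual table holds one row per
subject: an event count ``y_ij``, an individual design matrix ``X`` (with
intercept) and the subject's region.  The region table holds one row per
region in the canonical order fixed by the adjacency structure: the group
covariate matrix ``U``.

Region membership implicitly defines the ``n x M`` replication matrix ``Z``
(one 1 per row).  ``Z`` is never formed densely: products with ``Z`` and
``Z^T`` are group scatter/gather operations on ``region_index``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import DataError


@dataclass
class IndividualTable:
    """Subject-level outcomes, design matrix and region membership.

    Attributes
    ----------
    y
        Non-negative integer event counts, length ``n``.
    X
        ``n x p`` design matrix of individual covariates, including an
        intercept column.
    region_index
        Per-subject 0-based region position in the canonical order, length
        ``n``.
    n_regions
        Total number of regions ``M`` in the canonical order (regions with
        no subjects are permitted at this level but rejected by the fitters).
    x_names
        Column names of ``X``.
    frame
        Optional raw covariate columns (pre dummy-expansion), used for
        stratified standardization.
    region_labels
        Optional canonical region labels (length ``n_regions``).
    """

    y: np.ndarray
    X: np.ndarray
    region_index: np.ndarray
    n_regions: int
    x_names: list = field(default_factory=list)
    frame: pd.DataFrame | None = None
    region_labels: list | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.X = np.asarray(self.X, dtype=float)
        self.region_index = np.asarray(self.region_index, dtype=np.intp)
        if self.y.ndim != 1 or self.X.ndim != 2 or self.region_index.ndim != 1:
            raise DataError("y and region_index must be 1-d, X 2-d")
        if not (len(self.y) == self.X.shape[0] == len(self.region_index)):
            raise DataError("y, X and region_index have inconsistent lengths")
        if not np.issubdtype(self.y.dtype, np.integer):
            yf = np.asarray(self.y, dtype=float)
            if not np.all(np.isfinite(yf)) or np.any(yf != np.round(yf)):
                raise DataError("y must contain finite integers")
            self.y = yf.astype(np.int64)
        if np.any(self.y < 0):
            raise DataError("y must be non-negative")
        if not np.all(np.isfinite(self.X)):
            raise DataError("X contains missing or non-finite values")
        if len(self.region_index) and (
            self.region_index.min() < 0 or self.region_index.max() >= self.n_regions
        ):
            raise DataError("region_index out of range [0, n_regions)")
        if not self.x_names:
            self.x_names = [f"x{k}" for k in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def counts_per_region(self) -> np.ndarray:
        """Number of subjects ``n_j`` in each region."""
        return np.bincount(self.region_index, minlength=self.n_regions)


@dataclass
class RegionTable:
    """Region-level covariates aligned to the canonical region order."""

    U: np.ndarray
    region_labels: list
    u_names: list = field(default_factory=list)

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        if self.U.ndim != 2:
            raise DataError("U must be 2-d (M x q); use shape (M, 0) for q = 0")
        if self.U.shape[0] != len(self.region_labels):
            raise DataError("U rows do not match region_labels")
        if not np.all(np.isfinite(self.U)):
            raise DataError("U contains missing or non-finite values")
        if not self.u_names:
            self.u_names = [f"u{k}" for k in range(self.U.shape[1])]

    @property
    def M(self) -> int:
        return self.U.shape[0]

    @property
    def q(self) -> int:
        return self.U.shape[1]


def aggregate_counts(data: IndividualTable) -> np.ndarray:
    """Region-level aggregated counts ``Y_c = Z^T Y`` (length ``M``)."""
    return np.bincount(
        data.region_index, weights=np.asarray(data.y, dtype=float),
        minlength=data.n_regions,
    ).astype(np.int64)


def individual_offset_to_group(data: IndividualTable, beta: np.ndarray) -> np.ndarray:
    """Group offset ``O1 = log{ Z^T exp(X beta) }`` (length ``M``).

    Component ``j`` is the log of the summed individual-level Poisson means
    over subjects of region ``j``; computed in log-space (per-region
    log-sum-exp) for stability.  Regions with no subjects are rejected: the
    offset would be ``log 0``.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (data.p,):
        raise DataError(f"beta must have length p={data.p}")
    n_j = data.counts_per_region()
    if np.any(n_j == 0):
        empty = np.flatnonzero(n_j == 0)
        raise DataError(
            f"{empty.size} region(s) have no subjects (first: {empty[:5].tolist()}); "
            "the group offset log sum exp(X beta) is undefined there"
        )
    eta = data.X @ beta
    g = data.region_index
    m = np.full(data.n_regions, -np.inf)
    np.maximum.at(m, g, eta)
    s = np.bincount(g, weights=np.exp(eta - m[g]), minlength=data.n_regions)
    return m + np.log(s)


def group_offset_to_individual(
    data: IndividualTable, region_effects: np.ndarray
) -> np.ndarray:
    """Individual offset ``O2 = Z v`` replicating a region-level vector ``v``."""
    region_effects = np.asarray(region_effects, dtype=float)
    if region_effects.shape != (data.n_regions,):
        raise DataError(f"region_effects must have length M={data.n_regions}")
    return region_effects[data.region_index]


# ---------------------------------------------------------------------------
# CSV reading with a declared covariate schema
# ---------------------------------------------------------------------------

def load_schema(path) -> dict:
    """Load a covariate schema from a YAML or JSON file.

    Expected keys: ``region_column``, ``outcome_column`` and ``covariates``,
    a list of ``{name, type}`` entries where ``type`` is ``numeric`` or
    ``categorical``; categorical entries declare their ``levels`` in order,
    the first level being the reference absorbed into the intercept.
    """
    text = open(path, encoding="utf-8").read()
    schema = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    for key in ("region_column", "outcome_column", "covariates"):
        if key not in schema:
            raise DataError(f"schema is missing required key {key!r}")
    for cov in schema["covariates"]:
        if cov.get("type") not in ("numeric", "categorical"):
            raise DataError(f"covariate {cov.get('name')!r}: type must be "
                            "'numeric' or 'categorical'")
        if cov["type"] == "categorical" and not cov.get("levels"):
            raise DataError(f"categorical covariate {cov['name']!r} needs 'levels'")
    return schema


def build_design(df: pd.DataFrame, schema: dict):
    """Build the individual design matrix (intercept first) from a schema.

    Categorical covariates are reference-coded: with levels ``l1, ..., lk``
    declared in the schema, columns ``name[l2], ..., name[lk]`` are emitted
    and ``l1`` is the reference level.
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for cov in schema["covariates"]:
        name = cov["name"]
        if name not in df.columns:
            raise DataError(f"covariate column {name!r} not found in table")
        col = df[name]
        if cov["type"] == "numeric":
            vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            bad = np.flatnonzero(~np.isfinite(vals))
            if bad.size:
                raise DataError(f"column {name!r}: non-numeric/missing value "
                                f"at row {bad[0] + 2} of the CSV")
            cols.append(vals)
            names.append(name)
        else:
            levels = [str(l) for l in cov["levels"]]
            vals = col.astype(str).to_numpy()
            unknown = ~np.isin(vals, levels)
            if unknown.any():
                row = int(np.flatnonzero(unknown)[0])
                raise DataError(
                    f"column {name!r}: level {vals[row]!r} at row {row + 2} "
                    f"not among declared levels {levels}"
                )
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float))
                names.append(f"{name}[{lev}]")
    return np.column_stack(cols), names


def read_individual_csv(path, schema, region_labels=None) -> IndividualTable:
    """Read the individual-level table from CSV.

    Parameters
    ----------
    path
        CSV file with a header row; comma-separated, UTF-8.
    schema
        Covariate schema (dict, or path accepted by :func:`load_schema`).
    region_labels
        Canonical region ordering (from the adjacency structure).  When
        omitted, the sorted distinct labels found in the file are used.
        Every canonical region must appear at least once: the fitters
        require ``n_j >= 1``.
    """
    if not isinstance(schema, dict):
        schema = load_schema(schema)
    df = pd.read_csv(path, dtype={schema["region_column"]: str})
    for colname in (schema["region_column"], schema["outcome_column"]):
        if colname not in df.columns:
            raise DataError(f"{path}: missing required column {colname!r}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise DataError(f"{path}: missing cell at row {row + 2}")
    y_raw = pd.to_numeric(df[schema["outcome_column"]], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(y_raw) | (y_raw != np.round(y_raw)) | (y_raw < 0))
    if bad.size:
        raise DataError(f"{path}: outcome at row {bad[0] + 2} is not a "
                        "non-negative integer")
    labels = df[schema["region_column"]].to_numpy()
    if region_labels is None:
        region_labels = sorted(set(labels))
    index = {str(lab): j for j, lab in enumerate(region_labels)}
    region_index = np.empty(len(df), dtype=np.intp)
    for i, lab in enumerate(labels):
        j = index.get(str(lab))
        if j is None:
            raise DataError(f"{path}: unknown region id {lab!r} at row {i + 2}")
        region_index[i] = j
    present = np.bincount(region_index, minlength=len(region_labels))
    if np.any(present == 0):
        missing = [region_labels[j] for j in np.flatnonzero(present == 0)[:5]]
        raise DataError(f"{path}: region(s) with no subjects: {missing}")
    X, x_names = build_design(df, schema)
    raw_cols = [c["name"] for c in schema["covariates"]]
    return IndividualTable(
        y=y_raw.astype(np.int64), X=X, region_index=region_index,
        n_regions=len(region_labels), x_names=x_names,
        frame=df[raw_cols].copy(), region_labels=list(region_labels),
    )


def read_region_csv(path, region_labels=None, region_column="region") -> RegionTable:
    """Read the region-level covariate table from CSV.

    All non-region columns are interpreted as numeric group covariates.  When
    ``region_labels`` is given (canonical order from the adjacency), rows are
    reordered to match and every region must be present exactly once.
    """
    df = pd.read_csv(path, dtype={region_column: str})
    if region_column not in df.columns:
        raise DataError(f"{path}: missing region column {region_column!r}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise DataError(f"{path}: missing cell at row {row + 2}")
    labels = df[region_column].astype(str).to_numpy()
    if len(set(labels)) != len(labels):
        raise DataError(f"{path}: duplicate region rows")
    if region_labels is None:
        region_labels = list(labels)
        order = np.arange(len(labels))
    else:
        pos = {lab: i for i, lab in enumerate(labels)}
        try:
            order = np.array([pos[str(lab)] for lab in region_labels])
        except KeyError as exc:
            raise DataError(f"{path}: region {exc.args[0]!r} missing from table")
    u_names = [c for c in df.columns if c != region_column]
    U = df[u_names].to_numpy(dtype=float)[order]
    return RegionTable(U=U, region_labels=list(region_labels), u_names=u_names)
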
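"""Data model and bookkeeping for age-period-cohort (APC) records.

Age, period (calendar time) and birth cohort are linearly dependent
(``C = P - A``), which is the root of the APC identification problem.  This
module owns the categorisation conventions that every estimator in the
package relies on:

* equal-width (by default five-year) bins for age and period;
* *overlapping* cohort categories derived from the age and period category
  indices, ``c_idx = p_idx - a_idx + (n_age - 1)``, so that the linear
  identity survives categorisation and the number of cohort categories is
  ``n_age + n_period - 1``;
* reference-category dummy coding, giving ``n - 1`` indicator columns per
  dimension.

Bins are half-open ``[lo, hi)`` with the final bin closed at the declared
range maximum, so the oldest age and the last calendar year fall in the last
category.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DIMENSIONS = ("age", "period", "cohort")
_IDX_COL = {"age": "a_idx", "period": "p_idx", "cohort": "c_idx"}


class SchemeError(ValueError):
    """Raised for invalid categorisation schemes or out-of-range values."""


@dataclass(frozen=True)
class CategoryScheme:
    """Equal-width age/period bins plus the derived overlapping cohort categories.

    Parameters
    ----------
    age_edges, period_edges
        Ordered bin boundaries; ``len(edges) - 1`` bins, each ``[lo, hi)``
        except the last, which is closed at the range maximum.
    """

    age_edges: tuple[float, ...]
    period_edges: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, edges in (("age", self.age_edges), ("period", self.period_edges)):
            arr = np.asarray(edges, dtype=float)
            if arr.size < 2 or np.any(np.diff(arr) <= 0):
                raise SchemeError(f"{name} edges must be strictly increasing with >= 2 values")

    @property
    def n_age(self) -> int:
        return len(self.age_edges) - 1

    @property
    def n_period(self) -> int:
        return len(self.period_edges) - 1

    @property
    def n_cohort(self) -> int:
        # overlapping cohort categories preserve C = P - A after binning
        return self.n_age + self.n_period - 1

    def n_categories(self, dim: str) -> int:
        return {"age": self.n_age, "period": self.n_period, "cohort": self.n_cohort}[dim]

    def n_dummies(self, dim: str) -> int:
        return self.n_categories(dim) - 1

    def to_dict(self) -> dict:
        return {"age_edges": list(self.age_edges), "period_edges": list(self.period_edges)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CategoryScheme":
        return cls(tuple(d["age_edges"]), tuple(d["period_edges"]))


def build_scheme(
    age_range: tuple[float, float],
    period_range: tuple[float, float],
    width: float = 5.0,
) -> CategoryScheme:
    """Build a :class:`CategoryScheme` with equal-width bins.

    The last bin is extended (or shortened) to end exactly at the range
    maximum, so e.g. ages 40-95 with five-year bins give 11 age categories.
    """
    if width <= 0:
        raise SchemeError(f"bin width must be positive, got {width}")

    def edges(lo: float, hi: float, what: str) -> tuple[float, ...]:
        if hi <= lo:
            raise SchemeError(f"inverted or empty {what} range [{lo}, {hi}]")
        inner = np.arange(lo, hi, width, dtype=float)
        return tuple(np.append(inner, hi))

    return CategoryScheme(
        age_edges=edges(*map(float, age_range), "age"),
        period_edges=edges(*map(float, period_range), "period"),
    )


#: The study design the synthetic generator emulates: ages 40-95, calendar
#: years 1990-2015, five-year groups -> 11 age, 5 period, 15 cohort categories.
DEFAULT_SCHEME = build_scheme((40.0, 95.0), (1990.0, 2015.0), 5.0)


def _bin_index(values: np.ndarray, edges: Sequence[float], what: str) -> np.ndarray:
    edges_arr = np.asarray(edges, dtype=float)
    values = np.asarray(values, dtype=float)
    out_of_range = (values < edges_arr[0]) | (values > edges_arr[-1])
    if np.any(out_of_range):
        bad = values[out_of_range][:5]
        raise SchemeError(f"{what} values outside [{edges_arr[0]}, {edges_arr[-1]}]: {bad}")
    idx = np.searchsorted(edges_arr, values, side="right") - 1
    return np.minimum(idx, len(edges_arr) - 2)  # range max belongs to last bin


def categorize(
    age: np.ndarray | float,
    period: np.ndarray | float,
    scheme: CategoryScheme,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map continuous age/period to (a_idx, p_idx, c_idx) category indices.

    ``c_idx = p_idx - a_idx + (n_age - 1)`` so the earliest cohort (oldest
    age in the earliest period) gets index 0.
    """
    scalar = np.isscalar(age) and np.isscalar(period)
    a_idx = _bin_index(np.atleast_1d(age), scheme.age_edges, "age")
    p_idx = _bin_index(np.atleast_1d(period), scheme.period_edges, "period")
    c_idx = p_idx - a_idx + (scheme.n_age - 1)
    if scalar:
        return int(a_idx[0]), int(p_idx[0]), int(c_idx[0])
    return a_idx, p_idx, c_idx


@dataclass
class APCDataset:
    """Individual-level APC records plus the scheme that categorised them.

    ``df`` carries columns ``age, period, cohort, a_idx, p_idx, c_idx``, one
    column per mediator, an optional binary confounder column and an
    ``outcome`` column (binary death indicator, or continuous risk score in
    the linear variant).
    """

    df: pd.DataFrame
    scheme: CategoryScheme
    mediators: tuple[str, ...] = ()
    mediator_kinds: dict[str, str] = field(default_factory=dict)  # name -> continuous|binary
    confounder: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["age", "period", "cohort", "a_idx", "p_idx", "c_idx", "outcome"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        for m in self.mediators:
            if m not in self.df.columns:
                raise ValueError(f"mediator column {m!r} not in dataset")
        if self.confounder is not None and self.confounder not in self.df.columns:
            raise ValueError(f"confounder column {self.confounder!r} not in dataset")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def indices(self, dim: str) -> np.ndarray:
        return self.df[_IDX_COL[dim]].to_numpy()

    def mediator_kind(self, name: str) -> str:
        if name in self.mediator_kinds:
            return self.mediator_kinds[name]
        vals = self.df[name].dropna().unique()
        return "binary" if set(np.unique(vals)).issubset({0.0, 1.0, 0, 1}) else "continuous"

    def drop_mediators(self, names: Iterable[str]) -> "APCDataset":
        """Return a copy without the named mediator columns (all else intact)."""
        names = list(names)
        unknown = [m for m in names if m not in self.mediators]
        if unknown:
            raise KeyError(f"unknown mediator(s): {unknown}; have {list(self.mediators)}")
        if not names:
            return self
        keep = tuple(m for m in self.mediators if m not in names)
        return APCDataset(
            df=self.df.drop(columns=names),
            scheme=self.scheme,
            mediators=keep,
            mediator_kinds={m: k for m, k in self.mediator_kinds.items() if m in keep},
            confounder=self.confounder,
            provenance=dict(self.provenance, dropped=names),
        )

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path) -> None:
        """Write records as CSV plus a ``<path>.meta.json`` sidecar for the scheme."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        meta = {
            "scheme": self.scheme.to_dict(),
            "mediators": list(self.mediators),
            "mediator_kinds": dict(self.mediator_kinds),
            "confounder": self.confounder,
            "provenance": _jsonable(self.provenance),
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, scheme: CategoryScheme | None = None) -> "APCDataset":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = Path(str(path) + ".meta.json")
        mediators: tuple[str, ...] = ()
        kinds: dict[str, str] = {}
        confounder = None
        provenance: dict = {"source": str(path)}
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            scheme = scheme or CategoryScheme.from_dict(meta["scheme"])
            mediators = tuple(meta.get("mediators", ()))
            kinds = dict(meta.get("mediator_kinds", {}))
            confounder = meta.get("confounder")
            provenance.update(meta.get("provenance", {}))
        if scheme is None:
            raise ValueError("no sidecar metadata found; a CategoryScheme must be supplied")
        if not mediators:
            known = {"age", "period", "cohort", "a_idx", "p_idx", "c_idx", "outcome", "genotype"}
            mediators = tuple(c for c in df.columns if c not in known)
            if "genotype" in df.columns:
                confounder = "genotype"
        return cls(df=df, scheme=scheme, mediators=mediators,
                   mediator_kinds=kinds, confounder=confounder, provenance=provenance)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def dummy_column_names(scheme: CategoryScheme, dims: Sequence[str],
                       reference: Mapping[str, int] | None = None) -> list[str]:
    reference = reference or {}
    names = []
    for dim in dims:
        ref = reference.get(dim, 0)
        names.extend(f"{dim}_{k}" for k in range(scheme.n_categories(dim)) if k != ref)
    return names


def dummy_encode(
    dataset: APCDataset,
    dimensions: Sequence[str] = DIMENSIONS,
    reference: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Indicator columns for the requested time dimensions.

    One column per non-reference category, named ``<dim>_<k>``; the reference
    category (default: the first) contributes no column, so a record in the
    reference category of every dimension is an all-zero row.
    """
    reference = reference or {}
    cols: dict[str, np.ndarray] = {}
    for dim in dimensions:
        if dim not in DIMENSIONS:
            raise ValueError(f"unknown dimension {dim!r}")
        n_cat = dataset.scheme.n_categories(dim)
        ref = reference.get(dim, 0)
        if not 0 <= ref < n_cat:
            raise ValueError(f"reference index {ref} out of range for {dim} ({n_cat} categories)")
        idx = dataset.indices(dim)
        for k in range(n_cat):
            if k == ref:
                continue
            cols[f"{dim}_{k}"] = (idx == k).astype(float)
    return pd.DataFrame(cols, index=dataset.df.index)


@dataclass
class IdentityReport:
    passed: bool
    n_checked: int
    offending_rows: list[int]

    def __bool__(self) -> bool:
        return self.passed


def validate_identity(dataset: APCDataset, atol: float = 1e-9) -> IdentityReport:
    """Check ``cohort = period - age`` and the category-index identity per record."""
    df = dataset.df
    if len(df) == 0:
        return IdentityReport(True, 0, [])
    cont_ok = np.isclose(df["cohort"], df["period"] - df["age"], atol=atol)
    idx_ok = (df["c_idx"] == df["p_idx"] - df["a_idx"] + (dataset.scheme.n_age - 1)).to_numpy()
    in_range = (df["c_idx"] >= 0) & (df["c_idx"] <= dataset.scheme.n_cohort - 1)
    ok = cont_ok & idx_ok & in_range.to_numpy()
    bad = df.index[~ok].tolist()
    return IdentityReport(len(bad) == 0, len(df), bad)
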
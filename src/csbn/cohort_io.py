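"""Cohort tables, variable schemas and discretization.

A :class:`Cohort` is the single currency passed between all model-fitting
stages: a pandas DataFrame with one row per patient, a follow-up time
column, an event indicator (1 = death, 0 = censored) and categorical or
continuous covariates, together with a list of :class:`VariableSpec`
declaring each column's role.

Continuous covariates are discretized before any Bayesian-network stage:
either at explicit cut points (e.g. age into <45, 45-59, 60-74, >74 years)
or at empirical tertiles learned on the training subset and re-applied
verbatim to validation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "VariableSpec",
    "Cohort",
    "DiscretizationMap",
    "load_schema",
    "read_cohort",
    "write_cohort",
    "discretize",
    "complete_case_split",
    "DEFAULT_NA_TOKENS",
]

#: Cell contents treated as a missing value when reading CSV.
DEFAULT_NA_TOKENS = ("", "NA")

TERTILE_LABELS = ("T1", "T2", "T3")


class SchemaError(ValueError):
    """A cohort value or schema declaration violates the variable schema."""


@dataclass(frozen=True)
class VariableSpec:
    """Role and coding of one cohort column.

    Parameters
    ----------
    name
        Column name in the CSV header.
    role
        One of ``covariate``, ``time``, ``event``, ``id``.
    kind
        ``categorical`` or ``continuous`` (covariates only).
    levels
        Ordered category labels; required for categorical covariates.
    bins
        For continuous covariates: explicit increasing cut points (values
        at a cut point fall in the lower bin), or the token ``"tertile"``
        to learn empirical tertile cut points from training data.
    reference_level
        Baseline category; defaults to the first declared level.
    """

    name: str
    role: str = "covariate"
    kind: str = "categorical"
    levels: tuple[str, ...] = ()
    bins: object = None
    reference_level: str | None = None

    def __post_init__(self):
        if self.role not in {"covariate", "time", "event", "id"}:
            raise SchemaError(f"{self.name}: unknown role {self.role!r}")
        if self.kind not in {"categorical", "continuous"}:
            raise SchemaError(f"{self.name}: unknown kind {self.kind!r}")
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        if self.role == "covariate" and self.kind == "categorical":
            if not self.levels:
                raise SchemaError(f"{self.name}: categorical variable needs levels")
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"{self.name}: duplicate levels")
        if self.bins is not None and not isinstance(self.bins, str):
            cuts = [float(c) for c in self.bins]
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise SchemaError(f"{self.name}: cut points must strictly increase")
            object.__setattr__(self, "bins", tuple(cuts))

    @property
    def reference(self) -> str:
        if self.reference_level is not None:
            return str(self.reference_level)
        return self.levels[0]


def _validate_schema(schema: list[VariableSpec]) -> None:
    names = [s.name for s in schema]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate variable names in schema")
    for role in ("time", "event"):
        k = sum(s.role == role for s in schema)
        if k != 1:
            raise SchemaError(f"schema must declare exactly one {role} variable, found {k}")


@dataclass
class Cohort:
    """Patient-by-variable table plus its schema.

    Missing covariate values are represented as NaN/None cells in ``df``.
    Time values must be positive and finite; event values must be 0 or 1.
    """

    schema: list[VariableSpec]
    df: pd.DataFrame

    def __post_init__(self):
        _validate_schema(self.schema)
        missing_cols = [s.name for s in self.schema if s.name not in self.df.columns]
        if missing_cols:
            raise SchemaError(f"columns absent from table: {missing_cols}")
        if len(self.df) < 1:
            raise SchemaError("cohort must contain at least one row")
        self.df = self.df.reset_index(drop=True)
        self._check_values()

    def _check_values(self) -> None:
        t = pd.to_numeric(self.df[self.time_name], errors="coerce")
        if t.isna().any():
            row = int(t.index[t.isna()][0])
            raise SchemaError(f"non-numeric time at row {row}")
        if not np.all(np.isfinite(t)) or (t <= 0).any():
            raise SchemaError("time values must be positive finite numbers")
        self.df[self.time_name] = t.astype(float)
        e = pd.to_numeric(self.df[self.event_name], errors="coerce")
        if not e.isin([0, 1]).all():
            bad = self.df.index[~e.isin([0, 1])][0]
            raise SchemaError(
                f"event value {self.df.loc[bad, self.event_name]!r} at row "
                f"{int(bad)} is not in {{0,1}}"
            )
        self.df[self.event_name] = e.astype(int)
        for spec in self.schema:
            if spec.role == "covariate" and spec.kind == "categorical":
                col = self.df[spec.name]
                obs = col.dropna().astype(str)
                bad = ~obs.isin(spec.levels)
                if bad.any():
                    row = int(obs.index[bad][0])
                    raise SchemaError(
                        f"value {obs[row]!r} in column {spec.name!r} at row {row} "
                        f"is not a declared level of {list(spec.levels)}"
                    )

    # -- convenience accessors -------------------------------------------
    def _one(self, role: str) -> str:
        return next(s.name for s in self.schema if s.role == role)

    @property
    def time_name(self) -> str:
        return self._one("time")

    @property
    def event_name(self) -> str:
        return self._one("event")

    @property
    def covariate_names(self) -> list[str]:
        return [s.name for s in self.schema if s.role == "covariate"]

    @property
    def N(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.covariate_names)

    @property
    def time(self) -> np.ndarray:
        return self.df[self.time_name].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.df[self.event_name].to_numpy(dtype=int)

    def spec(self, name: str) -> VariableSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(name)

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of missing cells over the covariate columns."""
        return self.df[self.covariate_names].isna()

    def subset(self, index) -> "Cohort":
        """New cohort restricted to the given positional row index."""
        return Cohort(self.schema, self.df.iloc[np.asarray(index)].copy())


@dataclass
class DiscretizationMap:
    """Learned cut points, per continuous variable requesting tertiles."""

    cuts: dict[str, tuple[float, float]] = field(default_factory=dict)


def load_schema(path) -> list[VariableSpec]:
    """Read a schema from a YAML (or JSON) document.

    Expected layout::

        variables:
          - {name: time_years, role: time}
          - {name: death, role: event}
          - {name: age, kind: continuous, bins: [44, 59, 74]}
          - {name: stage, levels: [I, II, III, IV]}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = []
    for item in doc["variables"]:
        item = dict(item)
        if "levels" in item:
            item["levels"] = tuple(item["levels"])
        specs.append(VariableSpec(**item))
    _validate_schema(specs)
    return specs


def read_cohort(path, schema: list[VariableSpec], na_tokens=DEFAULT_NA_TOKENS) -> Cohort:
    """Read a cohort CSV, preserving missing markers.

    Header must contain every schema name; cells equal to a token in
    ``na_tokens`` become missing values.
    """
    _validate_schema(schema)
    df = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=list(na_tokens),
        skipinitialspace=True,
    )
    absent = [s.name for s in schema if s.name not in df.columns]
    if absent:
        raise SchemaError(f"header does not match schema; missing columns {absent}")
    for spec in schema:
        if spec.role == "covariate" and spec.kind == "continuous":
            df[spec.name] = pd.to_numeric(df[spec.name], errors="raise")
    return Cohort(schema, df[[s.name for s in schema]])


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to CSV; missing cells become empty fields."""
    cohort.df.to_csv(path, index=False, na_rep="")


def _explicit_bin_labels(cuts: tuple[float, ...]) -> tuple[str, ...]:
    def fmt(c: float) -> str:
        return f"{c:g}"

    labels = [f"<={fmt(cuts[0])}"]
    labels += [f"({fmt(a)},{fmt(b)}]" for a, b in zip(cuts, cuts[1:])]
    labels.append(f">{fmt(cuts[-1])}")
    return tuple(labels)


def _assign_bins(values: pd.Series, cuts, labels) -> pd.Series:
    # values equal to a cut point fall in the lower bin (right-closed bins)
    idx = np.searchsorted(np.asarray(cuts, dtype=float), values.to_numpy(dtype=float), side="left")
    out = pd.Series(np.asarray(labels, dtype=object)[idx], index=values.index)
    return out


def discretize(cohort: Cohort, dmap: DiscretizationMap | str = "learn") -> tuple[Cohort, DiscretizationMap]:
    """Make every covariate categorical.

    Continuous variables with explicit ``bins`` are cut at those points
    (right-closed intervals); variables declaring ``bins="tertile"`` are cut
    at the empirical 1/3 and 2/3 quantiles, learned here when
    ``dmap="learn"`` or re-applied verbatim from a previously learned
    :class:`DiscretizationMap`. Missing values stay missing.
    """
    learn = isinstance(dmap, str)
    out_map = DiscretizationMap() if learn else dmap
    df = cohort.df.copy()
    new_schema: list[VariableSpec] = []
    for spec in cohort.schema:
        if spec.role != "covariate" or spec.kind != "continuous":
            new_schema.append(spec)
            continue
        col = df[spec.name]
        if spec.bins == "tertile":
            if learn:
                vals = col.dropna().to_numpy(dtype=float)
                if vals.size == 0 or np.all(vals == vals[0]):
                    raise SchemaError(
                        f"{spec.name}: tertile cut points undefined (degenerate variable)"
                    )
                cuts = tuple(np.quantile(vals, [1 / 3, 2 / 3], method="linear"))
                out_map.cuts[spec.name] = cuts
            else:
                if spec.name not in out_map.cuts:
                    raise SchemaError(f"{spec.name}: no learned cut points in map")
                cuts = out_map.cuts[spec.name]
            labels = TERTILE_LABELS
        elif spec.bins is not None:
            cuts = tuple(spec.bins)
            labels = _explicit_bin_labels(cuts)
        else:
            raise SchemaError(f"{spec.name}: continuous variable without bins rule")
        keep = col.notna()
        binned = pd.Series(np.nan, index=col.index, dtype=object)
        binned[keep] = _assign_bins(col[keep], cuts, labels)
        df[spec.name] = binned
        new_schema.append(
            replace(spec, kind="categorical", levels=tuple(labels), bins=None)
        )
    return Cohort(new_schema, df), out_map


def complete_case_split(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition into (complete-case training, remainder-with-missing).

    Mirrors a derivation design where the model is developed on patients
    with no missing covariates and validated on the rest. Raises if no row
    is complete.
    """
    complete = ~cohort.missing_mask().any(axis=1)
    if not complete.any():
        raise SchemaError("no complete-case rows; model cannot be fit")
    idx = np.arange(cohort.N)
    training = cohort.subset(idx[complete.to_numpy()])
    rest_idx = idx[~complete.to_numpy()]
    if rest_idx.size == 0:
        validation = _empty_like(cohort)
    else:
        validation = cohort.subset(rest_idx)
    return training, validation


class _EmptyCohort(Cohort):
    """Zero-row cohort; only produced by :func:`complete_case_split`."""

    def __post_init__(self):  # bypass N >= 1 check
        _validate_schema(self.schema)
        self.df = self.df.reset_index(drop=True)


def _empty_like(cohort: Cohort) -> Cohort:
    return _EmptyCohort(cohort.schema, cohort.df.iloc[:0].copy())
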
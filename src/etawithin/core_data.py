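"""Tidy data model for pairwise-comparison designs.

Everything downstream (t-tests, ANOVA, mixed models) consumes a
:class:`LongTable`: one observation per row, with identifier columns for
the random units (participant, optionally stimulus), label columns for
the experimental factors, optional replicate columns, and one numeric
response column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LongTable",
    "CellSummary",
    "SchemaError",
    "read_long_csv",
    "wide_to_long",
    "long_to_wide",
    "center_by_unit",
    "cell_summaries",
]


class SchemaError(ValueError):
    """The table does not match the declared column roles."""


@dataclass
class LongTable:
    """A validated long-format observation table.

    Parameters
    ----------
    data
        One observation per row.  Factor and unit columns are kept as
        strings; the response column must be numeric and finite.
    response
        Name of the numeric response column.
    participant
        Name of the participant identifier column.
    stimulus
        Name of the stimulus identifier column, if the design crosses
        participants with stimuli.
    factors
        Names of the fixed-factor columns (two observed levels each for
        the designs in scope).
    replicates
        Names of columns that index repeated measurements within a cell
        (e.g. day of testing, parallel test form).  Models ignore them;
        they exist so rows stay uniquely identified.
    """

    data: pd.DataFrame
    response: str
    participant: str
    stimulus: str | None = None
    factors: list[str] = field(default_factory=list)
    replicates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        cols = list(self.data.columns)
        for col in [self.response, self.participant, *self.unit_columns[1:],
                    *self.factors, *self.replicates]:
            if col not in cols:
                raise SchemaError(f"column {col!r} not present in table")
        resp = pd.to_numeric(self.data[self.response], errors="coerce")
        if resp.isna().any():
            bad = int(resp.isna().idxmax())
            raise SchemaError(
                f"non-numeric or missing response at row {bad}"
            )
        if not np.isfinite(resp.to_numpy(dtype=float)).all():
            raise SchemaError("response contains non-finite values")
        self.data[self.response] = resp.astype(float)
        for col in [self.participant, *([self.stimulus] if self.stimulus else []),
                    *self.factors, *self.replicates]:
            self.data[col] = self.data[col].astype(str)
        for f in self.factors:
            nlev = self.data[f].nunique()
            if nlev < 2:
                raise SchemaError(f"factor {f!r} has {nlev} observed level(s); need >= 2")
        key = self.key_columns
        if key and self.data.duplicated(subset=key).any():
            raise SchemaError(
                "rows are not uniquely identified by "
                f"{key}; declare a replicate column or deduplicate"
            )

    @property
    def unit_columns(self) -> list[str]:
        cols = [self.participant]
        if self.stimulus is not None:
            cols.append(self.stimulus)
        return cols

    @property
    def key_columns(self) -> list[str]:
        return [*self.unit_columns, *self.factors, *self.replicates]

    def levels(self, factor: str) -> list[str]:
        """Observed levels of ``factor`` in sorted (lexicographic) order."""
        return sorted(self.data[factor].unique())

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def with_response(self, values: np.ndarray) -> "LongTable":
        new = self.data.copy()
        new[self.response] = np.asarray(values, dtype=float)
        return replace(self, data=new)


@dataclass(frozen=True)
class CellSummary:
    """Descriptives for one design cell: n, mean (M) and SD (n-1 denominator)."""

    cell: tuple[str, ...]
    n: int
    mean: float
    sd: float | None  # None when n == 1 (SD undefined)


def read_long_csv(path, *, response: str, participant: str,
                  stimulus: str | None = None,
                  factors: list[str] | None = None,
                  replicates: list[str] | None = None,
                  sep: str = ",") -> LongTable:
    """Read a long-format CSV/TSV into a :class:`LongTable`.

    Factor and identifier columns are read as strings, never coerced to
    numbers; the response column must parse as numeric.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise SchemaError(f"{path}: empty table")
    return LongTable(
        data=df,
        response=response,
        participant=participant,
        stimulus=stimulus,
        factors=list(factors or []),
        replicates=list(replicates or []),
    )


def wide_to_long(wide: pd.DataFrame, *, unit: str,
                 mapping: dict[str, dict[str, str]],
                 response: str = "response",
                 keep: list[str] | None = None) -> pd.DataFrame:
    """Reshape a wide table (one row per unit) to long format.

    ``mapping`` sends each wide value column to the factor levels (and
    optionally a replicate label) it encodes, e.g.::

        {"d1s1": {"day": "day1", "stimulus_type": "s1"},
         "d1s2": {"day": "day1", "stimulus_type": "s2"}}

    Every mapped column must carry a distinct level combination.  Values
    are transferred bit-exactly (no averaging, no rounding).  Returns a
    plain DataFrame; wrap in :class:`LongTable` with the roles declared.
    """
    keep = list(keep or [])
    for col in [unit, *keep, *mapping]:
        if col not in wide.columns:
            raise SchemaError(f"wide table lacks column {col!r}")
    unmapped = [c for c in wide.columns if c not in mapping
                and c != unit and c not in keep]
    if unmapped:
        raise SchemaError(f"unmapped wide columns: {unmapped}")
    seen: dict[tuple, str] = {}
    for col, levels in mapping.items():
        sig = tuple(sorted(levels.items()))
        if sig in seen:
            raise SchemaError(
                f"columns {seen[sig]!r} and {col!r} map to the same cell {levels}"
            )
        seen[sig] = col
    rows = []
    for _, row in wide.iterrows():
        for col, levels in mapping.items():
            rec = {unit: row[unit]}
            for k in keep:
                rec[k] = row[k]
            rec.update(levels)
            rec[response] = row[col]
            rows.append(rec)
    return pd.DataFrame(rows)


def long_to_wide(table: LongTable, *, columns: list[str]) -> pd.DataFrame:
    """Inverse of :func:`wide_to_long`: one row per participant, one
    column per combination of the ``columns`` levels (joined by '_')."""
    df = table.data.copy()
    key = df[columns[0]].astype(str)
    for c in columns[1:]:
        key = key + "_" + df[c].astype(str)
    df["_cell"] = key
    wide = df.pivot(index=table.participant, columns="_cell",
                    values=table.response)
    wide.columns.name = None
    return wide.reset_index()


def center_by_unit(table: LongTable, unit: str) -> LongTable:
    """Subtract each unit's own mean response from its observations.

    The mean is the plain mean over all of the unit's rows (replicates
    included), so after centering every unit's mean is 0 and all
    between-unit variance is removed while within-unit contrasts are
    untouched.  Idempotent.
    """
    if unit not in table.data.columns:
        raise SchemaError(f"unknown unit column {unit!r}")
    y = table.data[table.response]
    centered = y - y.groupby(table.data[unit]).transform("mean")
    return table.with_response(centered.to_numpy())


def cell_summaries(table: LongTable, factors: list[str] | None = None,
                   collapse_replicates: bool = False) -> list[CellSummary]:
    """Per-cell n, mean and SD, one :class:`CellSummary` per observed cell.

    With ``collapse_replicates`` each participant's replicate scores are
    averaged within the cell before summarizing, reproducing descriptives
    computed on participant cell means.
    """
    factors = list(factors if factors is not None else table.factors)
    for f in factors:
        if f not in table.data.columns:
            raise SchemaError(f"unknown factor {f!r}")
    df = table.data
    if collapse_replicates:
        df = (df.groupby([table.participant, *factors], sort=True)
                [table.response].mean().reset_index())
    out = []
    for cell, grp in df.groupby(factors, sort=True):
        if not isinstance(cell, tuple):
            cell = (cell,)
        vals = grp[table.response].to_numpy(dtype=float)
        n = len(vals)
        sd = float(np.std(vals, ddof=1)) if n > 1 else None
        out.append(CellSummary(cell=tuple(map(str, cell)), n=n,
                               mean=float(np.mean(vals)), sd=sd))
    return out
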
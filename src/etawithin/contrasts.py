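"""Contrast coding for two-level factors and design-matrix construction.

Three codings are supported for a two-level factor:

* ``dummy`` — 0/1 against a reference level; the intercept is the
  reference-cell mean, and with interactions present a "main effect"
  coefficient is really a simple effect at the other factor's reference
  level.
* ``sum`` — -1/+1; the intercept is the grand mean but coefficients are
  half the level difference.
* ``deviation`` — -0.5/+0.5 (the default); the intercept is the grand
  mean and each main-effect coefficient equals the marginal level
  difference, which is the natural scale for 2x2 designs with
  interactions.

Fitted values of any linear(-mixed) model are invariant to the choice;
only the meaning of individual coefficients changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import LongTable

__all__ = ["CodingScheme", "DesignMatrix", "encode_factor", "build_design_matrix"]

_CODES = {"dummy": (0.0, 1.0), "sum": (-1.0, 1.0), "deviation": (-0.5, 0.5)}


@dataclass(frozen=True)
class CodingScheme:
    """kind in {'dummy', 'sum', 'deviation'}; ``reference`` names the
    level coded 0 (dummy) or low (-1 / -0.5); defaults to the first
    level in sorted order."""

    kind: str = "deviation"
    reference: str | None = None

    def __post_init__(self):
        if self.kind not in _CODES:
            raise ValueError(f"unknown coding {self.kind!r}; "
                             f"expected one of {sorted(_CODES)}")


@dataclass
class DesignMatrix:
    """Fixed-effects design matrix with term bookkeeping.

    ``columns`` holds the matrix as a DataFrame (intercept first, then
    main effects in term order, then interactions as elementwise
    products of their parents).  ``term_map`` sends each model term to
    its column name; for two-level factors every term occupies exactly
    one column.  ``codes`` records the per-level numeric code of each
    factor so coefficient signs can be reported against level labels.
    """

    columns: pd.DataFrame
    term_map: dict[str, str]
    codes: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return list(self.term_map)

    @property
    def array(self) -> np.ndarray:
        return self.columns.to_numpy(dtype=float)


def encode_factor(levels, scheme: CodingScheme) -> dict[str, float]:
    """Numeric code per level of a two-level factor under ``scheme``."""
    levels = list(levels)
    if len(levels) != 2:
        raise ValueError(
            f"only two-level factors are supported, got {len(levels)} levels: {levels}"
        )
    lo, hi = _CODES[scheme.kind]
    if scheme.reference is not None:
        if scheme.reference not in levels:
            raise ValueError(f"reference {scheme.reference!r} not among levels {levels}")
        ref = scheme.reference
    else:
        ref = levels[0]
    other = levels[0] if ref == levels[1] else levels[1]
    return {ref: lo, other: hi}


def _parse_term(term: str) -> list[str]:
    return [p.strip() for p in term.split(":")]


def build_design_matrix(table: LongTable, fixed: list[str],
                        scheme: CodingScheme | None = None) -> DesignMatrix:
    """Build the fixed-effects design matrix for ``fixed`` terms.

    Terms are factor names or colon-joined interactions (``"A:B"``);
    an interaction column is the product of its parents' columns.  An
    intercept column of ones is always first.
    """
    scheme = scheme or CodingScheme()
    n = table.n_rows
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(n)}
    term_map = {"(Intercept)": "(Intercept)"}
    codes: dict[str, dict[str, float]] = {}

    factors_needed: list[str] = []
    for term in fixed:
        for f in _parse_term(term):
            if f not in table.data.columns:
                raise ValueError(f"term {term!r} references unknown factor {f!r}")
            if f not in factors_needed:
                factors_needed.append(f)

    coded: dict[str, np.ndarray] = {}
    for f in factors_needed:
        levels = table.levels(f)
        ref = scheme.reference if (scheme.reference in levels) else None
        codes[f] = encode_factor(levels, CodingScheme(scheme.kind, ref))
        coded[f] = table.data[f].map(codes[f]).to_numpy(dtype=float)

    mains = [t for t in fixed if ":" not in t]
    inters = [t for t in fixed if ":" in t]
    for term in [*mains, *inters]:
        parts = _parse_term(term)
        col = np.ones(n)
        for f in parts:
            col = col * coded[f]
        name = ":".join(parts)
        cols[name] = col
        term_map[name] = name
    return DesignMatrix(columns=pd.DataFrame(cols), term_map=term_map, codes=codes)
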
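"""Sum-of-squares decompositions for balanced pairwise designs.

Three designs are covered: one-way between groups, one-way repeated
measures, and two-way fully-within (each factor with two levels).  The
decomposition is computed from cell/marginal means, which is exact for
balanced complete data; unbalanced or incomplete data are the province
of the mixed-model module.

Three eta-squared variants are derived from the table:

* eta^2 ("total") — SS_effect over the total SS about the grand mean: the
  effect's share of *all* variance, including differences in overall
  level between subjects.
* eta_p^2 ("partial") — SS_effect over (SS_effect + SS_error(effect)):
  a transform of the F statistic.  In multifactor repeated-measures
  designs the per-term error strata differ, so these values are not
  shares of any common variance and can sum past 1.
* eta_w^2 ("within") — SS_effect over the sum of *all* within-subject
  strata (every effect SS plus every error SS): the effect's share of
  the variance that remains once between-subject level differences are
  removed.  Equivalently, eta^2 computed on subject-centered data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import LongTable

__all__ = ["AnovaTable", "anova_between", "anova_rm", "eta_squared"]


@dataclass
class AnovaTable:
    """Per-term SS/df/MS/F/p rows with their stratum (between/within)
    and error-term assignment."""

    rows: pd.DataFrame  # term, stratum, SS, df, MS, F, p, error_term
    design: str         # 'between' | 'within'

    @property
    def total_ss(self) -> float:
        return float(self.rows["SS"].sum())

    def row(self, term: str) -> pd.Series:
        match = self.rows[self.rows["term"] == term]
        if match.empty:
            raise KeyError(f"no term {term!r} in table")
        return match.iloc[0]

    @property
    def effect_terms(self) -> list[str]:
        mask = self.rows["F"].notna()
        return list(self.rows.loc[mask, "term"])


def _collapse(table: LongTable, by: list[str]) -> pd.DataFrame:
    """Average replicates: one value per combination of ``by`` columns."""
    return (table.data.groupby(by, sort=True)[table.response]
            .mean().reset_index())


def _finish(rows: list[dict], design: str) -> AnovaTable:
    df = pd.DataFrame(rows, columns=["term", "stratum", "SS", "df", "MS",
                                     "F", "p", "error_term"])
    return AnovaTable(rows=df, design=design)


def anova_between(table: LongTable, factor: str,
                  collapse_replicates: bool = False) -> AnovaTable:
    """One-way between-groups ANOVA (one observation per participant).

    With two groups the F statistic equals the square of the pooled
    (student) t on the same data, and eta^2 equals the R^2 of the
    regression of the response on the group indicator.
    """
    if factor not in table.data.columns:
        raise ValueError(f"unknown factor {factor!r}")
    if table.data[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} is constant")
    if collapse_replicates:
        df = _collapse(table, [table.participant, factor])
    else:
        df = table.data
        if df.duplicated(subset=[table.participant]).any():
            raise ValueError(
                "several observations per participant; pass "
                "collapse_replicates=True to average them first"
            )
    y = df[table.response].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    groups = df.groupby(factor)[table.response]
    ss_effect = float((groups.size() * (groups.mean() - grand) ** 2).sum())
    ss_resid = ss_total - ss_effect
    df_effect = groups.ngroups - 1
    df_resid = len(y) - groups.ngroups
    ms_e, ms_r = ss_effect / df_effect, ss_resid / df_resid
    f = ms_e / ms_r if ms_r > 0 else np.inf
    p = float(stats.f.sf(f, df_effect, df_resid))
    rows = [
        dict(term=factor, stratum="between", SS=ss_effect, df=df_effect,
             MS=ms_e, F=f, p=p, error_term="Residuals"),
        dict(term="Residuals", stratum="between", SS=ss_resid, df=df_resid,
             MS=ms_r, F=np.nan, p=np.nan, error_term=None),
    ]
    return _finish(rows, "between")


def _marginal_ss(df: pd.DataFrame, response: str, by: list[str],
                 grand: float, mult: int) -> tuple[pd.Series, float]:
    means = df.groupby(by, sort=True)[response].mean()
    return means, float(mult * ((means - grand) ** 2).sum())


def anova_rm(table: LongTable, within: list[str], subject: str | None = None,
             collapse_replicates: bool = False) -> AnovaTable:
    """Repeated-measures ANOVA with one or two within-subject factors.

    Requires a balanced complete design with exactly one value per
    subject x cell (average replicates first via
    ``collapse_replicates=True``).  Each within effect is tested against
    its own effect-by-subject error stratum.  All factors have two
    levels here, so sphericity holds trivially and no correction is
    applied.
    """
    subject = subject or table.participant
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within factors supported")
    if collapse_replicates:
        df = _collapse(table, [subject, *within])
    else:
        df = table.data[[subject, *within, table.response]]
    counts = df.groupby([subject, *within], sort=False).size()
    if (counts != 1).any():
        raise ValueError(
            "design is not one value per subject and cell; average "
            "replicates with collapse_replicates=True, or use the "
            "mixed-model path (fit_lmm), which handles unbalanced and "
            "missing data"
        )
    n_cells = int(np.prod([df[w].nunique() for w in within]))
    per_subj = df.groupby(subject).size()
    if (per_subj != n_cells).any():
        raise ValueError(
            "incomplete design: some subjects lack cells; use the "
            "mixed-model path (fit_lmm) for missing data"
        )

    resp = table.response
    y = df[resp].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    n_subj = df[subject].nunique()
    lev = {w: sorted(df[w].unique()) for w in within}

    _, ss_subj = _marginal_ss(df, resp, [subject], grand, n_cells)
    rows = [dict(term="subject", stratum="between", SS=ss_subj,
                 df=n_subj - 1, MS=ss_subj / (n_subj - 1),
                 F=np.nan, p=np.nan, error_term=None)]

    def add_effect(term, ss_eff, df_eff, ss_err, df_err):
        ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
        f = ms_eff / ms_err if ms_err > 0 else np.inf
        p = float(stats.f.sf(f, df_eff, df_err))
        err_name = f"{term}:subject"
        rows.append(dict(term=term, stratum="within", SS=ss_eff, df=df_eff,
                         MS=ms_eff, F=f, p=p, error_term=err_name))
        rows.append(dict(term=err_name, stratum="within", SS=ss_err,
                         df=df_err, MS=ms_err, F=np.nan, p=np.nan,
                         error_term=None))

    if len(within) == 1:
        (a,) = within
        ka = len(lev[a])
        _, ss_a = _marginal_ss(df, resp, [a], grand, n_subj)
        ss_err = ss_total - ss_subj - ss_a
        add_effect(a, ss_a, ka - 1, ss_err, (ka - 1) * (n_subj - 1))
    else:
        a, b = within
        ka, kb = len(lev[a]), len(lev[b])
        m_a, ss_a = _marginal_ss(df, resp, [a], grand, n_subj * kb)
        m_b, ss_b = _marginal_ss(df, resp, [b], grand, n_subj * ka)
        m_s = df.groupby(subject)[resp].mean()
        m_ab = df.groupby([a, b])[resp].mean()
        dev_ab = {(ia, ib): m_ab[(ia, ib)] - m_a[ia] - m_b[ib] + grand
                  for ia in lev[a] for ib in lev[b]}
        ss_ab = float(n_subj * sum(v**2 for v in dev_ab.values()))
        m_as = df.groupby([a, subject])[resp].mean()
        ss_as = float(kb * sum(
            (m_as[(ia, s)] - m_a[ia] - m_s[s] + grand) ** 2
            for ia in lev[a] for s in m_s.index))
        m_bs = df.groupby([b, subject])[resp].mean()
        ss_bs = float(ka * sum(
            (m_bs[(ib, s)] - m_b[ib] - m_s[s] + grand) ** 2
            for ib in lev[b] for s in m_s.index))
        ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)
        ss_abs = max(ss_abs, 0.0)
        add_effect(a, ss_a, ka - 1, ss_as, (ka - 1) * (n_subj - 1))
        add_effect(b, ss_b, kb - 1, ss_bs, (kb - 1) * (n_subj - 1))
        add_effect(f"{a}:{b}", ss_ab, (ka - 1) * (kb - 1), ss_abs,
                   (ka - 1) * (kb - 1) * (n_subj - 1))
    return _finish(rows, "within")


def eta_squared(table: AnovaTable, variant: str = "total") -> dict[str, float]:
    """Per-effect eta squared from an :class:`AnovaTable`.

    ``variant`` is ``'total'`` (SS_effect / total SS), ``'partial'``
    (SS_effect / (SS_effect + SS_error)), or ``'within'`` (SS_effect /
    sum of all within-stratum SS).  The within variant is defined only
    for repeated-measures terms; on a pure between design it returns an
    empty mapping with a warning.
    """
    if variant not in ("total", "partial", "within"):
        raise ValueError(f"unknown variant {variant!r}")
    rows = table.rows
    out: dict[str, float] = {}
    if variant == "within":
        within = rows[rows["stratum"] == "within"]
        if within.empty:
            warnings.warn("no within-subject stratum: eta squared within "
                          "is undefined for a pure between design")
            return out
        denom = float(within["SS"].sum())
        for term in table.effect_terms:
            r = table.row(term)
            if r["stratum"] == "within":
                out[term] = float(r["SS"]) / denom
        return out
    for term in table.effect_terms:
        r = table.row(term)
        if variant == "total":
            out[term] = float(r["SS"]) / table.total_ss
        else:
            err = table.row(r["error_term"])
            out[term] = float(r["SS"]) / float(r["SS"] + err["SS"])
    return out
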
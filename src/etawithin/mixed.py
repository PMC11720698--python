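"""Linear mixed-effects models and their standardized effect sizes.

The model is the Gaussian LMM

    y = X beta + sum_g Z_g b_g + e,   b_g ~ N(0, Sigma_g),  e ~ N(0, sigma^2 I),

with one or more crossed random-effects groupings (participants,
stimuli), each with a random intercept and optionally random slopes for
factors that vary within the grouping unit.  Estimation is restricted
maximum likelihood (REML) over the relative Cholesky factors of each
Sigma_g (variances bounded at zero, correlations free), profiling out
beta and sigma^2.

On top of the fit, the module computes the effect-size layer:

* ``marginal_r2`` — variance of the fixed-effects contribution over the
  total (fixed + random + residual) variance, the mixed-model analogue
  of eta squared / R^2.
* ``semipartial_r2`` — the same ratio per fixed term, using that term's
  own fitted contribution; in balanced orthogonal designs the per-term
  values add up to the marginal R^2.
* ``eta2w_lmm`` — eta squared within: the response is centered per
  grouping unit (removing that unit's level differences), the identical
  model is refit, and the semi-partial R^2 of the centered fit gives
  each effect's share of the within-unit variance.
* ``satterthwaite_df`` — fractional denominator degrees of freedom for
  the fixed-effect t statistics, from the delta method applied to the
  REML variance-parameter covariance.

Partial eta squared can be requested but is emitted with a warning: its
value is a transform of t and the (model-dependent) df, not a share of
any fixed variance pool, and it is unstable across random-effects
specifications that fit the data equally well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .contrasts import CodingScheme, build_design_matrix
from .core_data import LongTable, center_by_unit

__all__ = [
    "RandomSpec",
    "MixedFit",
    "EffectSizeReport",
    "ConvergenceError",
    "fit_lmm",
    "satterthwaite_df",
    "marginal_r2",
    "semipartial_r2",
    "eta2w_lmm",
    "effect_report",
]

_SINGULAR_TOL = 1e-4


class ConvergenceError(RuntimeError):
    """REML optimization failed after restarts; carries diagnostics."""


@dataclass(frozen=True)
class RandomSpec:
    """Random-effects terms for one grouping factor.

    ``terms`` uses ``"1"`` for the intercept and factor names (or
    colon-joined interactions) for slopes; slopes are only meaningful
    for factors that vary within the grouping unit.
    """

    grouping: str
    terms: tuple[str, ...] = ("1",)

    def __post_init__(self):
        if "1" not in self.terms:
            object.__setattr__(self, "terms", ("1", *self.terms))


@dataclass
class _Group:
    """Design pieces for one random grouping factor.  ``U`` holds the
    random-term columns standardized to unit RMS (``scale`` restores the
    original column scale), which keeps the relative-Cholesky start
    values well conditioned across coding schemes."""

    name: str
    terms: list[str]          # "1", factor names, interactions
    levels: list[str]
    U: np.ndarray             # n x k standardized random-term columns
    scale: np.ndarray         # per-column RMS of the raw columns
    codes: np.ndarray         # row -> level index
    k: int
    n_theta: int
    tril: tuple[np.ndarray, np.ndarray]

    @property
    def U_raw(self) -> np.ndarray:
        return self.U * self.scale


class _REMLProblem:
    """Profiled REML criterion for a given response/design.

    With W(theta) = I + sum_g Z_g T_g T_g' Z_g' (relative covariance
    factors T_g), the criterion profiled over beta and sigma^2 is

        log|W| + log|X' W^-1 X| + (n-p) (1 + log(2 pi r^2 / (n-p)))

    where r^2 is the GLS residual sum of squares.  All n-sized work is
    done once up front: the Woodbury identity reduces every evaluation
    to algebra on the random-effects sufficient statistics (Z'Z, Z'X,
    Z'y).  The grouping factor with the most levels contributes a
    block-diagonal piece that is handled with batched k x k algebra;
    any remaining (crossed) groupings are folded in through a Schur
    complement of their much smaller stacked dimension.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: list[_Group]):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.n_theta = sum(g.n_theta for g in groups)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # the grouping with the most random-effect columns becomes the
        # batched block-diagonal part; the rest are stacked densely
        big = max(range(len(groups)), key=lambda i: len(groups[i].levels) * groups[i].k)
        self.groups = [groups[big]] + [g for i, g in enumerate(groups) if i != big]
        g = self.groups[0]
        L, k = len(g.levels), g.k
        order = np.argsort(g.codes, kind="stable")
        counts = np.bincount(g.codes, minlength=L)
        splits = np.split(order, np.cumsum(counts)[:-1])
        self._G = np.zeros((L, k, k))
        self._A = np.zeros((L, k, self.p))
        self._a = np.zeros((L, k))
        for i, idx in enumerate(splits):
            Ui = g.U[idx]
            self._G[i] = Ui.T @ Ui
            self._A[i] = Ui.T @ X[idx]
            self._a[i] = Ui.T @ y[idx]
        self._rest = self.groups[1:]
        if self._rest:
            from scipy import sparse
            cols, vals, rows = [], [], []
            off = 0
            self._slices = []
            for gr in self._rest:
                Lr, kr = len(gr.levels), gr.k
                for j in range(kr):
                    rows.append(np.arange(self.n))
                    cols.append(off + gr.codes * kr + j)
                    vals.append(gr.U[:, j])
                self._slices.append((off, Lr, kr))
                off += Lr * kr
            self.q_r = off
            Zr = sparse.coo_matrix(
                (np.concatenate(vals),
                 (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.n, self.q_r)).tocsr()
            self._ZrtZr = (Zr.T @ Zr).toarray()
            self._ZrtX = np.asarray(Zr.T @ X)
            self._Zrty = np.asarray(Zr.T @ y)
            # per-level cross blocks Zp' Zr, batched (L, k, q_r)
            self._C = np.zeros((L, k, self.q_r))
            Zr_csr = Zr.tocsr()
            for i, idx in enumerate(splits):
                self._C[i] = g.U[idx].T @ np.asarray(Zr_csr[idx].todense())

    def _scale_rest(self, M: np.ndarray, Ts: list[np.ndarray]) -> np.ndarray:
        """Lambda_rest' M: rows scaled by the per-level T_g' blocks of
        the stacked non-block groupings."""
        out = np.empty_like(M, dtype=float)
        for (off, L, k), T in zip(self._slices, Ts):
            blk = M[off:off + L * k].reshape(L, k, -1)
            out[off:off + L * k] = (T.T[None] @ blk).reshape(L * k, M.shape[1])
        return out

    def split_theta(self, theta: np.ndarray) -> list[np.ndarray]:
        out, i = [], 0
        for g in self.groups:
            T = np.zeros((g.k, g.k))
            T[g.tril] = theta[i:i + g.n_theta]
            i += g.n_theta
            out.append(T)
        return out

    def theta0(self) -> np.ndarray:
        theta = []
        for g in self.groups:
            T = np.eye(g.k)
            theta.extend(T[g.tril])
        return np.asarray(theta)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        bnds = []
        for g in self.groups:
            T = np.zeros((g.k, g.k), dtype=bool)
            np.fill_diagonal(T, True)
            for on_diag in T[g.tril]:
                bnds.append((0.0, None) if on_diag else (None, None))
        return bnds

    # -- core linear algebra -------------------------------------------
    def _quantities(self, theta: np.ndarray):
        """Return (logdet W, X'W^-1X, X'W^-1y, y'W^-1y) via Woodbury:
        W^-1 = I - Z Lam (I + Lam'Z'Z Lam)^-1 Lam'Z'."""
        Ts = self.split_theta(theta)
        T = Ts[0]
        k = T.shape[0]
        TG = T.T[None] @ self._G @ T                   # (L,k,k)
        D = np.eye(k)[None] + TG
        sign, ld = np.linalg.slogdet(D)
        if np.any(sign <= 0):
            raise linalg.LinAlgError("non-PD block in W")
        logdet = float(ld.sum())
        Dinv = np.linalg.inv(D)
        U_X = T.T[None] @ self._A                      # (L,k,p)
        U_y = self._a @ T                              # (L,k)

        if not self._rest:
            MTA = Dinv @ U_X
            XtWX = self.XtX - np.einsum("lkp,lkq->pq", U_X, MTA)
            XtWy = self.Xty - np.einsum("lkp,lk->p", MTA, U_y)
            ytWy = self.yty - float(np.einsum("lk,lkj,lj->", U_y, Dinv, U_y))
            return logdet, XtWX, XtWy, ytWy

        Ts_rest = Ts[1:]
        L = D.shape[0]
        A_rr = np.eye(self.q_r) + self._scale_rest(
            self._scale_rest(self._ZrtZr, Ts_rest).T, Ts_rest)
        TC = (T.T[None] @ self._C).reshape(L * k, self.q_r)
        B = self._scale_rest(TC.T, Ts_rest).T.reshape(L, k, self.q_r)
        S = A_rr - np.einsum("lkq,lkj,ljr->qr", B, Dinv, B)
        c, low = linalg.cho_factor(S, lower=True)
        logdet += 2.0 * np.log(np.diag(c)).sum()
        V_X = self._scale_rest(self._ZrtX, Ts_rest)    # (q_r,p)
        V_y = self._scale_rest(self._Zrty[:, None], Ts_rest)[:, 0]

        def solve(U, V):
            # A^-1 [U; V] by the Schur complement of the rest block
            t1 = Dinv @ U                              # (L,k,m)
            V2 = V - np.einsum("lkq,lkm->qm", B, t1)
            w = linalg.cho_solve((c, low), V2)         # (q_r,m)
            u = t1 - Dinv @ np.einsum("lkq,qm->lkm", B, w)
            return u, w

        u_X, w_X = solve(U_X, V_X)
        u_y, w_y = solve(U_y[:, :, None], V_y[:, None])
        XtWX = self.XtX - (np.einsum("lkm,lkn->mn", U_X, u_X) + V_X.T @ w_X)
        XtWy = self.Xty - (np.einsum("lkm,lk->m", u_X, U_y) + w_X.T @ V_y)
        ytWy = self.yty - float(
            np.einsum("lk,lk->", U_y, u_y[:, :, 0]) + V_y @ w_y[:, 0])
        return logdet, XtWX, XtWy, ytWy

    def gls(self, theta: np.ndarray):
        """GLS solve at theta: beta, (X'W^-1X)^-1, r^2, logdets."""
        logdetW, XtWX, XtWy, ytWy = self._quantities(theta)
        cf = linalg.cho_factor(XtWX, lower=True)
        beta = linalg.cho_solve(cf, XtWy)
        XtWX_inv = linalg.cho_solve(cf, np.eye(self.p))
        logdetXtWX = 2.0 * np.log(np.diag(cf[0])).sum()
        r2 = float(ytWy - beta @ XtWy)
        return beta, XtWX_inv, max(r2, 1e-300), logdetW, logdetXtWX

    # large finite penalty for infeasible theta: derivative-free line
    # searches cope with a plateau but not with inf/NaN arithmetic
    _PENALTY = 1e12

    def deviance(self, theta: np.ndarray) -> float:
        """Profiled REML deviance (-2 restricted log-likelihood)."""
        try:
            _, _, r2, logdetW, logdetXtWX = self.gls(theta)
        except (linalg.LinAlgError, ValueError):
            return self._PENALTY
        npp = self.n - self.p
        out = float(logdetW + logdetXtWX
                    + npp * (1.0 + np.log(2.0 * np.pi * r2 / npp)))
        return out if np.isfinite(out) else self._PENALTY

    def deviance_full(self, phi: np.ndarray) -> float:
        """REML deviance as a function of (theta, sigma): the
        non-profiled criterion used for the variance-parameter Hessian."""
        theta, sigma = phi[:-1], phi[-1]
        if sigma <= 0:
            return self._PENALTY
        try:
            _, _, r2, logdetW, logdetXtWX = self.gls(theta)
        except (linalg.LinAlgError, ValueError):
            return self._PENALTY
        npp = self.n - self.p
        out = float(logdetW + logdetXtWX + npp * np.log(2 * np.pi * sigma**2)
                    + r2 / sigma**2)
        return out if np.isfinite(out) else self._PENALTY

    def var_beta(self, phi: np.ndarray) -> np.ndarray:
        """cov(beta) = sigma^2 (X'W^-1X)^-1 at variance parameters phi."""
        theta, sigma = phi[:-1], phi[-1]
        _, XtWX_inv, _, _, _ = self.gls(theta)
        return sigma**2 * XtWX_inv


@dataclass
class MixedFit:
    """REML fit: fixed-effect table, per-grouping variance components,
    residual SD, and convergence diagnostics.  Downstream effect-size
    operations consume this object."""

    fixed: pd.DataFrame                 # term, estimate, SE, t
    components: dict[str, dict]         # grouping -> {sd: {term: SD}, corr, variance}
    residual_sd: float
    icc: dict[str, float]
    loglik: float
    converged: bool
    singular: bool
    n_obs: int
    coding: CodingScheme = field(default_factory=CodingScheme)
    # private machinery for df / refits
    _problem: _REMLProblem | None = field(default=None, repr=False)
    _theta: np.ndarray | None = field(default=None, repr=False)
    _beta: np.ndarray | None = field(default=None, repr=False)
    _cov_beta: np.ndarray | None = field(default=None, repr=False)
    _terms: list[str] = field(default_factory=list, repr=False)
    _X_df: pd.DataFrame | None = field(default=None, repr=False)
    _random: tuple[RandomSpec, ...] = (),

    @property
    def terms(self) -> list[str]:
        return list(self._terms)

    def coef(self, term: str) -> float:
        return float(self.fixed.set_index("term").loc[term, "estimate"])


@dataclass
class EffectSizeReport:
    """Per-term effect sizes composed from one mixed-model analysis."""

    table: pd.DataFrame        # term, estimate, SE, t, df, p, eta2, eta2_w[, eta2_p]
    r2_marginal: float
    fit: MixedFit
    center_by: str | None
    notes: list[str] = field(default_factory=list)


def _random_design(table: LongTable, spec: RandomSpec,
                   scheme: CodingScheme) -> _Group:
    if spec.grouping not in table.data.columns:
        raise ValueError(f"unknown grouping column {spec.grouping!r}")
    slopes = [t for t in spec.terms if t != "1"]
    n = table.n_rows
    if slopes:
        dm = build_design_matrix(table, slopes, scheme)
        U = np.column_stack([np.ones(n)] +
                            [dm.columns[t].to_numpy() for t in slopes])
    else:
        U = np.ones((n, 1))
    terms = ["1", *slopes]
    codes_raw = table.data[spec.grouping]
    levels = sorted(codes_raw.unique())
    if len(levels) < 2:
        raise ValueError(f"grouping {spec.grouping!r} needs >= 2 units")
    level_idx = {l: i for i, l in enumerate(levels)}
    codes = codes_raw.map(level_idx).to_numpy()
    for j, t in enumerate(terms[1:], start=1):
        col = pd.Series(U[:, j])
        if (col.groupby(codes_raw.to_numpy()).nunique() == 1).all():
            raise ValueError(
                f"random slope {t!r} is constant within every "
                f"{spec.grouping!r} unit; drop it or use an intercept-only spec"
            )
    k = len(terms)
    tril = np.tril_indices(k)
    scale = np.sqrt(np.mean(U**2, axis=0))
    scale[scale == 0] = 1.0
    return _Group(name=spec.grouping, terms=terms, levels=levels,
                  U=U / scale, scale=scale, codes=codes, k=k,
                  n_theta=k * (k + 1) // 2, tril=tril)


def _optimize_reml(problem: _REMLProblem, restarts: int = 2,
                   seed: int = 0) -> tuple[np.ndarray, bool]:
    bounds = problem.bounds()
    rng = np.random.default_rng(seed)
    best, best_dev, any_success = None, np.inf, False
    start = problem.theta0()
    starts = [start, 0.5 * start]
    starts += [np.clip(start + rng.normal(scale=0.4, size=start.shape),
                       0, None) for _ in range(restarts)]
    for theta in starts:
        res = optimize.minimize(problem.deviance, theta, method="Powell",
                                bounds=bounds,
                                options={"xtol": 1e-10, "ftol": 1e-10,
                                         "maxiter": 10000})
        res2 = optimize.minimize(problem.deviance, res.x, method="L-BFGS-B",
                                 bounds=bounds,
                                 options={"ftol": 1e-13, "gtol": 1e-10})
        any_success = any_success or res.success or res2.success
        if res2.fun < res.fun:
            res = res2
        if np.isfinite(res.fun) and res.fun < best_dev - 1e-12:
            best, best_dev = res.x, res.fun
    if (best is None or not np.isfinite(best_dev)
            or best_dev >= _REMLProblem._PENALTY or not any_success):
        raise ConvergenceError(
            f"REML optimization failed after {restarts} restarts "
            f"(best deviance {best_dev})"
        )
    return np.asarray(best), True


def fit_lmm(table: LongTable, fixed: list[str], random: list[RandomSpec],
            coding: CodingScheme | None = None) -> MixedFit:
    """Fit the linear mixed model by REML.

    ``fixed`` lists fixed terms (factor names and ``"A:B"``
    interactions); ``random`` gives one :class:`RandomSpec` per grouping
    factor.  Deterministic given data and options.  Singular fits
    (variance components estimated at zero, or degenerate correlations)
    are returned with ``singular=True``, not raised.
    """
    coding = coding or CodingScheme()
    dm = build_design_matrix(table, fixed, coding)
    X = dm.array
    y = table.data[table.response].to_numpy(dtype=float)
    groups = [_random_design(table, spec, coding) for spec in random]
    problem = _REMLProblem(y, X, groups)
    theta, converged = _optimize_reml(problem)
    beta, XtWX_inv, r2, logdetW, logdetXtWX = problem.gls(theta)
    n, p = problem.n, problem.p
    sigma2 = r2 / (n - p)
    sigma = float(np.sqrt(sigma2))
    cov_beta = sigma2 * XtWX_inv
    se = np.sqrt(np.diag(cov_beta))
    fixed_tab = pd.DataFrame({
        "term": dm.terms,
        "estimate": beta,
        "SE": se,
        "t": beta / se,
    })
    Ts = problem.split_theta(theta)
    components: dict[str, dict] = {}
    singular = False
    total_random = 0.0
    intercept_var: dict[str, float] = {}
    for g, T in zip(groups, Ts):
        Sigma = sigma2 * (T @ T.T) / np.outer(g.scale, g.scale)
        sds = np.sqrt(np.diag(Sigma))
        if np.any(np.diag(T @ T.T) < _SINGULAR_TOL**2):
            singular = True
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = Sigma / np.outer(sds, sds)
        corr[~np.isfinite(corr)] = 0.0
        if Sigma.shape[0] > 1:
            offdiag = corr[np.tril_indices_from(corr, -1)]
            if np.any(np.abs(offdiag) > 1 - _SINGULAR_TOL):
                singular = True
        components[g.name] = {
            "terms": list(g.terms),
            "sd": {t: float(s) for t, s in zip(g.terms, sds)},
            "variance": {t: float(s**2) for t, s in zip(g.terms, sds)},
            "corr": corr,
            "Sigma": Sigma,
        }
        # mean per-observation variance contributed by this grouping
        U_raw = g.U_raw
        total_random += float(np.mean(np.einsum("ij,jk,ik->i", U_raw, Sigma, U_raw)))
        intercept_var[g.name] = float(Sigma[0, 0])
    icc = {name: v / (total_random + sigma2)
           for name, v in intercept_var.items()}
    dev = problem.deviance(theta)
    fit = MixedFit(
        fixed=fixed_tab,
        components=components,
        residual_sd=sigma,
        icc=icc,
        loglik=-dev / 2.0,
        converged=converged,
        singular=singular,
        n_obs=n,
        coding=coding,
        _problem=problem,
        _theta=theta,
        _beta=beta,
        _cov_beta=cov_beta,
        _terms=dm.terms,
        _X_df=dm.columns,
        _random=tuple(random),
    )
    return fit


def _phi(fit: MixedFit) -> np.ndarray:
    return np.concatenate([fit._theta, [fit.residual_sd]])


def satterthwaite_df(fit: MixedFit, term: str) -> float:
    """Satterthwaite denominator df for a fixed-effect t statistic.

    df = 2 (c' V_b c)^2 / Var(c' V_b c), where the denominator comes
    from the delta method with the asymptotic covariance of the REML
    variance parameters (twice the inverse Hessian of the restricted
    deviance).  In balanced classical designs this reduces to the
    textbook df.  With a singular fit the Hessian is rank-deficient and
    the returned df (via pseudo-inverse) is approximate.
    """
    if term not in fit._terms:
        raise KeyError(f"unknown fixed term {term!r}")
    prob = fit._problem
    j = fit._terms.index(term)
    phi = _phi(fit)
    vb = float(prob.var_beta(phi)[j, j])

    h = 1e-4 * np.maximum(np.abs(phi), 0.1)
    m = len(phi)
    # evaluation points may not cross the variance boundary: clip the
    # nonnegative parameters (theta diagonals and sigma)
    lower = np.array([b[0] if b[0] is not None else -np.inf
                      for b in prob.bounds()] + [1e-10])

    def vb_at(p):
        return float(prob.var_beta(np.maximum(p, lower))[j, j])

    grad = np.zeros(m)
    for i in range(m):
        e = np.zeros(m)
        e[i] = h[i]
        grad[i] = (vb_at(phi + e) - vb_at(phi - e)) / (2 * h[i])

    def dev(p):
        return prob.deviance_full(np.maximum(p, lower))
    H = np.zeros((m, m))
    f0 = dev(phi)
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        for k in range(i, m):
            ek = np.zeros(m); ek[k] = h[k]
            if i == k:
                H[i, i] = (dev(phi + ei) - 2 * f0 + dev(phi - ei)) / h[i]**2
            else:
                H[i, k] = H[k, i] = (
                    dev(phi + ei + ek) - dev(phi + ei - ek)
                    - dev(phi - ei + ek) + dev(phi - ei - ek)
                ) / (4 * h[i] * h[k])
    try:
        A = 2.0 * linalg.inv(H)
    except linalg.LinAlgError:
        A = 2.0 * linalg.pinv(H)
    denom = float(grad @ A @ grad)
    if denom <= 0:
        A = 2.0 * linalg.pinvh(H)
        denom = float(grad @ A @ grad)
    if denom <= 0:
        return float(fit.n_obs - len(fit._terms))
    df = 2.0 * vb**2 / denom
    return float(max(df, 1.0))


def _variance_decomposition(fit: MixedFit) -> dict:
    """Sample variances of the fitted fixed contributions plus total
    random and residual variance (the marginal/semi-partial R^2 pieces)."""
    X = fit._X_df.to_numpy(dtype=float)
    beta = fit._beta
    fitted_fixed = X @ beta
    var_f = float(np.var(fitted_fixed, ddof=1))
    per_term = {}
    for j, term in enumerate(fit._terms):
        if term == "(Intercept)":
            continue
        per_term[term] = float(np.var(X[:, j] * beta[j], ddof=1))
    total_random = 0.0
    for g, spec in zip(fit._problem.groups, fit._random):
        Sigma = fit.components[g.name]["Sigma"]
        U_raw = g.U_raw
        total_random += float(np.mean(
            np.einsum("ij,jk,ik->i", U_raw, Sigma, U_raw)))
    return {
        "var_fixed": var_f,
        "var_term": per_term,
        "var_random": total_random,
        "var_residual": fit.residual_sd**2,
    }


def marginal_r2(fit: MixedFit) -> float:
    """Marginal R^2: fixed-effects fitted variance over the total of
    fixed, random and residual variance (Nakagawa-Schielzeth, with
    Johnson's extension for random slopes)."""
    d = _variance_decomposition(fit)
    return d["var_fixed"] / (d["var_fixed"] + d["var_random"] + d["var_residual"])


def semipartial_r2(fit: MixedFit) -> dict[str, float]:
    """Per-term semi-partial R^2 (the eta-squared analogue): variance of
    X_j beta_j over the same total-variance denominator as
    :func:`marginal_r2`.  In balanced orthogonal designs the values sum
    to the marginal R^2."""
    d = _variance_decomposition(fit)
    denom = d["var_fixed"] + d["var_random"] + d["var_residual"]
    X = fit._X_df.to_numpy(dtype=float)
    nonint = [j for j, t in enumerate(fit._terms) if t != "(Intercept)"]
    if len(nonint) > 1:
        sub = X[:, nonint]
        rank = np.linalg.matrix_rank(sub - sub.mean(axis=0))
        if rank < len(nonint):
            warnings.warn("collinear fixed terms: per-term semi-partial "
                          "R^2 values overlap and should be read with care")
    return {t: v / denom for t, v in d["var_term"].items()}


def eta2w_lmm(table: LongTable, fixed: list[str], random: list[RandomSpec],
              center_unit: str, coding: CodingScheme | None = None
              ) -> dict[str, float | None]:
    """Eta squared within via a centered refit.

    The response is centered per ``center_unit`` (one of the random
    grouping columns), the identical model is refit — the random
    intercept for the centered unit is retained, which does not affect
    the ratio since only the allocation of variance over components
    changes, not the total — and the semi-partial R^2 of the centered
    fit is returned per term.  A term that is constant within every
    centered unit (a pure between-unit effect under this centering) has
    no within-unit variance to explain: its value is None.
    """
    if center_unit not in {s.grouping for s in random}:
        raise ValueError(
            f"center_unit {center_unit!r} is not one of the random "
            f"groupings {[s.grouping for s in random]}"
        )
    centered = center_by_unit(table, center_unit)
    cfit = fit_lmm(centered, fixed, random, coding)
    values: dict[str, float | None] = dict(semipartial_r2(cfit))
    X_df = cfit._X_df
    unit = table.data[center_unit].to_numpy()
    for term in list(values):
        col = pd.Series(X_df[term].to_numpy())
        if (col.groupby(unit).nunique() == 1).all():
            values[term] = None
    return values


def effect_report(table: LongTable, fixed: list[str],
                  random: list[RandomSpec],
                  coding: CodingScheme | None = None,
                  center_by: str | None = None,
                  include_eta2p: bool = False,
                  df_method: str = "satterthwaite") -> EffectSizeReport:
    """One mixed-model analysis, reported per fixed term.

    Composes the REML fit, Satterthwaite df and p, semi-partial R^2
    (eta squared), and eta squared within from a refit centered on
    ``center_by`` (default: the first random grouping within whose
    units every fixed term varies).  ``include_eta2p=True`` adds partial
    eta squared computed as t^2/(t^2+df), with a warning about its
    df instability.
    """
    fit = fit_lmm(table, fixed, random, coding)
    notes: list[str] = []
    if fit.singular:
        notes.append("singular fit: at least one variance component is "
                     "at the zero boundary or a correlation is degenerate")
    if center_by is None:
        unit_cols = [s.grouping for s in random]
        X_df = fit._X_df
        for cand in unit_cols:
            unit = table.data[cand].to_numpy()
            varies = all(
                not (pd.Series(X_df[t].to_numpy()).groupby(unit).nunique() == 1).all()
                for t in fit.terms if t != "(Intercept)"
            )
            if varies:
                center_by = cand
                break
        if center_by is None:
            center_by = unit_cols[0]
        notes.append(f"eta squared within centered by {center_by!r}")
    eta2 = semipartial_r2(fit)
    eta2w = eta2w_lmm(table, fixed, random, center_by, coding)
    rows = []
    for _, r in fit.fixed.iterrows():
        term = r["term"]
        if df_method == "satterthwaite":
            df = satterthwaite_df(fit, term)
        elif df_method == "residual":
            df = float(fit.n_obs - len(fit.terms))
        else:
            raise ValueError(f"unknown df method {df_method!r}")
        t = float(r["t"])
        p = float(2 * stats.t.sf(abs(t), df))
        row = dict(term=term, estimate=float(r["estimate"]),
                   SE=float(r["SE"]), t=t, df=df, p=p,
                   eta2=eta2.get(term, np.nan),
                   eta2_w=eta2w.get(term, np.nan))
        if include_eta2p:
            row["eta2_p"] = t**2 / (t**2 + df)
        rows.append(row)
    if include_eta2p:
        warnings.warn(
            "partial eta squared from a mixed model is a transform of t "
            "and the model-dependent df, not a variance share; it can "
            "change substantially between random-effects specifications "
            "that fit equally well"
        )
        notes.append("eta2_p included on request; see warning")
    tab = pd.DataFrame(rows)
    return EffectSizeReport(table=tab, r2_marginal=marginal_r2(fit),
                            fit=fit, center_by=center_by, notes=notes)
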
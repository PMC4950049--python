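"""Inbreeding-depression regressions: REML animal models and PQL GLMMs.

Continuous traits are analysed with Gaussian linear mixed models ("animal
models") fitting individual and maternal inbreeding coefficients as fixed
effects and, as random effects, a year-of-birth effect, an additive genetic
effect structured by the pedigree numerator relationship matrix, a maternal
additive genetic effect (the dam's breeding value, also pedigree-structured)
and a maternal environment effect (iid per dam). Variance components are
estimated by REML using average-information updates with a positivity-
preserving expectation-maximisation-style fallback; fixed effects are tested
with Wald statistics.

Binary and count fitness components (first-year survival, annual survival,
annual breeding success) are analysed with generalized linear mixed models
(logit or log link) fitted by penalized quasi-likelihood: iteratively
reweighted working responses passed through the same REML engine with the
residual variance fixed at one. Slopes are reported with 95% Wald intervals.

Effect sizes are converted to interpretable scales: percent change in a trait
per 0.1 increase in F, and the odds-scale percent reduction in survival per
0.1 increase in F (``100 x (1 - exp(0.1 x slope))``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import UNKNOWN, Pedigree, kinship_matrix


class ModelError(ValueError):
    pass


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------


@dataclass
class RandomEffect:
    """One random term: u ~ N(0, sigma^2 K), entering as Z u."""

    name: str
    Z: np.ndarray  # n x q incidence/design
    K: np.ndarray | None = None  # q x q covariance structure; None = identity

    def cov_contribution(self) -> np.ndarray:
        if self.K is None:
            return self.Z @ self.Z.T
        return self.Z @ self.K @ self.Z.T


@dataclass
class ModelFit:
    """Fixed-effect estimates, variance components and fit diagnostics."""

    fixed_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    varcomp: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    n_records: int
    n_individuals: int
    message: str = ""
    family: str = "gaussian"

    @property
    def ci_low(self) -> np.ndarray:
        return self.beta - 1.96 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.beta + 1.96 * self.se

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.beta / self.se

    @property
    def wald_p(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.wald_z))

    def coef(self, name: str) -> tuple[float, float]:
        i = self.fixed_names.index(name)
        return float(self.beta[i]), float(self.se[i])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.fixed_names,
                "estimate": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "z": self.wald_z,
                "p": self.wald_p,
            }
        )


# ----------------------------------------------------------------------
# REML core
# ----------------------------------------------------------------------


def fit_lmm_reml(
    y: np.ndarray,
    X: np.ndarray,
    random_effects: Sequence[RandomEffect],
    fixed_names: Sequence[str] | None = None,
    weights: np.ndarray | None = None,
    fix_residual: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_individuals: int | None = None,
    start_sigma: Sequence[float] | None = None,
) -> ModelFit:
    """REML fit of ``y = X beta + sum_k Z_k u_k + e``.

    ``u_k ~ N(0, sigma_k^2 K_k)`` and ``e ~ N(0, sigma_e^2 diag(1/w))``.
    Average-information updates with step-halving into a multiplicative
    EM-style fallback keep variances nonnegative; components hitting the lower
    boundary are clamped to zero. Start values split the phenotypic variance
    equally over all components. Non-convergence is reported via the
    ``converged`` flag, not an exception.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if X.shape[0] != n:
        raise ModelError("X and y have different numbers of records")
    # drop aliased fixed-effect columns
    names = list(fixed_names) if fixed_names else [f"x{i}" for i in range(X.shape[1])]
    X, names = _drop_aliased(X, names)
    p = X.shape[1]
    if n <= p:
        raise ModelError("more fixed-effect columns than records")

    R = np.ones(n) if weights is None else 1.0 / np.asarray(weights, dtype=float)
    G = [re.cov_contribution() for re in random_effects]
    k_re = len(G)
    vary = float(np.var(y, ddof=1)) if n > 1 else 1.0
    n_comp = k_re + 1
    if start_sigma is not None:
        if len(start_sigma) != k_re:
            raise ModelError("start_sigma length does not match random effects")
        # keep warm starts strictly positive so updates are not stuck at zero
        sigma = np.maximum(np.asarray(start_sigma, dtype=float), 1e-6 * vary)
    else:
        sigma = np.full(k_re, vary / max(n_comp, 1))
    sigma_e = fix_residual if fix_residual is not None else vary / n_comp
    floor = 1e-8 * max(vary, 1e-12)

    def build_V(sig: np.ndarray, se_: float) -> np.ndarray:
        V = se_ * np.diag(R)
        for g, s in zip(G, sig):
            if s > 0:
                V = V + s * g
        return V

    def reml_pieces(sig: np.ndarray, se_: float):
        V = build_V(sig, se_)
        try:
            c, low = _chol(V)
        except np.linalg.LinAlgError:
            return None
        Vinv = _chol_inv(c)
        XtVi = X.T @ Vinv
        XtViX = XtVi @ X
        try:
            XtViX_inv = np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            return None
        P = Vinv - XtVi.T @ XtViX_inv @ XtVi
        Py = P @ y
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        sign, logdetX = np.linalg.slogdet(XtViX)
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))
        return V, Vinv, P, Py, ll, XtViX_inv, XtVi

    est_resid = fix_residual is None
    pieces = reml_pieces(sigma, sigma_e)
    if pieces is None:
        raise ModelError("initial covariance matrix not positive definite")
    ll_old = pieces[4]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, Vinv, P, Py, ll_old, _, _ = pieces
        # score and AI matrix over active components (+ residual if estimated)
        comps: list[np.ndarray] = [g for g in G]
        if est_resid:
            comps.append(np.diag(R))
        m = len(comps)
        score = np.empty(m)
        tr_PG = np.empty(m)
        yPGPy = np.empty(m)
        PGPy = []
        for j, g in enumerate(comps):
            gPy = g @ Py
            PGPy.append(P @ gPy)
            # tr(P G) via elementwise sum; both matrices are symmetric
            tr_PG[j] = float(np.sum(P * g))
            yPGPy[j] = float(Py @ gPy)
            score[j] = -0.5 * (tr_PG[j] - yPGPy[j])
        AI = np.empty((m, m))
        for j in range(m):
            for l in range(j, m):
                AI[j, l] = AI[l, j] = 0.5 * float(Py @ (comps[j] @ PGPy[l]))
        theta = np.concatenate([sigma, [sigma_e]]) if est_resid else sigma.copy()

        new_theta = None
        try:
            delta = np.linalg.solve(AI, score)
            for step in (1.0, 0.5, 0.25, 0.1):
                cand = theta + step * delta
                if np.all(cand >= 0):
                    trial = _unpack(cand, k_re, est_resid, sigma_e)
                    trial_pieces = reml_pieces(*trial)
                    if trial_pieces is not None and trial_pieces[4] >= ll_old - 1e-6:
                        new_theta, pieces = cand, trial_pieces
                        break
        except np.linalg.LinAlgError:
            pass
        if new_theta is None:
            # multiplicative EM-style fallback: sigma <- sigma * yPGPy / tr(PG)
            cand = theta.copy()
            for j in range(m):
                if tr_PG[j] > 0 and theta[j] > 0:
                    cand[j] = theta[j] * yPGPy[j] / tr_PG[j]
            new_theta = np.maximum(cand, 0.0)
            trial = _unpack(new_theta, k_re, est_resid, sigma_e)
            trial_pieces = reml_pieces(*trial)
            if trial_pieces is None:
                break
            pieces = trial_pieces
        sigma, sigma_e = _unpack(new_theta, k_re, est_resid, sigma_e)
        sigma[sigma < floor] = 0.0
        ll_new = pieces[4]
        if abs(ll_new - ll_old) < tol * (1 + abs(ll_old)):
            converged = True
            break

    V, Vinv, P, Py, ll, XtViX_inv, XtVi = pieces
    beta = XtViX_inv @ (XtVi @ y)
    se = np.sqrt(np.diag(XtViX_inv))
    varcomp = {re.name: float(s) for re, s in zip(random_effects, sigma)}
    varcomp["residual"] = float(sigma_e)
    return ModelFit(
        fixed_names=names,
        beta=beta,
        se=se,
        varcomp=varcomp,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        n_records=n,
        n_individuals=n_individuals if n_individuals is not None else n,
        message="" if converged else "REML did not converge within max_iter",
    )


def _unpack(theta: np.ndarray, k_re: int, est_resid: bool, sigma_e: float):
    if est_resid:
        return theta[:k_re].copy(), float(theta[k_re])
    return theta[:k_re].copy(), sigma_e


def _chol(V: np.ndarray):
    jitter = 0.0
    base = np.mean(np.diag(V))
    for _ in range(4):
        try:
            return np.linalg.cholesky(V + jitter * np.eye(len(V))), jitter
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * base)
    raise np.linalg.LinAlgError("covariance not positive definite")


def _chol_inv(c: np.ndarray) -> np.ndarray:
    ident = np.eye(len(c))
    from scipy.linalg import solve_triangular

    w = solve_triangular(c, ident, lower=True)
    return w.T @ w


def _drop_aliased(X: np.ndarray, names: list[str]):
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1e-300)
    if keep.all():
        return X, names
    return X[:, keep], [nm for nm, k in zip(names, keep) if k]


# ----------------------------------------------------------------------
# PQL GLMM
# ----------------------------------------------------------------------


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    random_effects: Sequence[RandomEffect],
    family: str = "binomial",
    fixed_names: Sequence[str] | None = None,
    max_outer: int = 50,
    tol: float = 1e-4,
    n_individuals: int | None = None,
) -> ModelFit:
    """Penalized-quasi-likelihood GLMM (binomial-logit or poisson-log).

    Iterates working responses/weights through the REML engine with the
    residual variance fixed at 1. Complete separation (diverging linear
    predictor) is flagged, not raised.
    """
    if family not in ("binomial", "poisson"):
        raise ModelError(f"unsupported family {family!r}")
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ModelError("binomial response must be 0/1")
    if family == "poisson" and (np.any(y < 0) or np.any(y != np.floor(y))):
        raise ModelError("poisson response must be nonnegative integers")

    # start from the fixed-effects GLM
    eta = _glm_start(y, X, family)
    G = list(random_effects)
    Zs = [re.Z for re in G]
    Ks = [re.K for re in G]
    u = [np.zeros(z.shape[1]) for z in Zs]
    beta_old = None
    fit = None
    separated = False
    it = 0
    for it in range(1, max_outer + 1):
        mu, w = _mu_weights(eta, family)
        if np.any(w < 1e-10):
            separated = True
            w = np.maximum(w, 1e-10)
        z_work = eta + (y - mu) / np.maximum(w, 1e-10)
        start = None
        if fit is not None:  # warm-start variances from the previous pass
            start = [fit.varcomp[re.name] for re in G]
        fit = fit_lmm_reml(
            z_work,
            X,
            G,
            fixed_names=fixed_names,
            weights=w,
            fix_residual=1.0,
            max_iter=100 if start is None else 30,
            tol=1e-7,
            n_individuals=n_individuals,
            start_sigma=start,
        )
        # BLUPs of the random effects at the current variance estimates
        V = np.diag(1.0 / w)
        for g, s in zip(G, [fit.varcomp[re.name] for re in G]):
            if s > 0:
                V += s * g.cov_contribution()
        resid = z_work - X @ fit.beta
        Vinv_r = np.linalg.solve(V, resid)
        eta_new = X @ fit.beta
        for j, (Zj, Kj) in enumerate(zip(Zs, Ks)):
            s = fit.varcomp[G[j].name]
            if s > 0:
                uj = s * (Zj.T @ Vinv_r)
                if Kj is not None:
                    uj = Kj @ (s * (Zj.T @ Vinv_r))
                u[j] = uj
                eta_new = eta_new + Zj @ uj
        if np.max(np.abs(eta_new)) > 30:
            separated = True
            eta_new = np.clip(eta_new, -30, 30)
        if beta_old is not None and np.max(np.abs(fit.beta - beta_old)) < tol * (
            1 + np.max(np.abs(beta_old))
        ):
            eta = eta_new
            break
        beta_old = fit.beta.copy()
        eta = eta_new

    assert fit is not None
    fit.family = family
    fit.n_iter = it
    if separated:
        fit.converged = False
        fit.message = (fit.message + "; " if fit.message else "") + \
            "possible complete separation (extreme linear predictor)"
    return fit


def _glm_start(y: np.ndarray, X: np.ndarray, family: str) -> np.ndarray:
    """A few IRLS steps of the fixed-effects GLM for starting values."""
    n, p = X.shape
    beta = np.zeros(p)
    if family == "binomial":
        beta[0] = np.log((y.mean() + 1e-3) / (1 - y.mean() + 1e-3)) if p else 0.0
    else:
        beta[0] = np.log(y.mean() + 1e-3)
    eta = X @ beta
    for _ in range(25):
        mu, w = _mu_weights(eta, family)
        z = eta + (y - mu) / np.maximum(w, 1e-10)
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
        eta = np.clip(X @ beta, -30, 30)
    return np.clip(X @ beta, -30, 30)


def _mu_weights(eta: np.ndarray, family: str):
    if family == "binomial":
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
    else:
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu
    return mu, w


# ----------------------------------------------------------------------
# convenience model builders
# ----------------------------------------------------------------------


def _indicator(values: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(values))
    Z = (values.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    return Z, levels


def animal_model_effects(
    df: pd.DataFrame, ped: Pedigree, year_col: str = "cohort", dam_col: str = "dam"
) -> list[RandomEffect]:
    """Random terms of the animal model for phenotyped rows of ``df``:
    year of birth, additive genetic (pedigree A matrix), maternal genetic
    (dam's breeding value, A over dams) and maternal environment (iid dam)."""
    km = kinship_matrix(ped)
    ids = df["id"].astype(str)
    dams = df[dam_col].astype(str)
    Z_year, _ = _indicator(df[year_col])
    Z_ind, ind_levels = _indicator(ids)
    A_ind = 2.0 * km.loc[ind_levels, ind_levels].to_numpy()
    Z_dam, dam_levels = _indicator(dams)
    A_dam = 2.0 * km.loc[dam_levels, dam_levels].to_numpy()
    return [
        RandomEffect("year", Z_year),
        RandomEffect("additive", Z_ind, A_ind),
        RandomEffect("maternal_genetic", Z_dam, A_dam),
        RandomEffect("maternal_env", Z_dam.copy()),
    ]


def build_fixed(
    df: pd.DataFrame,
    f_col: str = "F_ind",
    maternal_f_col: str | None = "F_mat",
    covariates: Sequence[str] = ("sex",),
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, individual F, optional maternal F, covariates
    (categorical columns are dummy-coded dropping the first level)."""
    cols = [np.ones(len(df))]
    names = ["intercept", f_col]
    cols.append(df[f_col].to_numpy(dtype=float))
    if maternal_f_col is not None:
        cols.append(df[maternal_f_col].to_numpy(dtype=float))
        names.append(maternal_f_col)
    for cv in covariates:
        v = df[cv]
        if v.dtype.kind in "ifu":
            cols.append(v.to_numpy(dtype=float))
            names.append(cv)
        else:
            levels = list(pd.unique(v))[1:]
            for lev in levels:
                cols.append((v == lev).to_numpy(dtype=float))
                names.append(f"{cv}[{lev}]")
    return np.column_stack(cols), names


def fit_trait_model(
    traits: pd.DataFrame,
    trait: str,
    ped: Pedigree,
    f_col: str = "F_ind",
    maternal_f_col: str | None = "F_mat",
    covariates: Sequence[str] = ("sex",),
) -> ModelFit:
    """Animal model of one trait on individual (and maternal) inbreeding.

    Rows with a missing trait value or (when a maternal term is requested)
    missing maternal F are dropped.
    """
    df = traits.dropna(subset=[trait, f_col]).copy()
    if maternal_f_col is not None:
        df = df.dropna(subset=[maternal_f_col])
    X, names = build_fixed(df, f_col, maternal_f_col, covariates)
    res = animal_model_effects(df, ped)
    return fit_lmm_reml(
        df[trait].to_numpy(dtype=float), X, res, fixed_names=names,
        n_individuals=df["id"].nunique(),
    )


def fit_fitness_model(
    fitness: pd.DataFrame,
    component: str,
    sex: str,
    f_col: str = "F_ind",
    maternal_f_col: str | None = "F_mat",
) -> ModelFit:
    """Sex-specific GLMM of one fitness component on inbreeding.

    Binomial-logit for survival components, Poisson-log for breeding success.
    Random effects: year; plus individual identity for repeated annual records.
    """
    family = "poisson" if "breeding" in component else "binomial"
    df = fitness[(fitness["component"] == component) & (fitness["sex"] == sex)]
    df = df.dropna(subset=[f_col] + ([maternal_f_col] if maternal_f_col else []))
    if df.empty:
        raise ModelError(f"no records for {component}/{sex}")
    X, names = build_fixed(df, f_col, maternal_f_col, covariates=())
    res = [RandomEffect("year", _indicator(df["year"])[0])]
    if df["id"].duplicated().any():
        res.append(RandomEffect("individual", _indicator(df["id"])[0]))
    return fit_glmm(
        df["response"].to_numpy(dtype=float), X, res, family=family,
        fixed_names=names, n_individuals=df["id"].nunique(),
    )


# ----------------------------------------------------------------------
# birthweight age correction and effect conversions
# ----------------------------------------------------------------------


def correct_birthweight_for_age(
    records: pd.DataFrame,
    weight_col: str = "weight",
    age_col: str = "age_days",
    max_age_days: float = 10.0,
) -> pd.Series:
    """Residual birthweights from a cubic polynomial of weight on capture age.

    Only records captured at ``max_age_days`` or earlier enter the fit and the
    output; later captures are excluded. Raises if fewer than 8 usable records
    remain (cubic underdetermined guard).
    """
    if (records[age_col] < 0).any():
        raise ModelError("capture ages must be nonnegative")
    sub = records[records[age_col] <= max_age_days].dropna(
        subset=[weight_col, age_col]
    )
    if len(sub) < 8:
        raise ModelError(
            f"only {len(sub)} usable records (need >= 8 for a cubic fit)"
        )
    age = sub[age_col].to_numpy(dtype=float)
    wt = sub[weight_col].to_numpy(dtype=float)
    coefs = np.polynomial.polynomial.polyfit(age, wt, deg=3)
    resid = wt - np.polynomial.polynomial.polyval(age, coefs)
    return pd.Series(resid, index=sub.index, name="birthweight_resid")


def pct_change_per_deltaF(
    slope: float, trait_mean: float, deltaF: float = 0.1
) -> float:
    """Percent change in a trait per ``deltaF`` increase in inbreeding:
    ``100 x |slope| x deltaF / trait_mean``."""
    if trait_mean == 0:
        raise ModelError("trait mean must be nonzero")
    return 100.0 * abs(slope) * deltaF / trait_mean


def odds_reduction_per_deltaF(logit_slope: float, deltaF: float = 0.1) -> float:
    """Percent reduction on the odds scale per ``deltaF`` increase in F:
    ``100 x (1 - exp(deltaF x slope))``."""
    if not np.isfinite(logit_slope):
        raise ModelError("slope must be finite")
    return 100.0 * (1.0 - np.exp(deltaF * logit_slope))
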
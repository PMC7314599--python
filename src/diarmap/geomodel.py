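"""Bayesian binomial geostatistical model on the cell x year grid.

Model
-----
For cluster c with N_c children and y_c diarrhoea cases,

    y_c ~ Binomial(N_c, logit^-1(eta_{i(c)})),
    eta_i = sum_j w_j logit(g_j(i)) + u_i,          w on the simplex,
    u ~ N(0, sigma^2 Matern32(space, range) (x) AR1(time, rho) + tau^2 I),

where g_j are the stacked-learner prevalence surfaces and i indexes cell-years.
The nugget tau is per cell-year, so posterior draws of eta carry both the
smooth field and the fine-scale overdispersion.

Inference is empirical-Bayes Laplace: for candidate GP hyperparameters the
latent field posterior is approximated by a Gaussian at its mode (damped Newton
iterations), hyperparameters maximise the Laplace marginal likelihood plus
hyperpriors (log-normal range, half-normal sds, uniform rho), and joint
posterior draws of eta come from the Gaussian approximation at the optimum.
The scheme satisfies the pipeline's inference contract — it returns joint draws
of eta over all cells and years — while staying dense-linear-algebra simple at
grids up to roughly 3000 cell-years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import expit, logit

from .gp import ar1_correlation, matern32_correlation
from .stacker import LEARNER_FAMILIES, StackResult, fit_stack
from .worldgen import GPParams, World, survey_cell_index

__all__ = [
    "Priors",
    "FitConfig",
    "GeoFit",
    "PrevalenceDraws",
    "CVReport",
    "fit_geostat",
    "sample_posterior",
    "cross_validate",
    "cv_metrics",
    "fit_stack_weights",
]


@dataclass(frozen=True)
class Priors:
    """Hyperpriors for the GP hyperparameters (MAP estimation)."""

    range_log_mean: float | None = None  # default: log(grid extent / 4)
    range_log_sd: float = 1.0
    spatial_sd_scale: float = 1.0  # half-normal scale
    nugget_sd_scale: float = 0.5  # half-normal scale
    # temporal rho: uniform(-1, 1)


@dataclass(frozen=True)
class FitConfig:
    weight_mode: str = "simplex"  # or "free"
    optimize_hyperparameters: bool = True
    init: GPParams = GPParams(spatial_range=5.0, spatial_sd=0.5,
                              temporal_rho=0.7, nugget_sd=0.2)
    max_fev: int = 60
    newton_tol: float = 1e-8
    newton_maxiter: int = 50
    jitter: float = 1e-8
    # number of hyperparameter values mixed into the posterior draws (MAP plus
    # hyper_samples-1 samples from the Gaussian approximation of the
    # hyperparameter posterior); 1 = plug-in empirical Bayes
    hyper_samples: int = 8
    hessian_step: float = 0.15  # central-difference step, transformed scale
    offset: str = "cross-fitted"  # learner surfaces for the offset, or "full"


@dataclass
class GeoFit:
    learner_names: list[str]
    weights: np.ndarray  # on the simplex (or free coefficients)
    gp_params: GPParams  # MAP hyperparameters
    mean_logit: np.ndarray  # (ncells, nyears) fixed-effect offset actually used
    f_hat: np.ndarray  # (ncells, nyears) latent-field posterior mode at the MAP
    years: tuple[int, ...]
    diagnostics: dict
    # internals needed for joint posterior sampling
    _K: np.ndarray = field(repr=False, default=None)
    _sqW: np.ndarray = field(repr=False, default=None)
    _chol_cov: np.ndarray | None = field(repr=False, default=None)
    _theta_star: np.ndarray | None = field(repr=False, default=None)
    _theta_chol: np.ndarray | None = field(repr=False, default=None)
    _coords: np.ndarray | None = field(repr=False, default=None)
    _Y: np.ndarray | None = field(repr=False, default=None)
    _N: np.ndarray | None = field(repr=False, default=None)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def posterior_covariance(self, K: np.ndarray | None = None,
                             sqW: np.ndarray | None = None) -> np.ndarray:
        """Gaussian-approximation covariance of the latent field (flattened)."""
        K = self._K if K is None else K
        sqW = self._sqW if sqW is None else sqW
        B = np.eye(K.shape[0]) + sqW[:, None] * K * sqW[None, :]
        LB = cho_factor(B, lower=True)
        R = sqW[:, None] * K
        cov = K - R.T @ cho_solve(LB, R)
        return 0.5 * (cov + cov.T)


@dataclass
class PrevalenceDraws:
    """Joint posterior draws on the grid: (ncells, nyears, ndraws)."""

    values: np.ndarray
    years: tuple[int, ...]
    measure: str = "prevalence"
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return self.values.shape[2]

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=2)

    def interval(self, lo: float = 2.5, hi: float = 97.5):
        return (
            np.percentile(self.values, lo, axis=2),
            np.percentile(self.values, hi, axis=2),
        )

    def year_index(self, year: int) -> int:
        return self.years.index(year)


# ---------------------------------------------------------------------------
# stacking weights
# ---------------------------------------------------------------------------


def fit_stack_weights(
    oos_logits: np.ndarray,
    cases: np.ndarray,
    children: np.ndarray,
    mode: str = "simplex",
) -> np.ndarray:
    """Second-stage weights on learner logits by binomial maximum likelihood.

    ``simplex`` constrains the weights to be non-negative and sum to one (the
    stacking-in-MBG convention, optimised through a softmax parametrisation);
    ``free`` fits unconstrained coefficients.
    """
    n, j = oos_logits.shape
    if j == 1 and mode == "simplex":
        return np.array([1.0])

    def nll(v):
        w = _softmax_pad(v) if mode == "simplex" else v
        eta = oos_logits @ w
        return -np.sum(cases * eta - children * np.logaddexp(0.0, eta))

    x0 = np.zeros(j - 1 if mode == "simplex" else j)
    if mode == "free":
        x0 = np.full(j, 1.0 / j)
    res = optimize.minimize(nll, x0, method="BFGS")
    w = _softmax_pad(res.x) if mode == "simplex" else res.x
    if mode == "simplex":
        w = w / w.sum()  # exact simplex to numerical precision
    return w


def _softmax_pad(v: np.ndarray) -> np.ndarray:
    z = np.concatenate([v, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# Laplace approximation
# ---------------------------------------------------------------------------


def _build_K(params: GPParams, coords: np.ndarray, nyears: int) -> np.ndarray:
    """Dense covariance sigma^2 Matern (x) AR1 + tau^2 I, cell-major layout."""
    rs = matern32_correlation(coords, params.spatial_range)
    rt = ar1_correlation(nyears, params.temporal_rho)
    K = params.spatial_sd**2 * np.kron(rs, rt)
    K[np.diag_indices_from(K)] += params.nugget_sd**2
    return K


def _binom_loglik(f, m, Y, N):
    eta = m + f
    return float(np.sum(Y * eta - N * np.logaddexp(0.0, eta)))


def _laplace_mode(K, m, Y, N, f0=None, tol=1e-8, maxiter=50):
    """Newton mode-finding with step-halving (Rasmussen-Williams style).

    Returns (f_hat, sqW, log_marginal_likelihood, n_iter, converged).
    """
    n = K.shape[0]
    f = np.zeros(n) if f0 is None else f0.copy()
    a = np.linalg.solve(K, f) if f0 is not None and np.any(f0) else np.zeros(n)
    psi = _binom_loglik(f, m, Y, N) - 0.5 * float(a @ f)
    LB = None
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        p = expit(m + f)
        W = N * p * (1.0 - p)
        sqW = np.sqrt(W)
        B = np.eye(n) + sqW[:, None] * K * sqW[None, :]
        LB = cho_factor(B, lower=True)
        b = W * f + (Y - N * p)
        a_new = b - sqW * cho_solve(LB, sqW * (K @ b))
        f_new = K @ a_new
        step = 1.0
        while True:
            f_try = (1 - step) * f + step * f_new
            a_try = (1 - step) * a + step * a_new
            psi_try = _binom_loglik(f_try, m, Y, N) - 0.5 * float(a_try @ f_try)
            if psi_try >= psi - 1e-12 or step < 1e-4:
                break
            step *= 0.5
        delta = abs(psi_try - psi)
        f, a, psi = f_try, a_try, psi_try
        if delta < tol:
            converged = True
            break
    # recompute curvature at the mode for the determinant term
    p = expit(m + f)
    W = N * p * (1.0 - p)
    sqW = np.sqrt(W)
    B = np.eye(n) + sqW[:, None] * K * sqW[None, :]
    LB = cho_factor(B, lower=True)
    logml = psi - float(np.sum(np.log(np.diag(LB[0]))))
    return f, sqW, logml, it, converged


def _log_hyperprior(params: GPParams, priors: Priors, range0: float) -> float:
    mu = priors.range_log_mean if priors.range_log_mean is not None else np.log(range0)
    lp = -0.5 * ((np.log(params.spatial_range) - mu) / priors.range_log_sd) ** 2
    lp -= np.log(params.spatial_range)
    lp -= 0.5 * (params.spatial_sd / priors.spatial_sd_scale) ** 2
    lp -= 0.5 * (params.nugget_sd / priors.nugget_sd_scale) ** 2
    return float(lp)


def _theta_to_params(theta: np.ndarray) -> GPParams:
    return GPParams(
        spatial_range=float(np.exp(theta[0])),
        spatial_sd=float(np.exp(theta[1])),
        temporal_rho=float(np.tanh(theta[2])),
        nugget_sd=float(np.exp(theta[3])),
    )


def _params_to_theta(p: GPParams) -> np.ndarray:
    return np.array([
        np.log(p.spatial_range),
        np.log(max(p.spatial_sd, 1e-6)),
        np.arctanh(np.clip(p.temporal_rho, -0.999, 0.999)),
        np.log(max(p.nugget_sd, 1e-6)),
    ])


def fit_geostat(
    records: pd.DataFrame,
    world: World,
    stack_result: StackResult,
    priors: Priors = Priors(),
    config: FitConfig = FitConfig(),
    seed: int = 0,
) -> GeoFit:
    """Fit the binomial space-time model and return a sampling-ready GeoFit.

    Stacking weights are estimated first from the learners' out-of-sample
    predictions; the residual latent field and its hyperparameters are then
    estimated by Laplace-approximate MAP on the full cell x year grid.

    The fixed-effect offset is the children-weighted out-of-sample stacked
    logit at observed cell-years and the cross-fitted learner surface
    elsewhere.  Using OOS predictions where there are data keeps the ensemble
    from deflating the residual variance through memorised cluster rates,
    which would otherwise shrink the posterior intervals well below nominal.
    """
    if (records["n_children"] <= 0).any():
        raise ValueError("records must have positive n_children")
    ncells, nyears = world.grid.ncells, world.nyears
    cell = survey_cell_index(records, world.grid)
    if (cell < 0).any():
        raise ValueError("fit_geostat requires point records")
    tidx = np.array([world.year_index(int(y)) for y in records["year"]])
    flat = cell * nyears + tidx
    cases = records["n_cases"].to_numpy().astype(float)
    children = records["n_children"].to_numpy().astype(float)

    oos_logits = logit(stack_result.oos_matrix())
    w = fit_stack_weights(oos_logits, cases, children, mode=config.weight_mode)
    surf_logits = logit(
        stack_result.surface_matrix(cross_fitted=config.offset == "cross-fitted")
    )  # (ncells, nyears, J)
    m_flat = (surf_logits @ w).ravel()

    # aggregate records sharing a cell-year: the offset is identical for them
    Y = np.zeros(ncells * nyears)
    N = np.zeros(ncells * nyears)
    np.add.at(Y, flat, cases)
    np.add.at(N, flat, children)
    # OOS offset where there are observations
    oos_eta = oos_logits @ w
    num = np.zeros(ncells * nyears)
    np.add.at(num, flat, oos_eta * children)
    observed = N > 0
    m_flat[observed] = num[observed] / N[observed]
    mean_logit = m_flat.reshape(ncells, nyears)

    coords = world.grid.coords()
    range0 = max(min(world.grid.nrows, world.grid.ncols) / 4.0, 1.0)
    state = {"f": None}

    def objective(theta):
        params = _theta_to_params(theta)
        if params.spatial_range > 50 * range0 or params.spatial_sd > 50:
            return 1e12
        K = _build_K(params, coords, nyears)
        f, _, logml, _, _ = _laplace_mode(
            K, m_flat, Y, N, f0=state["f"],
            tol=config.newton_tol, maxiter=config.newton_maxiter,
        )
        state["f"] = f
        return -(logml + _log_hyperprior(params, priors, range0))

    n_evals = 0
    theta_chol = None
    if config.optimize_hyperparameters:
        theta0 = _params_to_theta(config.init)
        res = optimize.minimize(
            objective, theta0, method="Nelder-Mead",
            options={"maxfev": config.max_fev, "fatol": 1e-2, "xatol": 5e-2},
        )
        theta_star = res.x
        params = _theta_to_params(theta_star)
        n_evals = int(res.nfev)
        if config.hyper_samples > 1:
            theta_chol = _hyper_posterior_chol(
                objective, theta_star, config.hessian_step
            )
    else:
        params = config.init
        theta_star = _params_to_theta(params)

    K = _build_K(params, coords, nyears)
    f_hat, sqW, logml, iters, newton_ok = _laplace_mode(
        K, m_flat, Y, N, f0=state["f"],
        tol=config.newton_tol, maxiter=config.newton_maxiter,
    )
    if not newton_ok:
        warnings.warn("Laplace Newton iteration did not fully converge", stacklevel=2)
    return GeoFit(
        learner_names=list(stack_result.learner_names),
        weights=w,
        gp_params=params,
        mean_logit=mean_logit,
        f_hat=f_hat.reshape(ncells, nyears),
        years=tuple(world.years),
        diagnostics={
            "converged": bool(newton_ok),
            "newton_iterations": iters,
            "hyperparameter_evaluations": n_evals,
            "log_marginal_likelihood": logml,
            "hyper_samples": config.hyper_samples if theta_chol is not None else 1,
        },
        _K=K,
        _sqW=sqW,
        _theta_star=theta_star,
        _theta_chol=theta_chol,
        _coords=coords,
        _Y=Y,
        _N=N,
    )


def _hyper_posterior_chol(objective, theta_star, step):
    """Cholesky of the Gaussian hyperparameter-posterior covariance.

    Central-difference Hessian of the negative log marginal posterior at the
    MAP; eigenvalues floored so a flat direction yields a wide but finite
    proposal rather than a failure.
    """
    p = len(theta_star)
    H = np.zeros((p, p))
    f0 = objective(theta_star)
    fp = np.zeros(p)
    fm = np.zeros(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = step
        fp[i] = objective(theta_star + e)
        fm[i] = objective(theta_star - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / step**2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = step
            ej = np.zeros(p); ej[j] = step
            fpp = objective(theta_star + ei + ej)
            fmm = objective(theta_star - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] - fm[i] - fm[j] + fmm + 2 * f0
            ) / (2 * step**2)
    vals, vecs = np.linalg.eigh(H)
    vals = np.clip(vals, 1e-2, None)
    cov = vecs @ np.diag(1.0 / vals) @ vecs.T
    return np.linalg.cholesky(cov)


def _chol_with_jitter(cov: np.ndarray) -> np.ndarray:
    if np.abs(cov).max() < 1e-14:
        return np.zeros_like(cov)
    jitter = 1e-10 * max(np.trace(cov) / cov.shape[0], 1.0)
    for _ in range(8):
        try:
            return cholesky(cov + jitter * np.eye(cov.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter *= 100
    raise np.linalg.LinAlgError("posterior covariance not factorizable")  # pragma: no cover


def sample_posterior(fit: GeoFit, n_draws: int = 250, seed: int = 0) -> PrevalenceDraws:
    """Joint draws of prevalence over all cells and years.

    A draw index selects one coherent surface.  Draws come from the Laplace
    Gaussian approximation N(f_hat, (K^-1 + W)^-1) of the latent field plus
    the fixed-effect offset, pushed through the inverse logit.  When the fit
    carries a hyperparameter-posterior approximation, the draws are a mixture:
    the MAP component plus components at hyperparameter values sampled from
    that approximation, each with its own Laplace mode and covariance, so the
    intervals reflect hyperparameter uncertainty as well.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2 (intervals are undefined below)")
    ncells, nyears = fit.f_hat.shape
    n = ncells * nyears
    rng = np.random.default_rng(seed)
    n_comp = int(fit.diagnostics.get("hyper_samples", 1))
    if fit._theta_chol is None or n_comp <= 1 or n_draws < 2 * n_comp:
        if fit._chol_cov is None:
            fit._chol_cov = _chol_with_jitter(fit.posterior_covariance())
        mean_flat = (fit.mean_logit + fit.f_hat).ravel()
        eta = mean_flat[:, None] + fit._chol_cov @ rng.standard_normal((n, n_draws))
        values = expit(eta).reshape(ncells, nyears, n_draws)
        return PrevalenceDraws(values=values, years=fit.years,
                               measure="prevalence", seed=seed)

    thetas = [fit._theta_star] + [
        fit._theta_star + fit._theta_chol @ rng.standard_normal(len(fit._theta_star))
        for _ in range(n_comp - 1)
    ]
    per = [n_draws // n_comp] * n_comp
    for i in range(n_draws - sum(per)):
        per[i] += 1
    m_flat = fit.mean_logit.ravel()
    f_warm = fit.f_hat.ravel()
    pieces = []
    for k, (theta, nd) in enumerate(zip(thetas, per)):
        if k == 0:
            K, sqW, f_hat = fit._K, fit._sqW, f_warm
        else:
            params = _theta_to_params(theta)
            K = _build_K(params, fit._coords, nyears)
            f_hat, sqW, _, _, _ = _laplace_mode(K, m_flat, fit._Y, fit._N,
                                                f0=f_warm)
        L = _chol_with_jitter(fit.posterior_covariance(K, sqW))
        eta = (m_flat + f_hat)[:, None] + L @ rng.standard_normal((n, nd))
        pieces.append(expit(eta))
    values = np.concatenate(pieces, axis=1).reshape(ncells, nyears, n_draws)
    return PrevalenceDraws(values=values, years=fit.years, measure="prevalence",
                           seed=seed)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def cv_metrics(
    observed: np.ndarray,
    predicted: np.ndarray,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> dict[str, float]:
    """Bias (mean error), RMSE, 95%-interval coverage, Pearson correlation."""
    err = predicted - observed
    out = {
        "bias": float(err.mean()),
        "rmse": float(np.sqrt(np.mean(err**2))),
    }
    if lower is not None and upper is not None:
        out["coverage95"] = float(
            np.mean((observed >= lower) & (observed <= upper))
        )
    if np.std(observed) == 0 or np.std(predicted) == 0:
        out["correlation"] = 1.0 if np.allclose(observed, predicted) else np.nan
    else:
        out["correlation"] = float(np.corrcoef(observed, predicted)[0, 1])
    return out


@dataclass
class CVReport:
    records: pd.DataFrame  # per-record observed/predicted/lower/upper/fold
    fold_metrics: pd.DataFrame
    pooled: dict[str, float]


def cross_validate(
    records: pd.DataFrame,
    world: World,
    covariate_names: Sequence[str],
    n_folds: int = 5,
    learners: tuple[str, ...] = LEARNER_FAMILIES,
    priors: Priors = Priors(),
    config: FitConfig | None = None,
    n_draws: int = 100,
    group_by: str = "admin_unit_id",
    seed: int = 0,
) -> CVReport:
    """Source/admin2-stratified K-fold validation of the full pipeline.

    Folds hold out whole groups (by default the admin2 unit of each cluster);
    the stack and the geostatistical model are refit per fold, and held-out
    cluster prevalences y/N are scored against binomial predictive draws:
    bias, RMSE, 95%-interval coverage, and Pearson correlation, per fold and
    pooled.  The default per-fold fit is lighter than the main fit (fewer
    optimizer evaluations, plug-in hyperparameters): held-out coverage is
    dominated by binomial sampling noise, not hyperparameter uncertainty.
    """
    if config is None:
        config = FitConfig(max_fev=30, hyper_samples=1)
    groups = records[group_by].to_numpy()
    unique_groups = np.unique(groups)
    if len(unique_groups) < n_folds:
        raise ValueError(
            f"need at least {n_folds} distinct {group_by} groups, "
            f"got {len(unique_groups)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique_groups))
    fold_of_group = {g: int(perm[i] % n_folds) for i, g in enumerate(unique_groups)}
    fold = np.array([fold_of_group[g] for g in groups])

    rows = []
    for f in range(n_folds):
        hold = fold == f
        if not hold.any():
            warnings.warn(f"fold {f} has no held-out records; skipped", stacklevel=2)
            continue
        train = records[~hold].reset_index(drop=True)
        test = records[hold]
        stack = fit_stack(train, world, list(covariate_names),
                          n_folds=n_folds, learners=learners, seed=seed + f)
        fit = fit_geostat(train, world, stack, priors=priors, config=config,
                          seed=seed + f)
        draws = sample_posterior(fit, n_draws=max(n_draws, 2), seed=seed + 100 + f)
        cell = survey_cell_index(test, world.grid)
        tidx = np.array([world.year_index(int(y)) for y in test["year"]])
        p_draws = draws.values[cell, tidx, :]  # (n_test, n_draws)
        n_child = test["n_children"].to_numpy()
        obs = test["n_cases"].to_numpy() / n_child
        # binomial predictive: interval for the observed fraction
        y_star = rng.binomial(n_child[:, None], p_draws) / n_child[:, None]
        lower = np.percentile(y_star, 2.5, axis=1)
        upper = np.percentile(y_star, 97.5, axis=1)
        pred = p_draws.mean(axis=1)
        for i in range(len(test)):
            rows.append({
                "fold": f,
                "observed": obs[i],
                "predicted": pred[i],
                "lower": lower[i],
                "upper": upper[i],
            })
    rec = pd.DataFrame(rows)
    fold_rows = []
    for f, grp in rec.groupby("fold"):
        metrics = cv_metrics(grp["observed"].to_numpy(), grp["predicted"].to_numpy(),
                             grp["lower"].to_numpy(), grp["upper"].to_numpy())
        fold_rows.append({"fold": f, **metrics})
    pooled = cv_metrics(rec["observed"].to_numpy(), rec["predicted"].to_numpy(),
                        rec["lower"].to_numpy(), rec["upper"].to_numpy())
    return CVReport(records=rec, fold_metrics=pd.DataFrame(fold_rows), pooled=pooled)
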
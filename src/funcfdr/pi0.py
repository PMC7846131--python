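"""Estimators for the functional null proportion pi0(z).

The prior probability that a null hypothesis is true is allowed to vary with
the informative variable z.  All three estimators exploit the same thresholding
identity: for any lambda in [0,1), the indicator xi = 1{P > lambda} satisfies

    E[xi | Z = z] / (1 - lambda)  >=  pi0(z),

with equality when every alternative p-value falls below lambda.  Estimating
the conditional mean of xi therefore yields a conservative estimate of pi0(z).

Three conditional-mean models are provided:

* ``glm``    — scaled-logit regression with a linear predictor in z
               (monotone in z by construction);
* ``gam``    — the same scaled-logit likelihood with a cubic B-spline
               predictor, effective degrees of freedom chosen by GCV;
* ``kernel`` — factorizes E[xi|z] = Pr(Z=z | P>lambda) Pr(P>lambda) and
               estimates the first factor by a probit-transform KDE of the
               retained z values and the second by the Storey estimator
               #{p_i > lambda} / (m (1 - lambda)).

The scaled-logit mean (1 - lambda) * expit(eta) is not a standard GLM link, so
the glm/gam fits run a direct numerical maximum likelihood (L-BFGS) rather
than reusing an off-the-shelf logistic regression and rescaling, which could
return values above 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtri
from scipy.stats import gaussian_kde

from .datamodel import Dataset
from .errors import FitFailureError, InsufficientDataError, InvalidTuningError

#: lower floor of every returned pi0 evaluation
EPS_PI0 = 1e-8

#: cap on |linear predictor| to avoid overflow at likelihood boundaries
ETA_CAP = 30.0

DEFAULT_DF_GRID = (3, 4, 5, 6, 8)
DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 0.95, 0.05), 2))


@dataclass(frozen=True)
class Pi0Estimate:
    """A fitted functional null proportion.

    ``eval`` maps z in [0,1] (scalar or array) to pi0_hat(z) in [EPS_PI0, 1].
    ``params`` holds method-specific fitted quantities: for ``glm`` the
    coefficients (beta0, beta1); for ``gam`` the spline coefficients and the
    selected degrees of freedom; for ``kernel`` the scalar Storey estimate and
    the fitted conditional density of z given p > lambda.
    """

    method: str
    lam: float
    eval: Callable[[np.ndarray], np.ndarray]
    params: dict

    def __call__(self, z) -> np.ndarray:
        return self.eval(z)


def xi_indicator(p, lam: float):
    """Indicator 1{p > lambda}; strict inequality, so xi(lam, lam) = 0."""
    if lam >= 1 or lam < 0:
        raise InvalidTuningError(f"lambda must lie in [0, 1), got {lam}")
    return (np.asarray(p) > lam).astype(int)


def _scaled_logit_nll(beta, X, xi, c):
    """Negative log-likelihood and gradient for xi ~ Bern(c * expit(X beta))."""
    eta = X @ beta
    clipped = np.abs(eta) >= ETA_CAP
    eta = np.clip(eta, -ETA_CAP, ETA_CAP)
    s = expit(eta)
    mu = c * s
    # guard exact 0/1 means (only reachable when c == 1 and eta at the cap)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    nll = -np.sum(xi * np.log(mu) + (1 - xi) * np.log1p(-mu))
    dnll_deta = -(xi * (1 - s) - (1 - xi) * c * s * (1 - s) / (1 - mu))
    dnll_deta[clipped] = 0.0
    return nll, X.T @ dnll_deta


def _fit_scaled_logit(X: np.ndarray, xi: np.ndarray, lam: float) -> np.ndarray:
    """Maximize the scaled-logit Bernoulli likelihood; returns coefficients."""
    c = 1.0 - lam
    xbar = min(max(np.mean(xi) / c, 1e-6), 1 - 1e-6)
    beta0 = np.zeros(X.shape[1])
    # start the intercept-like direction at the pooled estimate
    col_means = X.mean(axis=0)
    # solve col_means . beta = logit(xbar) along the constant direction
    beta0 += np.linalg.lstsq(
        col_means[None, :], np.array([logit(xbar)]), rcond=None
    )[0]
    res = minimize(
        _scaled_logit_nll,
        beta0,
        args=(X, xi, c),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3 * len(xi):
        raise FitFailureError(
            "scaled-logit fit did not converge (possible complete separation); "
            "consider the kernel method"
        )
    return res.x


def _warn_small(m: int) -> None:
    if m < 50:
        import warnings

        warnings.warn(
            f"only {m} tests: pi0(z) estimates will be unstable below m = 50",
            stacklevel=3,
        )


def estimate_pi0_glm(dataset: Dataset, lam: float = 0.5) -> Pi0Estimate:
    """Scaled-logit GLM estimate of pi0(z); monotone in z.

    Fits xi_i ~ Bernoulli((1-lam) * expit(b0 + b1 z_i)) by maximum likelihood
    and returns pi0_hat(z) = expit(b0_hat + b1_hat z), which lies in (0,1) by
    construction of the link.
    """
    _warn_small(dataset.m)
    xi = xi_indicator(dataset.p, lam)
    X = np.column_stack([np.ones(dataset.m), dataset.z])
    beta = _fit_scaled_logit(X, xi, lam)

    def _eval(z):
        eta = np.clip(beta[0] + beta[1] * np.asarray(z, dtype=float), -ETA_CAP, ETA_CAP)
        return np.clip(expit(eta), EPS_PI0, 1.0)

    return Pi0Estimate(
        method="glm", lam=lam, eval=_eval, params={"beta0": beta[0], "beta1": beta[1]}
    )


def _bspline_design(z: np.ndarray, knots_z: np.ndarray, df: int):
    """Cubic (or lower-order, for small df) B-spline design matrix with df
    basis functions spanning constants; interior knots at z-quantiles."""
    degree = min(3, df - 1)
    n_interior = df - degree - 1
    if n_interior > 0:
        qs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(knots_z, qs)
    else:
        interior = np.array([])
    t = np.concatenate(
        [np.zeros(degree + 1), interior, np.ones(degree + 1)]
    )
    X = BSpline.design_matrix(
        np.clip(z, 0.0, 1.0), t, degree, extrapolate=False
    ).toarray()
    return X, t, degree


def estimate_pi0_gam(
    dataset: Dataset,
    lam: float = 0.5,
    df_grid: Sequence[int] = DEFAULT_DF_GRID,
) -> Pi0Estimate:
    """Scaled-logit GAM estimate of pi0(z) with a B-spline linear predictor.

    The effective degrees of freedom are chosen from ``df_grid`` by generalized
    cross-validation, GCV(df) = (deviance / m) / (1 - k/m)^2 with k the number
    of fitted coefficients.  ``df = 1`` degenerates to the GLM's linear
    predictor, so the GAM family nests the GLM.  Unlike the GLM the result is
    not constrained to be monotone in z.
    """
    if len(df_grid) == 0:
        raise InvalidTuningError("df grid must be non-empty")
    _warn_small(dataset.m)
    xi = xi_indicator(dataset.p, lam)
    m = dataset.m
    best = None
    for df in df_grid:
        if df <= 1:
            X = np.column_stack([np.ones(m), dataset.z])
            spline = None
        else:
            X, t, degree = _bspline_design(dataset.z, dataset.z, df)
            spline = (t, degree)
        try:
            beta = _fit_scaled_logit(X, xi, lam)
        except FitFailureError:
            continue
        nll, _ = _scaled_logit_nll(beta, X, xi, 1.0 - lam)
        k = X.shape[1]
        gcv = (2 * nll / m) / (1 - k / m) ** 2
        if best is None or gcv < best["gcv"]:
            best = {"gcv": gcv, "beta": beta, "df": df, "spline": spline}
    if best is None:
        raise FitFailureError("no GAM fit converged on the supplied df grid")

    beta, spline = best["beta"], best["spline"]

    def _eval(z):
        z = np.asarray(z, dtype=float)
        scalar = z.ndim == 0
        z1 = np.atleast_1d(z)
        if spline is None:
            eta = beta[0] + beta[1] * z1
        else:
            t, degree = spline
            X = BSpline.design_matrix(
                np.clip(z1, 0.0, 1.0), t, degree, extrapolate=False
            ).toarray()
            eta = X @ beta
        out = np.clip(expit(np.clip(eta, -ETA_CAP, ETA_CAP)), EPS_PI0, 1.0)
        return out[0] if scalar else out

    return Pi0Estimate(
        method="gam",
        lam=lam,
        eval=_eval,
        params={"beta": beta, "df": best["df"], "gcv": best["gcv"]},
    )


def storey_pi0(p: np.ndarray, lam: float) -> float:
    """Scalar Storey estimate #{p_i > lambda} / (m (1 - lambda)), uncapped."""
    if lam >= 1 or lam < 0:
        raise InvalidTuningError(f"lambda must lie in [0, 1), got {lam}")
    p = np.asarray(p, dtype=float)
    return float(np.sum(p > lam) / (len(p) * (1.0 - lam)))


def estimate_pi0_kernel(dataset: Dataset, lam: float = 0.5) -> Pi0Estimate:
    """Kernel estimate of pi0(z): Storey scalar times a conditional density.

    The density h_lam of z among tests with p > lambda is estimated by a
    Gaussian KDE on the probit scale (Silverman bandwidth) and back-transformed
    with the probit Jacobian, so the estimate respects the [0,1] support.
    pi0_hat(z) = h_lam_hat(z) * pi0_S_hat(lambda), clipped to [EPS_PI0, 1].
    """
    pi0_s = storey_pi0(dataset.p, lam)
    keep = dataset.p > lam
    if np.sum(keep) < 20:
        raise InsufficientDataError(
            f"only {int(np.sum(keep))} tests with p > {lam}; need at least 20"
        )
    u = ndtri(np.clip(dataset.z[keep], 1e-12, 1 - 1e-12))
    kde = gaussian_kde(u, bw_method="silverman")

    def _h_raw(z):
        z = np.clip(np.asarray(z, dtype=float), 1e-9, 1 - 1e-9)
        uu = ndtri(z)
        phi = np.exp(-0.5 * uu**2) / np.sqrt(2 * np.pi)
        return kde(np.atleast_1d(uu)) / np.maximum(phi, 1e-300)

    # renormalize on [0,1]: the probit back-transform loses the KDE's tail
    # mass beyond the unit interval (~1e-3), and h_lambda is a density there
    z_norm = np.linspace(1e-9, 1 - 1e-9, 2048)
    norm = np.trapezoid(_h_raw(z_norm), z_norm)

    def _h(z):
        return _h_raw(z) / norm

    def _eval(z):
        z = np.asarray(z, dtype=float)
        scalar = z.ndim == 0
        out = np.clip(_h(np.atleast_1d(z)) * pi0_s, EPS_PI0, 1.0)
        return out[0] if scalar else out

    return Pi0Estimate(
        method="kernel",
        lam=lam,
        eval=_eval,
        params={"pi0_storey": pi0_s, "h_lambda": _h},
    )


_METHODS = {
    "glm": estimate_pi0_glm,
    "gam": estimate_pi0_gam,
    "kernel": estimate_pi0_kernel,
}


def estimate_pi0(dataset: Dataset, method: str = "gam", lam: float = 0.5, **kw) -> Pi0Estimate:
    """Dispatch to one of the pi0(z) estimators by name."""
    if method not in _METHODS:
        raise InvalidTuningError(f"unknown pi0 method {method!r}; use glm/gam/kernel")
    return _METHODS[method](dataset, lam, **kw)


def select_lambda(
    dataset: Dataset,
    method: str = "gam",
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    n_bootstrap: int = 100,
    seed: int | None = 0,
    z_grid_size: int = 101,
) -> float:
    """Choose lambda by a bootstrap MISE surrogate.

    For each grid lambda the pointwise variance of pi0_hat(z; lambda) is
    estimated from ``n_bootstrap`` resamples of the tests, and the pointwise
    bias is taken as the excess of pi0_hat(z; lambda) above the reference
    curve pi0_hat(z; lambda_max) beyond twice the reference's own bootstrap
    standard error: the thresholding estimators are biased upward (they count
    alternatives with p > lambda as nulls) and the bias shrinks as lambda
    grows, so a lambda's significant excess above the least-biased reference
    estimates its bias, while excess explained by the reference's sampling
    noise is not charged.  The returned lambda minimizes the
    trapezoid integral of bias^2 + variance over z in [0,1]; ties within 1e-4
    break toward the smallest lambda so more of the data is retained.
    Deterministic given ``seed``.
    """
    lambda_grid = sorted(set(float(l) for l in lambda_grid))
    if len(lambda_grid) == 0:
        raise InvalidTuningError("lambda grid must be non-empty")
    if max(lambda_grid) > 0.95 or min(lambda_grid) < 0:
        raise InvalidTuningError("lambda grid must lie within [0, 0.95]")
    if len(lambda_grid) == 1:
        return lambda_grid[0]

    rng = np.random.default_rng(seed)
    zg = np.linspace(0.0, 1.0, z_grid_size)
    fit = _METHODS[method]

    curves = {}
    for lam in lambda_grid:
        curves[lam] = fit(dataset, lam)(zg)
    ref = curves[lambda_grid[-1]]

    # one shared set of bootstrap index draws keeps the comparison paired
    boot_idx = [
        rng.integers(0, dataset.m, size=dataset.m) for _ in range(n_bootstrap)
    ]

    def _boot_curves(lam):
        boot = np.empty((n_bootstrap, z_grid_size))
        for b, idx in enumerate(boot_idx):
            ds_b = Dataset(
                ids=np.arange(dataset.m),
                p=dataset.p[idx],
                z_raw=dataset.z_raw[idx],
                z=dataset.z[idx],
            )
            try:
                boot[b] = fit(ds_b, lam)(zg)
            except (FitFailureError, InsufficientDataError):
                boot[b] = curves[lam]
        return boot

    ref_sd = _boot_curves(lambda_grid[-1]).std(axis=0, ddof=1)
    mise = []
    for lam in lambda_grid:
        var = _boot_curves(lam).var(axis=0, ddof=1)
        bias = np.maximum(0.0, curves[lam] - ref - 2.0 * ref_sd)
        mise.append(float(np.trapezoid(bias**2 + var, zg)))

    mise = np.asarray(mise)
    best = mise.min()
    # smallest lambda whose MISE is within 1e-4 of the minimum
    for lam, val in zip(lambda_grid, mise):
        if val <= best + 1e-4:
            return lam
    return lambda_grid[int(np.argmin(mise))]
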
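"""Synthetic data from the two-group model with an informative variable.

The generative model: Z ~ Uniform(0,1); H | Z=z ~ Bernoulli(1 - pi0(z));
P | H=0 ~ Uniform(0,1); P | H=1, Z=z has density f1(p|z) = a(z) p^(a(z)-1)
(a Beta(a(z), 1) draw) with a(z) in (0,1), so alternative p-values pile up
near zero and the joint density f(p,z) = pi0(z) + (1-pi0(z)) f1(p|z) is
non-increasing in p for every z.

Because pi0(z) and f1 are known in closed form, the posterior null
probability r(p,z), the pFDR/pFNR of any threshold region, and the Bayes
error of the optimal rule are available as numeric oracles; these validate
the plug-in estimators end to end.

Functional forms are named in compact spec strings, e.g.
``"linear-logit:b0=0.4,b1=1.2"`` for pi0(z) = expit(0.4 + 1.2 z) and
``"beta:a=0.25"`` for a constant Beta shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .core import (
    FfdrResult,
    call_significant,
    ffdr_pipeline,
    standard_qvalues,
)
from .datamodel import Dataset
from .errors import ConfigurationError, InvalidTuningError

#: points per axis of the oracle quadrature grid
QUAD_GRID = 512

#: the p axis is integrated on the power-transformed grid p = s^PGRID_POWER,
#: which absorbs the p^(a-1) singularity at p = 0 for a >= 1/PGRID_POWER
PGRID_POWER = 4


def _parse_kv(spec: str) -> tuple[str, dict[str, float]]:
    name, _, rest = spec.partition(":")
    params = {}
    if rest:
        for item in rest.split(","):
            k, _, v = item.partition("=")
            try:
                params[k.strip()] = float(v)
            except ValueError as exc:
                raise ConfigurationError(f"bad parameter {item!r} in {spec!r}") from exc
    return name.strip(), params


def pi0_function(spec: str) -> Callable[[np.ndarray], np.ndarray]:
    """Build pi0(z) from a spec string.

    Supported forms: ``constant:c=0.8``; ``linear-logit:b0=0.4,b1=1.2``
    (expit(b0 + b1 z), monotone); ``cosine:base=0.6,amp=0.3``
    (base + amp*cos(2 pi z), non-monotone); ``linear:c0=0.6,c1=0.3``
    (c0 + c1 z clipped to [0,1]).
    """
    name, kv = _parse_kv(spec)
    if name == "constant":
        c = kv.get("c", 0.8)
        if not 0 <= c <= 1:
            raise ConfigurationError(f"constant pi0 must lie in [0,1], got {c}")
        return lambda z: np.full_like(np.asarray(z, dtype=float), c)
    if name == "linear-logit":
        b0, b1 = kv.get("b0", 0.4), kv.get("b1", 1.2)
        return lambda z: expit(b0 + b1 * np.asarray(z, dtype=float))
    if name == "cosine":
        base, amp = kv.get("base", 0.6), kv.get("amp", 0.3)
        return lambda z: np.clip(
            base + amp * np.cos(2 * np.pi * np.asarray(z, dtype=float)), 0.0, 1.0
        )
    if name == "linear":
        c0, c1 = kv.get("c0", 0.6), kv.get("c1", 0.3)
        return lambda z: np.clip(c0 + c1 * np.asarray(z, dtype=float), 0.0, 1.0)
    raise ConfigurationError(f"unknown pi0 form {name!r}")


def alt_shape_function(spec: str) -> Callable[[np.ndarray], np.ndarray]:
    """Build the Beta shape a(z) in (0,1) from a spec string.

    Supported forms: ``beta:a=0.25`` (constant shape) and
    ``beta-linear:a0=0.2,a1=0.3`` (a0 + a1 z, clipped into (0,1)).
    Smaller a(z) means better-powered alternatives.
    """
    name, kv = _parse_kv(spec)
    if name == "beta":
        a = kv.get("a", 0.25)
        if not 0 < a < 1:
            raise ConfigurationError(f"beta shape must lie in (0,1), got {a}")
        return lambda z: np.full_like(np.asarray(z, dtype=float), a)
    if name == "beta-linear":
        a0, a1 = kv.get("a0", 0.2), kv.get("a1", 0.3)
        return lambda z: np.clip(
            a0 + a1 * np.asarray(z, dtype=float), 1e-6, 1 - 1e-6
        )
    raise ConfigurationError(f"unknown alternative form {name!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic study condition."""

    m: int
    pi0_spec: str = "linear-logit:b0=0.4,b1=1.2"
    alt_spec: str = "beta:a=0.25"
    seed: int = 0

    def pi0(self) -> Callable[[np.ndarray], np.ndarray]:
        return pi0_function(self.pi0_spec)

    def alt_shape(self) -> Callable[[np.ndarray], np.ndarray]:
        return alt_shape_function(self.alt_spec)


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Draw m tests from the two-group model; true statuses are recorded.

    The raw covariate column holds the latent uniform Z draws; the dataset's
    working z is their rank-based quantile normalization, exactly as a real
    covariate would be processed.  Alternative p-values are U^(1/a(z))
    (inverse-CDF of Beta(a(z), 1)).  Bitwise reproducible given the seed.
    """
    pi0_fn, a_fn = config.pi0(), config.alt_shape()
    rng = np.random.default_rng(config.seed)
    z = rng.uniform(size=config.m)
    h = (rng.uniform(size=config.m) < 1.0 - pi0_fn(z)).astype(int)
    p = rng.uniform(size=config.m)
    alt = h == 1
    p[alt] = p[alt] ** (1.0 / a_fn(z[alt]))
    return Dataset.from_arrays(p=p, z_raw=z, h=h)


def oracle_r(config: SimulationConfig, p, z):
    """True posterior null probability r(p,z) = pi0(z) / f(p,z).

    At p = 0 with a(z) < 1 the alternative density diverges, so the posterior
    mass on the null vanishes: the limit value 0 is returned.
    """
    p = np.asarray(p, dtype=float)
    z = np.asarray(z, dtype=float)
    scalar = p.ndim == 0 and z.ndim == 0
    p1, z1 = np.atleast_1d(p).copy(), np.atleast_1d(z)
    pi0 = config.pi0()(z1)
    a = config.alt_shape()(z1)
    zero = p1 <= 0
    p1[zero] = 0.5  # placeholder, overwritten below
    f1 = a * p1 ** (a - 1.0)
    r = pi0 / (pi0 + (1.0 - pi0) * f1)
    r[zero & (a < 1)] = 0.0
    r[pi0 >= 1.0] = 1.0
    out = np.clip(r, 0.0, 1.0)
    return float(out[0]) if scalar else out


def _quad_grids():
    """(s, p(s), dp/ds, z) grids for oracle quadrature on [0,1]^2."""
    s = np.linspace(0.0, 1.0, QUAD_GRID)
    p = s**PGRID_POWER
    jac = PGRID_POWER * s ** (PGRID_POWER - 1)
    z = np.linspace(0.0, 1.0, QUAD_GRID)
    return s, p, jac, z


def _joint_pieces(config: SimulationConfig):
    """Null and alternative joint-density pieces on the quadrature grid.

    Returns (r, null_part, alt_part, s, z) where null_part = pi0(z) dp/ds and
    alt_part = (1-pi0(z)) f1(p|z) dp/ds, both already carrying the p-grid
    Jacobian so trapezoid integration runs over (s, z).
    """
    s, p, jac, z = _quad_grids()
    pi0 = config.pi0()(z)[None, :]
    a = config.alt_shape()(z)[None, :]
    # f1 * jac = a p^(a-1) * k s^(k-1) = a k s^(k a - 1): bounded for a >= 1/k
    with np.errstate(divide="ignore"):
        f1_jac = a * PGRID_POWER * np.where(
            s[:, None] > 0, s[:, None] ** (PGRID_POWER * a - 1.0),
            np.where(PGRID_POWER * a > 1.0, 0.0, PGRID_POWER * a * 1.0),
        )
    # exact limit at s=0: 0 if k*a > 1, a*k if k*a == 1; grid never hits k*a<1 exactly
    null_part = pi0 * jac[:, None] * np.ones_like(f1_jac)
    alt_part = (1.0 - pi0) * f1_jac
    r = oracle_r(config, *np.meshgrid(p, z, indexing="ij"))
    return r, null_part, alt_part, s, z


def _integrate(values, s, z):
    return float(np.trapezoid(np.trapezoid(values, z, axis=1), s))


@dataclass(frozen=True)
class PfdrPfnr:
    """Oracle (pFDR, pFNR) of the region {r(p,z) <= tau}; ``empty`` flags a
    tau below the infimum of r, where pFDR is undefined."""

    pfdr: float
    pfnr: float
    mass_rejected: float
    empty: bool = False


def oracle_pfdr_pfnr(config: SimulationConfig, tau: float) -> PfdrPfnr:
    """Conditional-probability pFDR and pFNR of the region r(p,z) <= tau.

    pFDR = Pr(H=0 | T in region) and pFNR = Pr(H=1 | T outside region),
    computed by trapezoid quadrature of the closed-form joint law.
    """
    r, null_part, alt_part, s, z = _joint_pieces(config)
    inside = r <= tau
    mass_in = _integrate(np.where(inside, null_part + alt_part, 0.0), s, z)
    if mass_in <= 1e-12:
        return PfdrPfnr(pfdr=float("nan"), pfnr=float("nan"),
                        mass_rejected=0.0, empty=True)
    null_in = _integrate(np.where(inside, null_part, 0.0), s, z)
    alt_out = _integrate(np.where(~inside, alt_part, 0.0), s, z)
    mass_out = max(1.0 - mass_in, 1e-12)
    return PfdrPfnr(
        pfdr=null_in / mass_in, pfnr=alt_out / mass_out, mass_rejected=mass_in
    )


def bayes_error(config: SimulationConfig, tau: float) -> float:
    """Weighted misclassification risk of the region {r <= tau}:
    (1-tau) Pr(reject, H=0) + tau Pr(accept, H=1)."""
    r, null_part, alt_part, s, z = _joint_pieces(config)
    inside = r <= tau
    fp = _integrate(np.where(inside, null_part, 0.0), s, z)
    fn = _integrate(np.where(~inside, alt_part, 0.0), s, z)
    return (1.0 - tau) * fp + tau * fn


def p_threshold_bayes_error(config: SimulationConfig, t: float, tau: float) -> float:
    """Bayes risk of the p-only rule 'reject when p <= t' under the same
    loss weights as :func:`bayes_error`."""
    z = np.linspace(0.0, 1.0, QUAD_GRID)
    pi0 = config.pi0()(z)
    a = config.alt_shape()(z)
    fp = float(np.trapezoid(pi0, z)) * t
    fn = float(np.trapezoid((1.0 - pi0) * (1.0 - t ** a), z))
    return (1.0 - tau) * fp + tau * fn


def rejection_mass_p_rule(config: SimulationConfig, t: float) -> float:
    """Pr(P <= t) under the model: integral of pi0 t + (1-pi0) t^a over z."""
    z = np.linspace(0.0, 1.0, QUAD_GRID)
    pi0 = config.pi0()(z)
    a = config.alt_shape()(z)
    return float(np.trapezoid(pi0 * t + (1.0 - pi0) * t ** a, z))


def matched_p_threshold(config: SimulationConfig, mass: float) -> float:
    """p-cutoff whose rejection region has probability ``mass``."""
    if mass <= 0:
        return 0.0
    if mass >= 1:
        return 1.0
    return brentq(lambda t: rejection_mass_p_rule(config, t) - mass, 0.0, 1.0)


@dataclass(frozen=True)
class StudyResult:
    """Replicate-level and summary output of a simulation study."""

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    n_failures: int


def _fdp_tp(significant: np.ndarray, h: np.ndarray) -> tuple[float, int]:
    n_sig = int(significant.sum())
    fp = int(np.sum(significant & (h == 0)))
    tp = int(np.sum(significant & (h == 1)))
    return (fp / n_sig if n_sig > 0 else 0.0), tp


def run_simulation_study(
    config: SimulationConfig,
    replicates: int,
    alpha: float = 0.05,
    pi0_method: str = "glm",
    lam: float = 0.5,
    grid_size: int = 128,
) -> StudyResult:
    """Replicate the full pipeline against the covariate-free baseline.

    For each replicate a fresh dataset is generated (replicate k uses seed
    ``config.seed + k``), the functional FDR pipeline and the standard
    q-value baseline are both run at level ``alpha``, and the false discovery
    proportion and true-positive count of each are recorded.  The summary
    holds means and Monte-Carlo standard errors.  Replicate failures are
    recorded, never silently dropped.
    """
    if replicates < 2:
        raise InvalidTuningError("need at least 2 replicates")
    rows = []
    n_fail = 0
    for k in range(replicates):
        cfg = SimulationConfig(
            m=config.m, pi0_spec=config.pi0_spec, alt_spec=config.alt_spec,
            seed=config.seed + k,
        )
        ds = generate_dataset(cfg)
        try:
            res = ffdr_pipeline(
                ds, alpha=alpha, pi0_method=pi0_method, lam=lam,
                grid_size=grid_size, seed=cfg.seed,
            )
        except Exception as exc:  # recorded, not dropped
            n_fail += 1
            rows.append({"replicate": k, "failed": True, "error": str(exc)})
            continue
        q_std = standard_qvalues(ds.p, lam=lam)
        sig_std = call_significant(q_std, alpha)
        fdp_f, tp_f = _fdp_tp(res.significant, ds.h)
        fdp_s, tp_s = _fdp_tp(sig_std, ds.h)
        rows.append(
            {
                "replicate": k, "failed": False, "error": "",
                "fdp_ffdr": fdp_f, "tp_ffdr": tp_f,
                "fdp_standard": fdp_s, "tp_standard": tp_s,
            }
        )
    per = pd.DataFrame(rows)
    ok = per[~per["failed"]]
    metrics = ["fdp_ffdr", "tp_ffdr", "fdp_standard", "tp_standard"]
    n = len(ok)
    summary = pd.DataFrame(
        {
            "metric": metrics,
            "mean": [ok[c].mean() for c in metrics],
            "se": [ok[c].std(ddof=1) / np.sqrt(n) for c in metrics],
            "n": n,
        }
    )
    return StudyResult(per_replicate=per, summary=summary, n_failures=n_fail)
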
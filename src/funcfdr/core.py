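"""Functional local FDR, functional q-values, and the significance rule.

Given fitted components pi0_hat(z) and f_hat(p, z), the functional local FDR
(posterior error probability) of test i is

    r_hat_i = min(1, pi0_hat(z_i) / f_hat(p_i, z_i)),

the posterior probability that the null is true given (p_i, z_i).  The
functional q-value of test i averages r_hat over every test at least as
extreme,

    q_hat_i = mean{ r_hat_j : r_hat_j <= r_hat_i },

which estimates the positive FDR of the significance region that just admits
test i.  Calling tests with q_hat <= alpha targets pFDR level alpha.

A covariate-free baseline (`standard_qvalues`, the classic Storey q-value) is
provided for power comparisons; `ffdr_pipeline` wires normalization, pi0 fit,
density fit and q-values into one call.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import Dataset
from .density import (
    JointDensityEstimate,
    estimate_joint_density,
    evaluate_density,
)
from .errors import InvalidInputError, InvalidTuningError
from .pi0 import Pi0Estimate, estimate_pi0, select_lambda, storey_pi0

logger = logging.getLogger("funcfdr")


@dataclass(frozen=True)
class FfdrResult:
    """Per-test functional FDR quantities at a target level alpha.

    Invariants: q_i <= r_i; q is non-decreasing in r; tied r share a q;
    significance sets are nested in alpha.
    """

    r: np.ndarray
    q: np.ndarray
    alpha: float
    significant: np.ndarray
    pi0_at_z: np.ndarray
    lam: float | None = None

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def compute_local_fdr(
    pi0: Pi0Estimate, density: JointDensityEstimate, dataset: Dataset
) -> np.ndarray:
    """r_hat_i = min(1, pi0_hat(z_i) / f_hat(p_i, z_i)), in (0, 1].

    The plug-in ratio can exceed 1 even though the estimand is a posterior
    probability; it is capped at 1.
    """
    if dataset.m == 0:
        raise InvalidInputError("dataset is empty")
    f = evaluate_density(density, dataset.p, dataset.z)
    return np.minimum(1.0, pi0(dataset.z) / f)


def compute_q_values(r: Sequence[float] | np.ndarray) -> np.ndarray:
    """Cumulative-mean q-values: q_i = mean of all r_j <= r_i.

    Sort-based O(m log m) evaluation; ties share the running mean at the last
    tied position (the defining set uses a non-strict inequality, so tied
    tests have identical averaging sets).  Output is in input order.
    """
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise InvalidInputError("cannot compute q-values of an empty collection")
    if np.any((r <= 0) | (r > 1)):
        raise InvalidInputError("local FDR values must lie in (0, 1]")
    order = np.argsort(r, kind="stable")
    r_sorted = r[order]
    running_mean = np.cumsum(r_sorted) / np.arange(1, r.size + 1)
    # propagate the mean at the last index of each tied block backwards
    last_of_block = np.r_[r_sorted[1:] != r_sorted[:-1], True]
    block_mean = running_mean[last_of_block]
    block_id = np.cumsum(np.r_[True, r_sorted[1:] != r_sorted[:-1]]) - 1
    q_sorted = block_mean[block_id]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def call_significant(q: np.ndarray, alpha: float) -> np.ndarray:
    """significant_i <=> q_i <= alpha."""
    if not 0 <= alpha <= 1:
        raise InvalidTuningError(f"alpha must lie in [0, 1], got {alpha}")
    return np.asarray(q) <= alpha


def standard_qvalues(p: Sequence[float] | np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Covariate-free Storey q-values.

    pi0 is the scalar estimate #{p_i > lambda} / (m (1 - lambda)) capped at 1;
    q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j over order statistics.  Output
    is in input order, capped into (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise InvalidInputError("cannot compute q-values of an empty collection")
    pi0 = min(1.0, storey_pi0(p, lam))
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    raw = pi0 * m * p_sorted / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.clip(q_sorted, np.finfo(float).tiny, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def ffdr_pipeline(
    dataset: Dataset,
    alpha: float = 0.05,
    pi0_method: str = "gam",
    lam: float | str = "auto",
    monotone: bool = True,
    grid_size: int = 128,
    n_bootstrap: int = 100,
    seed: int | None = 0,
) -> FfdrResult:
    """Run the full functional FDR procedure on a dataset.

    Steps: (optional) data-driven lambda selection, pi0(z) fit, joint density
    fit, local FDR, q-values, significance calls at ``alpha``.  Deterministic
    given ``seed``.

    Parameters
    ----------
    lam
        Threshold above which p-values are treated as mostly null.  ``"auto"``
        selects it from the default grid by the bootstrap MISE surrogate.
    """
    t0 = time.perf_counter()
    if lam == "auto":
        lam = select_lambda(
            dataset, method=pi0_method, n_bootstrap=n_bootstrap, seed=seed
        )
        logger.info("lambda selection: chose %.2f (%.1fs)", lam, time.perf_counter() - t0)
    lam = float(lam)

    t1 = time.perf_counter()
    pi0 = estimate_pi0(dataset, method=pi0_method, lam=lam)
    logger.info(
        "pi0 fit [%s, lambda=%.2f] done (%.1fs)", pi0_method, lam, time.perf_counter() - t1
    )

    t2 = time.perf_counter()
    density = estimate_joint_density(
        dataset, monotone=monotone, grid_size=grid_size, seed=seed
    )
    logger.info(
        "density fit [nn fraction %.2f] done (%.1fs)",
        density.bandwidth_info.get("nn_fraction", float("nan")),
        time.perf_counter() - t2,
    )

    r = compute_local_fdr(pi0, density, dataset)
    q = compute_q_values(r)
    sig = call_significant(q, alpha)
    logger.info(
        "m=%d tests, lambda=%.2f, %d significant at alpha=%.3g (total %.1fs)",
        dataset.m, lam, int(sig.sum()), alpha, time.perf_counter() - t0,
    )
    return FfdrResult(
        r=r, q=q, alpha=alpha, significant=sig, pi0_at_z=pi0(dataset.z), lam=lam
    )
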
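"""Truncated-normal selection mathematics.

Participation is modelled as a liability-threshold process: a latent standard-normal
score ``X`` with an individual participating iff ``X > t_alpha``, where ``t_alpha``
is the upper ``alpha`` quantile and ``alpha`` the participation rate.  Every
distortion that selection induces on second moments of jointly Gaussian variables
is governed by a single scalar, the variance-reduction factor

    xi(alpha) = 1 - Var(X | X > t_alpha) = lambda * (lambda - t_alpha),

with ``lambda = phi(t_alpha) / alpha`` the inverse Mills ratio of the upper tail.
This module provides ``xi``, the mean-shift <-> phenotypic-correlation maps, the
Pearson-Lawley conditional-covariance operator, and a Monte-Carlo oracle for
truncated multivariate-normal moments used to verify every closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import norm

__all__ = [
    "SelectionConstants",
    "MCOracleResult",
    "selection_constants",
    "mean_shift_from_rho",
    "rho_from_mean_shift",
    "selected_cov",
    "mc_truncated_mvn",
]


@dataclass(frozen=True)
class SelectionConstants:
    """Threshold and variance-reduction factor for a given participation rate.

    Attributes
    ----------
    alpha : float
        Participation rate in (0, 1].
    t_alpha : float
        Liability threshold Phi^-1(1 - alpha); ``-inf`` when ``alpha == 1``
        (no selection).
    xi : float
        Variance reduction of the liability under truncation,
        ``1 - Var(X | X > t_alpha)``; 0 iff ``alpha == 1``.
    mills : float
        Upper-tail inverse Mills ratio ``phi(t_alpha) / alpha``, which equals
        ``E[X | X > t_alpha]``.
    """

    alpha: float
    t_alpha: float
    xi: float
    mills: float

    @property
    def phi_t(self) -> float:
        """Standard-normal density at the threshold, phi(t_alpha)."""
        return self.mills * self.alpha


def selection_constants(alpha: float) -> SelectionConstants:
    """Compute the liability threshold and variance-reduction factor xi(alpha).

    ``alpha = 1`` is handled as a no-selection special case (xi = 0, threshold
    at -inf) so downstream formulas degrade gracefully.

    Raises
    ------
    ValueError
        If ``alpha`` is not in (0, 1].
    """
    alpha = float(alpha)
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"participation rate alpha must be in (0, 1], got {alpha}")
    if alpha == 1.0:
        return SelectionConstants(alpha=1.0, t_alpha=-math.inf, xi=0.0, mills=0.0)
    t = float(ndtri(1.0 - alpha))
    # log-space ratio avoids cancellation in phi(t)/alpha for small alpha
    mills = math.exp(norm.logpdf(t) - math.log(alpha))
    xi = mills * (mills - t)
    return SelectionConstants(alpha=alpha, t_alpha=t, xi=xi, mills=mills)


def mean_shift_from_rho(rho: float, constants: SelectionConstants) -> float:
    """Expected standardized mean shift of a phenotype given its correlation with X.

    ``delta = rho * lambda / sqrt(1 - xi * rho**2)``: the difference in the
    phenotype mean between participants and the population, standardized by the
    *selected-sample* standard deviation.
    """
    rho = float(rho)
    if abs(rho) > 1.0:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    return rho * constants.mills / math.sqrt(1.0 - constants.xi * rho * rho)


def rho_from_mean_shift(delta: float, constants: SelectionConstants) -> float:
    """Phenotypic correlation with the participation liability from a mean shift.

    Exact inverse of :func:`mean_shift_from_rho`:
    ``rho = alpha*delta / sqrt(xi * alpha**2 * delta**2 + phi(t_alpha)**2)``.
    Stays in (-1, 1) for any ``delta`` attainable under the model
    (|delta| < mills/sqrt(1 - xi)); a noisy estimate beyond that range maps
    monotonically to |rho| > 1 (up to 1/sqrt(xi)) and is returned raw so the
    caller can flag it.  When ``alpha == 1`` the shift is identically zero and
    rho is unidentifiable; 0.0 is returned.
    """
    delta = float(delta)
    if not math.isfinite(delta):
        raise ValueError("delta must be finite")
    if constants.alpha == 1.0:
        return 0.0
    a_d = constants.alpha * delta
    return a_d / math.sqrt(constants.xi * a_d * a_d + constants.phi_t**2)


def selected_cov(
    cov_uv: float, cov_ux: float, cov_vx: float, constants: SelectionConstants
) -> float:
    """Covariance of two Gaussian variables after selection on the liability.

    For (U, V, X) jointly Gaussian with unit-variance X (the Pearson-Lawley
    selection identity):

        Cov(U, V | X > t_alpha) = Cov(U, V) - xi * Cov(U, X) * Cov(V, X).
    """
    return cov_uv - constants.xi * cov_ux * cov_vx


@dataclass
class MCOracleResult:
    """Empirical truncated-MVN moments with Monte-Carlo standard errors.

    ``mean``/``cov`` hold the estimated moments of all variables conditional on
    ``X > t_alpha`` (X is coordinate 0); ``se_mean``/``se_cov`` their per-entry
    Monte-Carlo standard errors; reproducible given ``seed``.
    """

    mean: np.ndarray
    cov: np.ndarray
    se_mean: np.ndarray
    se_cov: np.ndarray
    n_draws: int
    seed: int
    alpha: float

    def corr(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.cov))
        return self.cov / np.outer(sd, sd)


def mc_truncated_mvn(
    mean,
    cov,
    alpha: float,
    n_draws: int = 10_000_000,
    seed: int | None = None,
    method: str = "conditional",
    batch: int = 2_000_000,
) -> MCOracleResult:
    """Monte-Carlo moments of an MVN conditional on its first coordinate's upper tail.

    The first coordinate is the selection variable X and must have unit variance.
    Sampling draws X from its truncated marginal by inverse-CDF on the tail and
    the remaining coordinates from their Gaussian conditional -- never rejection,
    which is infeasible for small participation rates.  ``method="rejection"`` is
    accepted only for ``alpha >= 0.2`` and is intended for cross-checks.

    Parameters
    ----------
    mean, cov : array-like
        Unconditional mean vector and covariance matrix; ``cov[0, 0]`` must be 1.
    alpha : float
        Participation rate (upper-tail mass).
    n_draws : int
        Total Monte-Carlo draws.
    seed : int
        Mandatory RNG seed (reproducibility contract).
    """
    if seed is None:
        raise ValueError("a seed is mandatory for the Monte-Carlo oracle")
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    k = mean.shape[0]
    if cov.shape != (k, k):
        raise ValueError("mean/cov shape mismatch")
    if abs(cov[0, 0] - 1.0) > 1e-12 or abs(mean[0]) > 1e-12:
        raise ValueError(
            "the selection coordinate X (index 0) must be standard normal "
            "(mean 0, unit variance)"
        )
    consts = selection_constants(alpha)
    if method == "rejection" and alpha < 0.2:
        raise ValueError(
            "rejection sampling is infeasible for alpha < 0.2; "
            "use the conditional sampling path (method='conditional')"
        )
    rng = np.random.default_rng(seed)

    if k > 1:
        s_rx = cov[1:, 0]  # Cov(rest, X); Var(X) = 1
        schur = cov[1:, 1:] - np.outer(s_rx, s_rx)
        # guard tiny negative eigenvalues from degenerate configurations
        w, v = np.linalg.eigh(schur)
        w = np.clip(w, 0.0, None)
        chol_like = v * np.sqrt(w)

    sum1 = np.zeros(k)
    sum_op = np.zeros((k, k))  # sum of centered outer products (two-pass via shift)
    sum_op2 = np.zeros((k, k))  # sum of squared products, for MC SEs
    shift = mean.copy()  # fixed shift point for numerically stable accumulation
    total = 0
    while total < n_draws:
        nb = min(batch, n_draws - total)
        if method == "rejection":
            z = rng.standard_normal((nb, k)) @ np.linalg.cholesky(cov).T + mean
            keep = z[:, 0] > consts.t_alpha
            draws = z[keep]
        else:
            u = 1.0 - rng.random(nb)  # in (0, 1]: keeps the ndtri argument below 1
            x = ndtri(1.0 - alpha * u)  # X | X > t_alpha, exact inverse-CDF on the tail
            if k > 1:
                rest = (
                    mean[1:]
                    + np.outer(x - mean[0], s_rx)
                    + rng.standard_normal((nb, k - 1)) @ chol_like.T
                )
                draws = np.column_stack([x, rest])
            else:
                draws = x[:, None]
        d = draws - shift
        sum1 += d.sum(axis=0)
        op = d.T @ d
        sum_op += op
        sum_op2 += np.einsum("ni,nj->ij", d * d, d * d)
        total += len(draws)
    n = total
    m_hat = shift + sum1 / n
    dm = m_hat - shift
    cov_hat = sum_op / n - np.outer(dm, dm)
    # SE of means
    var_diag = np.clip(np.diag(cov_hat), 0.0, None)
    se_mean = np.sqrt(var_diag / n)
    # SE of covariance entries: sd of centered products / sqrt(n)
    mean_op = sum_op / n
    var_op = sum_op2 / n - mean_op**2
    se_cov = np.sqrt(np.clip(var_op, 0.0, None) / n)
    return MCOracleResult(
        mean=m_hat,
        cov=cov_hat,
        se_mean=se_mean,
        se_cov=se_cov,
        n_draws=n,
        seed=seed,
        alpha=alpha,
    )
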
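"""Minimal LD-score regression: SNP heritability and genetic correlation.

Implements the two regressions the adjustment consumes:

* heritability: E[chi2_j] = intercept + (N * h2 / M) * l_j, fitted by weighted
  least squares on per-SNP chi-square statistics against LD scores;
* genetic correlation: E[z1_j * z2_j] = intercept + (sqrt(N1*N2) * rho_G / M) * l_j,
  with the intercept optionally fixed to 0 (the participation-phenotype
  convention when the two GWAS share no samples).

Weights follow common LDSC practice -- an overcounting factor 1/l_j times a
heteroscedasticity factor 1/E[chi2_j]^2 (or its bivariate analogue) -- with the
heteroscedasticity part updated in a fixed two-step iteration for determinism.
Standard errors and the leave-one-block-out series consumed by the
participation-bias adjustment come from a block jackknife over contiguous SNP
blocks in the supplied (genomic) order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("partbias.ldsc")

__all__ = [
    "LdscFit",
    "RgFit",
    "h2_regression",
    "rg_regression",
    "block_jackknife",
    "align_sumstats",
]

_WEIGHT_ITERATIONS = 2  # fixed, for determinism


@dataclass
class LdscFit:
    """Heritability fit with jackknife leave-one-block-out series."""

    h2: float
    intercept: float
    se: float
    delete_values: np.ndarray  # leave-one-block-out h2 estimates
    n_blocks: int
    flags: list

    @property
    def blocks(self) -> np.ndarray:
        return self.delete_values


@dataclass
class RgFit:
    """Genetic-correlation fit with aligned jackknife series."""

    gcov: float
    rg: float
    intercept: float
    se_rg: float
    delete_gcov: np.ndarray
    delete_rg: np.ndarray
    n_blocks: int
    n_dropped: int
    flags: list


def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous block boundaries; remainder spread over the first blocks."""
    if n_blocks < 2 or n_blocks > n:
        raise ValueError(f"n_blocks must be in [2, {n}], got {n_blocks}")
    sizes = np.full(n_blocks, n // n_blocks)
    sizes[: n % n_blocks] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


def block_jackknife(values_per_snp, n_blocks: int) -> tuple[float, float, np.ndarray]:
    """Delete-one-block jackknife of a per-SNP mean statistic.

    Returns the full-data mean, its jackknife SE, and the leave-one-block-out
    series (in block order) for downstream pseudovalue processing.
    """
    v = np.asarray(values_per_snp, dtype=float)
    bounds = _block_bounds(len(v), n_blocks)
    total, n = v.sum(), len(v)
    full = total / n
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        loo[b] = (total - v[lo:hi].sum()) / (n - (hi - lo))
    # jackknife SE from pseudovalues
    p = n_blocks * full - (n_blocks - 1) * loo
    se = math.sqrt(p.var(ddof=1) / n_blocks)
    return full, se, loo


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, fit_intercept: bool):
    """Weighted least squares returning (slope, intercept)."""
    if fit_intercept:
        X = np.column_stack([x, np.ones_like(x)])
    else:
        X = x[:, None]
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    xty = Xw.T @ y
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular LDSC design (need >= 2 distinct LD scores)") from e
    return (beta[0], beta[1]) if fit_intercept else (beta[0], 0.0)


def _wls_jackknife(x, y, w, fit_intercept, n_blocks):
    """Slope/intercept on full data plus leave-one-block-out slope series.

    Delete-block fits reuse the full-data weights (standard LDSC practice)
    and are computed from per-block sufficient statistics.
    """
    X = np.column_stack([x, np.ones_like(x)]) if fit_intercept else x[:, None]
    Xw = X * w[:, None]
    bounds = _block_bounds(len(x), n_blocks)
    k = X.shape[1]
    xtx_b = np.empty((n_blocks, k, k))
    xty_b = np.empty((n_blocks, k))
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        xtx_b[b] = X[lo:hi].T @ Xw[lo:hi]
        xty_b[b] = Xw[lo:hi].T @ y[lo:hi]
    xtx = xtx_b.sum(axis=0)
    xty = xty_b.sum(axis=0)
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular LDSC design (need >= 2 distinct LD scores)") from e
    loo_slope = np.empty(n_blocks)
    for b in range(n_blocks):
        bb = np.linalg.solve(xtx - xtx_b[b], xty - xty_b[b])
        loo_slope[b] = bb[0]
    intercept = beta[1] if fit_intercept else 0.0
    return beta[0], intercept, loo_slope


def _check_tables(sumstats: pd.DataFrame, ldscores: pd.DataFrame) -> pd.DataFrame:
    need = {"SNP", "N", "Z"}
    if not need.issubset(sumstats.columns):
        raise ValueError(f"sumstats table missing columns {need - set(sumstats.columns)}")
    if not {"SNP", "L2"}.issubset(ldscores.columns):
        raise ValueError("LD score table must have columns SNP, L2")
    merged = sumstats.merge(ldscores[["SNP", "L2"]], on="SNP", how="inner")
    if len(merged) == 0:
        raise ValueError("no SNPs shared between sumstats and LD scores")
    if len(merged) < len(sumstats):
        logger.warning("dropped %d sumstats SNPs without LD scores",
                       len(sumstats) - len(merged))
    return merged


def h2_regression(
    sumstats: pd.DataFrame,
    ldscores: pd.DataFrame,
    m_total: int | None = None,
    intercept_free: bool = True,
    n_blocks: int = 200,
) -> LdscFit:
    """SNP heritability by LD-score regression on chi-square statistics.

    Parameters
    ----------
    sumstats : DataFrame with columns SNP, N, Z (A1/A2 optional here).
    ldscores : DataFrame with columns SNP, L2.
    m_total : total number of SNPs the LD scores sum over; defaults to the
        number of regression SNPs.
    intercept_free : fit the intercept (the convention for phenotype
        heritability, absorbing relatedness/stratification); when False the
        intercept is fixed at 1.
    """
    d = _check_tables(sumstats, ldscores)
    m = int(m_total) if m_total is not None else len(d)
    ell = d["L2"].to_numpy(dtype=float)
    n_eff = d["N"].to_numpy(dtype=float)
    chi2 = d["Z"].to_numpy(dtype=float) ** 2
    n_bar = n_eff.mean()
    x = ell * n_eff / m  # slope coefficient is h2 directly
    y = chi2 if intercept_free else chi2 - 1.0

    w_l = 1.0 / np.maximum(ell, 1.0)
    h2 = 0.0
    for _ in range(_WEIGHT_ITERATIONS):
        het = 1.0 + n_bar * max(h2, 0.0) * ell / m
        w = w_l / het**2
        slope, intercept = _wls(x, y, w, intercept_free)
        h2 = slope
    slope, intercept, loo = _wls_jackknife(x, y, w, intercept_free, n_blocks)
    h2 = slope
    if not intercept_free:
        intercept = 1.0
    p = n_blocks * h2 - (n_blocks - 1) * loo
    se = math.sqrt(p.var(ddof=1) / n_blocks)
    flags = []
    if h2 <= 0.0:
        flags.append("nonpositive_h2")
    return LdscFit(h2=h2, intercept=intercept, se=se, delete_values=loo,
                   n_blocks=n_blocks, flags=flags)


def align_sumstats(s1: pd.DataFrame, s2: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Join two sumstats tables on SNP, aligning alleles.

    A SNP whose alleles are swapped between tables has its second z negated;
    a SNP with irreconcilable alleles is dropped.  Returns the merged table
    (columns Z1, Z2, N1, N2) and the number of dropped SNPs; more than 10%
    dropped is an error.
    """
    m = s1.merge(s2, on="SNP", suffixes=("_1", "_2"))
    if "A1_1" in m.columns and "A1_2" in m.columns:
        same = (m["A1_1"] == m["A1_2"]) & (m["A2_1"] == m["A2_2"])
        flipped = (m["A1_1"] == m["A2_2"]) & (m["A2_1"] == m["A1_2"])
        z2 = np.where(flipped, -m["Z_2"].to_numpy(float), m["Z_2"].to_numpy(float))
        keep = (same | flipped).to_numpy()
        n_dropped = int((~keep).sum())
        if n_dropped > 0.1 * len(m):
            raise ValueError(
                f"{n_dropped}/{len(m)} SNPs have irreconcilable alleles"
            )
        if n_dropped:
            logger.warning("dropped %d SNPs with irreconcilable alleles", n_dropped)
        out = pd.DataFrame({
            "SNP": m["SNP"], "Z1": m["Z_1"], "Z2": z2,
            "N1": m["N_1"], "N2": m["N_2"],
        })[keep]
    else:
        n_dropped = 0
        out = pd.DataFrame({
            "SNP": m["SNP"], "Z1": m["Z_1"], "Z2": m["Z_2"],
            "N1": m["N_1"], "N2": m["N_2"],
        })
    return out.reset_index(drop=True), n_dropped


def rg_regression(
    sumstats_1: pd.DataFrame,
    sumstats_2: pd.DataFrame,
    ldscores: pd.DataFrame,
    m_total: int | None = None,
    intercept_zero: bool = False,
    n_blocks: int = 200,
    h2_1: LdscFit | None = None,
    h2_2: LdscFit | None = None,
) -> RgFit:
    """Genetic correlation by cross-trait LD-score regression.

    ``intercept_zero=True`` fixes the cross intercept at 0 (used for the
    participation-phenotype correlation, where the two GWAS share no samples).
    The per-trait heritabilities entering rg are estimated here (free
    intercept) unless prefitted ``h2_1``/``h2_2`` are supplied; their jackknife
    series share this function's SNP blocks, so the delete-one-block rg series
    is internally consistent.
    """
    aligned, n_dropped = align_sumstats(sumstats_1, sumstats_2)
    both = aligned.merge(ldscores[["SNP", "L2"]], on="SNP", how="inner")
    m = int(m_total) if m_total is not None else len(both)
    ell = both["L2"].to_numpy(float)
    z1, z2 = both["Z1"].to_numpy(float), both["Z2"].to_numpy(float)
    n1, n2 = both["N1"].to_numpy(float), both["N2"].to_numpy(float)
    y = z1 * z2
    x = np.sqrt(n1 * n2) * ell / m  # slope is the genetic covariance

    if h2_1 is None:
        h2_1 = h2_regression(sumstats_1, ldscores, m_total=m, n_blocks=n_blocks)
    if h2_2 is None:
        h2_2 = h2_regression(sumstats_2, ldscores, m_total=m, n_blocks=n_blocks)

    n1b, n2b = n1.mean(), n2.mean()
    w_l = 1.0 / np.maximum(ell, 1.0)
    gcov, icpt = 0.0, 0.0
    for _ in range(_WEIGHT_ITERATIONS):
        v1 = 1.0 + n1b * max(h2_1.h2, 0.0) * ell / m
        v2 = 1.0 + n2b * max(h2_2.h2, 0.0) * ell / m
        cross = math.sqrt(n1b * n2b) * gcov * ell / m + icpt
        w = w_l / (v1 * v2 + cross**2)
        gcov, icpt = _wls(x, y, w, fit_intercept=not intercept_zero)
    gcov, icpt, loo_gcov = _wls_jackknife(x, y, w, not intercept_zero, n_blocks)

    flags = []
    denom = h2_1.h2 * h2_2.h2
    if denom <= 0.0:
        # noisy heritability fit went nonpositive; rg is undefined, not fatal
        flags.append("nonpositive_h2_denominator")
        rg = math.nan
        loo_rg = np.full(n_blocks, math.nan)
        se_rg = math.nan
    else:
        rg = gcov / math.sqrt(denom)
        loo_rg = loo_gcov / np.sqrt(np.clip(h2_1.delete_values * h2_2.delete_values,
                                            1e-12, None))
        if abs(rg) > 1.0:
            flags.append("rg_out_of_range")
        p = n_blocks * rg - (n_blocks - 1) * loo_rg
        se_rg = math.sqrt(p.var(ddof=1) / n_blocks)
    return RgFit(gcov=gcov, rg=rg, intercept=icpt, se_rg=se_rg,
                 delete_gcov=loo_gcov, delete_rg=loo_rg,
                 n_blocks=n_blocks, n_dropped=n_dropped, flags=flags)
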
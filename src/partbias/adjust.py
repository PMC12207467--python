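"""Adjustment of participant-sample estimates back to population scale.

Given (i) LDSC-style estimates computed in the selected sample (heritability
``hy2_hat``, genetic correlation with participation ``rho_g_hat``, optionally a
cross-phenotype genetic correlation ``phi_g_hat``), (ii) the population-scale
SNP heritability of the participation liability ``hx2_hat`` (an external input,
e.g. from an IBD-based participation GWAS), (iii) the participation rate
``alpha``, and (iv) the standardized phenotype mean shift ``delta_hat`` between
participants and a population-representative cohort, this module recovers
population-scale heritability and genetic correlations.

The chain is the exact algebraic inverse of the forward bias expressions:
round-tripping forward -> adjust reproduces the population parameters to
floating-point precision.  Standard errors come from a block jackknife applied
to pseudovalues of the full adjustment chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, norm

from .trunc import SelectionConstants, rho_from_mean_shift, selection_constants

__all__ = [
    "RawEstimates",
    "AdjustedEstimates",
    "raw_genetic_covariance",
    "adjusted_genetic_covariance",
    "adjusted_h2",
    "adjusted_rg_participation",
    "adjusted_rho_e",
    "adjusted_rg_two_phenotypes",
    "adjust_single",
    "adjust_pair",
    "jackknife_adjust",
    "compute_mean_shift",
]


# ---------------------------------------------------------------------------
# elementary steps of the chain
# ---------------------------------------------------------------------------

def raw_genetic_covariance(
    rho_g_hat: float, hx2_hat: float, hy2_hat: float, constants: SelectionConstants
) -> float:
    """Apparent genetic covariance of X and Y from the apparent correlation.

    rho_G_hat = rho_g_hat * sqrt((1 - xi*hx2_hat) * hx2_hat * hy2_hat).
    """
    if hx2_hat <= 0.0 or hy2_hat <= 0.0:
        raise ValueError("heritabilities must be positive to form a genetic covariance")
    return rho_g_hat * math.sqrt((1.0 - constants.xi * hx2_hat) * hx2_hat * hy2_hat)


def adjusted_genetic_covariance(
    rho_G_hat: float, rho_hat: float, hx2_hat: float, constants: SelectionConstants
) -> float:
    """Population-scale genetic covariance of X and Y.

    rho_G_tilde = sqrt(1 - xi*rho_hat^2) * rho_G_hat + xi * rho_hat * hx2_hat:
    the first term undoes the selected-sample standardization of Y, the second
    restores the covariance removed by collider selection.
    """
    if abs(rho_hat) >= 1.0:
        raise ValueError("|rho_hat| must be < 1")
    xi = constants.xi
    return math.sqrt(1.0 - xi * rho_hat**2) * rho_G_hat + xi * rho_hat * hx2_hat


def adjusted_h2(
    hy2_hat: float,
    rho_hat: float,
    rho_G_tilde: float,
    hx2_hat: float,
    constants: SelectionConstants,
) -> float:
    """Population-scale heritability of Y (exact inverse of the apparent form).

    Out-of-[0,1] results are returned raw; flagging happens at the
    :func:`adjust_single` level so that jackknife pseudovalues stay linear.
    """
    xi = constants.xi
    out = (
        hy2_hat * (1.0 - xi * rho_hat**2)
        + 2.0 * xi * rho_hat * rho_G_tilde
        - xi**2 * rho_hat**2 * hx2_hat
    )
    if hx2_hat > 0.0 or xi > 0.0:
        out -= (xi / (1.0 - xi * hx2_hat)) * (rho_G_tilde - xi * rho_hat * hx2_hat) ** 2
    return out


def adjusted_rg_participation(
    rho_G_tilde: float, hx2_hat: float, hy2_tilde: float
) -> float:
    """Population-scale genetic correlation of participation and the phenotype."""
    if hx2_hat <= 0.0 or hy2_tilde <= 0.0:
        raise ValueError("degenerate heritability in adjusted genetic correlation")
    return rho_G_tilde / math.sqrt(hx2_hat * hy2_tilde)


def adjusted_rho_e(
    rho_hat: float, rho_g_tilde: float, hx2_hat: float, hy2_tilde: float
) -> float:
    """Nongenetic correlation implied by the composition rho = rho_G + rho_E."""
    if hx2_hat >= 1.0 or hy2_tilde >= 1.0:
        raise ValueError("nongenetic correlation undefined for fully heritable traits")
    num = rho_hat - rho_g_tilde * math.sqrt(hx2_hat * hy2_tilde)
    return num / math.sqrt((1.0 - hx2_hat) * (1.0 - hy2_tilde))


def adjusted_rg_two_phenotypes(
    phi_g_hat: float,
    hy2_hat_1: float,
    hy2_hat_2: float,
    rho_hat_1: float,
    rho_hat_2: float,
    rho_G_tilde_1: float,
    rho_G_tilde_2: float,
    hy2_tilde_1: float,
    hy2_tilde_2: float,
    hx2_hat: float,
    constants: SelectionConstants,
) -> tuple[float, float]:
    """Population-scale cross-phenotype genetic covariance and correlation.

    Solves the apparent cross-phenotype correlation for the population genetic
    covariance phi_G.  The participation genetic covariances entering the
    cross terms are the *adjusted* (population-scale) ones, which makes the
    map the exact algebraic inverse of the forward expression.
    """
    xi = constants.xi
    phi_G_hat = phi_g_hat * math.sqrt(hy2_hat_1 * hy2_hat_2)
    phi_G = (
        math.sqrt((1.0 - xi * rho_hat_1**2) * (1.0 - xi * rho_hat_2**2)) * phi_G_hat
        + xi * (rho_hat_1 * rho_G_tilde_2 + rho_hat_2 * rho_G_tilde_1)
        - xi**2 * rho_hat_1 * rho_hat_2 * hx2_hat
        - (xi / (1.0 - xi * hx2_hat))
        * (rho_G_tilde_1 - xi * rho_hat_1 * hx2_hat)
        * (rho_G_tilde_2 - xi * rho_hat_2 * hx2_hat)
    )
    if hy2_tilde_1 <= 0.0 or hy2_tilde_2 <= 0.0:
        raise ValueError("degenerate adjusted heritability in cross-phenotype step")
    phi_g = phi_G / math.sqrt(hy2_tilde_1 * hy2_tilde_2)
    return phi_G, phi_g


# ---------------------------------------------------------------------------
# full chains
# ---------------------------------------------------------------------------

def adjust_single(
    hy2_hat: float,
    rho_g_hat: float,
    hx2_hat: float,
    delta_hat: float,
    alpha: float,
    hx2_scale: float = 1.0,
) -> dict:
    """Full adjustment chain for one phenotype.

    Parameters
    ----------
    hy2_hat : float
        LDSC heritability of the phenotype in the selected sample.
    rho_g_hat : float
        LDSC genetic correlation of the phenotype with participation
        (participation statistics on the population scale, intercept fixed to 0).
    hx2_hat : float
        Population-scale SNP heritability of the participation liability.
    delta_hat : float
        Mean shift (participants minus population, standardized by the
        participant-sample SD).
    alpha : float
        Participation rate.
    hx2_scale : float
        Sensitivity multiplier on ``hx2_hat`` (default 1.0) covering
        invitation-stage bias scenarios, e.g. 0.75.

    Returns
    -------
    dict
        All intermediates (``xi``, ``rho_hat``, ``rho_G_hat``, ``rho_G_tilde``)
        and the adjusted values ``hy2_tilde``, ``rho_g_tilde``, ``rho_e_tilde``,
        plus out-of-range ``flags`` (values are never silently clamped).
    """
    c = selection_constants(alpha)
    hx2 = hx2_hat * hx2_scale
    rho_hat = rho_from_mean_shift(delta_hat, c)
    rho_G_hat = raw_genetic_covariance(rho_g_hat, hx2, hy2_hat, c)
    rho_G_tilde = adjusted_genetic_covariance(rho_G_hat, rho_hat, hx2, c)
    hy2_tilde = adjusted_h2(hy2_hat, rho_hat, rho_G_tilde, hx2, c)
    flags: list[str] = []
    if not (0.0 <= hy2_tilde <= 1.0):
        flags.append("hy2_tilde_out_of_range")
    if hy2_tilde > 0.0:
        rho_g_tilde = adjusted_rg_participation(rho_G_tilde, hx2, hy2_tilde)
    else:
        rho_g_tilde = math.nan
        flags.append("rho_g_tilde_undefined")
    if abs(rho_g_tilde) > 1.0:
        flags.append("rho_g_tilde_out_of_range")
    if hx2 < 1.0 and 0.0 < hy2_tilde < 1.0:
        rho_e_tilde = adjusted_rho_e(rho_hat, rho_g_tilde, hx2, hy2_tilde)
        if abs(rho_e_tilde) > 1.0:
            flags.append("rho_e_tilde_out_of_range")
    else:
        rho_e_tilde = math.nan
        flags.append("rho_e_tilde_undefined")
    return {
        "xi": c.xi,
        "rho_hat": rho_hat,
        "rho_G_hat": rho_G_hat,
        "rho_G_tilde": rho_G_tilde,
        "hy2_tilde": hy2_tilde,
        "rho_g_tilde": rho_g_tilde,
        "rho_e_tilde": rho_e_tilde,
        "flags": flags,
    }


def adjust_pair(
    hy2_hat_1: float,
    hy2_hat_2: float,
    rho_g_hat_1: float,
    rho_g_hat_2: float,
    delta_hat_1: float,
    delta_hat_2: float,
    phi_g_hat: float,
    hx2_hat: float,
    alpha: float,
    hx2_scale: float = 1.0,
) -> dict:
    """Full adjustment chain for a pair of phenotypes (cross genetic correlation).

    The phenotypic correlations with participation are recomputed internally
    from the two mean shifts, keeping one canonical path.
    """
    c = selection_constants(alpha)
    one = adjust_single(hy2_hat_1, rho_g_hat_1, hx2_hat, delta_hat_1, alpha, hx2_scale)
    two = adjust_single(hy2_hat_2, rho_g_hat_2, hx2_hat, delta_hat_2, alpha, hx2_scale)
    hx2 = hx2_hat * hx2_scale
    phi_G_tilde, phi_g_tilde = adjusted_rg_two_phenotypes(
        phi_g_hat,
        hy2_hat_1,
        hy2_hat_2,
        one["rho_hat"],
        two["rho_hat"],
        one["rho_G_tilde"],
        two["rho_G_tilde"],
        one["hy2_tilde"],
        two["hy2_tilde"],
        hx2,
        c,
    )
    flags = [f + "_y1" for f in one["flags"]] + [f + "_y2" for f in two["flags"]]
    if abs(phi_g_tilde) > 1.0:
        flags.append("phi_g_tilde_out_of_range")
    return {
        "y1": one,
        "y2": two,
        "phi_G_tilde": phi_G_tilde,
        "phi_g_tilde": phi_g_tilde,
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# estimates containers and jackknife
# ---------------------------------------------------------------------------

@dataclass
class RawEstimates:
    """Participant-sample (biased) estimates plus aligned jackknife series.

    ``jackknife`` maps a quantity name (``"hy2_hat"``, ``"rho_g_hat"``, ...)
    to its length-B leave-one-block-out series.  Heritability estimates may
    fall outside [0, 1] from sampling noise and are stored raw.
    """

    hy2_hat: float
    rho_g_hat: float
    hx2_hat: float
    delta_hat: float
    alpha: float
    phi_g_hat: float | None = None
    hy2_hat_2: float | None = None
    rho_g_hat_2: float | None = None
    delta_hat_2: float | None = None
    jackknife: dict = field(default_factory=dict)

    def n_blocks(self) -> int:
        lengths = {len(v) for v in self.jackknife.values()}
        if len(lengths) > 1:
            raise ValueError(f"jackknife series lengths disagree: {sorted(lengths)}")
        return lengths.pop() if lengths else 0


@dataclass
class AdjustedEstimates:
    """Population-scale outputs with block-jackknife standard errors."""

    hy2_tilde: float
    rho_g_tilde: float
    rho_e_tilde: float
    rho_hat: float
    se_hy2_tilde: float = math.nan
    se_rho_g_tilde: float = math.nan
    se_rho_e_tilde: float = math.nan
    phi_g_tilde: float | None = None
    se_phi_g_tilde: float = math.nan
    flags: list = field(default_factory=list)


def _pseudovalue_stats(full: float, loo: np.ndarray) -> tuple[float, float]:
    """Point estimate and SE from jackknife pseudovalues.

    p_b = B*theta_full - (B-1)*theta_(-b); estimate = mean(p),
    SE = sqrt(Var(p)/B) with the unbiased variance.
    """
    loo = np.asarray(loo, dtype=float)
    B = len(loo)
    p = B * full - (B - 1) * loo
    return float(p.mean()), float(math.sqrt(p.var(ddof=1) / B))


def jackknife_adjust(raw: RawEstimates, hx2_scale: float = 1.0) -> AdjustedEstimates:
    """Apply the full adjustment chain to jackknife pseudovalues.

    For each leave-one-block-out replicate the complete chain is recomputed;
    pseudovalues of the adjusted quantities then give point estimates and SEs.
    Quantities without a jackknife series (e.g. ``delta_hat`` measured from
    cohort means) are held at their full-data values in every replicate.
    """
    B = raw.n_blocks()
    if B < 2:
        raise ValueError("need at least 2 jackknife blocks")

    def series(name: str, fallback: float) -> np.ndarray:
        if name in raw.jackknife:
            s = np.asarray(raw.jackknife[name], dtype=float)
            if len(s) != B:
                raise ValueError(f"jackknife series {name!r} has length {len(s)} != {B}")
            return s
        return np.full(B, fallback)

    nan_single = {"hy2_tilde": math.nan, "rho_g_tilde": math.nan,
                  "rho_e_tilde": math.nan, "rho_hat": math.nan,
                  "flags": ["chain_domain_error"]}

    def safe_single(*args):
        try:
            return adjust_single(*args, hx2_scale=hx2_scale)
        except ValueError:
            return dict(nan_single)

    def safe_pair(*args):
        try:
            return adjust_pair(*args, hx2_scale=hx2_scale)
        except ValueError:
            return {"phi_g_tilde": math.nan, "flags": ["chain_domain_error"]}

    pair = raw.phi_g_hat is not None
    full = safe_single(raw.hy2_hat, raw.rho_g_hat, raw.hx2_hat, raw.delta_hat,
                       raw.alpha)
    flags = list(full["flags"])

    hy2_s = series("hy2_hat", raw.hy2_hat)
    rg_s = series("rho_g_hat", raw.rho_g_hat)
    hx2_s = series("hx2_hat", raw.hx2_hat)
    d_s = series("delta_hat", raw.delta_hat)
    loo = {"hy2_tilde": [], "rho_g_tilde": [], "rho_e_tilde": []}
    if pair:
        full_pair = safe_pair(
            raw.hy2_hat, raw.hy2_hat_2, raw.rho_g_hat, raw.rho_g_hat_2,
            raw.delta_hat, raw.delta_hat_2, raw.phi_g_hat, raw.hx2_hat,
            raw.alpha,
        )
        flags += [f for f in full_pair["flags"] if f not in flags]
        hy2b_s = series("hy2_hat_2", raw.hy2_hat_2)
        rgb_s = series("rho_g_hat_2", raw.rho_g_hat_2)
        db_s = series("delta_hat_2", raw.delta_hat_2)
        phig_s = series("phi_g_hat", raw.phi_g_hat)
        loo["phi_g_tilde"] = []
    for b in range(B):
        one = safe_single(hy2_s[b], rg_s[b], hx2_s[b], d_s[b], raw.alpha)
        loo["hy2_tilde"].append(one["hy2_tilde"])
        loo["rho_g_tilde"].append(one["rho_g_tilde"])
        loo["rho_e_tilde"].append(one["rho_e_tilde"])
        if pair:
            pr = safe_pair(hy2_s[b], hy2b_s[b], rg_s[b], rgb_s[b], d_s[b], db_s[b],
                           phig_s[b], hx2_s[b], raw.alpha)
            loo["phi_g_tilde"].append(pr["phi_g_tilde"])

    est_h, se_h = _pseudovalue_stats(full["hy2_tilde"], np.array(loo["hy2_tilde"]))
    est_rg, se_rg = _pseudovalue_stats(full["rho_g_tilde"], np.array(loo["rho_g_tilde"]))
    est_re, se_re = _pseudovalue_stats(full["rho_e_tilde"], np.array(loo["rho_e_tilde"]))
    out = AdjustedEstimates(
        hy2_tilde=est_h, rho_g_tilde=est_rg, rho_e_tilde=est_re,
        rho_hat=full["rho_hat"],
        se_hy2_tilde=se_h, se_rho_g_tilde=se_rg, se_rho_e_tilde=se_re,
        flags=flags,
    )
    if pair:
        est_p, se_p = _pseudovalue_stats(full_pair["phi_g_tilde"],
                                         np.array(loo["phi_g_tilde"]))
        out.phi_g_tilde = est_p
        out.se_phi_g_tilde = se_p
    return out


# ---------------------------------------------------------------------------
# mean shift from individual-level phenotypes
# ---------------------------------------------------------------------------

def _rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset 3/8)."""
    n = len(values)
    r = rankdata(values, method="average")
    return norm.ppf((r - 0.375) / (n + 0.25))


def _residualize(y: np.ndarray, x: np.ndarray | None, coefs: np.ndarray) -> np.ndarray:
    design = np.ones((len(y), 1)) if x is None else np.column_stack([np.ones(len(y)), x])
    return y - design @ coefs


def compute_mean_shift(
    sample_y,
    reference_y,
    sample_covariates=None,
    reference_covariates=None,
    inverse_normal: bool = False,
    sample_strata=None,
    reference_strata=None,
) -> float:
    """Standardized mean shift of a phenotype between participants and population.

    Pipeline: optional rank-based inverse-normal transform applied to the two
    cohorts *pooled* (per stratum when strata are given, e.g. sex) so that the
    location difference survives the transform; covariate model fitted on the
    reference cohort and applied to both; then

        delta_hat = (mean_sample - mean_reference) / SD_sample.

    Because ranks are taken on the pooled data, applying any strictly monotone
    transform to the raw values beforehand leaves the result unchanged.
    """
    ys = np.asarray(sample_y, dtype=float)
    yr = np.asarray(reference_y, dtype=float)
    if len(ys) == 0 or len(yr) == 0:
        raise ValueError("both cohorts must be nonempty")
    if inverse_normal:
        pooled = np.concatenate([ys, yr])
        if sample_strata is None:
            pooled = _rank_inverse_normal(pooled)
        else:
            strata = np.concatenate(
                [np.asarray(sample_strata), np.asarray(reference_strata)]
            )
            pooled = pooled.copy()
            for s in np.unique(strata):
                m = strata == s
                pooled[m] = _rank_inverse_normal(pooled[m])
        ys, yr = pooled[: len(ys)], pooled[len(ys):]
    xs = None if sample_covariates is None else np.atleast_2d(
        np.asarray(sample_covariates, dtype=float).reshape(len(ys), -1))
    xr = None if reference_covariates is None else np.atleast_2d(
        np.asarray(reference_covariates, dtype=float).reshape(len(yr), -1))
    design_r = np.ones((len(yr), 1)) if xr is None else np.column_stack(
        [np.ones(len(yr)), xr])
    coefs, _, rank, _ = np.linalg.lstsq(design_r, yr, rcond=None)
    if rank < design_r.shape[1]:
        raise ValueError("reference covariate design matrix is rank deficient")
    res_r = yr - design_r @ coefs
    res_s = _residualize(ys, xs, coefs)
    sd_s = res_s.std(ddof=1)
    if sd_s == 0.0:
        raise ValueError("sample residual SD is zero; mean shift undefined")
    return float((res_s.mean() - res_r.mean()) / sd_s)
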
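"""Closed-form "apparent" (participant-sample) heritability and genetic correlations.

The population model for participation liability X and a phenotype Y is

    X = Gx + eps_x,    Y = Gy + eps_y,

with Var(Gx) = hx2, Var(Gy) = hy2, genetic correlation rho_g = Corr(Gx, Gy) and
nongenetic correlation rho_e = Corr(eps_x, eps_y).  Decomposing
Gy = a*Gx + Gw and eps_y = b*eps_x + eps_w (Gw, eps_w orthogonal to X), selection
on X > t_alpha shrinks the variance of Gx and eps_x and makes them negatively
correlated (collider bias), which distorts what heritability and genetic-
correlation estimators target in the selected sample.

Every closed form here has a constructive twin (``*_constructive``) built purely
from the Pearson-Lawley operator :func:`partbias.trunc.selected_cov`; the two are
required to agree to numerical precision, which pins down the term grouping of
the apparent-heritability and apparent-correlation expressions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .trunc import SelectionConstants, selected_cov, selection_constants

__all__ = [
    "ModelParams",
    "DecompositionCoefficients",
    "BiasedMoments",
    "decompose",
    "compose_rho",
    "apparent_h2",
    "apparent_h2_constructive",
    "apparent_rg_participation",
    "apparent_rg_participation_constructive",
    "apparent_rg_two_phenotypes",
    "apparent_rg_two_phenotypes_constructive",
    "biased_moments",
]


@dataclass(frozen=True)
class ModelParams:
    """Population-scale parameters of one phenotype-participation system.

    Attributes
    ----------
    hx2 : float
        Heritability of the participation liability, in [0, 1].
    hy2 : float
        Heritability of the phenotype, in [0, 1].
    rho_g : float
        Genetic correlation Corr(Gx, Gy), in [-1, 1].
    rho_e : float
        Nongenetic correlation Corr(eps_x, eps_y), in [-1, 1].
    alpha : float
        Participation rate, in (0, 1].
    """

    hx2: float
    hy2: float
    rho_g: float
    rho_e: float
    alpha: float

    def __post_init__(self):
        for name in ("hx2", "hy2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("rho_g", "rho_e"):
            v = getattr(self, name)
            if not (-1.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [-1, 1], got {v}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        rho = self.rho_G + self.rho_E
        if abs(rho) > 1.0 + 1e-12:
            raise ValueError(
                f"implied phenotypic correlation rho = {rho:.6f} outside [-1, 1]"
            )

    @property
    def rho_G(self) -> float:
        """Genetic covariance Cov(Gx, Gy) = rho_g * sqrt(hx2 * hy2)."""
        return self.rho_g * math.sqrt(self.hx2 * self.hy2)

    @property
    def rho_E(self) -> float:
        """Nongenetic covariance Cov(eps_x, eps_y)."""
        return self.rho_e * math.sqrt((1.0 - self.hx2) * (1.0 - self.hy2))

    def constants(self) -> SelectionConstants:
        return selection_constants(self.alpha)


@dataclass(frozen=True)
class DecompositionCoefficients:
    """Loadings of the Gy = a*Gx + Gw and eps_y = b*eps_x + eps_w decomposition.

    ``a_prime`` is the selected-sample regression loading of Gx in the genetic
    component (a' < a when rho_g, rho_e > 0, because the collider-induced
    negative correlation between Gx and eps_x is absorbed into the genetic
    component).
    """

    a: float
    b: float
    var_gw: float
    var_ew: float
    a_prime: float


@dataclass(frozen=True)
class BiasedMoments:
    """Apparent (participant-sample) quantities for one phenotype."""

    hy_pb2: float
    rho_g_pb: float
    var_y_sel: float
    clamped: bool = False


def compose_rho(params: ModelParams) -> float:
    """Phenotypic correlation rho = rho_G + rho_E between X and Y."""
    rho = params.rho_G + params.rho_E
    if abs(rho) > 1.0 + 1e-12:
        raise ValueError(f"composed rho = {rho} outside [-1, 1]")
    return rho


def decompose(params: ModelParams) -> DecompositionCoefficients:
    """Decomposition loadings a, b and the orthogonal variances, plus a'.

    Requires hx2 > 0 when rho_g != 0 (a genetic correlation with a
    nonheritable liability is contradictory) and hx2 < 1 when rho_e != 0.
    """
    p = params
    if p.hx2 == 0.0 and p.rho_g != 0.0:
        raise ValueError("genetic correlation with a nonheritable liability (hx2 = 0)")
    if p.hx2 == 1.0 and p.rho_e != 0.0:
        raise ValueError("nongenetic correlation with a fully heritable liability (hx2 = 1)")
    a = 0.0 if p.rho_g == 0.0 else p.rho_g * math.sqrt(p.hy2 / p.hx2)
    b = 0.0 if p.rho_e == 0.0 else p.rho_e * math.sqrt((1.0 - p.hy2) / (1.0 - p.hx2))
    var_gw = (1.0 - p.rho_g**2) * p.hy2
    var_ew = (1.0 - p.rho_e**2) * (1.0 - p.hy2)
    c = p.constants()
    rho = compose_rho(p)
    if p.hx2 == 0.0:
        a_prime = 0.0
    else:
        # regression loading of Gx in the selected sample:
        # Cov(Y, Gx | sel) / Var(Gx | sel)
        a_prime = (p.rho_G - c.xi * rho * p.hx2) / (p.hx2 * (1.0 - c.xi * p.hx2))
    return DecompositionCoefficients(a=a, b=b, var_gw=var_gw, var_ew=var_ew, a_prime=a_prime)


def apparent_h2(params: ModelParams) -> float:
    """Apparent heritability of Y in the selected sample (closed form).

    hy_pb2 = [hy2 - xi*rho_G*(rho_G + 2*rho_E) + xi^2*hx2*rho_E^2/(1 - xi*hx2)]
             / (1 - xi*rho^2),

    whose denominator is the variance of Y after selection.  The grouping --
    (1 - xi*hx2) divides only the xi^2 term -- is certified by equality with
    :func:`apparent_h2_constructive`.
    """
    p = params
    c = p.constants()
    xi = c.xi
    rho = compose_rho(p)
    rG, rE = p.rho_G, p.rho_E
    num = p.hy2 - xi * rG * (rG + 2.0 * rE)
    if p.hx2 > 0.0:
        num += xi**2 * p.hx2 * rE**2 / (1.0 - xi * p.hx2)
    return num / (1.0 - xi * rho**2)


def apparent_h2_constructive(params: ModelParams) -> float:
    """Apparent heritability rebuilt from the Pearson-Lawley operator.

    Projects Y onto the (post-selection still orthogonal) pair (Gx, Gw) using
    selected covariances only; serves as the independent cross-check for the
    closed form.
    """
    p = params
    c = p.constants()
    rho = compose_rho(p)
    var_gw = (1.0 - p.rho_g**2) * p.hy2
    var_y_sel = selected_cov(1.0, rho, rho, c)
    num = 0.0
    if p.hx2 > 0.0:
        cov_y_gx = selected_cov(p.rho_G, rho, p.hx2, c)
        var_gx = selected_cov(p.hx2, p.hx2, p.hx2, c)
        num += cov_y_gx**2 / var_gx
    if var_gw > 0.0:
        cov_y_gw = selected_cov(var_gw, rho, 0.0, c)  # Cov(Y, Gw) = Var(Gw)
        num += cov_y_gw**2 / var_gw
    return num / var_y_sel


def apparent_rg_participation(params: ModelParams) -> float:
    """Apparent genetic correlation between participation and the phenotype.

    rho_g_pb = (rho_G - xi*hx2*rho) /
               sqrt((1 - xi*rho^2) * (1 - xi*hx2) * hx2 * hy_pb2).

    With rho_g = 0 but rho != 0 this is nonzero with sign opposite to rho:
    pure collider bias.
    """
    p = params
    if p.hx2 <= 0.0:
        raise ValueError("hx2 must be positive for a participation genetic correlation")
    c = p.constants()
    rho = compose_rho(p)
    h2pb = apparent_h2(p)
    if h2pb <= 0.0:
        raise ValueError("degenerate phenotype: apparent heritability is zero")
    num = p.rho_G - c.xi * p.hx2 * rho
    den = math.sqrt((1.0 - c.xi * rho**2) * (1.0 - c.xi * p.hx2) * p.hx2 * h2pb)
    return num / den


def apparent_rg_participation_constructive(params: ModelParams) -> float:
    """Corr(Gx, Gy' | selection) built from selected covariances only."""
    p = params
    c = p.constants()
    rho = compose_rho(p)
    var_gx_sel = selected_cov(p.hx2, p.hx2, p.hx2, c)
    cov_y_gx_sel = selected_cov(p.rho_G, rho, p.hx2, c)
    a_prime = cov_y_gx_sel / var_gx_sel
    var_gw = (1.0 - p.rho_g**2) * p.hy2
    var_gy_sel = a_prime**2 * var_gx_sel + var_gw
    return a_prime * var_gx_sel / math.sqrt(var_gx_sel * var_gy_sel)


def apparent_rg_two_phenotypes(
    params_y1: ModelParams, params_y2: ModelParams, phi_g: float
) -> float:
    """Apparent genetic correlation between two phenotypes in the selected sample.

    Both phenotypes must share the participation system (same alpha and hx2).
    ``phi_g`` is the population genetic correlation of Y1 and Y2.
    """
    p1, p2 = params_y1, params_y2
    if p1.alpha != p2.alpha or p1.hx2 != p2.hx2:
        raise ValueError("both phenotypes must share alpha and hx2")
    if not (-1.0 <= phi_g <= 1.0):
        raise ValueError("phi_g must be in [-1, 1]")
    c = p1.constants()
    xi = c.xi
    hx2 = p1.hx2
    rG1, rE1, rho1 = p1.rho_G, p1.rho_E, compose_rho(p1)
    rG2, rE2, rho2 = p2.rho_G, p2.rho_E, compose_rho(p2)
    phi_G = phi_g * math.sqrt(p1.hy2 * p2.hy2)
    num = phi_G - xi * (rE1 * rG2 + rE2 * rG1 + rG1 * rG2)
    if hx2 > 0.0:
        num += xi**2 * hx2 * rE1 * rE2 / (1.0 - xi * hx2)
    h2pb1, h2pb2 = apparent_h2(p1), apparent_h2(p2)
    den = math.sqrt(
        (1.0 - xi * rho1**2) * (1.0 - xi * rho2**2) * h2pb1 * h2pb2
    )
    return num / den


def apparent_rg_two_phenotypes_constructive(
    params_y1: ModelParams, params_y2: ModelParams, phi_g: float
) -> float:
    """Corr(Gy1', Gy2' | selection) via the a' decomposition and selected_cov."""
    p1, p2 = params_y1, params_y2
    if p1.alpha != p2.alpha or p1.hx2 != p2.hx2:
        raise ValueError("both phenotypes must share alpha and hx2")
    c = p1.constants()
    hx2 = p1.hx2
    phi_G = phi_g * math.sqrt(p1.hy2 * p2.hy2)
    var_gx_sel = selected_cov(hx2, hx2, hx2, c)
    ap = []
    for p in (p1, p2):
        rho = compose_rho(p)
        ap.append(selected_cov(p.rho_G, rho, hx2, c) / var_gx_sel)
    # Cov(Gw1, Gw2) = phi_G - rho_G1*rho_G2/hx2, unchanged by selection
    cov_gw = phi_G - (p1.rho_G * p2.rho_G / hx2 if hx2 > 0 else 0.0)
    num = ap[0] * ap[1] * var_gx_sel + cov_gw
    v1 = ap[0] ** 2 * var_gx_sel + (1.0 - p1.rho_g**2) * p1.hy2
    v2 = ap[1] ** 2 * var_gx_sel + (1.0 - p2.rho_g**2) * p2.hy2
    return num / math.sqrt(v1 * v2)


def biased_moments(params: ModelParams) -> BiasedMoments:
    """Bundle of apparent quantities; hy_pb2 clamped to [0, 1] only for reporting."""
    rho = compose_rho(params)
    c = params.constants()
    raw = apparent_h2(params)
    clamped = not (0.0 <= raw <= 1.0)
    return BiasedMoments(
        hy_pb2=min(max(raw, 0.0), 1.0) if clamped else raw,
        rho_g_pb=apparent_rg_participation(params),
        var_y_sel=1.0 - c.xi * rho**2,
        clamped=clamped,
    )
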
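"""Synthetic GWAS engine for participation-bias experiments.

Emulates the validation design: genotypes in 50-SNP LD blocks with AR(1)
correlation (block correlation and allele frequency drawn from Unif(0.1, 0.9)),
10% causal SNPs with multivariate-normal effect sizes, liability construction
X = G beta + eps_x / Y_k = G gamma_k + eps_yk, threshold selection of the top
alpha of the participation liability, per-SNP GWAS, and an oracle participation
GWAS (regression of the latent liability on dosages in a population cohort)
standing in for IBD-based participation statistics.

``run_experiment`` chains simulate -> GWAS -> LD-score regression -> mean shift
-> adjustment and reports per-replicate raw and adjusted estimates.  For large
cohorts it generates genotypes only at causal sites for the full invited cohort
(exact Markov skip-sampling) and completes participants' genotypes by Markov
bridges, so memory stays modest at biobank-like sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import multivariate_normal

from . import markov
from .adjust import adjust_pair, adjust_single, compute_mean_shift
from .ldsc import h2_regression, rg_regression
from .trunc import selection_constants

__all__ = [
    "LDBlockSpec",
    "EffectSizes",
    "SimCohort",
    "SimConfig",
    "make_ld_blocks",
    "true_ld_scores",
    "sample_genotypes",
    "sample_effects",
    "calibrate_sib_env",
    "sample_cohort",
    "gwas",
    "participation_oracle_gwas",
    "run_experiment",
]


@dataclass(frozen=True)
class LDBlockSpec:
    """One LD block: contiguous SNPs with AR(1) correlation rho_l^|i-j|."""

    block_index: int
    start: int
    p_l: int
    rho_l: float
    freqs: np.ndarray  # per-SNP allele frequencies (constant by default)

    @property
    def stop(self) -> int:
        return self.start + self.p_l

    @property
    def homogeneous(self) -> bool:
        return float(np.ptp(self.freqs)) == 0.0


@dataclass
class EffectSizes:
    """Per-SNP causal effects on the participation liability and phenotype(s).

    ``beta[:, 0]`` is the effect on X; remaining columns on Y1 (, Y2).  Effects
    act on population-standardized dosages; nonzero only on ``causal_idx``.
    """

    beta: np.ndarray          # (m, 1 + n_phenotypes)
    causal_idx: np.ndarray
    causal_fraction: float

    @property
    def causal_mask(self) -> np.ndarray:
        mask = np.zeros(self.beta.shape[0], dtype=bool)
        mask[self.causal_idx] = True
        return mask


@dataclass
class SimCohort:
    """A simulated cohort with liabilities and participation indicator."""

    genotypes: np.ndarray | None  # (n, m) int8 dosages, None in causal-only mode
    x_liability: np.ndarray
    y_phenotypes: np.ndarray      # (n, n_phenotypes)
    participated: np.ndarray
    specs: list
    effects: EffectSizes
    alpha: float
    sib_x_liability: np.ndarray | None = None  # co-sib liability (sib-pair mode)


@dataclass
class SimConfig:
    """Study conditions for one experiment.

    Defaults reproduce the validation design at desk scale: 10,000 SNPs in
    50-SNP blocks, 10% causal, participation heritability 0.125, participation
    rate 0.055, two phenotypes with heritabilities (0.5, 0.2), each with
    genetic/nongenetic participation correlations 0.25/0.5, cross-phenotype
    genetic correlation 0.5.  ``n_individuals`` = 550,000 invited yields about
    30,000 participants (the full-scale design of 5e6 sibling pairs is exposed by
    raising it; expect proportional memory/time).
    """

    n_individuals: int = 550_000
    n_oracle: int = 100_000
    m_snps: int = 10_000
    block_size: int = 50
    causal_fraction: float = 0.10
    hx2: float = 0.125
    hy2: tuple = (0.5, 0.2)
    rho_g: tuple = (0.25, 0.25)
    rho_e: tuple = (0.5, 0.5)
    phi_g: float = 0.5
    phi_e: float | None = None   # default: rho_e1 * rho_e2 (eps_w1 _|_ eps_w2)
    alpha: float = 0.055
    lambda_s: float = 2.0
    sib_pairs: bool = False
    n_ldsc_blocks: int = 200
    seed: int = 0

    def __post_init__(self):
        for name in ("hy2", "rho_g", "rho_e"):
            v = getattr(self, name)
            if isinstance(v, (int, float)):
                setattr(self, name, (float(v),))
            else:
                setattr(self, name, tuple(float(x) for x in v))
        k = len(self.hy2)
        if not (len(self.rho_g) == len(self.rho_e) == k):
            raise ValueError("hy2, rho_g, rho_e must have matching lengths")
        if k not in (1, 2):
            raise ValueError("one or two phenotypes are supported")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    @property
    def n_phenotypes(self) -> int:
        return len(self.hy2)


# ---------------------------------------------------------------------------
# LD blocks and genotypes
# ---------------------------------------------------------------------------

def make_ld_blocks(m_snps: int, block_size: int = 50, seed=None) -> list:
    """Draw LD-block specifications: rho_l ~ U(0.1, 0.9), freq ~ U(0.1, 0.9).

    One allele frequency is drawn per block (shared by its SNPs), which keeps
    every AR(1) correlation target feasible for binary data.  A trailing block
    shorter than ``block_size`` is allowed.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    specs = []
    start = 0
    idx = 0
    while start < m_snps:
        p = min(block_size, m_snps - start)
        rho = rng.uniform(0.1, 0.9)
        f = rng.uniform(0.1, 0.9)
        specs.append(LDBlockSpec(block_index=idx, start=start, p_l=p, rho_l=rho,
                                 freqs=np.full(p, f)))
        start += p
        idx += 1
    return specs


def true_ld_scores(specs: list) -> np.ndarray:
    """Population LD scores l_j = sum_k rho_l^(2|j-k|) within each block."""
    m = specs[-1].stop
    ell = np.empty(m)
    for sp in specs:
        r2 = sp.rho_l**2
        powers = r2 ** np.abs(np.subtract.outer(np.arange(sp.p_l), np.arange(sp.p_l)))
        ell[sp.start:sp.stop] = powers.sum(axis=1)
    return ell


def sample_genotypes(specs: list, n: int, rng) -> np.ndarray:
    """Full (n, m) int8 dosage matrix, block by block.

    Stored SNP-major internally (the returned array is a transpose view), so
    per-SNP operations on ``G.T`` touch contiguous memory.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = specs[-1].stop
    Gm = np.empty((m, n), dtype=np.int8)
    for sp in specs:
        try:
            markov.sample_block(sp.freqs, sp.rho_l, n, rng, out=Gm[sp.start:sp.stop])
        except ValueError as e:
            raise ValueError(f"block {sp.block_index}: {e}") from e
    return Gm.T


def _standardize(G: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Population-frequency standardization of dosages (known truth in simulation)."""
    mu = 2.0 * freqs
    sd = np.sqrt(2.0 * freqs * (1.0 - freqs))
    return (G.astype(np.float32) - mu.astype(np.float32)) / sd.astype(np.float32)


def _dosage_scores(Gm: np.ndarray, freqs: np.ndarray, beta: np.ndarray,
                   chunk: int = 256) -> np.ndarray:
    """Standardized-genotype scores, SNP-major input.

    ``Gm`` is (n_snps, n) int8; returns (n, n_traits) float equal to
    ``standardized(Gm).T @ beta`` without materializing the standardized
    matrix (chunked float32 slabs).
    """
    sd = np.sqrt(2.0 * freqs * (1.0 - freqs))
    b = (beta.T / sd).astype(np.float32)            # (traits, snps), 1/sd folded in
    out = np.full((beta.shape[1], Gm.shape[1]),
                  (-(2.0 * freqs / sd) @ beta)[:, None], dtype=np.float32)
    n = Gm.shape[1]
    col = max(1, int(2e7 // max(chunk, 1)))  # bound the float32 slab to ~80 MB
    for lo in range(0, Gm.shape[0], chunk):
        hi = min(lo + chunk, Gm.shape[0])
        for c0 in range(0, n, col):
            c1 = min(c0 + col, n)
            out[:, c0:c1] += b[:, lo:hi] @ Gm[lo:hi, c0:c1].astype(np.float32)
    return out.T.astype(np.float64)


def block_freqs(specs: list) -> np.ndarray:
    return np.concatenate([sp.freqs for sp in specs])


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def sample_effects(
    m: int,
    causal_fraction: float,
    variances,
    corr,
    rng,
) -> EffectSizes:
    """Multivariate-normal effect sizes on a random causal subset.

    ``variances`` are the target heritabilities (hx2, hy2, ...); each causal
    SNP's effect has variance h2 / m_causal so the genetic variances hit their
    targets on standardized genotypes.  ``corr`` is the effect correlation
    matrix (participation first); must be positive semidefinite.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    variances = np.asarray(variances, dtype=float)
    k = len(variances)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise ValueError("corr shape must match number of traits")
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-10:
        raise ValueError("effect correlation matrix is not positive semidefinite")
    m_causal = int(round(m * causal_fraction))
    causal_idx = np.sort(rng.choice(m, size=m_causal, replace=False))
    sd = np.sqrt(variances / m_causal)
    cov = corr * np.outer(sd, sd)
    chol_w, chol_v = np.linalg.eigh(cov)
    L = chol_v * np.sqrt(np.clip(chol_w, 0, None))
    beta = np.zeros((m, k))
    beta[causal_idx] = rng.standard_normal((m_causal, k)) @ L.T
    return EffectSizes(beta=beta, causal_idx=causal_idx, causal_fraction=causal_fraction)


def _effect_corr(config: SimConfig) -> np.ndarray:
    """Correlation matrix of (beta_x, gamma_1[, gamma_2])."""
    k = config.n_phenotypes
    C = np.eye(1 + k)
    for i in range(k):
        C[0, 1 + i] = C[1 + i, 0] = config.rho_g[i]
    if k == 2:
        C[1, 2] = C[2, 1] = config.phi_g
    return C


def _residual_corr(config: SimConfig) -> np.ndarray:
    k = config.n_phenotypes
    C = np.eye(1 + k)
    for i in range(k):
        C[0, 1 + i] = C[1 + i, 0] = config.rho_e[i]
    if k == 2:
        phi_e = config.phi_e
        if phi_e is None:
            phi_e = config.rho_e[0] * config.rho_e[1]
        C[1, 2] = C[2, 1] = phi_e
    return C


def _residual_draw(config: SimConfig, n: int, rng) -> np.ndarray:
    """(n, 1+k) residuals with variances (1-hx2, 1-hy2...) and the model correlations."""
    C = _residual_corr(config)
    sd = np.sqrt(np.concatenate([[1.0 - config.hx2], 1.0 - np.asarray(config.hy2)]))
    cov = C * np.outer(sd, sd)
    w, v = np.linalg.eigh(cov)
    L = v * np.sqrt(np.clip(w, 0, None))
    return rng.standard_normal((n, L.shape[0])).astype(np.float64) @ L.T


# ---------------------------------------------------------------------------
# sibling recurrence calibration
# ---------------------------------------------------------------------------

def sib_recurrence(r: float, alpha: float) -> float:
    """lambda_s implied by sibling liability correlation r: P(X2>t | X1>t)/alpha."""
    t = selection_constants(alpha).t_alpha
    if r >= 1.0:
        return 1.0 / alpha
    # upper orthant by central symmetry
    p_both = multivariate_normal(cov=[[1.0, r], [r, 1.0]]).cdf([-t, -t])
    return p_both / alpha**2


def calibrate_sib_env(alpha: float, lambda_s: float, hx2: float) -> float:
    """Shared-environment variance c2 giving sibling recurrence risk lambda_s.

    Sibling liabilities are bivariate normal with correlation
    r = 0.5*hx2 + c2 (half the genetic variance is shared, plus a shared
    nongenetic component).  Solves P(X_sib > t | X > t) = lambda_s * alpha for
    r, then c2 = r - 0.5*hx2.  Raises if the target is infeasible (requires
    r > 1) or would need c2 < 0.
    """
    if lambda_s * alpha > 1.0:
        raise ValueError("lambda_s * alpha cannot exceed 1")
    lo, hi = sib_recurrence(0.0, alpha), sib_recurrence(0.999999, alpha)
    if not (lo <= lambda_s <= hi):
        raise ValueError(
            f"lambda_s = {lambda_s} outside achievable range [{lo:.4f}, {hi:.4f}]"
        )
    r = brentq(lambda rr: sib_recurrence(rr, alpha) - lambda_s, 0.0, 0.999999,
               xtol=1e-10)
    c2 = r - 0.5 * hx2
    if c2 < 0.0:
        raise ValueError(
            f"infeasible shared environment: required sibling correlation {r:.4f} "
            f"is below the genetic floor 0.5*hx2 = {0.5 * hx2:.4f}"
        )
    return c2


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _liabilities(G: np.ndarray, specs: list, effects: EffectSizes,
                 residuals: np.ndarray) -> np.ndarray:
    """(n, 1+k) liabilities from full genotypes: standardized G @ beta + residuals."""
    freqs = block_freqs(specs)
    ci = effects.causal_idx
    scores = _dosage_scores(G.T[ci], freqs[ci], effects.beta[ci])
    return scores + residuals


def sample_cohort(config: SimConfig, rng=None, effects: EffectSizes | None = None,
                  specs: list | None = None) -> SimCohort:
    """Simulate a cohort with full genotypes held in memory.

    Suitable for small-to-moderate n*m; :func:`run_experiment` uses a
    memory-light path for biobank-scale runs.  In sib-pair mode
    (``config.sib_pairs``) genotypes are built by per-block Mendelian
    transmission from simulated parental haplotypes, nongenetic liabilities
    share a calibrated component, and only the first sib of each pair is
    returned as the cohort (with the co-sib's liability retained for
    recurrence checks).
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    if specs is None:
        specs = make_ld_blocks(config.m_snps, config.block_size, rng)
    if effects is None:
        effects = sample_effects(
            config.m_snps, config.causal_fraction,
            np.concatenate([[config.hx2], config.hy2]),
            _effect_corr(config), rng,
        )
    n = config.n_individuals
    t_alpha = selection_constants(config.alpha).t_alpha
    if not config.sib_pairs:
        G = sample_genotypes(specs, n, rng)
        liab = _liabilities(G, specs, effects, _residual_draw(config, n, rng))
        x = liab[:, 0]
        return SimCohort(
            genotypes=G, x_liability=x, y_phenotypes=liab[:, 1:],
            participated=x > t_alpha, specs=specs, effects=effects,
            alpha=config.alpha,
        )
    # sib-pair mode
    c2 = calibrate_sib_env(config.alpha, config.lambda_s, config.hx2)
    G1, G2 = _sample_sib_genotypes(specs, n, rng)
    res1 = _residual_draw(config, n, rng)
    res2 = _residual_draw(config, n, rng)
    # carve the shared component out of eps_x while keeping Var(eps_x) = 1-hx2
    var_ex = 1.0 - config.hx2
    w_shared = math.sqrt(c2 / var_ex)
    w_unique = math.sqrt(1.0 - c2 / var_ex)
    shared = rng.standard_normal(n) * math.sqrt(var_ex)
    res1[:, 0] = w_shared * shared + w_unique * res1[:, 0]
    res2[:, 0] = w_shared * shared + w_unique * res2[:, 0]
    liab1 = _liabilities(G1, specs, effects, res1)
    liab2 = _liabilities(G2, specs, effects, res2)
    x1 = liab1[:, 0]
    return SimCohort(
        genotypes=G1, x_liability=x1, y_phenotypes=liab1[:, 1:],
        participated=x1 > t_alpha, specs=specs, effects=effects,
        alpha=config.alpha, sib_x_liability=liab2[:, 0],
    )


def _sample_sib_genotypes(specs: list, n_pairs: int, rng):
    """Two sibling genotype matrices sharing parental haplotypes per block."""
    m = specs[-1].stop
    G1 = np.empty((m, n_pairs), dtype=np.int8)
    G2 = np.empty((m, n_pairs), dtype=np.int8)
    for sp in specs:
        if not sp.homogeneous:
            raise ValueError("sib-pair transmission requires homogeneous blocks")
        f, r, p = float(sp.freqs[0]), sp.rho_l, sp.p_l
        # four parental haplotype chains (binary) per block, SNP-major
        haps = np.empty((4, p, n_pairs), dtype=np.int8)
        q0, q1 = np.float32(f * (1 - r)), np.float32(f + r * (1 - f))
        for h in range(4):
            s = (rng.random(n_pairs, dtype=np.float32) < f).astype(np.int8)
            haps[h, 0] = s
            for j in range(1, p):
                u = rng.random(n_pairs, dtype=np.float32)
                thr = np.where(s == 1, q1, q0)
                s = (u < thr).astype(np.int8)
                haps[h, j] = s
        for G in (G1, G2):
            pick_m = rng.integers(0, 2, n_pairs)
            pick_p = rng.integers(0, 2, n_pairs)
            mat = np.where(pick_m[None, :] == 0, haps[0], haps[1])
            pat = np.where(pick_p[None, :] == 0, haps[2], haps[3])
            G[sp.start:sp.stop] = mat + pat
    return G1.T, G2.T


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def snp_ids(m: int) -> np.ndarray:
    return np.array([f"snp{j:06d}" for j in range(m)])


def gwas(genotypes: np.ndarray, phenotype: np.ndarray, subset=None,
         chunk: int | None = None) -> pd.DataFrame:
    """Per-SNP simple linear regression z-statistics.

    Returns an LDSC-style table (SNP, A1, A2, N, Z).  Monomorphic SNPs in the
    subset get z = 0.  Genotypes are sample-centered; z is computed from the
    sample correlation r as z = r * sqrt((n-2) / (1-r^2)).
    """
    if subset is not None:
        genotypes = genotypes[subset]
        phenotype = np.asarray(phenotype)[subset]
    n, m = genotypes.shape
    if n == 0:
        raise ValueError("empty subset")
    if chunk is None:
        chunk = max(8, int(2e7 // max(n, 1)))  # ~80 MB float32 slab
    # work SNP-major; free when genotypes came from sample_genotypes
    Gm = genotypes.T
    if not Gm.flags.c_contiguous:
        Gm = np.ascontiguousarray(Gm)
    y = np.asarray(phenotype, dtype=np.float64)
    yc = (y - y.mean()).astype(np.float32)
    ss_y = float(np.dot(yc.astype(np.float64), yc.astype(np.float64)))
    yc_sum = float(yc.sum())
    z = np.empty(m)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        g = Gm[lo:hi].astype(np.float32)
        gs = g.sum(axis=1, dtype=np.float64)
        gm = gs / n
        num = g @ yc - gm * yc_sum
        ss_g = np.einsum("ij,ij->i", g, g, dtype=np.float64) - n * gm**2
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / np.sqrt(ss_g * ss_y)
            r = np.clip(r, -0.999999, 0.999999)
            zz = r * np.sqrt((n - 2) / (1.0 - r**2))
        zz[ss_g <= 0] = 0.0
        z[lo:hi] = zz
    return pd.DataFrame({
        "SNP": snp_ids(m), "A1": "A", "A2": "G",
        "N": np.full(m, n, dtype=np.int64), "Z": z,
    })


def participation_oracle_gwas(cohort: SimCohort) -> pd.DataFrame:
    """Population-scale participation GWAS oracle.

    Regresses the latent participation liability X on dosages in the full
    (pre-selection) cohort -- an oracle for what IBD-based sib-pair contrasts
    estimate without nonparticipant genotypes.  The output is tagged with
    ``table.attrs['oracle'] = True``.
    """
    if cohort.x_liability is None:
        raise ValueError("cohort does not retain the latent liability X")
    if cohort.genotypes is None:
        raise ValueError("cohort does not retain genotypes")
    out = gwas(cohort.genotypes, cohort.x_liability)
    out.attrs["oracle"] = True
    return out


# ---------------------------------------------------------------------------
# experiment loop (memory-light at scale)
# ---------------------------------------------------------------------------

def _simulate_replicate(config: SimConfig, specs: list, ell: np.ndarray,
                        rng: np.random.Generator) -> dict:
    """One replicate: simulate, GWAS, LDSC, mean shift, adjust."""
    k = config.n_phenotypes
    m = config.m_snps
    effects = sample_effects(
        m, config.causal_fraction,
        np.concatenate([[config.hx2], config.hy2]),
        _effect_corr(config), rng,
    )
    ci = effects.causal_idx
    freqs = block_freqs(specs)
    t_alpha = selection_constants(config.alpha).t_alpha
    ld_table = pd.DataFrame({"SNP": snp_ids(m), "L2": ell})

    # --- invited cohort: causal-only genotypes (exact skip-sampling, SNP-major) ---
    n = config.n_individuals
    causal_by_block = []
    Gc = np.empty((len(ci), n), dtype=np.int8)
    row = 0
    for sp in specs:
        local = ci[(ci >= sp.start) & (ci < sp.stop)] - sp.start
        causal_by_block.append(local)
        if len(local):
            Gc[row:row + len(local)] = markov.sample_block_skip(
                float(sp.freqs[0]), sp.rho_l, local, n, rng)
            row += len(local)
    residuals = _residual_draw(config, n, rng)
    liab = _dosage_scores(Gc, freqs[ci], effects.beta[ci]) + residuals
    x = liab[:, 0]
    part = x > t_alpha
    n_part = int(part.sum())

    # mean shifts: participants vs full invited cohort, sample-SD standardized
    deltas = [compute_mean_shift(liab[part, 1 + i], liab[:, 1 + i])
              for i in range(k)]

    # --- participants: complete genotypes by Markov bridges (SNP-major) ---
    Gc_part = np.ascontiguousarray(Gc[:, part])
    del Gc
    Gp = np.empty((m, n_part), dtype=np.int8)
    row = 0
    for sp, local in zip(specs, causal_by_block):
        if len(local):
            Gp[sp.start:sp.stop] = markov.fill_block_conditional(
                float(sp.freqs[0]), sp.rho_l, sp.p_l, local,
                Gc_part[row:row + len(local)], rng)
            row += len(local)
        else:
            markov.sample_block(sp.freqs, sp.rho_l, n_part, rng,
                                out=Gp[sp.start:sp.stop])
    del Gc_part

    y_stats = [gwas(Gp.T, liab[part, 1 + i]) for i in range(k)]
    del Gp

    # --- fresh population cohort for the participation oracle GWAS ---
    Go = sample_genotypes(specs, config.n_oracle, rng)
    res_o = rng.standard_normal(config.n_oracle) * math.sqrt(1.0 - config.hx2)
    x_o = _dosage_scores(Go.T[ci], freqs[ci], effects.beta[ci, :1])[:, 0] + res_o
    x_stats = gwas(Go, x_o)
    del Go

    # --- LD-score regressions ---
    nb = config.n_ldsc_blocks
    hx2_fit = h2_regression(x_stats, ld_table, m_total=m, n_blocks=nb)
    hy2_fits = [h2_regression(s, ld_table, m_total=m, n_blocks=nb) for s in y_stats]
    rg_fits = [rg_regression(x_stats, s, ld_table, m_total=m, intercept_zero=True,
                             n_blocks=nb, h2_1=hx2_fit, h2_2=hy2_fits[i])
               for i, s in enumerate(y_stats)]

    nan_adj = {"hy2_tilde": math.nan, "rho_g_tilde": math.nan,
               "rho_e_tilde": math.nan}
    out = {"n_participants": n_part, "hx2_hat": hx2_fit.h2}
    for i in range(k):
        try:
            adj = adjust_single(hy2_fits[i].h2, rg_fits[i].rg, hx2_fit.h2,
                                deltas[i], config.alpha)
        except ValueError:  # degenerate small-scale fit; keep raw values
            adj = nan_adj
        out[f"hy2_hat_{i + 1}"] = hy2_fits[i].h2
        out[f"rho_g_hat_{i + 1}"] = rg_fits[i].rg
        out[f"delta_hat_{i + 1}"] = deltas[i]
        out[f"hy2_tilde_{i + 1}"] = adj["hy2_tilde"]
        out[f"rho_g_tilde_{i + 1}"] = adj["rho_g_tilde"]
        out[f"rho_e_tilde_{i + 1}"] = adj["rho_e_tilde"]
    if k == 2:
        phi_fit = rg_regression(y_stats[0], y_stats[1], ld_table, m_total=m,
                                intercept_zero=False, n_blocks=nb,
                                h2_1=hy2_fits[0], h2_2=hy2_fits[1])
        try:
            pair = adjust_pair(hy2_fits[0].h2, hy2_fits[1].h2,
                               rg_fits[0].rg, rg_fits[1].rg,
                               deltas[0], deltas[1], phi_fit.rg, hx2_fit.h2,
                               config.alpha)
            phi_tilde = pair["phi_g_tilde"]
        except ValueError:
            phi_tilde = math.nan
        out["phi_g_hat"] = phi_fit.rg
        out["phi_g_tilde"] = phi_tilde
    out["_tables"] = {"participation": x_stats, "ldscores": ld_table,
                      **{f"y{i + 1}": s for i, s in enumerate(y_stats)}}
    return out


def run_experiment(config: SimConfig, n_replicates: int = 20,
                   seed: int | None = None, progress: bool = False,
                   keep_tables: bool = False):
    """Replicated simulate -> GWAS -> LDSC -> mean-shift -> adjust pipeline.

    Returns a per-replicate table of raw and adjusted estimates; column means
    are the quantities compared against the closed-form expectations.  LD
    blocks are redrawn each replicate (as are effects, genotypes and
    residuals); all randomness flows from ``seed`` (default ``config.seed``).
    With ``keep_tables=True`` returns ``(table, tables)`` where ``tables``
    holds the final replicate's summary-statistic and LD-score tables.
    """
    base = np.random.default_rng(seed if seed is not None else config.seed)
    rows = []
    tables = None
    for rep in range(n_replicates):
        rng = np.random.default_rng(base.integers(0, 2**31 - 1))
        specs = make_ld_blocks(config.m_snps, config.block_size, rng)
        ell = true_ld_scores(specs)
        row = _simulate_replicate(config, specs, ell, rng)
        tables = row.pop("_tables")
        row["replicate"] = rep
        rows.append(row)
        if progress:
            print(f"replicate {rep + 1}/{n_replicates}: "
                  + ", ".join(f"{k2}={v:.4g}" for k2, v in row.items()
                              if isinstance(v, float)))
    df = pd.DataFrame(rows)
    return (df, tables) if keep_tables else df
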
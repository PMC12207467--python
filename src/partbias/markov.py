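"""Stationary Markov-chain samplers for LD-blocked binary haplotypes.

Within an LD block, haplotype alleles form a stationary two-state Markov chain
with stationary frequency f and lag-1 correlation rho; because a binary chain
has linear autoregression, the lag-k correlation is exactly rho**k, i.e. the
AR(1) block correlation matrix is reproduced exactly.  A genotype is the sum
of two independent haplotype chains, which (by exchangeability) is itself a
Markov chain on {0, 1, 2} -- so genotype dosages can be sampled directly,
site by site, with one uniform variate per entry.

Three samplers are provided:

* :func:`sample_block` -- full sequential generation of a block;
* :func:`sample_block_skip` -- exact marginal generation at a subset of
  positions using lag-k transitions (the subchain of a Markov chain is Markov);
* :func:`fill_block_conditional` -- exact conditional generation of the
  remaining positions given realized values at the subset (Markov bridges).

Skip + fill is distributionally identical to full generation; it lets a large
cohort carry genotypes only at causal sites while any sub-cohort (e.g. the
participants) is completed to all sites afterwards.

All samplers use a SNP-major layout (one contiguous row per site) so the
site-by-site writes stay cache-friendly at biobank-scale n.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "hap_transition",
    "geno_transition",
    "geno_stationary",
    "sample_block",
    "sample_block_skip",
    "fill_block_conditional",
]


def hap_transition(f: float, rho: float, k: int = 1) -> np.ndarray:
    """k-step haplotype transition matrix T[h, h'] (lag-k correlation rho**k)."""
    rk = rho**k
    q0 = f * (1.0 - rk)          # P(1 | 0)
    q1 = f + rk * (1.0 - f)      # P(1 | 1)
    return np.array([[1.0 - q0, q0], [1.0 - q1, q1]])


def geno_stationary(f: float) -> np.ndarray:
    """Hardy-Weinberg stationary distribution of the genotype chain."""
    return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f**2])


def geno_transition(f: float, rho: float, k: int = 1) -> np.ndarray:
    """k-step genotype transition matrix M[s, s'] on dosage states {0, 1, 2}."""
    H = hap_transition(f, rho, k)
    return _convolve_pair(H[0, 1], H[1, 1])


def _convolve_pair(q0: float, q1: float) -> np.ndarray:
    """Genotype transition from haplotype success probabilities (per prev state)."""
    M = np.empty((3, 3))
    for s in range(3):
        pa = q1 if s >= 1 else q0
        pb = q1 if s >= 2 else q0
        M[s, 0] = (1.0 - pa) * (1.0 - pb)
        M[s, 1] = pa * (1.0 - pb) + pb * (1.0 - pa)
        M[s, 2] = pa * pb
    return M


def _draw3(u: np.ndarray, c0, c1) -> np.ndarray:
    """States {0,1,2} from uniforms and cumulative thresholds (arrays or scalars)."""
    return (u > c0).view(np.int8) + (u > c1).view(np.int8)


def _step(prev: np.ndarray, M: np.ndarray, rng) -> np.ndarray:
    C = np.cumsum(M, axis=1).astype(np.float32)
    u = rng.random(prev.shape[0], dtype=np.float32)
    return _draw3(u, np.take(C[:, 0], prev), np.take(C[:, 1], prev))


def _stationary_draw(f: float, n: int, rng) -> np.ndarray:
    pi = np.cumsum(geno_stationary(f)).astype(np.float32)
    u = rng.random(n, dtype=np.float32)
    return _draw3(u, pi[0], pi[1])


def _hetero_transition(f_prev: float, f_cur: float, rho: float) -> np.ndarray:
    """One-step genotype transition for adjacent sites with unequal frequencies.

    The binary chain matches marginals (f_prev, f_cur) and correlation rho;
    raises when the implied haplotype transition leaves [0, 1] (the binary
    correlation bound).
    """
    c = rho * np.sqrt(f_prev * (1 - f_prev) * f_cur * (1 - f_cur))
    q1 = f_cur + c / f_prev
    q0 = f_cur - c / (1.0 - f_prev)
    if not (0.0 <= q0 <= 1.0 and 0.0 <= q1 <= 1.0):
        raise ValueError(
            f"infeasible transition: freqs ({f_prev:.3f} -> {f_cur:.3f}) with "
            f"rho = {rho:.3f} imply haplotype transition probabilities outside [0, 1]"
        )
    return _convolve_pair(q0, q1)


def sample_block(freqs: np.ndarray, rho: float, n: int, rng,
                 out: np.ndarray | None = None) -> np.ndarray:
    """Sample a (p, n) int8 dosage block (SNP-major), site by site.

    ``freqs`` gives the per-site allele frequency; a constant array yields the
    homogeneous stationary chain, otherwise the heterogeneous chain (with
    feasibility checks) is used.
    """
    p = len(freqs)
    G = out if out is not None else np.empty((p, n), dtype=np.int8)
    homogeneous = np.ptp(freqs) == 0.0
    s = _stationary_draw(float(freqs[0]), n, rng)
    G[0] = s
    if homogeneous:
        C = np.cumsum(geno_transition(float(freqs[0]), rho, 1), axis=1).astype(np.float32)
        c0, c1 = C[:, 0], C[:, 1]
        u_all = rng.random((p - 1, n), dtype=np.float32) if p > 1 else None
        for j in range(1, p):
            s = _draw3(u_all[j - 1], np.take(c0, s), np.take(c1, s))
            G[j] = s
    else:
        for j in range(1, p):
            M = _hetero_transition(float(freqs[j - 1]), float(freqs[j]), rho)
            s = _step(s, M, rng)
            G[j] = s
    return G


def sample_block_skip(freq: float, rho: float, positions: np.ndarray, n: int,
                      rng) -> np.ndarray:
    """Sample only the given (sorted) positions of a homogeneous block, exactly.

    Returns a (len(positions), n) int8 array.
    """
    positions = np.asarray(positions)
    k = len(positions)
    S = np.empty((k, n), dtype=np.int8)
    s = _stationary_draw(freq, n, rng)
    S[0] = s
    for t in range(1, k):
        gap = int(positions[t] - positions[t - 1])
        s = _step(s, geno_transition(freq, rho, gap), rng)
        S[t] = s
    return S


def fill_block_conditional(freq: float, rho: float, block_size: int,
                           positions: np.ndarray, values: np.ndarray,
                           rng) -> np.ndarray:
    """Complete a homogeneous block given realized dosages at some positions.

    ``values`` is (len(positions), n).  Exact conditional sampling: positions
    before the first anchor use the time-reversed chain, interior gaps use
    Markov bridges P(s_j | s_{j-1}, s_end), and positions after the last
    anchor run the chain forward.  Returns the full (block_size, n) int8 block.
    """
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=np.int8)
    n = values.shape[1]
    G = np.empty((block_size, n), dtype=np.int8)
    G[positions] = values
    pi = geno_stationary(freq)
    M1 = geno_transition(freq, rho, 1)

    # leading segment, backward: P(prev = c | cur = v) = pi[c] M1[c, v] / pi[v]
    first = int(positions[0])
    if first > 0:
        Bw = pi[:, None] * M1
        Bw /= Bw.sum(axis=0, keepdims=True)
        C = np.cumsum(Bw, axis=0).astype(np.float32)  # cumulate over c, per v
        c0, c1 = np.ascontiguousarray(C[0]), np.ascontiguousarray(C[1])
        s = values[0]
        for j in range(first - 1, -1, -1):
            u = rng.random(n, dtype=np.float32)
            s = _draw3(u, np.take(c0, s), np.take(c1, s))
            G[j] = s

    # interior bridges
    for t in range(len(positions) - 1):
        i, e = int(positions[t]), int(positions[t + 1])
        prev = values[t]
        end = values[t + 1].astype(np.intp)
        for j in range(i + 1, e):
            g = e - j
            Mg = geno_transition(freq, rho, g)
            Mg1 = geno_transition(freq, rho, g + 1)
            # table[v, b, c] = M1[v, c] * Mg[c, b] / Mg1[v, b]
            T = M1[:, None, :] * Mg.T[None, :, :] / Mg1[:, :, None]
            C = np.cumsum(T, axis=2).astype(np.float32)
            idx = prev.astype(np.intp) * 3 + end
            u = rng.random(n, dtype=np.float32)
            prev = _draw3(
                u, np.take(C[:, :, 0].ravel(), idx), np.take(C[:, :, 1].ravel(), idx)
            )
            G[j] = prev

    # trailing segment, forward
    last = int(positions[-1])
    if last < block_size - 1:
        C = np.cumsum(M1, axis=1).astype(np.float32)
        c0, c1 = C[:, 0].copy(), C[:, 1].copy()
        s = values[-1]
        for j in range(last + 1, block_size):
            u = rng.random(n, dtype=np.float32)
            s = _draw3(u, np.take(c0, s), np.take(c1, s))
            G[j] = s
    return G
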
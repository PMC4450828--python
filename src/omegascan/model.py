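"""Goldman–Yang-style codon substitution model.

The instantaneous rate from sense codon *i* to *j* is nonzero only for
single-nucleotide changes:

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

The matrix is reversible with stationary distribution pi, so the
transition probabilities exp(Qt) are computed through a symmetric
eigendecomposition (similarity transform by diag(pi)^{1/2}), which is
both faster and more stable than a general matrix exponential.

Branch lengths are measured in expected substitutions per codon (the
codeml convention); :func:`scale_factor` gives the expected flux of the
unscaled matrix so callers can rescale per branch (free-ratio: with that
branch's omega) or per mixture (site-class models: class-proportion
averaged rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetics import GeneticCode, STANDARD_CODE, NUCLEOTIDES


@dataclass
class CodonModelParams:
    """Global parameters of the codon model (omega is supplied per use)."""

    kappa: float
    pi: np.ndarray  # (61,) equilibrium frequencies over sense codons
    code: GeneticCode = STANDARD_CODE

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (self.code.n_sense,):
            raise ValueError("pi must have one entry per sense codon")
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi entries must be >= 0 and sum to 1")
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise ValueError("kappa must be finite and positive")


def uniform_frequencies(code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    return np.full(code.n_sense, 1.0 / code.n_sense)


def observed_frequencies(states: np.ndarray, code: GeneticCode = STANDARD_CODE,
                         pseudocount: float = 0.0) -> np.ndarray:
    """Empirical sense-codon frequencies from a clean state matrix."""
    counts = np.bincount(states[states >= 0].ravel(), minlength=code.n_sense
                         ).astype(float) + pseudocount
    if counts.sum() == 0:
        raise ValueError("no sense codons observed")
    freqs = np.maximum(counts / counts.sum(), 1e-10 if pseudocount == 0 else 0.0)
    return freqs / freqs.sum()


def f3x4_frequencies(states: np.ndarray, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """F3x4 codon frequencies: products of position-specific nucleotide
    frequencies, with stop-codon mass renormalised away."""
    nt_index = {n: k for k, n in enumerate(NUCLEOTIDES)}
    counts = np.zeros((3, 4))
    flat = states[states >= 0].ravel()
    for s in np.bincount(flat, minlength=code.n_sense).nonzero()[0]:
        n = np.count_nonzero(flat == s)
        for pos, nuc in enumerate(code.codons[s]):
            counts[pos, nt_index[nuc]] += n
    if counts.sum() == 0:
        raise ValueError("no sense codons observed")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([
        freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]] * freqs[2, nt_index[c[2]]]
        for c in code.codons
    ])
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate position-specific frequencies")
    # floor unobserved codons: zero equilibrium mass breaks reversible
    # eigendecomposition and is an artifact of finite data anyway
    pi = np.maximum(pi / total, 1e-10)
    return pi / pi.sum()


def codon_frequencies(states: np.ndarray, scheme: str = "f3x4",
                      code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    if scheme == "f3x4":
        return f3x4_frequencies(states, code)
    if scheme == "observed":
        return observed_frequencies(states, code, pseudocount=0.5)
    if scheme == "uniform":
        return uniform_frequencies(code)
    raise ValueError(f"unknown frequency scheme {scheme!r}")


def rate_matrix_unscaled(params: CodonModelParams, omega: float) -> np.ndarray:
    """Unscaled GY rate matrix for a given omega (diagonal set to -rowsum)."""
    if not (np.isfinite(omega) and omega > 0):
        raise ValueError("omega must be finite and positive")
    code = params.code
    single = code.ndiff == 1
    mult = np.where(single, np.where(code.is_ts, params.kappa, 1.0), 0.0)
    mult = mult * np.where(code.is_syn, 1.0, omega)
    Q = mult * params.pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def scale_factor(params: CodonModelParams, omega: float) -> float:
    """Expected substitutions per codon per unit time of the unscaled Q."""
    Q = rate_matrix_unscaled(params, omega)
    return float(-(params.pi * np.diag(Q)).sum())


def build_rate_matrix(params: CodonModelParams, omega: float) -> np.ndarray:
    """Rate matrix scaled to one expected substitution per codon per unit t."""
    Q = rate_matrix_unscaled(params, omega)
    return Q / scale_factor(params, omega)


@dataclass
class EigenQ:
    """Eigendecomposition of a reversible Q for fast exp(Qt)."""

    U: np.ndarray
    lam: np.ndarray
    Uinv: np.ndarray

    def transition_probabilities(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self.U * np.exp(self.lam * t)) @ self.Uinv
        np.clip(P, 0.0, None, out=P)
        return P


def eigen_decompose(Q: np.ndarray, pi: np.ndarray) -> EigenQ:
    sqrt_pi = np.sqrt(pi)
    A = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    A = 0.5 * (A + A.T)  # symmetrise away rounding noise
    lam, V = np.linalg.eigh(A)
    U = V / sqrt_pi[:, None]
    Uinv = V.T * sqrt_pi[None, :]
    return EigenQ(U=U, lam=lam, Uinv=Uinv)


def transition_probabilities(Q: np.ndarray, t: float, pi: np.ndarray | None = None
                             ) -> np.ndarray:
    """P(t) = exp(Qt).  If pi is given the reversible fast path is used."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if pi is not None:
        return eigen_decompose(Q, pi).transition_probabilities(t)
    from scipy.linalg import expm

    P = expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    return P


def count_site_opportunities(params: CodonModelParams) -> tuple[float, float]:
    """Synonymous and nonsynonymous sites per codon, (S, N) with S + N = 3.

    Defined by the neutral (omega = 1) mutational flux: rho_S and rho_N
    are the equilibrium rates into synonymous and nonsynonymous
    neighbours; S = 3 rho_S / (rho_S + rho_N).  This is the
    mutational-opportunity convention used to convert (t, omega) into Ka
    and Ks.
    """
    code = params.code
    Q = rate_matrix_unscaled(params, 1.0)
    flux = params.pi[:, None] * Q
    off = code.ndiff == 1
    rho_s = float(flux[off & code.is_syn].sum())
    rho_n = float(flux[off & ~code.is_syn].sum())
    total = rho_s + rho_n
    return 3.0 * rho_s / total, 3.0 * rho_n / total


def ka_ks_from_branch(t: float, omega: float, params: CodonModelParams
                      ) -> tuple[float, float]:
    """Convert a branch length (subs/codon) and omega into (Ka, Ks).

    The t expected substitutions per codon split into nonsynonymous and
    synonymous in proportion omega*rho_N : rho_S; dividing by the
    per-codon site counts N and S gives the per-site rates, so that
    Ka*N + Ks*S = t and Ka/Ks = omega exactly.
    """
    S, N = count_site_opportunities(params)
    rho_s, rho_n = S / 3.0, N / 3.0  # proportional to the neutral fluxes
    frac_n = omega * rho_n / (omega * rho_n + rho_s)
    ka = t * frac_n / N
    ks = t * (1.0 - frac_n) / S
    return ka, ks
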
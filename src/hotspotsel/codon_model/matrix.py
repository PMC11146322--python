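"""GY94-style codon rate matrix and transition probabilities.

Rates between codons differing at one position are proportional to the
target codon frequency, multiplied by kappa for transitions and by the
branch-class omega for nonsynonymous changes; multi-step rates are zero.
Each class matrix is scaled to one expected substitution per codon per
unit time, so branch lengths are in substitutions/codon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from hotspotsel.codon_model.frequencies import CodonFrequencies
from hotspotsel.codon_model.states import CodonStateSpace, get_state_space

KAPPA_BOUNDS = (1e-3, 100.0)
OMEGA_BOUNDS = (1e-4, 50.0)

BACKGROUND = "background"
FOREGROUND = "foreground"


@dataclass(frozen=True)
class CodonModelParams:
    """kappa, background/foreground omega, and equilibrium frequencies."""

    kappa: float
    omega_background: float
    freqs: CodonFrequencies
    omega_foreground: float | None = None  # None => one-ratio model

    def __post_init__(self):
        if not (KAPPA_BOUNDS[0] <= self.kappa <= KAPPA_BOUNDS[1]):
            raise ValueError(f"kappa {self.kappa} outside {KAPPA_BOUNDS}")
        for w in (self.omega_background, self.omega_foreground):
            if w is not None and not (OMEGA_BOUNDS[0] <= w <= OMEGA_BOUNDS[1]):
                raise ValueError(f"omega {w} outside {OMEGA_BOUNDS}")

    def omega(self, omega_class: str) -> float:
        if omega_class == FOREGROUND:
            return (
                self.omega_foreground
                if self.omega_foreground is not None
                else self.omega_background
            )
        if omega_class == BACKGROUND:
            return self.omega_background
        raise ValueError(f"unknown omega class {omega_class!r}")

    def with_(self, **kw) -> "CodonModelParams":
        return replace(self, **kw)


def build_rate_matrix(
    params: CodonModelParams,
    omega_class: str = BACKGROUND,
    space: CodonStateSpace | None = None,
) -> np.ndarray:
    """Scaled rate matrix Q for one omega class; rows sum to zero."""
    space = space or get_state_space(1)
    pi = np.asarray(params.freqs.pi, dtype=float)
    omega = params.omega(omega_class)
    n = space.n
    Q = np.zeros((n, n))
    rate = np.ones(space.pair_i.shape[0])
    rate[space.pair_transition] *= params.kappa
    rate[space.pair_nonsyn] *= omega
    i, j = space.pair_i, space.pair_j
    Q[i, j] = rate * pi[j]
    Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero expected rate)")
    return Q / scale


class EigenSystem:
    """Cached spectral decomposition of a reversible Q for fast P(t).

    The generator is symmetrized as B = D^(1/2) Q D^(-1/2) with D = diag(pi),
    so a real eigendecomposition applies.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        mask = pi > 0
        if not mask.all():
            raise ValueError("eigendecomposition requires strictly positive pi")
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        self.eigval = eigval
        self.left = eigvec.T * sqrt_pi[None, :]       # rows: U^T D^(1/2)
        self.right = eigvec / sqrt_pi[:, None]        # D^(-1/2) U

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self.right * np.exp(self.eigval * t)) @ self.left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_and_rate(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """P(t) and dP/dt = Q P(t), from the same decomposition."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        e = np.exp(self.eigval * t)
        P = (self.right * e) @ self.left
        dP = (self.right * (self.eigval * e)) @ self.left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P, dP


def transition_matrix(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = expm(Q t); spectral route when pi is given, scipy otherwise."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if pi is not None:
        return EigenSystem(Q, pi).transition(t)
    from scipy.linalg import expm

    P = expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P
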
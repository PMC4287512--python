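"""Time-reversible 20-state substitution model: Q = R*diag(pi), gamma rates, comparisons.

The instantaneous rate matrix is built from a symmetric exchangeability
matrix R = {r_xy} and equilibrium frequencies pi as q_xy = r_xy * pi_y
(x != y), with the diagonal set so rows sum to zero.  Reversibility
(pi_x q_xy = pi_y q_yx) follows from the symmetry of R and makes the
matrix similar to a symmetric one, so transition matrices P(t) = exp(Qt)
are computed through a real eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaincinv, gammainc
from scipy.stats import pearsonr

from .io import MatrixFile, ValidationError, lower_triangle

N_STATES = 20


class RateMatrix:
    """A reversible rate matrix with its eigendecomposition.

    Parameters
    ----------
    R : (20, 20) symmetric non-negative exchangeabilities, zero diagonal.
    pi : (20,) positive equilibrium frequencies summing to 1.
    normalize : if True (default), rescale so the expected substitution
        rate at equilibrium, -sum_x pi_x q_xx, equals 1 and branch lengths
        read as expected substitutions per site.
    """

    def __init__(self, R: np.ndarray, pi: np.ndarray, normalize: bool = True):
        R = np.asarray(R, dtype=float)
        pi = np.asarray(pi, dtype=float)
        if R.shape != (N_STATES, N_STATES):
            raise ValidationError("R must be 20x20")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValidationError("R must be symmetric")
        if np.any(pi <= 0):
            raise ValidationError("frequencies must be strictly positive")
        off = R[~np.eye(N_STATES, dtype=bool)]
        if np.any(off < 0):
            raise ValidationError("exchangeabilities must be non-negative")
        pi = pi / pi.sum()

        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -float(np.dot(pi, np.diag(Q)))
        if rate <= 0:
            raise ValidationError("degenerate rate matrix (zero total rate)")
        if normalize:
            Q = Q / rate
            R = R / rate
            rate = 1.0

        self.R = R
        self.pi = pi
        self.Q = Q
        self.expected_rate = rate

        # eigendecomposition of the symmetric similarity transform
        # S = diag(sqrt(pi)) Q diag(1/sqrt(pi))
        d = np.sqrt(pi)
        S = (d[:, None] * Q) / d[None, :]
        S = 0.5 * (S + S.T)  # enforce exact symmetry
        lam, V = np.linalg.eigh(S)
        self.eigenvalues = lam
        #: U such that Q = U diag(lam) U^-1
        self.U = V / d[:, None]
        self.Uinv = V.T * d[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1; tiny negative entries clamped to 0."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        P = (self.U * np.exp(self.eigenvalues * t)[None, :]) @ self.Uinv
        if np.min(P) < -1e-9:
            raise ValidationError("transition matrix entry strongly negative")
        np.clip(P, 0.0, None, out=P)
        return P

    def to_matrix_file(self, name: str = "") -> MatrixFile:
        """Export (R, pi) with R rescaled to the unit-expected-rate convention."""
        norm = self if self.expected_rate == 1.0 else RateMatrix(self.R, self.pi)
        return MatrixFile.from_r_matrix(norm.R, norm.pi, name=name)

    @classmethod
    def from_matrix_file(cls, mat: MatrixFile, pi: np.ndarray | None = None,
                         normalize: bool = True) -> "RateMatrix":
        return cls(mat.r_matrix(), mat.frequencies if pi is None else pi,
                   normalize=normalize)


def build_rate_matrix(R: np.ndarray, pi: np.ndarray, normalize: bool = True) -> RateMatrix:
    """Compose a reversible rate matrix from exchangeabilities and frequencies."""
    return RateMatrix(R, pi, normalize=normalize)


@dataclass(frozen=True)
class RateModel:
    """Discrete-gamma among-site rate variation: ``ncat`` equiprobable categories."""

    alpha: float
    ncat: int
    rates: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.ncat, 1.0 / self.ncat)


def discrete_gamma(alpha: float, ncat: int) -> RateModel:
    """Discretize a mean-1 gamma distribution into equiprobable bin-mean rates.

    The rate of category i is the conditional mean of Gamma(alpha, 1/alpha)
    within its quantile bin, so the probability-weighted mean rate is exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if ncat < 1:
        raise ValueError(f"need at least one rate category, got {ncat}")
    if ncat == 1:
        return RateModel(alpha=alpha, ncat=1, rates=np.array([1.0]))
    # quantile boundaries of Gamma(alpha, scale=1)
    probs = np.arange(1, ncat) / ncat
    bounds = gammaincinv(alpha, probs)
    upper = np.concatenate([gammainc(alpha + 1.0, bounds), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, bounds)])
    # conditional bin mean of Gamma(alpha, scale=1/alpha), bins equiprobable
    rates = ncat * (upper - lower)
    rates = rates / (rates.mean())  # exact mean 1 despite roundoff
    return RateModel(alpha=float(alpha), ncat=int(ncat), rates=rates)


def matrix_correlation(m1: MatrixFile, m2: MatrixFile) -> tuple[float, float]:
    """Pearson correlations of two matrices: (190 exchangeabilities, 20 frequencies).

    Pearson correlation is scale-invariant, so the normalization convention
    of each input is irrelevant.
    """
    e1, e2 = m1.exchangeabilities, m2.exchangeabilities
    f1, f2 = m1.frequencies, m2.frequencies
    for v in (e1, e2, f1, f2):
        if np.std(v) == 0:
            raise ValidationError("zero-variance input: correlation undefined")
    r_exch = float(pearsonr(e1, e2).statistic)
    r_freq = float(pearsonr(f1, f2).statistic)
    return r_exch, r_freq


def exchangeability_correlation(R1: np.ndarray, R2: np.ndarray) -> float:
    """Pearson correlation between the 190 free entries of two symmetric matrices."""
    v1, v2 = lower_triangle(R1), lower_triangle(R2)
    return float(pearsonr(v1, v2).statistic)
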
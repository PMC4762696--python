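"""Length distributions of random vectors and subvectors of unit vectors.

A random vector ``v`` in ``D`` dimensions with i.i.d. normal components has a
chi-like length distribution.  Normalizing ``v`` to unit length and taking the
first ``m`` components yields a subvector whose length follows what we call the
*square-root beta* distribution: the squared length is ``Beta(m/2, n/2)`` with
``n = D - m``.  These distributions describe which values a neural ensemble
representing an ``m``-dimensional slice of a unit semantic pointer actually has
to encode, and are the foundation of the representational-radius optimization
in :mod:`nefopt.radius_opt`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "VectorLengthDist",
    "SqrtBetaDist",
    "vector_length_pdf",
    "sqrt_beta_pdf",
    "sqrt_beta_cdf",
    "sample_subvector_lengths",
]


def _check_nm(n: int, m: int) -> None:
    if n < 1 or m < 1:
        raise ValueError(f"parameters must satisfy n >= 1 and m >= 1, got n={n}, m={m}")


@dataclass(frozen=True)
class VectorLengthDist:
    """Distribution of the Euclidean length of a ``D``-dimensional vector with
    i.i.d. ``N(0, sigma^2)`` components (a scaled chi distribution).

    Parameters
    ----------
    sigma : float
        Per-component standard deviation; must be positive.
    D : int
        Dimensionality; must be at least 1.  ``D = 1`` gives a half-normal
        distribution and ``D = 2`` a Rayleigh distribution.
    """

    sigma: float
    D: int
    log_kD: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.D < 1:
            raise ValueError(f"D must be a positive integer, got {self.D}")
        # k_D = 1 / (2^(D/2 - 1) sigma^D Gamma(D/2)); kept in log space so the
        # density remains evaluable at large D where k_D itself underflows
        log_kD = -(
            (self.D / 2.0 - 1.0) * np.log(2.0)
            + self.D * np.log(self.sigma)
            + special.gammaln(self.D / 2.0)
        )
        object.__setattr__(self, "log_kD", float(log_kD))

    @property
    def kD(self) -> float:
        return float(np.exp(self.log_kD))

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            logpow = np.where(x > 0, (self.D - 1) * np.log(np.maximum(x, 1e-300)), 0.0)
        out = np.where(
            x < 0,
            0.0,
            np.exp(self.log_kD + logpow - x**2 / (2.0 * self.sigma**2)),
        )
        # x = 0: density is k_D for D = 1, zero otherwise
        out = np.where(x == 0, self.kD if self.D == 1 else 0.0, out)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class SqrtBetaDist:
    """Length distribution of an ``m``-component subvector of a uniformly
    random unit vector in ``n + m`` dimensions.

    The squared length follows ``Beta(m/2, n/2)``, hence the name.  Support is
    ``[0, 1]``; density outside is defined as 0 and the CDF is clamped.
    """

    n: int
    m: int

    def __post_init__(self) -> None:
        _check_nm(self.n, self.m)

    def pdf(self, x):
        return sqrt_beta_pdf(x, self.n, self.m)

    def cdf(self, x):
        return sqrt_beta_cdf(x, self.n, self.m)

    def mean_square(self) -> float:
        """E[x^2] = m / (m + n), the mean of the underlying beta distribution."""
        return self.m / (self.m + self.n)


def vector_length_pdf(x, sigma: float, D: int):
    """PDF of the length of a ``D``-vector of i.i.d. ``N(0, sigma^2)`` draws.

    Evaluates ``k_D x^(D-1) exp(-x^2 / (2 sigma^2))`` with the chi-type
    normalizing constant ``k_D = 1 / (2^(D/2-1) sigma^D Gamma(D/2))``.
    """
    return VectorLengthDist(sigma=sigma, D=D).pdf(x)


def sqrt_beta_pdf(x, n: int, m: int):
    """Square-root-beta density ``(2 / B(n/2, m/2)) x^(m-1) (1 - x^2)^(n/2 - 1)``.

    ``x`` outside ``[0, 1]`` has density 0.  The formula is evaluated in log
    space so large ``n`` does not underflow.
    """
    _check_nm(n, m)
    x = np.asarray(x, dtype=float)
    inside = (x >= 0) & (x <= 1)
    xs = np.clip(x, 0.0, 1.0)
    log_norm = np.log(2.0) - special.betaln(n / 2.0, m / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pow = (m - 1) * np.log(xs) + (n / 2.0 - 1.0) * np.log1p(-(xs**2))
        dens = np.exp(log_norm + log_pow)
    # boundary values where the log form is indeterminate
    dens = np.where((xs == 0) & (m == 1), np.exp(log_norm), dens)
    dens = np.where((xs == 0) & (m > 1), 0.0, dens)
    if n == 2:
        dens = np.where(xs == 1, np.exp(log_norm), dens)
    elif n > 2:
        dens = np.where(xs == 1, 0.0, dens)
    out = np.where(inside, dens, 0.0)
    return out if out.ndim else float(out)


def sqrt_beta_cdf(x, n: int, m: int):
    """Square-root-beta CDF: the regularized incomplete beta function at
    ``x^2`` with parameters ``(m/2, n/2)``.  Clamped to ``[0, 1]`` outside the
    support.
    """
    _check_nm(n, m)
    x = np.asarray(x, dtype=float)
    xs = np.clip(x, 0.0, 1.0)
    out = special.betainc(m / 2.0, n / 2.0, xs**2)
    return out if out.ndim else float(out)


def sample_subvector_lengths(
    D: int, m: int, count: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``count`` subvector lengths by the generative construction.

    Each sample is the norm of the first ``m`` components of a uniformly
    random unit vector in ``D`` dimensions (standard-normal draw, normalized).
    The result follows ``SqrtBetaDist(n=D - m, m=m)``.
    """
    if m < 1 or m > D:
        raise ValueError(f"require 1 <= m <= D, got m={m}, D={D}")
    if count < 1:
        raise ValueError("count must be positive")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((count, D))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.linalg.norm(v[:, :m], axis=1)
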
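"""Minimal Neural Engineering Framework representation layer.

A population ("ensemble") of ``N`` leaky integrate-and-fire neurons encodes an
``m``-dimensional value ``x`` through the current

    J_i(x) = alpha_i * (e_i . x / r) + J_bias_i

where ``e_i`` is the neuron's unit-norm preferred direction, ``r`` the
representational radius, and ``(alpha_i, J_bias_i)`` gain and background
current chosen so the neuron starts firing at its intercept and reaches its
maximum rate at the edge of the radius.  The represented value is recovered by
a linear decode whose weights are found with a regularized least-squares fit
over evaluation points drawn from the solid ``m``-ball of radius ``r``.

The radius convention used throughout the package: inputs are divided by ``r``
before encoding, and decoders are solved against targets in original units, so
the decoded estimate of ``r * x`` at radius ``r`` equals ``r`` times the
estimate of ``x`` at radius 1 (same seed).  Downstream this lets the
radius-dependent distortion be computed from a single unit-radius solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "LIFParams",
    "Ensemble",
    "DecoderSolution",
    "lif_rate",
    "solve_gain_bias",
    "build_ensemble",
    "default_eval_count",
    "sample_eval_points",
    "activity_matrix",
    "solve_decoders",
    "connection_weights",
]

#: Threshold current; gains and biases absorb all per-neuron heterogeneity.
J_THRESHOLD = 1.0


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron parameters.

    tau_ref : refractory period in seconds (default 2 ms)
    tau_rc : membrane time constant in seconds (default 20 ms)
    rate_range : interval of maximum firing rates in Hz, sampled per neuron
    intercept_range : interval of intercepts in normalized represented space
    """

    tau_ref: float = 0.002
    tau_rc: float = 0.02
    rate_range: tuple[float, float] = (200.0, 400.0)
    intercept_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.tau_ref <= 0 or self.tau_rc <= 0:
            raise ValueError("time constants must be positive")
        lo, hi = self.rate_range
        if not (0 < lo < hi):
            raise ValueError(f"need 0 < rate_min < rate_max, got {self.rate_range}")


def lif_rate(J, params: LIFParams = LIFParams()):
    """Steady-state LIF firing rate ``1 / (tau_ref - tau_rc ln(1 - J_thr/J))``
    for ``J > J_thr`` (normalized to 1), and 0 otherwise.
    """
    J = np.asarray(J, dtype=float)
    above = J > J_THRESHOLD
    Jsafe = np.where(above, J, J_THRESHOLD + 1.0)
    rate = np.where(
        above,
        1.0 / (params.tau_ref - params.tau_rc * np.log1p(-J_THRESHOLD / Jsafe)),
        0.0,
    )
    return rate if rate.ndim else float(rate)


def solve_gain_bias(
    max_rate: float, intercept: float, params: LIFParams = LIFParams()
) -> tuple[float, float]:
    """Gain and bias putting the rate at 0 at the intercept and at ``max_rate``
    at the edge of the normalized range (input 1 along the encoder).

    Inverts the rate equation for the current producing ``max_rate`` and
    solves the two linear conditions J(intercept) = J_thr, J(1) = J_max.
    """
    if intercept >= 1.0:
        raise ValueError(f"intercept must be < 1 to be solvable, got {intercept}")
    if max_rate <= 0:
        raise ValueError("max_rate must be positive")
    inv = params.tau_ref - 1.0 / max_rate
    if inv >= 0:
        raise ValueError(
            f"max_rate {max_rate} Hz exceeds the refractory limit "
            f"{1.0 / params.tau_ref} Hz"
        )
    J_max = J_THRESHOLD / (1.0 - np.exp(inv / params.tau_rc))
    gain = (J_max - J_THRESHOLD) / (1.0 - intercept)
    bias = J_THRESHOLD - gain * intercept
    return float(gain), float(bias)


@dataclass
class Ensemble:
    """A population of LIF neurons representing an ``m``-dimensional value."""

    N: int
    m: int
    radius: float
    encoders: np.ndarray  # (N, m), unit rows
    gains: np.ndarray  # (N,), positive
    biases: np.ndarray  # (N,)
    max_rates: np.ndarray  # (N,)
    intercepts: np.ndarray  # (N,)
    params: LIFParams
    seed: int

    def currents(self, points: np.ndarray) -> np.ndarray:
        """Input currents, shape (N, Q), for points of shape (Q, m)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] != self.m:
            raise ValueError(
                f"points have dimensionality {points.shape[1]}, expected {self.m}"
            )
        proj = self.encoders @ points.T / self.radius
        return self.gains[:, None] * proj + self.biases[:, None]

    def rates(self, points: np.ndarray) -> np.ndarray:
        return lif_rate(self.currents(points), self.params)


def build_ensemble(
    N: int,
    m: int,
    radius: float = 1.0,
    params: LIFParams = LIFParams(),
    seed: int = 0,
) -> Ensemble:
    """Sample a heterogeneous ensemble.

    Encoders are uniform on the unit ``(m-1)``-sphere (for ``m = 1`` they are
    -1 or +1), maximum rates uniform in ``params.rate_range`` and intercepts
    uniform in ``params.intercept_range``; everything is deterministic for a
    fixed seed.
    """
    if N < 1 or m < 1 or radius <= 0:
        raise ValueError("need N >= 1, m >= 1, radius > 0")
    rng = np.random.default_rng(seed)
    enc = rng.standard_normal((N, m))
    enc /= np.linalg.norm(enc, axis=1, keepdims=True)
    max_rates = rng.uniform(*params.rate_range, size=N)
    intercepts = rng.uniform(*params.intercept_range, size=N)
    gains = np.empty(N)
    biases = np.empty(N)
    for i in range(N):
        gains[i], biases[i] = solve_gain_bias(max_rates[i], intercepts[i], params)
    return Ensemble(
        N=N,
        m=m,
        radius=float(radius),
        encoders=enc,
        gains=gains,
        biases=biases,
        max_rates=max_rates,
        intercepts=intercepts,
        params=params,
        seed=seed,
    )


def default_eval_count(N: int, m: int) -> int:
    """Default number of evaluation points:
    ``max(2 N m, min(max(500 m, 750), 2500))``.
    """
    return int(max(2 * N * m, min(max(500 * m, 750), 2500)))


def sample_eval_points(
    Q: int, m: int, radius: float = 1.0, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """``Q`` points uniform in the solid ``m``-ball of the given radius."""
    if Q < 1:
        raise ValueError("Q must be positive")
    rng = np.random.default_rng(seed)
    directions = rng.standard_normal((Q, m))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = radius * rng.uniform(size=Q) ** (1.0 / m)
    return directions * radii[:, None]


def activity_matrix(ensemble: Ensemble, points: np.ndarray) -> np.ndarray:
    """Firing rates of every neuron at every evaluation point, shape (N, Q)."""
    return ensemble.rates(points)


@dataclass
class DecoderSolution:
    decoders: np.ndarray  # (N, k)
    gamma: float
    Q: int
    target_function: str = "identity"


def solve_decoders(
    A: np.ndarray,
    targets: np.ndarray,
    gamma: float = 0.1,
    target_function: str = "identity",
) -> DecoderSolution:
    """Regularized least-squares decoders.

    Solves ``(A A^T + Q gamma^2 max(A)^2 I) d = A X`` where ``max(A)`` is the
    largest matrix element; with ``gamma = 0`` an exactly singular Gram matrix
    raises a solver error.
    """
    A = np.asarray(A, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    N, Q = A.shape
    if targets.shape[0] != Q:
        raise ValueError(
            f"targets have {targets.shape[0]} rows but A has {Q} evaluation points"
        )
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    G = A @ A.T
    G[np.diag_indices_from(G)] += Q * gamma**2 * float(A.max()) ** 2
    try:
        dec = scipy.linalg.solve(G, A @ targets, assume_a="pos")
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"decoder system singular (gamma={gamma}); increase regularization"
        ) from err
    return DecoderSolution(
        decoders=dec, gamma=float(gamma), Q=Q, target_function=target_function
    )


def connection_weights(
    post_encoders: np.ndarray, P: np.ndarray, pre_decoders: np.ndarray
) -> np.ndarray:
    """Full synaptic weight matrix ``W_ij = e_i^T P d_j`` implementing the
    linear transform ``P`` between a decoded pre-population and an encoding
    post-population.  ``P = I`` gives a communication channel.
    """
    post_encoders = np.atleast_2d(post_encoders)
    pre_decoders = np.atleast_2d(pre_decoders)
    P = np.atleast_2d(P)
    if post_encoders.shape[1] != P.shape[0] or P.shape[1] != pre_decoders.shape[1]:
        raise ValueError(
            "incompatible shapes: encoders (N_post, k_post), P (k_post, k_pre), "
            "decoders (N_pre, k_pre)"
        )
    return post_encoders @ P @ pre_decoders.T
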
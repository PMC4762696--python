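"""Radius-dependent distortion model and its minimization.

An ensemble representing an ``m``-dimensional subvector of a ``D``-dimensional
unit semantic pointer sees inputs whose lengths follow the square-root-beta
distribution with parameters ``(n, m)``, ``n = D - m``.  Choosing the
representational radius ``r`` trades off two static error sources:

* values with length above ``r`` saturate — modelled as a hard projection onto
  the radius-``r`` sphere, giving squared error ``(y - r)^2``;
* values inside the radius are decoded with the ensemble's intrinsic
  distortion, which scales as ``r^2`` times the unit-radius distortion ``E1``
  because the same evaluation-point budget is spread over a ball of radius
  ``r``.

Weighting the two regimes by the probability of each gives the total error

    E(r) = r^2 E1 F_SB(r; n, m) + E_out(r) (1 - F_SB(r; n, m))

which is unimodal in practice and minimized by bounded scalar search.  The
unit-radius distortion ``E1`` is estimated once from a single decoder solve;
no per-candidate refitting is needed.  Spiking noise is independent of ``r``
and excluded from the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special

from .nef_core import (
    LIFParams,
    activity_matrix,
    build_ensemble,
    default_eval_count,
    sample_eval_points,
    solve_decoders,
)
from .sqrt_beta import sqrt_beta_cdf, sqrt_beta_pdf

__all__ = [
    "RadiusContext",
    "DistortionModel",
    "RadiusOptResult",
    "NeuronReduction",
    "distortion_inside_unit",
    "distortion_outside",
    "total_error",
    "optimize_radius",
    "reduced_neuron_count",
]


@dataclass(frozen=True)
class RadiusContext:
    """Dimensional bookkeeping: a ``D``-dimensional pointer split into
    ``s = D / m`` subvectors of ``m`` components each."""

    D: int
    m: int

    def __post_init__(self) -> None:
        if not (1 <= self.m <= self.D):
            raise ValueError(f"require 1 <= m <= D, got m={self.m}, D={self.D}")

    @property
    def n(self) -> int:
        return self.D - self.m

    @property
    def s(self) -> float:
        return self.D / self.m


@dataclass(frozen=True)
class DistortionModel:
    """Unit-radius inside-distortion estimate together with its context."""

    E1: float
    context: RadiusContext

    def __post_init__(self) -> None:
        if self.E1 < 0:
            raise ValueError("E1 must be nonnegative")


@dataclass(frozen=True)
class RadiusOptResult:
    r_opt: float
    E_total: float
    E_inside: float
    E_outside: float
    curve: np.ndarray  # (n_grid, 2) columns (r, E(r))

    def to_dict(self) -> dict:
        return {
            "r_opt": self.r_opt,
            "E_total": self.E_total,
            "E_inside": self.E_inside,
            "E_outside": self.E_outside,
            "curve": self.curve.tolist(),
        }


@dataclass(frozen=True)
class NeuronReduction:
    factor: float
    N_baseline: int
    N_reduced: int
    floor: int


def distortion_inside_unit(ensemble, eval_points: np.ndarray, gamma: float = 0.1):
    """Static distortion of a unit-radius ensemble.

    Solves identity decoders on ``eval_points`` and returns the mean squared
    residual ``E1 = (1/Q) sum_q ||y_q - sum_i a_i(y_q) d_i||^2`` on those same
    points.  The inside-distortion at radius ``r`` is then ``r^2 * E1`` by the
    package radius convention.  Returns ``(E1, decoders)``.
    """
    if ensemble.radius != 1.0:
        raise ValueError("distortion_inside_unit expects a unit-radius ensemble")
    A = activity_matrix(ensemble, eval_points)
    sol = solve_decoders(A, eval_points, gamma=gamma)
    residual = eval_points - A.T @ sol.decoders
    E1 = float(np.mean(np.sum(residual**2, axis=1)))
    return E1, sol


def distortion_outside(r: float, context: RadiusContext) -> float:
    """Expected squared error of values saturating beyond the radius.

    Conditional on length ``y > r``, the hard-projection error is
    ``(y - r)^2``; the expectation over the square-root-beta length
    distribution is evaluated by adaptive quadrature.  Defined as 0 at
    ``r = 1`` (empty range).
    """
    if not (0 <= r <= 1):
        raise ValueError(f"r must lie in [0, 1], got {r}")
    n, m = context.n, context.m
    if n == 0:  # whole vector in one ensemble: length is exactly 1
        return float((1.0 - r) ** 2)
    # upper-tail probability computed directly to avoid cancellation at
    # radii where the CDF rounds to 1
    tail = float(special.betaincc(m / 2.0, n / 2.0, r * r))
    if tail <= 1e-300 or r >= 1.0:
        return 0.0
    if tail < 1e-12:
        # the conditional expectation is a ratio of two underflowing
        # quantities; quadrature cannot resolve it but the incomplete-beta
        # form can
        return distortion_outside_beta_form(r, context)
    val, _ = integrate.quad(
        lambda y: (y - r) ** 2 * sqrt_beta_pdf(y, n, m),
        r,
        1.0,
        epsabs=1e-12,
        epsrel=1e-10,
        limit=200,
    )
    return float(val / tail)


def distortion_outside_beta_form(r: float, context: RadiusContext) -> float:
    """Closed form of :func:`distortion_outside` via incomplete beta functions.

    Expanding ``(y - r)^2`` gives upper-tail fractional moments of the
    square-root-beta distribution, each expressible with ``betainc``.  Used as
    an independent cross-check of the quadrature path.
    """
    if not (0 <= r <= 1):
        raise ValueError(f"r must lie in [0, 1], got {r}")
    n, m = context.n, context.m
    if n == 0:
        return float((1.0 - r) ** 2)
    a, b = m / 2.0, n / 2.0
    x = r * r
    tail = special.betaincc(a, b, x)  # P(y > r)
    if tail <= 1e-300 or r >= 1.0:
        return 0.0
    # E[y^2 ; y > r] and E[y ; y > r]
    ey2 = (a / (a + b)) * special.betaincc(a + 1.0, b, x)
    half_moment = np.exp(special.betaln(a + 0.5, b) - special.betaln(a, b))
    ey1 = half_moment * special.betaincc(a + 0.5, b, x)
    return float((ey2 - 2.0 * r * ey1 + r * r * tail) / tail)


def total_error(r: float, model: DistortionModel) -> float:
    """Complete static error
    ``E(r) = r^2 E1 F_SB(r) + E_out(r) (1 - F_SB(r))``."""
    if not (0 < r <= 1):
        raise ValueError(f"r must lie in (0, 1], got {r}")
    ctx = model.context
    if ctx.n == 0:
        # degenerate: all probability mass at length exactly 1
        return float(r * r * model.E1 if r >= 1.0 else (1.0 - r) ** 2)
    F = sqrt_beta_cdf(r, ctx.n, ctx.m)
    E_out = distortion_outside(r, ctx)
    return float(r * r * model.E1 * F + E_out * (1.0 - F))


def estimate_distortion_model(
    N: int,
    D: int,
    m: int,
    gamma: float = 0.1,
    seed: int = 0,
    params: LIFParams = LIFParams(),
    Q: int | None = None,
) -> DistortionModel:
    """Build a unit-radius ensemble and estimate ``E1`` for it."""
    ctx = RadiusContext(D=D, m=m)
    if Q is None:
        Q = default_eval_count(N, m)
    ens = build_ensemble(N, m, radius=1.0, params=params, seed=seed)
    pts = sample_eval_points(Q, m, radius=1.0, seed=np.random.default_rng(seed + 1))
    E1, _ = distortion_inside_unit(ens, pts, gamma=gamma)
    return DistortionModel(E1=E1, context=ctx)


def optimize_radius(
    N: int,
    D: int,
    m: int = 1,
    gamma: float = 0.1,
    seed: int = 0,
    params: LIFParams = LIFParams(),
    Q: int | None = None,
    n_curve: int = 100,
) -> RadiusOptResult:
    """Find the radius minimizing the static distortion model.

    Estimates the unit-radius distortion ``E1`` once, then minimizes ``E(r)``
    over ``(0, 1]`` by bounded scalar minimization (tolerance 1e-4 on ``r``).
    """
    model = estimate_distortion_model(
        N=N, D=D, m=m, gamma=gamma, seed=seed, params=params, Q=Q
    )
    ctx = model.context
    if ctx.n == 0:
        # whole vector in one ensemble: every represented value has length 1
        r_opt = 1.0
    else:
        res = optimize.minimize_scalar(
            lambda r: total_error(r, model),
            bounds=(1e-3, 1.0),
            method="bounded",
            options={"xatol": 1e-4},
        )
        if not res.success:  # pragma: no cover - bounded Brent rarely fails
            raise RuntimeError(f"radius optimization did not converge: {res.message}")
        r_opt = float(res.x)
    grid = np.linspace(max(1e-3, 1.0 / n_curve), 1.0, n_curve)
    curve = np.column_stack([grid, [total_error(r, model) for r in grid]])
    F = sqrt_beta_cdf(r_opt, ctx.n, ctx.m) if ctx.n > 0 else 1.0
    E_in = r_opt**2 * model.E1
    E_out = distortion_outside(r_opt, ctx) if ctx.n > 0 else 0.0
    return RadiusOptResult(
        r_opt=r_opt,
        E_total=float(E_in * F + E_out * (1.0 - F)),
        E_inside=float(E_in),
        E_outside=float(E_out),
        curve=curve,
    )


def reduced_neuron_count(N: int, factor: float, floor: int = 1) -> int:
    """Heuristically reduced neuron number ``max(floor, round(N / factor^2))``.

    Because the static mean square error scales as ``1/N``, an RMSE reduction
    by ``factor`` permits using ``factor^2`` fewer neurons at equal error.
    Rounding is round-half-to-even.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1 (no reduction justified), got {factor}")
    if floor < 1 or N < 1:
        raise ValueError("N and floor must be positive")
    return int(max(floor, round(N / factor**2)))
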
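"""Benchmark circuits: representation, circular-convolution binding, and
dot-product comparison, in rate and spiking modes.

Each circuit compiles to a small feedforward stack of scalar (or low-
dimensional) LIF ensembles with an affine input map, per-ensemble decoded
functions, and a linear output map.  Linear transforms (the DFT, product
recombination, summation) live in the connection weights; only the genuinely
nonlinear steps — representation and scalar products via the parabolic
difference-of-squares identity ``ab = ((a+b)^2 - (a-b)^2) / 4`` — are carried
by neurons.

Decoded outputs are filtered by an exponential synapse; the ideal reference
signal is passed through the identical filter cascade so that comparisons are
free of synaptic-delay bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np
from scipy import signal as sp_signal

from .nef_core import (
    LIFParams,
    Ensemble,
    build_ensemble,
    default_eval_count,
    sample_eval_points,
    solve_decoders,
)
from .radius_opt import optimize_radius
from .sp_algebra import SemanticPointer, is_unitary

__all__ = [
    "ExpSynapse",
    "EnsembleArray",
    "CircuitSpec",
    "Network",
    "SimResult",
    "build_representation",
    "build_convolution",
    "build_dot_product",
    "build_single_ensemble_network",
    "simulate",
]


@dataclass(frozen=True)
class ExpSynapse:
    """First-order exponential synapse ``exp(-t / tau)``, normalized to unit
    area (unit DC gain) in discrete time."""

    tau: float = 0.005

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("synaptic time constant must be positive")

    def discrete_coeff(self, dt: float) -> float:
        return float(np.exp(-dt / self.tau))

    def filt(self, x: np.ndarray, dt: float) -> np.ndarray:
        """Filter along axis 0 with zero initial state."""
        a = self.discrete_coeff(dt)
        return sp_signal.lfilter([1.0 - a], [1.0, -a], x, axis=0)


# ---------------------------------------------------------------------------
# compiled network representation


@dataclass
class _Layer:
    ensembles: list[Ensemble]
    W_in: np.ndarray  # (dims_total, prev_dim)
    b_in: np.ndarray  # (dims_total,)
    enc_w: np.ndarray  # (N_total, dims_total): rows gain_i * e_i / r
    bias: np.ndarray  # (N_total,)
    dec: np.ndarray  # (k_total, N_total) block-diagonal decoders
    W_out: np.ndarray  # (out_dim, k_total)


@dataclass
class Network:
    """Compiled feedforward circuit.

    ``reference_fn`` maps the raw input series (T, input_dim) to the ideal
    output series; during simulation it is filtered through as many synapse
    stages as there are neuron layers.
    """

    layers: list[_Layer]
    input_dim: int
    output_dim: int
    reference_fn: Callable[[np.ndarray], np.ndarray]
    meta: dict = field(default_factory=dict)

    @property
    def n_filter_stages(self) -> int:
        return len(self.layers)


@dataclass
class EnsembleArray:
    """``s`` ensembles of ``m`` dimensions jointly representing ``D = s * m``
    dimensions, with per-ensemble radii."""

    sub_ensembles: list[Ensemble]
    D: int
    radius_mode: str
    radii: np.ndarray
    network: Network

    def __post_init__(self) -> None:
        if sum(e.m for e in self.sub_ensembles) != self.D:
            raise ValueError("sub-ensemble dimensionalities must sum to D")


@dataclass
class CircuitSpec:
    """Parameters of one benchmark circuit."""

    kind: Literal["represent", "convolve", "dot"]
    D: int
    neurons_per_dim: int = 50
    radius_mode: Literal["default", "optimized"] = "default"
    fixed_operand: Optional[SemanticPointer] = None
    seed: int = 0
    gamma: float = 0.1
    params: LIFParams = field(default_factory=LIFParams)


@dataclass
class SimResult:
    times: np.ndarray
    decoded: np.ndarray  # (T, out_dim)
    reference: np.ndarray  # (T, out_dim), synapse-filtered ideal output
    mode: str

    def errors(self, skip: float = 0.0, dt: float = 0.001) -> np.ndarray:
        """Per-step Euclidean errors after discarding the initial transient."""
        i0 = int(round(skip / dt))
        diff = self.decoded[i0:] - self.reference[i0:]
        return np.linalg.norm(np.atleast_2d(diff.T).T, axis=1)

    def to_frame(self):
        """Time series as a DataFrame: time, decoded and reference columns."""
        import pandas as pd

        k = self.decoded.shape[1]
        data = {"time": self.times}
        for j in range(k):
            data[f"decoded_{j}"] = self.decoded[:, j]
            data[f"reference_{j}"] = self.reference[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self, skip: float = 0.0, dt: float = 0.001) -> dict:
        err = self.errors(skip=skip, dt=dt)
        return {
            "mode": self.mode,
            "steps": int(self.times.size),
            "rmse": float(np.sqrt(np.mean(err**2))),
            "median_error": float(np.median(err)),
        }


# ---------------------------------------------------------------------------
# layer construction helpers


_TARGET_FUNCTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "square": lambda x: np.sum(x**2, axis=1, keepdims=True),
}


def _solve_function_decoders(ens: Ensemble, func: str, gamma: float, seed: int):
    """Decoders for ``func`` of the represented value, solved on evaluation
    points spanning the ensemble's radius, with targets in original units."""
    Q = default_eval_count(ens.N, ens.m)
    pts = ens.radius * sample_eval_points(Q, ens.m, radius=1.0, seed=seed)
    A = ens.rates(pts)
    targets = _TARGET_FUNCTIONS[func](pts)
    sol = solve_decoders(A, targets, gamma=gamma, target_function=func)
    return sol.decoders


def _compile_layer(
    ens_specs: list[tuple[Ensemble, str]],
    W_in: np.ndarray,
    b_in: np.ndarray,
    W_out: np.ndarray,
    gamma: float,
    seed: int,
) -> _Layer:
    """Stack ensembles into block matrices for vectorized simulation."""
    rng = np.random.default_rng(seed)
    ensembles = [e for e, _ in ens_specs]
    dims = sum(e.m for e in ensembles)
    N_tot = sum(e.N for e in ensembles)
    k_tot = 0
    dec_blocks = []
    for ens, func in ens_specs:
        d = _solve_function_decoders(ens, func, gamma, int(rng.integers(2**31)))
        dec_blocks.append(d)
        k_tot += d.shape[1]
    enc_w = np.zeros((N_tot, dims))
    bias = np.empty(N_tot)
    dec = np.zeros((k_tot, N_tot))
    n0 = d0 = k0 = 0
    for ens, dblk in zip(ensembles, dec_blocks):
        n1, d1, k1 = n0 + ens.N, d0 + ens.m, k0 + dblk.shape[1]
        enc_w[n0:n1, d0:d1] = ens.gains[:, None] * ens.encoders / ens.radius
        bias[n0:n1] = ens.biases
        dec[k0:k1, n0:n1] = dblk.T
        n0, d0, k0 = n1, d1, k1
    return _Layer(
        ensembles=ensembles,
        W_in=np.asarray(W_in, dtype=float),
        b_in=np.asarray(b_in, dtype=float),
        enc_w=enc_w,
        bias=bias,
        dec=dec,
        W_out=np.asarray(W_out, dtype=float),
    )


def _spawn_seeds(seed: int, count: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31, size=count)


# ---------------------------------------------------------------------------
# circuit builders


def build_single_ensemble_network(
    N: int,
    m: int,
    radius: float,
    params: LIFParams = LIFParams(),
    gamma: float = 0.1,
    seed: int = 0,
    input_dim: int | None = None,
) -> Network:
    """One ensemble representing the first ``m`` components of the input."""
    if input_dim is None:
        input_dim = m
    ens = build_ensemble(N, m, radius=radius, params=params, seed=seed)
    W_in = np.zeros((m, input_dim))
    W_in[:, :m] = np.eye(m)
    layer = _compile_layer(
        [(ens, "identity")],
        W_in=W_in,
        b_in=np.zeros(m),
        W_out=np.eye(m),
        gamma=gamma,
        seed=seed + 1,
    )
    return Network(
        layers=[layer],
        input_dim=input_dim,
        output_dim=m,
        reference_fn=lambda sig: np.atleast_2d(sig.T).T[:, :m],
        meta={"kind": "single", "radius": radius, "N": N, "m": m},
    )


def build_representation(spec: CircuitSpec) -> EnsembleArray:
    """``D`` single-dimension ensembles representing a ``D``-vector.

    Default mode uses radius 1 per ensemble; optimized mode sets every radius
    to the distortion-model optimum for component lengths of a unit
    ``D``-vector.
    """
    if spec.kind != "represent":
        raise ValueError("spec.kind must be 'represent'")
    D, N = spec.D, spec.neurons_per_dim
    if spec.radius_mode == "optimized":
        radius = optimize_radius(
            N, D, 1, gamma=spec.gamma, seed=spec.seed, params=spec.params
        ).r_opt
    else:
        radius = 1.0
    seeds = _spawn_seeds(spec.seed, D)
    ensembles = [
        build_ensemble(N, 1, radius=radius, params=spec.params, seed=int(s))
        for s in seeds
    ]
    layer = _compile_layer(
        [(e, "identity") for e in ensembles],
        W_in=np.eye(D),
        b_in=np.zeros(D),
        W_out=np.eye(D),
        gamma=spec.gamma,
        seed=spec.seed + 1,
    )
    net = Network(
        layers=[layer],
        input_dim=D,
        output_dim=D,
        reference_fn=lambda sig: sig,
        meta={"kind": "represent", "radius": radius, "radius_mode": spec.radius_mode},
    )
    return EnsembleArray(
        sub_ensembles=ensembles,
        D=D,
        radius_mode=spec.radius_mode,
        radii=np.full(D, radius),
        network=net,
    )


def real_dft_packing(D: int, unitary: bool) -> tuple[np.ndarray, list[dict]]:
    """Real-valued packing of the DFT of a length-``D`` real vector.

    Returns ``(T, bins)`` where ``T`` is the ``D x D`` matrix mapping ``v`` to
    packed coefficients and ``bins`` describes the layout.  Solo bins (k = 0
    and, for even ``D``, k = D/2) occupy one slot; interior bins occupy a
    (real, imaginary) pair.  With ``unitary=True`` rows are weighted (1/sqrt D
    for solo bins, sqrt(2/D) for pairs) making ``T`` orthogonal, so the packed
    coefficient vector of a unit vector is itself unit length.
    """
    j = np.arange(D)
    rows = []
    bins = []
    for k in range(D // 2 + 1):
        angle = 2.0 * np.pi * k * j / D
        solo = k == 0 or (D % 2 == 0 and k == D // 2)
        if solo:
            w = 1.0 / np.sqrt(D) if unitary else 1.0
            bins.append({"k": k, "solo": True, "idx": (len(rows),), "weight": w})
            rows.append(w * np.cos(angle))
        else:
            w = np.sqrt(2.0 / D) if unitary else 1.0
            bins.append(
                {"k": k, "solo": False, "idx": (len(rows), len(rows) + 1), "weight": w}
            )
            rows.append(w * np.cos(angle))
            rows.append(-w * np.sin(angle))
    assert len(rows) == D
    return np.array(rows), bins


def build_convolution(spec: CircuitSpec) -> Network:
    """Two-layer binding circuit: DFT in the input weights, one scalar product
    per required coefficient multiplication (each product realized by two
    parabolic square channels), inverse DFT in the output weights.

    The second operand is fixed to a unitary pointer and enters the product
    channels as a constant offset.  Default mode follows the common simulator
    convention: forward transform scale 1, inverse scale 1/D, channel radius 2.
    Optimized mode uses the orthogonal (unit-length-preserving) transform and
    channel radii ``(r_opt + |b|) / 2`` where ``r_opt`` is the distortion-model
    optimum for coefficient components and ``b`` the channel's fixed offset.
    """
    if spec.kind != "convolve":
        raise ValueError("spec.kind must be 'convolve'")
    if spec.fixed_operand is None or not is_unitary(spec.fixed_operand):
        raise ValueError("convolution requires a unitary fixed_operand")
    D, N = spec.D, spec.neurons_per_dim
    w = spec.fixed_operand.v
    unitary_scaling = spec.radius_mode == "optimized"
    T, bins = real_dft_packing(D, unitary=unitary_scaling)
    cw = T @ w  # fixed operand packed identically

    if spec.radius_mode == "optimized":
        r_opt = optimize_radius(
            N, D, 1, gamma=spec.gamma, seed=spec.seed, params=spec.params
        ).r_opt
    else:
        r_opt = None

    # products: (variable packed index, fixed packed value, output slot, sign,
    # recombination gain)
    products = []
    for b in bins:
        wgt = b["weight"]
        gain = 1.0 / wgt  # compensates the packing weight on the fixed operand
        if b["solo"]:
            (i,) = b["idx"]
            products.append((i, cw[i], i, 1.0, gain))
        else:
            ir, ii = b["idx"]
            # Re U = Re V Re W - Im V Im W ; Im U = Re V Im W + Im V Re W
            products.append((ir, cw[ir], ir, 1.0, gain))
            products.append((ii, cw[ii], ir, -1.0, gain))
            products.append((ir, cw[ii], ii, 1.0, gain))
            products.append((ii, cw[ir], ii, 1.0, gain))
    P = len(products)

    # channels: two per product, (x + b)/2 and (x - b)/2
    W_in = np.zeros((2 * P, D))
    b_in = np.zeros(2 * P)
    radii = np.empty(2 * P)
    for p, (ivar, bval, _, _, _) in enumerate(products):
        W_in[2 * p] = W_in[2 * p + 1] = 0.5 * T[ivar]
        b_in[2 * p] = 0.5 * bval
        b_in[2 * p + 1] = -0.5 * bval
        if spec.radius_mode == "optimized":
            radii[2 * p] = radii[2 * p + 1] = 0.5 * (r_opt + abs(bval))
        else:
            radii[2 * p] = radii[2 * p + 1] = 2.0

    # recombination: packed U from decoded squares, then the inverse transform
    R = np.zeros((D, 2 * P))
    for p, (_, _, islot, sign, gain) in enumerate(products):
        R[islot, 2 * p] = sign * gain
        R[islot, 2 * p + 1] = -sign * gain
    S = T.T if unitary_scaling else np.linalg.inv(T)
    W_out = S @ R

    seeds = _spawn_seeds(spec.seed + 17, 2 * P)
    ensembles = [
        build_ensemble(N, 1, radius=float(radii[i]), params=spec.params, seed=int(s))
        for i, s in enumerate(seeds)
    ]
    layer = _compile_layer(
        [(e, "square") for e in ensembles],
        W_in=W_in,
        b_in=b_in,
        W_out=W_out,
        gamma=spec.gamma,
        seed=spec.seed + 2,
    )
    circulant = w[(np.arange(D)[:, None] - np.arange(D)[None, :]) % D]
    net = Network(
        layers=[layer],
        input_dim=D,
        output_dim=D,
        reference_fn=lambda sig: sig @ circulant.T,
        meta={
            "kind": "convolve",
            "radius_mode": spec.radius_mode,
            "radii": radii,
            "r_opt": r_opt,
            "n_products": P,
        },
    )
    return net


def build_dot_product(spec: CircuitSpec) -> Network:
    """Dot-product comparison circuit.

    ``D`` parabolic multiplier subnetworks compute ``v_d * w_d`` against a
    fixed unit operand; their decoded outputs project linearly onto a single
    scalar ensemble that represents the sum.  Default mode uses radius 1
    everywhere.  Optimized mode shrinks the multiplier channel radii to
    ``(r_opt + |w_d|) / 2`` and the output-sum radius to ``r_opt``: component
    lengths of unit vectors follow the square-root-beta law, and so does the
    dot product of a random unit vector with a fixed one (it is one
    coordinate of a unit vector in a rotated basis), so the same optimum
    applies to the sum ensemble.
    """
    if spec.kind != "dot":
        raise ValueError("spec.kind must be 'dot'")
    if spec.fixed_operand is None:
        raise ValueError("dot circuit requires a fixed_operand")
    D, N = spec.D, spec.neurons_per_dim
    w = spec.fixed_operand.v
    if w.size != D:
        raise ValueError("fixed_operand dimensionality mismatch")

    if spec.radius_mode == "optimized":
        r_opt = optimize_radius(
            N, D, 1, gamma=spec.gamma, seed=spec.seed, params=spec.params
        ).r_opt
        radii = 0.5 * (r_opt + np.abs(w))
        sum_radius = r_opt
    else:
        r_opt = None
        radii = np.ones(D)
        sum_radius = 1.0

    W_in = np.zeros((2 * D, D))
    b_in = np.zeros(2 * D)
    chan_radii = np.empty(2 * D)
    for d in range(D):
        W_in[2 * d, d] = W_in[2 * d + 1, d] = 0.5
        b_in[2 * d] = 0.5 * w[d]
        b_in[2 * d + 1] = -0.5 * w[d]
        chan_radii[2 * d] = chan_radii[2 * d + 1] = radii[d]
    # sum of per-dimension products: dot(v, w) = sum_d (c1_d^2 - c2_d^2)
    W_sum = np.tile([1.0, -1.0], D)[None, :]

    seeds = _spawn_seeds(spec.seed + 29, 2 * D + 1)
    channels = [
        build_ensemble(
            N, 1, radius=float(chan_radii[i]), params=spec.params, seed=int(seeds[i])
        )
        for i in range(2 * D)
    ]
    layer1 = _compile_layer(
        [(e, "square") for e in channels],
        W_in=W_in,
        b_in=b_in,
        W_out=W_sum,
        gamma=spec.gamma,
        seed=spec.seed + 3,
    )
    sum_ens = build_ensemble(
        N, 1, radius=sum_radius, params=spec.params, seed=int(seeds[-1])
    )
    layer2 = _compile_layer(
        [(sum_ens, "identity")],
        W_in=np.eye(1),
        b_in=np.zeros(1),
        W_out=np.eye(1),
        gamma=spec.gamma,
        seed=spec.seed + 4,
    )
    net = Network(
        layers=[layer1, layer2],
        input_dim=D,
        output_dim=1,
        reference_fn=lambda sig: (sig @ w)[:, None],
        meta={
            "kind": "dot",
            "radius_mode": spec.radius_mode,
            "radii": radii,
            "r_opt": r_opt,
        },
    )
    return net


# ---------------------------------------------------------------------------
# simulation


def _lif_spiking_step(v, refractory, J, dt, tau_rc, tau_ref):
    """One Euler-exponential LIF step with sub-step refractory accounting.

    Voltage integrates exactly toward ``J`` over the non-refractory part of
    the step; threshold crossings estimate the crossing time within the step
    so long-run spike rates track the analytic rate curve.
    Returns a boolean spike mask.
    """
    refractory -= dt
    delta_t = np.clip(dt - refractory, 0.0, dt)
    v += (J - v) * -np.expm1(-delta_t / tau_rc)
    spiked = v > 1.0
    if np.any(spiked):
        overshoot = (v[spiked] - 1.0) / (J[spiked] - 1.0)
        t_spike = dt + tau_rc * np.log1p(-overshoot)
        refractory[spiked] = tau_ref + t_spike
        v[spiked] = 0.0
    v[v < 0] = 0.0
    return spiked


def simulate(
    network,
    input_signal,
    mode: Literal["rate", "spiking"] = "rate",
    synapse: ExpSynapse = ExpSynapse(0.005),
    dt: float = 0.001,
    seed: int = 0,
) -> SimResult:
    """Forward-simulate a compiled circuit at fixed time step.

    Rate mode evaluates the analytic LIF rate at each step (no spiking
    noise); spiking mode integrates LIF membrane dynamics with
    reset-to-zero, refractory clamping, and uniformly random initial voltages
    to desynchronize onset transients.  Decoded outputs of every neuron layer
    are filtered by the synapse; the reference passes through the identical
    filter cascade.
    """
    net: Network = getattr(network, "network", network)
    if isinstance(input_signal, np.ndarray):
        sig = np.atleast_2d(input_signal.T).T
    else:
        sig = np.atleast_2d(np.asarray(input_signal.samples, dtype=float).T).T
    if sig.shape[1] != net.input_dim:
        raise ValueError(
            f"signal dimensionality {sig.shape[1]} != network input {net.input_dim}"
        )
    if dt <= 0:
        raise ValueError("dt must be positive")
    T = sig.shape[0]
    times = np.arange(T) * dt

    if mode == "rate":
        y = sig
        for layer in net.layers:
            x = y @ layer.W_in.T + layer.b_in
            J = x @ layer.enc_w.T + layer.bias
            above = J > 1.0
            p = layer.ensembles[0].params
            with np.errstate(divide="ignore", invalid="ignore"):
                rates = np.where(
                    above,
                    1.0 / (p.tau_ref - p.tau_rc * np.log1p(-1.0 / np.where(above, J, 2.0))),
                    0.0,
                )
            decoded = rates @ layer.dec.T
            y = synapse.filt(decoded, dt) @ layer.W_out.T
        out = y
    elif mode == "spiking":
        p0 = net.layers[0].ensembles[0].params
        if dt >= p0.tau_ref:
            raise ValueError(
                f"dt={dt} must be smaller than the refractory period {p0.tau_ref}"
            )
        rng = np.random.default_rng(seed)
        states = []
        for layer in net.layers:
            N_tot = layer.enc_w.shape[0]
            states.append(
                {
                    "v": rng.uniform(0.0, 1.0, size=N_tot),
                    "ref": np.zeros(N_tot),
                    "filt": np.zeros(layer.dec.shape[0]),
                }
            )
        out = np.empty((T, net.output_dim))
        alpha = synapse.discrete_coeff(dt)
        for t in range(T):
            u = sig[t]
            for layer, st in zip(net.layers, states):
                x = layer.W_in @ u + layer.b_in
                J = layer.enc_w @ x + layer.bias
                p = layer.ensembles[0].params
                spiked = _lif_spiking_step(
                    st["v"], st["ref"], J, dt, p.tau_rc, p.tau_ref
                )
                decoded = (layer.dec[:, spiked].sum(axis=1)) / dt
                st["filt"] += (1.0 - alpha) * (decoded - st["filt"])
                u = layer.W_out @ st["filt"]
            out[t] = u
        out = np.atleast_2d(out.T).T
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ref = np.atleast_2d(net.reference_fn(sig).T).T
    for _ in range(net.n_filter_stages):
        ref = synapse.filt(ref, dt)
    return SimResult(times=times, decoded=out, reference=ref, mode=mode)
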
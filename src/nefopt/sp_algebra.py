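"""Exact (non-neural) semantic-pointer algebra.

Holographic Reduced Representations over real ``D``-vectors: circular
convolution as the binding operation, index-reversal involution for
approximate unbinding, unitary vectors for exact unbinding, and the dot
product as similarity.  These operations serve as the algebraic reference
against which the neural circuits in :mod:`nefopt.networks` are scored.
"""

from __future__ import annotations

import csv
import json

import numpy as np

__all__ = [
    "SemanticPointer",
    "circular_convolution",
    "circular_convolution_direct",
    "involution",
    "unbind",
    "make_unitary",
    "random_unit",
    "dot_similarity",
    "is_unitary",
    "save_vocabulary",
    "load_vocabulary",
]


class SemanticPointer:
    """A ``D``-dimensional real vector used as a symbol-like representation.

    Thin wrapper over a numpy array; operators ``*`` (binding via circular
    convolution), ``~`` (involution) and ``@`` (dot similarity) mirror common
    HRR notation.
    """

    __slots__ = ("v",)

    def __init__(self, values):
        self.v = np.asarray(values, dtype=float).reshape(-1)
        if self.v.size < 1:
            raise ValueError("a semantic pointer needs at least one component")

    @property
    def D(self) -> int:
        return self.v.size

    def norm(self) -> float:
        return float(np.linalg.norm(self.v))

    def normalized(self) -> "SemanticPointer":
        nrm = self.norm()
        if nrm == 0:
            raise ValueError("cannot normalize the zero vector")
        return SemanticPointer(self.v / nrm)

    def is_unit(self, tol: float = 1e-12) -> bool:
        return abs(self.norm() - 1.0) <= tol

    def __mul__(self, other):
        return circular_convolution(self, other)

    def __invert__(self):
        return involution(self)

    def __matmul__(self, other):
        return dot_similarity(self, other)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SemanticPointer(D={self.D}, norm={self.norm():.4f})"


def _as_array(x) -> np.ndarray:
    return x.v if isinstance(x, SemanticPointer) else np.asarray(x, dtype=float)


def _wrap_like(out: np.ndarray, *inputs) -> "SemanticPointer | np.ndarray":
    if any(isinstance(x, SemanticPointer) for x in inputs):
        return SemanticPointer(out)
    return out


def _check_same_dim(v: np.ndarray, w: np.ndarray) -> None:
    if v.size != w.size:
        raise ValueError(f"dimension mismatch: {v.size} vs {w.size}")


def circular_convolution(v, w):
    """Binding ``u = v * w`` with ``u_i = sum_j v_j w_((i - j) mod D)``.

    Computed through the FFT (element-wise product in Fourier space); the
    direct ``O(D^2)`` summation is available as
    :func:`circular_convolution_direct` and agrees to 1e-10.
    """
    va, wa = _as_array(v), _as_array(w)
    _check_same_dim(va, wa)
    out = np.fft.irfft(np.fft.rfft(va) * np.fft.rfft(wa), n=va.size)
    return _wrap_like(out, v, w)


def circular_convolution_direct(v, w):
    """Reference ``O(D^2)`` evaluation of the binding sum."""
    va, wa = _as_array(v), _as_array(w)
    _check_same_dim(va, wa)
    D = va.size
    idx = (np.arange(D)[:, None] - np.arange(D)[None, :]) % D
    out = wa[idx] @ va
    return _wrap_like(out, v, w)


def involution(w):
    """Index-reversal ``w^-1 = (w_1, w_D, w_(D-1), ..., w_2)`` (first element
    fixed, remainder reversed); its own inverse."""
    wa = _as_array(w)
    out = np.concatenate([wa[:1], wa[:0:-1]])
    return _wrap_like(out, w)


def unbind(u, w):
    """Approximate inverse of binding: ``u * involution(w)``.

    Exact (to numerical precision) when ``w`` is unitary; otherwise recovers
    the bound operand up to HRR noise.
    """
    return circular_convolution(u, involution(w))


def make_unitary(seed: int | np.random.Generator, D: int) -> SemanticPointer:
    """Random unitary pointer: all Fourier coefficient magnitudes equal 1.

    Free bins get uniform random phases; the zero-frequency bin (and Nyquist
    bin for even ``D``) get random signs.  Binding with the result preserves
    the norm of the other operand, and unbinding is exact.
    """
    if D < 1:
        raise ValueError("D must be positive")
    rng = np.random.default_rng(seed)
    n_bins = D // 2 + 1
    coeffs = np.empty(n_bins, dtype=complex)
    coeffs[0] = rng.choice([-1.0, 1.0])
    interior = n_bins - 1 - (1 if D % 2 == 0 else 0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=interior)
    coeffs[1 : 1 + interior] = np.exp(1j * phases)
    if D % 2 == 0:
        coeffs[-1] = rng.choice([-1.0, 1.0])
    return SemanticPointer(np.fft.irfft(coeffs, n=D))


def random_unit(seed: int | np.random.Generator, D: int) -> SemanticPointer:
    """Uniformly random unit pointer on the ``(D-1)``-sphere."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(D)
    return SemanticPointer(v / np.linalg.norm(v))


def is_unitary(w, tol: float = 1e-10) -> bool:
    wa = _as_array(w)
    mags = np.abs(np.fft.rfft(wa))
    return bool(np.all(np.abs(mags - 1.0) <= tol))


def dot_similarity(v, w) -> float:
    """Similarity ``v . w``; lies in [-1, 1] for unit vectors."""
    va, wa = _as_array(v), _as_array(w)
    _check_same_dim(va, wa)
    return float(va @ wa)


def save_vocabulary(path: str, vocab: dict[str, "SemanticPointer | np.ndarray"]):
    """Write a named pointer vocabulary.

    CSV (one row per pointer: name followed by the D components) when the
    path ends in ``.csv``, JSON mapping name -> component list otherwise.
    """
    items = {name: list(map(float, _as_array(p))) for name, p in vocab.items()}
    if str(path).endswith(".csv"):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for name, comps in items.items():
                writer.writerow([name, *comps])
    else:
        with open(path, "w") as fh:
            json.dump(items, fh, indent=2)


def load_vocabulary(path: str) -> dict[str, SemanticPointer]:
    """Read a vocabulary written by :func:`save_vocabulary`."""
    if str(path).endswith(".csv"):
        out = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if row:
                    out[row[0]] = SemanticPointer([float(x) for x in row[1:]])
        return out
    with open(path) as fh:
        return {name: SemanticPointer(c) for name, c in json.load(fh).items()}
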
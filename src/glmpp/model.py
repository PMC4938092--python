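"""The coupled linear–nonlinear Poisson model of group calling.

Each channel j (an individual, or an (individual, calltype) pair) emits
events with conditional intensity

    lambda_j(t) = sigma( b_j + sum_i (K_ij * y_i)(t) )

where b_j is a constant base drive, K_ij the influence kernel from channel i
to channel j (including the reflexive i == j entry), * denotes strictly
causal convolution with the observed event train y_i, and sigma a monotonic
non-negative nonlinearity.  Two link modes are supported:

- additive: influences sum on the (soft-thresholded) rate scale,
  sigma(x) = s * log(1 + exp(x / s))  (softplus with scale s);
- multiplicative: influences sum on the log-rate scale, sigma(x) = exp(x).

The likelihood is evaluated on a regular time grid of width Δ with a
Poisson count model per bin; an event cannot influence its own bin (the
convolution starts at a lag of one bin).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import oaconvolve
from scipy.special import expit, gammaln

from .basis import BasisSet, Kernel, make_cosine_basis
from .events import BinnedEvents

__all__ = [
    "Nonlinearity",
    "NetworkModel",
    "linear_drive",
    "intensity",
    "neg_log_likelihood",
]

_HUGE = 1e100


@dataclass(frozen=True)
class Nonlinearity:
    """Monotonic non-negative output nonlinearity sigma.

    kind='softplus': sigma(x) = scale * log(1 + exp(x / scale)); behaves like
    a soft threshold at zero, linear for large positive drive.
    kind='exponential': sigma(x) = exp(x); scale is ignored.
    """

    kind: str = "softplus"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("softplus", "exponential"):
            raise ValueError(f"unknown nonlinearity kind {self.kind!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "softplus":
            return self.scale * np.logaddexp(0.0, x / self.scale)
        return np.exp(np.minimum(x, 700.0))

    def deriv(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "softplus":
            return expit(x / self.scale)
        return np.exp(np.minimum(x, 700.0))

    def log(self, x):
        """log sigma(x), numerically safe for very negative drives."""
        x = np.asarray(x, dtype=float)
        if self.kind == "exponential":
            return x
        sp = np.logaddexp(0.0, x / self.scale)  # softplus on unit scale
        with np.errstate(divide="ignore"):
            out = math.log(self.scale) + np.log(sp)
        # for strongly negative x, softplus(x/s) ~ exp(x/s): use the exact limit
        tiny = sp < 1e-12
        if np.any(tiny):
            out = np.where(tiny, math.log(self.scale) + x / self.scale, out)
        return out

    def inverse(self, y: float) -> float:
        """Drive producing rate y; used to initialise base rates."""
        if y <= 0:
            raise ValueError("rate must be positive")
        if self.kind == "exponential":
            return math.log(y)
        z = y / self.scale
        if z > 30:
            return y
        return self.scale * math.log(math.expm1(z))


@dataclass
class NetworkModel:
    """Full generative model: base drives, kernel matrix, link.

    ``weights[i, j]`` holds the basis coefficients of kernel K_ij (influence
    of channel i on channel j); the matrix is square and includes reflexive
    entries.  ``link_mode`` ties the nonlinearity to the summation scale:
    additive uses softplus, multiplicative uses exponential.
    """

    channels: list[str]
    base_rates: np.ndarray  # per-channel pre-nonlinearity offsets b_j
    weights: np.ndarray  # (C, C, n_basis)
    basis: BasisSet
    nonlinearity: Nonlinearity = field(default_factory=Nonlinearity)
    link_mode: str = "additive"

    def __post_init__(self) -> None:
        C = len(self.channels)
        self.base_rates = np.asarray(self.base_rates, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.base_rates.shape != (C,):
            raise ValueError("base_rates must have one entry per channel")
        if self.weights.shape != (C, C, self.basis.n_basis):
            raise ValueError("weights must be (C, C, n_basis)")
        if self.link_mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown link_mode {self.link_mode!r}")
        expected = "softplus" if self.link_mode == "additive" else "exponential"
        if self.nonlinearity.kind != expected:
            raise ValueError(
                f"link_mode {self.link_mode!r} requires a {expected} nonlinearity"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def kernel(self, i, j) -> Kernel:
        """Influence kernel of channel i on channel j (labels or indices)."""
        ii = self.channels.index(i) if isinstance(i, str) else i
        jj = self.channels.index(j) if isinstance(j, str) else j
        return Kernel(self.weights[ii, jj], self.basis)

    def kernel_curves(self, lags=None) -> np.ndarray:
        """All kernels evaluated on a lag grid, shape (C, C, n_lags)."""
        if lags is None:
            lags = self.basis.lag_grid
        B = self.basis.evaluate(lags)  # (n_basis, n_lags)
        return np.einsum("ijb,bl->ijl", self.weights, B)

    @classmethod
    def homogeneous(cls, channels, rates, basis: BasisSet | None = None,
                    link_mode: str = "additive", scale: float = 0.1) -> "NetworkModel":
        """Uncoupled model whose channels fire at the given constant rates."""
        basis = basis or make_cosine_basis()
        nl = Nonlinearity("softplus" if link_mode == "additive" else "exponential", scale)
        rates = np.broadcast_to(np.asarray(rates, dtype=float), (len(channels),))
        b = np.array([nl.inverse(r) for r in rates])
        W = np.zeros((len(channels), len(channels), basis.n_basis))
        return cls(list(channels), b, W, basis, nl, link_mode)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "link_mode": self.link_mode,
            "nonlinearity": {"kind": self.nonlinearity.kind, "scale": self.nonlinearity.scale},
            "basis": self.basis.to_dict(),
            "base_rates": self.base_rates.tolist(),
            "kernel_weights": self.weights.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        return cls(
            channels=list(d["channels"]),
            base_rates=np.asarray(d["base_rates"], dtype=float),
            weights=np.asarray(d["kernel_weights"], dtype=float),
            basis=BasisSet.from_dict(d["basis"]),
            nonlinearity=Nonlinearity(**d["nonlinearity"]),
            link_mode=d["link_mode"],
        )

    @classmethod
    def from_json(cls, path) -> "NetworkModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _check_compat(model: NetworkModel, binned: BinnedEvents) -> None:
    if list(binned.channels) != list(model.channels):
        raise ValueError("binned channels do not match model channels")
    if not math.isclose(binned.bin_width, model.basis.bin_width, rel_tol=1e-9):
        raise ValueError("bin width mismatch between data and basis")


def linear_drive(model: NetworkModel, binned: BinnedEvents) -> np.ndarray:
    """Pre-nonlinearity drive u_j(t) = b_j + Σ_i (K_ij * y_i)(t), shape (C, T).

    The convolution is strictly causal with a minimum lag of one bin: counts
    in bin t contribute from bin t+1 onwards, so an event never influences
    its own bin.
    """
    _check_compat(model, binned)
    C, T = binned.counts.shape
    curves = model.kernel_curves()  # (C, C, L) at lags Δ..LΔ
    L = curves.shape[2]
    u = np.tile(model.base_rates[:, None], (1, T)).astype(float)
    counts = binned.counts.astype(float)
    for i in range(C):
        if not counts[i].any():
            continue
        # convolve sender i against its whole row of kernels at once
        if not curves[i].any():
            continue
        conv = oaconvolve(counts[i][None, :], curves[i], axes=1)[:, : T - 1]
        u[:, 1:] += conv
    return u


def intensity(model: NetworkModel, binned: BinnedEvents) -> np.ndarray:
    """Conditional intensity lambda_j(t) = sigma(u_j(t)), events/second."""
    return model.nonlinearity(linear_drive(model, binned))


def neg_log_likelihood(
    model: NetworkModel,
    binned: BinnedEvents,
    penalty: float = 0.0,
    *,
    with_grad: bool = False,
):
    """Penalised negative log-likelihood of the binned data under the model.

    NLL = Σ_j Σ_t [ λ_j(t)Δ − n_j(t) log(λ_j(t)Δ) + log n_j(t)! ]
          + penalty · ||kernel weights||²

    Base drives are unpenalised.  With ``with_grad`` also returns the exact
    gradient with respect to (base_rates, weights).
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    _check_compat(model, binned)
    dt = binned.bin_width
    n = binned.counts
    u = linear_drive(model, binned)
    lam = model.nonlinearity(u)
    loglam = model.nonlinearity.log(u)
    nll = float(np.sum(lam) * dt - np.sum(n * (loglam + math.log(dt)))
                + np.sum(gammaln(n + 1.0)))
    nll += penalty * float(np.sum(model.weights ** 2))
    if not np.isfinite(nll):
        nll = _HUGE
    if not with_grad:
        return nll

    # dNLL/du_j(t) = (Δ − n/λ) σ'(u); accumulate into b and weights
    sig_d = model.nonlinearity.deriv(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n > 0, n / np.maximum(lam, 1e-300), 0.0)
    g_u = (dt - ratio) * sig_d  # (C, T)
    grad_b = g_u.sum(axis=1)
    C, T = n.shape
    B = model.basis.n_basis
    bv = model.basis.basis_values  # (B, L)
    grad_w = np.zeros_like(model.weights)
    counts = binned.counts.astype(float)
    for i in range(C):
        if not counts[i].any():
            continue
        # design columns for sender i: D[t, b] = Σ_{k>=1} counts_i[t-k] bv_b(kΔ)
        conv = oaconvolve(counts[i][None, :], bv, axes=1)[:, : T - 1]
        grad_w[i, :, :] = g_u[:, 1:] @ conv.T
    grad_w += 2.0 * penalty * model.weights
    if not np.all(np.isfinite(grad_b)) or not np.all(np.isfinite(grad_w)):
        grad_b = np.nan_to_num(grad_b)
        grad_w = np.nan_to_num(grad_w)
    return nll, (grad_b, grad_w)
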
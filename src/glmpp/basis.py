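"""Raised-cosine temporal basis and influence kernels.

Influence kernels K_ij are represented as weighted sums of a small bank of
raised-cosine bumps whose peaks are spaced on a log-warped lag axis, so the
basis is denser at short lags where call interactions are fastest.  This is
the standard parameterisation for coupling filters in point-process GLMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BasisSet", "Kernel", "make_cosine_basis", "evaluate_kernel"]


@dataclass(frozen=True)
class BasisSet:
    """A bank of raised-cosine bumps over lags [0, support].

    Attributes
    ----------
    n_basis : int
        Number of bumps.
    support : float
        Kernel memory length in seconds; all bumps are zero beyond it.
    bin_width : float
        Time discretisation Δ (seconds) shared with the likelihood.
    stretch : float
        Log-warp offset; larger values make the spacing more linear,
        ``stretch <= 0`` disables warping entirely.
    centers, spacing : ndarray, float
        Bump peak positions and half-width in the warped coordinate.
    """

    n_basis: int
    support: float
    bin_width: float
    stretch: float
    centers: np.ndarray
    spacing: float

    def _warp(self, t: np.ndarray) -> np.ndarray:
        if self.stretch <= 0:
            return np.asarray(t, dtype=float)
        return np.log(np.asarray(t, dtype=float) + self.stretch)

    def evaluate(self, lags) -> np.ndarray:
        """Basis values, shape (n_basis, len(lags)); zero beyond support."""
        lags = np.atleast_1d(np.asarray(lags, dtype=float))
        x = self._warp(np.clip(lags, 0.0, None))
        out = np.zeros((self.n_basis, lags.size))
        for b, c in enumerate(self.centers):
            arg = (x - c) * np.pi / (2.0 * self.spacing)
            inside = np.abs(arg) <= np.pi
            out[b, inside] = 0.5 * (1.0 + np.cos(arg[inside]))
        out[:, (lags < 0) | (lags > self.support)] = 0.0
        return out

    @property
    def lag_grid(self) -> np.ndarray:
        """Strictly causal lag grid Δ, 2Δ, ..., L·Δ used by the likelihood."""
        n_lag = int(round(self.support / self.bin_width))
        return self.bin_width * np.arange(1, n_lag + 1)

    @property
    def basis_values(self) -> np.ndarray:
        """Basis sampled on the causal lag grid, shape (n_basis, n_lag)."""
        return self.evaluate(self.lag_grid)

    @property
    def peak_lags(self) -> np.ndarray:
        """Peak positions mapped back to seconds."""
        if self.stretch <= 0:
            return self.centers.copy()
        return np.exp(self.centers) - self.stretch

    def to_dict(self) -> dict:
        return {
            "n_basis": self.n_basis,
            "support": self.support,
            "bin_width": self.bin_width,
            "stretch": self.stretch,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSet":
        return make_cosine_basis(d["n_basis"], d["support"], d["bin_width"], d["stretch"])


def make_cosine_basis(
    n_basis: int = 8,
    support: float = 2.0,
    bin_width: float = 0.01,
    stretch: float = 0.1,
) -> BasisSet:
    """Build a raised-cosine basis with log-spaced peaks.

    Peaks are spaced linearly between warp(first_peak) and warp(0.8·support)
    in the warped coordinate warp(t) = log(t + stretch), so that the last
    bump has decayed essentially to zero by the end of the support.  The
    first peak is anchored at support/40 (50 ms for the default 2 s support
    — about the earliest a vocal response can begin), keeping the earliest
    bump wide enough to be estimable while still covering lag zero.  Each
    bump takes values in [0, 1] and is zero outside one half-period around
    its peak.
    """
    if n_basis < 1:
        raise ValueError("n_basis must be >= 1")
    if not (support > bin_width > 0):
        raise ValueError("require support > bin_width > 0")
    if stretch < 0:
        raise ValueError("stretch must be >= 0")
    probe = BasisSet(n_basis, support, bin_width, stretch,
                     centers=np.zeros(n_basis), spacing=1.0)
    first_peak = max(bin_width, support / 40.0)
    lo = float(probe._warp(np.array([first_peak]))[0])
    hi = float(probe._warp(np.array([0.8 * support]))[0])
    if n_basis == 1:
        centers = np.array([(lo + hi) / 2.0])
        spacing = (hi - lo) / 2.0 if hi > lo else 1.0
    else:
        centers = np.linspace(lo, hi, n_basis)
        spacing = float(centers[1] - centers[0])
    basis = BasisSet(n_basis, support, bin_width, stretch, centers=centers, spacing=spacing)
    vals = basis.basis_values
    if not np.all(np.isfinite(vals)):
        raise ValueError("basis values not finite")
    return basis


@dataclass
class Kernel:
    """A single influence curve: weighted combination of basis bumps."""

    weights: np.ndarray
    basis: BasisSet

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.basis.n_basis,):
            raise ValueError("weight vector length must equal n_basis")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel weights must be finite")

    def evaluate(self, lags) -> np.ndarray:
        return evaluate_kernel(self, lags)

    @classmethod
    def from_curve(cls, basis: BasisSet, lags, values) -> "Kernel":
        """Least-squares projection of a target curve onto the basis."""
        B = basis.evaluate(lags)  # (n_basis, n_lags)
        w, *_ = np.linalg.lstsq(B.T, np.asarray(values, dtype=float), rcond=None)
        return cls(w, basis)


def evaluate_kernel(kernel: Kernel, lags) -> np.ndarray:
    """Kernel value Σ_b w_b · basis_b(lag) at each lag; zero beyond support."""
    return kernel.weights @ kernel.basis.evaluate(lags)
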
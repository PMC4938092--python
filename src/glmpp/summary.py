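"""Kernel tables, aggregate bands, and the uncentered-PCA projection.

Fitted kernels are compared across directed pairs, sessions and relation
categories (self-self, self-partner, self-other) after evaluation on one
shared lag grid.  Dimensionality is reduced with *uncentered* PCA: the mean
curve is not subtracted, so the origin of the projected space keeps its
meaning as zero influence, and the distance of a kernel from the origin is
a simple scalar summary of its influence magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "KernelTable",
    "PCAProjection",
    "tabulate_kernels",
    "aggregate_band",
    "pca_project",
    "signed_magnitude",
]


@dataclass
class KernelTable:
    """One row per directed pair: metadata plus the kernel curve on a grid."""

    grid: np.ndarray  # shared lags (seconds)
    curves: np.ndarray  # (n_rows, n_lags)
    meta: pd.DataFrame  # sender, receiver, relation, session, [types]

    def __post_init__(self) -> None:
        if self.curves.shape[0] != len(self.meta):
            raise ValueError("curves and metadata row counts differ")
        if self.curves.shape[1] != len(self.grid):
            raise ValueError("curve length must match grid length")

    @property
    def n_rows(self) -> int:
        return self.curves.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"k_{k:03d}": self.curves[:, k] for k in range(len(self.grid))}
        return pd.concat([self.meta.reset_index(drop=True), pd.DataFrame(cols)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PCAProjection:
    """2-D uncentered-PCA coordinates of kernel curves.

    magnitudes are Euclidean distances from the origin of the projected
    space; because the PCA is uncentered the origin corresponds to the
    all-zero (no influence) kernel.
    """

    components: np.ndarray  # (n_components, n_lags), orthonormal rows
    coords: np.ndarray  # (n_rows, n_components)
    magnitudes: np.ndarray  # (n_rows,)
    explained: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _relation(sender_ind: str, receiver_ind: str, partner_map) -> str:
    if sender_ind == receiver_ind:
        return "self_self"
    if partner_map and partner_map.get(sender_ind) == receiver_ind:
        return "self_partner"
    return "self_other"


def tabulate_kernels(fits, partner_map=None, sessions=None, grid=None) -> KernelTable:
    """Evaluate every fitted kernel on one shared lag grid.

    Parameters
    ----------
    fits : list of FitResult
        One per session; all must share a compatible basis support.
    partner_map : dict, optional
        individual -> partner individual; enables the self_partner relation.
    sessions : list of str, optional
        Per-fit session labels (defaults to s0, s1, ...).
    grid : ndarray, optional
        Lag grid in seconds; defaults to 10 ms steps over [0, support].
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits given")
    support = min(f.model.basis.support for f in fits)
    if grid is None:
        grid = np.arange(0.0, support + 1e-9, 0.01)
    grid = np.asarray(grid, dtype=float)
    if grid.max() > support + 1e-9:
        raise ValueError("grid exceeds the kernel support of at least one fit")
    if sessions is None:
        sessions = [f"s{k}" for k in range(len(fits))]
    rows, curves = [], []
    for fit, sess in zip(fits, sessions):
        net = fit.model
        factor = None
        if fit.kernel_info:
            factor = {ch: fit.kernel_info[(ch, ch)] for ch in net.channels
                      if (ch, ch) in fit.kernel_info}
        for i, s in enumerate(net.channels):
            for j, r in enumerate(net.channels):
                s_ind = factor[s]["sender"] if factor else s
                r_ind = factor[r]["receiver"] if factor else r
                row = {
                    "sender": s, "receiver": r,
                    "sender_individual": s_ind, "receiver_individual": r_ind,
                    "relation": _relation(s_ind, r_ind, partner_map),
                    "session": sess,
                }
                if fit.kernel_info and (s, r) in fit.kernel_info:
                    ki = fit.kernel_info[(s, r)]
                    row["sender_type"] = ki["sender_type"]
                    row["receiver_type"] = ki["receiver_type"]
                    row["low_data"] = ki["low_data"]
                rows.append(row)
                curves.append(net.kernel(i, j).evaluate(grid))
    return KernelTable(grid=grid, curves=np.asarray(curves), meta=pd.DataFrame(rows))


def aggregate_band(kt: KernelTable, group_by: str = "relation",
                   percentiles=(5.0, 95.0)) -> dict:
    """Median curve and percentile band per category.

    Returns {category: {'median': curve, 'lo': curve, 'hi': curve, 'n': int}}.
    Empty categories are omitted (with a warning if the category level exists
    in the metadata but matches no rows).
    """
    out = {}
    for cat, idx in kt.meta.groupby(group_by).groups.items():
        sub = kt.curves[np.asarray(idx)]
        if sub.shape[0] == 0:
            warnings.warn(f"category {cat!r} has no kernels; omitted", stacklevel=2)
            continue
        out[cat] = {
            "median": np.median(sub, axis=0),
            "lo": np.percentile(sub, percentiles[0], axis=0),
            "hi": np.percentile(sub, percentiles[1], axis=0),
            "n": sub.shape[0],
        }
    return out


def pca_project(kt: KernelTable, n_components: int = 2) -> PCAProjection:
    """Uncentered PCA of the kernel table.

    The rows-by-grid matrix is decomposed by SVD without subtracting the
    mean; the top right-singular vectors are the components.  Sign
    convention: each component is flipped so that its largest-|loading|
    entry is positive, making projections reproducible.
    """
    if kt.n_rows < 2:
        raise ValueError("need at least 2 kernels for a PCA")
    M = kt.curves
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    comps = Vt[:n_components].copy()
    for k in range(comps.shape[0]):
        lead = np.argmax(np.abs(comps[k]))
        if comps[k, lead] < 0:
            comps[k] = -comps[k]
    coords = M @ comps.T
    mags = np.linalg.norm(coords, axis=1)
    total = float(np.sum(S ** 2))
    explained = (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PCAProjection(components=comps, coords=coords, magnitudes=mags,
                         explained=explained)


def signed_magnitude(kt: KernelTable, proj: PCAProjection) -> np.ndarray:
    """Magnitude with polarity: positive if the kernel's globally largest
    |value| is excitatory, negative if inhibitory; zero curve -> +0."""
    if proj.coords.shape[0] != kt.n_rows:
        raise ValueError("projection rows do not match table rows")
    out = np.empty(kt.n_rows)
    for r in range(kt.n_rows):
        c = kt.curves[r]
        k = int(np.argmax(np.abs(c)))
        sign = 1.0 if c[k] >= 0 else -1.0
        out[r] = sign * proj.magnitudes[r]
    return out
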
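"""Statistical tests and comparison analyses for influence networks.

Includes the multiple response permutation procedure (MRPP) on the 2-D
kernel projections, Latin-square day-to-day matchings and their matched
Pearson correlations, segment-to-segment predictability, the PSTH
correlation index, cross-correlation lag histograms, and a first-order
Markov transition baseline.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps

from .events import EventDataset

__all__ = [
    "MRPPResult",
    "CorrelationResult",
    "mrpp",
    "latin_matchings",
    "matched_correlation",
    "segment_predictability",
    "psth_index",
    "crosscorr_histogram",
    "markov_transitions",
]


@dataclass
class MRPPResult:
    """Multiple response permutation procedure outcome.

    observed_delta: group-size-weighted mean within-group pairwise distance.
    agreement_A: chance-corrected within-group agreement,
    A = 1 − observed/expected, where the expectation is over permutations.
    """

    observed_delta: float
    expected_delta: float
    agreement_A: float
    p_value: float
    n_perm: int
    seed: int | None = None
    method: str = "sampled"


@dataclass
class CorrelationResult:
    """Pearson correlation with a two-sided t-distribution p-value."""

    r: float
    p: float | None
    n: int
    label: str = ""
    flagged: bool = False


def _delta(dm: np.ndarray, labels: np.ndarray) -> float:
    """Weighted mean within-group distance, weights n_g / N."""
    N = len(labels)
    val = 0.0
    for g in np.unique(labels):
        idx = np.nonzero(labels == g)[0]
        n_g = len(idx)
        sub = dm[np.ix_(idx, idx)]
        mean_d = sub[np.triu_indices(n_g, k=1)].mean()
        val += (n_g / N) * mean_d
    return val


def _within_stratum_perms(labels, strata):
    """All distinct label arrangements obtained by permuting within strata."""
    strata = np.asarray(strata)
    groups = [np.nonzero(strata == s)[0] for s in np.unique(strata)]
    per_group = []
    for idx in groups:
        opts = sorted(set(itertools.permutations(labels[idx])))
        per_group.append(opts)
    for combo in itertools.product(*per_group):
        perm = np.array(labels, copy=True)
        for idx, arrangement in zip(groups, combo):
            perm[idx] = arrangement
        yield perm


def mrpp(points, labels, strata=None, n_perm: int = 999, seed: int | None = None,
         method: str = "sampled") -> MRPPResult:
    """MRPP test for between-group differences based on Euclidean distances.

    The observed statistic is the group-size-weighted mean within-group
    pairwise distance; the null is built by permuting group labels, within
    strata when given (e.g. stratifying by the identity of the listener).
    p uses the add-one estimator (1 + #{δ_perm ≤ δ_obs}) / (1 + n_perm), so
    p ≥ 1/(n_perm + 1).  ``method='exact'`` enumerates all distinct
    within-stratum label arrangements instead of sampling.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    N = len(labels)
    if points.shape[0] != N:
        raise ValueError("points and labels length mismatch")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group must have at least 2 items")
    strata_arr = np.zeros(N, dtype=int) if strata is None else np.asarray(strata)
    dm = squareform(pdist(points, metric="euclidean"))
    obs = _delta(dm, labels)

    if method == "exact":
        deltas = np.array([_delta(dm, p) for p in _within_stratum_perms(labels, strata_arr)])
        n_used = len(deltas)
        p_value = float(np.mean(deltas <= obs + 1e-12))
        expected = float(deltas.mean())
    elif method == "sampled":
        rng = np.random.default_rng(seed)
        deltas = np.empty(n_perm)
        perm = np.array(labels, copy=True)
        stratum_groups = [np.nonzero(strata_arr == s)[0] for s in np.unique(strata_arr)]
        for k in range(n_perm):
            for idx in stratum_groups:
                perm[idx] = perm[idx][rng.permutation(len(idx))]
            deltas[k] = _delta(dm, perm)
        n_used = n_perm
        p_value = float((1 + np.sum(deltas <= obs + 1e-12)) / (1 + n_perm))
        expected = float(deltas.mean())
    else:
        raise ValueError(f"unknown method {method!r}")

    if expected <= 0:
        warnings.warn("all pairwise distances are zero; agreement undefined, set to 0",
                      stacklevel=2)
        A = 0.0
    else:
        A = 1.0 - obs / expected
    return MRPPResult(observed_delta=float(obs), expected_delta=expected,
                      agreement_A=float(A), p_value=p_value, n_perm=int(n_used),
                      seed=seed, method=method)


def latin_matchings(ids_day1, ids_day2, locations_day1=None, locations_day2=None) -> dict:
    """Four ways of matching individuals on one day to the next.

    Returns a dict of label -> {id_day1: id_day2} bijections: 'individual'
    (identity on IDs), 'location' (same physical position on both days, if
    location maps are given), and two cyclic 'null' matchings with no
    meaningful interpretation, chosen distinct from the first two — rows of
    a Latin square over the group.
    """
    ids1, ids2 = list(ids_day1), list(ids_day2)
    if len(ids1) != len(ids2) or set(ids1) != set(ids2):
        raise ValueError("day 1 and day 2 must contain the same individuals")
    n = len(ids1)
    order = sorted(ids1)
    out = {"individual": {i: i for i in order}}
    if locations_day1 is not None and locations_day2 is not None:
        loc_to_id2 = {locations_day2[i]: i for i in order}
        if set(locations_day1[i] for i in order) != set(loc_to_id2):
            raise ValueError("location labels do not align across days")
        out["location"] = {i: loc_to_id2[locations_day1[i]] for i in order}
    else:
        warnings.warn("no location metadata; location matching omitted", stacklevel=2)
    taken = {tuple(m[i] for i in order) for m in out.values()}
    n_null = 0
    for shift in range(1, n):
        cand = {order[k]: order[(k + shift) % n] for k in range(n)}
        key = tuple(cand[i] for i in order)
        if key in taken:
            continue
        n_null += 1
        out[f"null{n_null}"] = cand
        taken.add(key)
        if n_null == 2:
            break
    return out


def _pearson(x: np.ndarray, y: np.ndarray, label: str) -> CorrelationResult:
    n = len(x)
    if n < 2 or np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(r=float("nan"), p=None, n=n, label=label, flagged=True)
    r, p = sps.pearsonr(x, y)
    if n < 3:
        return CorrelationResult(r=float(r), p=None, n=n, label=label, flagged=True)
    return CorrelationResult(r=float(r), p=float(p), n=n, label=label)


def matched_correlation(mags_day1: dict, mags_day2: dict, matching: dict,
                        label: str = "") -> CorrelationResult:
    """Correlate per-directed-pair magnitudes across days under a matching.

    ``mags_day*`` map directed pairs (sender, receiver) to signed kernel
    magnitudes; pair (i, j) on day 1 is compared with (m(i), m(j)) on day 2.
    Analyse self-self and self-other pairs separately: their kernels are
    different in kind.
    """
    x, y = [], []
    for (i, j), v in sorted(mags_day1.items()):
        key = (matching[i], matching[j])
        if key not in mags_day2:
            raise ValueError(f"matched pair {key} missing from day 2")
        x.append(v)
        y.append(mags_day2[key])
    return _pearson(np.asarray(x), np.asarray(y), label)


def segment_predictability(segment_mags) -> CorrelationResult:
    """How strongly one segment's magnitudes predict the immediately next.

    ``segment_mags`` is a sequence (ordered in time) of per-directed-pair
    magnitude vectors, or a list of such sequences (one per session).
    Sequential segment pairs are pooled across sessions before computing
    one Pearson correlation.
    """
    arrs = segment_mags
    if isinstance(arrs, np.ndarray) and arrs.ndim == 2:
        arrs = [arrs]
    elif len(arrs) and np.ndim(arrs[0]) == 1:
        arrs = [np.asarray(arrs)]
    x, y = [], []
    for sess in arrs:
        sess = np.asarray(sess, dtype=float)
        for k in range(sess.shape[0] - 1):
            x.extend(sess[k])
            y.extend(sess[k + 1])
    if not x:
        raise ValueError("need at least 2 segments")
    return _pearson(np.asarray(x), np.asarray(y), "segment")


def _merged_windows(stimuli: np.ndarray, lo: float, hi: float, duration: float):
    """Union of [t+lo, t+hi] windows clipped to [0, duration]."""
    starts = np.clip(stimuli + lo, 0.0, duration)
    ends = np.clip(stimuli + hi, 0.0, duration)
    merged = []
    for s, e in zip(starts, ends):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        elif e > s:
            merged.append((s, e))
    return merged


def psth_index(ds: EventDataset, window=(0.050, 0.500),
               include_self: bool = False) -> pd.DataFrame:
    """PSTH correlation index matrix: sender rows, receiver columns.

    For sender i and receiver j, the index is the rate of j's calls inside
    the union of windows [t+50 ms, t+500 ms] after each call t of i,
    divided by j's overall calling rate, minus 1.  Zero indicates
    statistical independence; undefined entries (receiver with no calls)
    are NaN.
    """
    if ds.n_channels < 2:
        raise ValueError("need at least 2 channels")
    lo, hi = window
    out = pd.DataFrame(np.nan, index=ds.channels, columns=ds.channels, dtype=float)
    for i in ds.channels:
        stim = ds.events[i]
        win = _merged_windows(stim, lo, hi, ds.duration)
        win_len = sum(e - s for s, e in win)
        for j in ds.channels:
            if i == j and not include_self:
                continue
            nj = len(ds.events[j])
            if nj == 0 or ds.duration <= 0:
                continue  # undefined, stays NaN
            if win_len == 0:
                continue
            t = ds.events[j]
            in_win = 0
            for s, e in win:
                in_win += int(np.searchsorted(t, e) - np.searchsorted(t, s))
            windowed_rate = in_win / win_len
            base_rate = nj / ds.duration
            out.loc[i, j] = windowed_rate / base_rate - 1.0
    return out


def crosscorr_histogram(ds: EventDataset, max_lag: float = 1.0,
                        bin_width: float = 0.01) -> dict:
    """Per-directed-pair histograms of positive lags t_j − t_i.

    Counts are normalised by the number of sender events, so a bin value is
    the mean number of receiver events at that lag per sender call.
    Returns {(i, j): (bin_edges, values)}.
    """
    if max_lag <= 0 or bin_width <= 0:
        raise ValueError("max_lag and bin_width must be positive")
    edges = np.arange(0.0, max_lag + bin_width / 2, bin_width)
    out = {}
    for i in ds.channels:
        ti = ds.events[i]
        for j in ds.channels:
            tj = ds.events[j]
            lags = []
            for t in ti:
                k0 = np.searchsorted(tj, t, side="right")
                k1 = np.searchsorted(tj, t + max_lag, side="right")
                lags.append(tj[k0:k1] - t)
            all_lags = np.concatenate(lags) if lags else np.empty(0)
            counts, _ = np.histogram(all_lags, bins=edges)
            norm = counts / max(len(ti), 1)
            out[(i, j)] = (edges, norm)
    return out


def markov_transitions(ds: EventDataset) -> pd.DataFrame:
    """First-order Markov transition matrix over the pooled call sequence.

    All events are pooled and time-ordered; the matrix holds the ML
    estimate counts[s -> s'] / counts[s -> .].  Rows with no outgoing
    transitions are NaN (flagged by construction).
    """
    seq = []
    for ch in ds.channels:
        for t in ds.events[ch]:
            seq.append((t, ch))
    if len(seq) < 2:
        raise ValueError("need at least 2 events in total")
    seq.sort(key=lambda x: (x[0], x[1]))
    symbols = [s for _, s in seq]
    counts = pd.DataFrame(0.0, index=ds.channels, columns=ds.channels)
    for a, b in zip(symbols[:-1], symbols[1:]):
        counts.loc[a, b] += 1
    totals = counts.sum(axis=1)
    probs = counts.div(totals.replace(0, np.nan), axis=0)
    return probs
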
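"""Maximal information coefficient (MIC) coupling between metric series.

MIC quantifies dependence between two series X, Y by gridding the scatter
plot with n_x x n_y axis-aligned grids, computing the empirical mutual
information I_g of the induced joint histogram for each grid g, and
normalizing by log2 min(n_x, n_y) so the score lies in [0, 1]:

    m_XY  = max_{g in G_xy} I_g / log2 min(n_x, n_y)
    MIC_XY = max_{n_x * n_y < B} m_XY,    B = N^0.6

with N the number of paired samples. The grid family depends only on the
sample orderings, so MIC is invariant under strictly monotone transforms
of either series, and captures nonlinear as well as linear coupling.

The full maximization is exponential, so the search follows the MINE
scheme: one axis is equipartitioned into q mass-balanced bins and the
other axis's partition is optimized by dynamic programming over candidate
cut points ("clumps", capped at ``clumps_c`` times the bin budget); both
axis orientations are searched and the larger score kept. When the
admissible grid family is small (N <= 25, where B restricts grids to
2x2 and 2x3) the search enumerates every cut placement exactly instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cardiac import CardiacIndexSeries
from .errors import InsufficientDataError
from .graph import METRICS, MetricSeries

__all__ = [
    "PairedSeries",
    "CouplingEstimate",
    "align_series",
    "grid_mutual_information",
    "mic",
    "mic_null",
    "coupling_table",
]

#: Largest sample size at which the exact grid enumeration is used.
EXACT_N_MAX = 25

CARDIAC_INDICES = ("csi", "cvi")


@dataclass(frozen=True)
class PairedSeries:
    """Complete (x, y) sample pairs on a common time grid."""

    x: np.ndarray
    y: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if not (x.size == y.size == t.size):
            raise ValueError("x, y, times must have equal length")
        keep = np.isfinite(x) & np.isfinite(y)
        object.__setattr__(self, "x", x[keep])
        object.__setattr__(self, "y", y[keep])
        object.__setattr__(self, "times", t[keep])

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class CouplingEstimate:
    """One MIC value for a (band, metric, cardiac index) combination."""

    mic: float
    best_grid: tuple[int, int]
    band: str = ""
    metric: str = ""
    cardiac_index: str = ""
    n_pairs: int = 0
    degenerate: bool = False


def align_series(
    metric_times: np.ndarray,
    metric_values: np.ndarray,
    cardiac_times: np.ndarray,
    cardiac_values: np.ndarray,
    tol: float = 0.5,
    min_pairs: int = 10,
) -> PairedSeries:
    """Pair two series by nearest-neighbor time matching within ``tol`` s.

    Rows with a missing member on either side are dropped (pairwise
    deletion, no interpolation).
    """
    mt = np.asarray(metric_times, dtype=float)
    ct = np.asarray(cardiac_times, dtype=float)
    mv = np.asarray(metric_values, dtype=float)
    cv = np.asarray(cardiac_values, dtype=float)
    if mt.size == 0 or ct.size == 0:
        raise InsufficientDataError("empty series")
    pos = np.searchsorted(ct, mt)
    pos = np.clip(pos, 1, ct.size - 1) if ct.size > 1 else np.zeros_like(pos)
    left = np.clip(pos - 1, 0, ct.size - 1)
    choose_left = np.abs(ct[left] - mt) <= np.abs(ct[np.clip(pos, 0, ct.size - 1)] - mt)
    nearest = np.where(choose_left, left, np.clip(pos, 0, ct.size - 1))
    ok = np.abs(ct[nearest] - mt) <= tol + 1e-12
    pair = PairedSeries(x=mv[ok], y=cv[nearest[ok]], times=mt[ok])
    if pair.n < min_pairs:
        raise InsufficientDataError(
            f"only {pair.n} complete pairs after alignment (need >= {min_pairs})"
        )
    return pair


def grid_mutual_information(
    x: np.ndarray, y: np.ndarray, edges_x: np.ndarray, edges_y: np.ndarray
) -> float:
    """Empirical mutual information (bits) of the binned joint histogram.

    ``edges_x``/``edges_y`` are interior cut values (strictly increasing);
    zero-count cells contribute 0.
    """
    edges_x = np.asarray(edges_x, dtype=float)
    edges_y = np.asarray(edges_y, dtype=float)
    for e in (edges_x, edges_y):
        if e.size and np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    xb = np.searchsorted(edges_x, x, side="right")
    yb = np.searchsorted(edges_y, y, side="right")
    p, q = edges_x.size + 1, edges_y.size + 1
    if p < 2 or q < 2:
        raise ValueError("need at least 2 bins per axis")
    joint = np.bincount(xb * q + yb, minlength=p * q).reshape(p, q).astype(float)
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    n = joint.sum()
    if n == 0:
        return 0.0
    pj = joint / n
    px = pj.sum(axis=1, keepdims=True)
    py = pj.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pj * np.log2(pj / (px * py))
    return float(np.nansum(terms))


# ----------------------------------------------------------------- MINE core


def _equipartition_assignment(v_sorted_runs: np.ndarray, n: int, q: int) -> np.ndarray:
    """Assign n points (given run lengths of equal sorted values) to q
    mass-balanced bins; equal values always share a bin. Returns the bin id
    per point in sorted order."""
    bins = np.empty(n, dtype=np.int64)
    target = n / q
    pos = 0
    b = 0
    filled = 0
    for run in v_sorted_runs:
        # advance to the next bin when the current one met its target
        if filled >= target * (b + 1) - 1e-9 and b < q - 1:
            b += 1
        bins[pos : pos + run] = b
        pos += run
        filled += run
    return bins


def _run_lengths(sorted_vals: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(np.diff(sorted_vals) != 0)
    bounds = np.concatenate([[-1], change, [sorted_vals.size - 1]])
    return np.diff(bounds)


def _superclump_boundaries(x_sorted: np.ndarray, cap: int) -> np.ndarray:
    """Candidate cut positions (indices into the sorted order, exclusive
    prefix lengths) respecting runs of equal x, at most ``cap`` groups."""
    runs = _run_lengths(x_sorted)
    ends = np.cumsum(runs)  # clump end positions, last == n
    if ends.size <= cap:
        return ends
    # merge clumps into ~cap mass-balanced superclumps
    n = x_sorted.size
    target = n / cap
    keep = []
    acc = 0
    for e in ends:
        if e - acc >= target - 1e-9 or e == n:
            keep.append(e)
            acc = e
    return np.asarray(keep, dtype=np.int64)


def _optimize_axis(
    x: np.ndarray, y: np.ndarray, B: float, c: int
) -> dict[tuple[int, int], float]:
    """For each q-equipartition of y, DP-optimize the x partition.

    Returns {(p, q): I} for every admissible grid shape with p bins on the
    optimized axis and q on the equipartitioned axis.
    """
    n = x.size
    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]

    results: dict[tuple[int, int], float] = {}
    q_max = int(np.floor(B / 2.0 - 1e-12))
    for q in range(2, q_max + 1):
        p_max = int(np.ceil(B / q) - 1)
        if p_max * q >= B:  # guard the strict inequality
            p_max -= 1
        if p_max < 2:
            continue
        # equipartition of y (ties share bins)
        y_order = np.argsort(ys, kind="stable")
        y_sorted = ys[y_order]
        yb_sorted = _equipartition_assignment(_run_lengths(y_sorted), n, q)
        ybin = np.empty(n, dtype=np.int64)
        ybin[y_order] = yb_sorted
        q_eff = int(ybin.max()) + 1
        if q_eff < 2:
            continue
        counts_q = np.bincount(ybin, minlength=q_eff).astype(float)
        h_q = -np.sum(
            (counts_q[counts_q > 0] / n) * np.log2(counts_q[counts_q > 0] / n)
        )

        cuts = _superclump_boundaries(xs, cap=max(c * p_max, p_max + 1))
        k = cuts.size  # number of candidate groups; cuts[-1] == n
        if k < 2:
            continue
        # cumulative y-bin counts at each candidate boundary (prefix 0 first)
        cum = np.zeros((k + 1, q_eff))
        prefix = np.zeros(q_eff)
        prev = 0
        for gi, e in enumerate(cuts):
            seg = ybin[prev:e]
            prefix = prefix + np.bincount(seg, minlength=q_eff)
            cum[gi + 1] = prefix
            prev = e

        # phi[s, t]: score of an x-bin covering groups (s, t]
        cell = cum[None, :, :] - cum[:, None, :]  # (s, t, q)
        tot = cell.sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            cell_term = np.where(cell > 0, (cell / n) * np.log2(cell / n), 0.0)
            tot_term = np.where(tot > 0, (tot / n) * np.log2(tot / n), 0.0)
        phi = -tot_term + cell_term.sum(axis=2)

        s_idx, t_idx = np.meshgrid(np.arange(k + 1), np.arange(k + 1), indexing="ij")
        invalid = s_idx >= t_idx
        f_prev = phi[0].copy()  # p = 1 bins ending at t
        f_prev[0] = -np.inf
        for p in range(2, p_max + 1):
            cand = f_prev[:, None] + phi
            cand[invalid] = -np.inf
            f_cur = cand.max(axis=0)
            i_pq = h_q + f_cur[k]
            if np.isfinite(i_pq):
                key = (p, q_eff)
                results[key] = max(results.get(key, -np.inf), float(i_pq))
            f_prev = f_cur
    return results


def _approx_mic(x: np.ndarray, y: np.ndarray, B: float, c: int):
    best = (0.0, (2, 2))
    for xx, yy, flip in ((x, y, False), (y, x, True)):
        for (p, q), i_val in _optimize_axis(xx, yy, B, c).items():
            score = i_val / np.log2(min(p, q))
            grid = (p, q) if not flip else (q, p)
            if score > best[0] + 1e-12:
                best = (score, grid)
    return min(best[0], 1.0), best[1]


# ------------------------------------------------------------- exact search


def _value_boundaries(v: np.ndarray) -> np.ndarray:
    """Cut positions (prefix lengths) between distinct sorted values."""
    sv = np.sort(v)
    return np.cumsum(_run_lengths(sv))[:-1]


def _exact_mic(x: np.ndarray, y: np.ndarray, B: float):
    """Enumerate every admissible grid placement (small n only)."""
    n = x.size
    order_x = np.argsort(x, kind="stable")
    order_y = np.argsort(y, kind="stable")
    posx = np.empty(n, dtype=np.int64)
    posx[order_x] = np.arange(n)
    posy = np.empty(n, dtype=np.int64)
    posy[order_y] = np.arange(n)
    bx = _value_boundaries(x)
    by = _value_boundaries(y)

    # cumulative 2D rank count: C[i, j] = #{points: posx < i and posy < j}
    grid_c = np.zeros((n + 1, n + 1), dtype=np.int64)
    grid_c[posx + 1, posy + 1] = 1
    grid_c = np.cumsum(np.cumsum(grid_c, axis=0), axis=1)

    def joint_counts(cuts_x, cuts_y):
        ex = np.concatenate([[0], cuts_x, [n]])
        ey = np.concatenate([[0], cuts_y, [n]])
        sub = grid_c[np.ix_(ex, ey)]
        return np.diff(np.diff(sub, axis=0), axis=1)

    best = (0.0, (2, 2))
    q_hi = int(np.floor(B / 2.0 - 1e-12))
    for p in range(2, q_hi + 1):
        for q in range(2, q_hi + 1):
            if p * q >= B:
                continue
            if len(bx) < p - 1 or len(by) < q - 1:
                continue
            norm = np.log2(min(p, q))
            for cuts_x in combinations(bx, p - 1):
                for cuts_y in combinations(by, q - 1):
                    joint = joint_counts(np.asarray(cuts_x), np.asarray(cuts_y))
                    score = _mi_from_joint(joint.astype(float)) / norm
                    if score > best[0] + 1e-12:
                        best = (score, (p, q))
    return min(best[0], 1.0), best[1]


def mic(
    pair: PairedSeries,
    alpha_exp: float = 0.6,
    clumps_c: int = 15,
    method: str = "auto",
    **labels,
) -> CouplingEstimate:
    """Maximal information coefficient of a paired series.

    ``method`` is ``'auto'`` (exact enumeration for n <= 25, MINE search
    beyond), ``'exact'`` or ``'approx'``. Constant input yields 0 with the
    degenerate flag set.
    """
    n = pair.n
    if n < 10:
        raise InsufficientDataError(f"MIC needs >= 10 pairs (got {n})")
    x, y = pair.x, pair.y
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CouplingEstimate(
            mic=0.0, best_grid=(0, 0), n_pairs=n, degenerate=True, **labels
        )
    B = float(n) ** alpha_exp
    if B <= 4.0:
        raise InsufficientDataError(
            f"B = n^{alpha_exp} = {B:.2f} <= 4: no admissible 2x2 grid"
        )
    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "approx"
    if method == "exact":
        value, grid = _exact_mic(x, y, B)
    elif method == "approx":
        value, grid = _approx_mic(x, y, B, clumps_c)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CouplingEstimate(
        mic=value, best_grid=grid, n_pairs=n, degenerate=False, **labels
    )


def mic_null(
    pair: PairedSeries,
    n_perm: int = 99,
    seed: int = 0,
    method: str = "circular",
    min_shift: int = 35,
    **mic_kwargs,
) -> np.ndarray:
    """Permutation null distribution of MIC for one pair.

    ``method='circular'`` rotates the y series by a random offset each
    draw, preserving both series' autocorrelation (appropriate for the
    smooth 1-s metric/cardiac series); offsets within ``min_shift``
    samples of zero (mod n) are excluded so surrogates are actually
    decorrelated from the original — choose it larger than the dominant
    autocorrelation time of the series. ``method='shuffle'`` permutes y
    freely (appropriate for exchangeable samples).
    """
    rng = np.random.default_rng(seed)
    n = pair.n
    lo = min(min_shift, n // 3) if method == "circular" else 1
    null = np.empty(n_perm)
    for i in range(n_perm):
        if method == "circular":
            shift = int(rng.integers(lo, n - lo + 1))
            y_perm = np.roll(pair.y, shift)
        elif method == "shuffle":
            y_perm = rng.permutation(pair.y)
        else:
            raise ValueError(f"unknown null method {method!r}")
        surrogate = PairedSeries(x=pair.x, y=y_perm, times=pair.times)
        null[i] = mic(surrogate, **mic_kwargs).mic
    return null


def coupling_table(
    metric_series: list[MetricSeries],
    cardiac: CardiacIndexSeries,
    alpha_exp: float = 0.6,
    clumps_c: int = 15,
    tol: float = 0.5,
) -> pd.DataFrame:
    """MIC for every (band x metric x cardiac index) combination.

    With the three canonical bands and four metrics this is the 24-row
    factorial coupling table for one subject/condition.
    """
    rows = []
    for ms in metric_series:
        for metric in METRICS:
            mv = ms.values[metric].to_numpy()
            for index_name in CARDIAC_INDICES:
                cv = getattr(cardiac, index_name)
                pair = align_series(ms.times, mv, cardiac.times, cv, tol=tol)
                est = mic(
                    pair,
                    alpha_exp=alpha_exp,
                    clumps_c=clumps_c,
                    band=ms.band,
                    metric=metric,
                    cardiac_index=index_name,
                )
                rows.append(
                    {
                        "band": est.band,
                        "metric": est.metric,
                        "cardiac_index": est.cardiac_index,
                        "mic": est.mic,
                        "n_pairs": est.n_pairs,
                        "best_grid": f"{est.best_grid[0]}x{est.best_grid[1]}",
                    }
                )
    return pd.DataFrame(rows)
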
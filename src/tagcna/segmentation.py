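"""Circular binary segmentation (CBS) for 1-D profiles.

The engine partitions a series into blocks of homogeneous mean by recursively
searching for the pair of split points (an arc of the series viewed as a
circle) that maximises a two-sample t statistic between the arc and its
complement, accepting a split when its permutation p-value falls below
``alpha``.  It drives two steps of the pipeline: partitioning the windowed
correlation profile into correlation blocks, and (optionally) re-segmenting a
subject's raw log2-ratios before thresholding.

Numerical notes
---------------
* Within-interval values are centred before computing the statistic, and a
  variance floor treats effectively-constant groups as exact: a zero pooled
  variance with a non-zero mean difference scores ``+inf`` (a perfect split),
  with a zero mean difference it scores ``0``.
* For intervals longer than 128 points the arc-length search runs on a
  geometric grid (all lengths up to 32, then multiplicative steps, mirrored
  from both ends of the interval).  Observed and permuted series share the
  grid, so the permutation test remains exchangeable; below 128 the search is
  exhaustive.
* Ties in the argmax are broken toward the leftmost pair (smallest arc start,
  then smallest arc end), making results deterministic.
* The permutation loop stops early once enough permuted maxima exceed the
  observed one to rule out significance at ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from numba import njit

__all__ = ["Segmentation", "cbs_segment", "segment_subject", "segment_cohort",
           "best_circular_split"]

_EXHAUSTIVE_MAX = 128
_GRID_DENSE = 32
_GRID_FACTOR = 1.12


@dataclass(frozen=True)
class Segmentation:
    """Blocks of a segmented series: start indices and per-block means."""

    breakpoints: np.ndarray  # ordered block start indices; first is 0
    segment_means: np.ndarray
    n: int

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=np.int64)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(
            self, "segment_means", np.asarray(self.segment_means, dtype=np.float64)
        )
        if bp.size == 0 or bp[0] != 0:
            raise ValueError("breakpoints must start at 0")
        if np.any(np.diff(bp) <= 0) or bp[-1] >= self.n:
            raise ValueError("breakpoints must be strictly increasing and < n")
        if len(self.segment_means) != bp.size:
            raise ValueError("one mean per block required")

    @property
    def n_blocks(self) -> int:
        return len(self.breakpoints)

    def blocks(self) -> list:
        """Half-open (start, end) index pairs covering [0, n)."""
        ends = np.append(self.breakpoints[1:], self.n)
        return [(int(s), int(e)) for s, e in zip(self.breakpoints, ends)]

    def expand(self) -> np.ndarray:
        """Piecewise-constant series of block means."""
        out = np.empty(self.n)
        for (s, e), m in zip(self.blocks(), self.segment_means):
            out[s:e] = m
        return out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _arc_lengths(n: int, min_width: int) -> np.ndarray:
    """Candidate arc lengths for an interval of length n."""
    lo = max(min_width, 1)
    hi = n - lo
    if lo > hi:
        return np.empty(0, dtype=np.int64)
    if n <= _EXHAUSTIVE_MAX:
        return np.arange(lo, hi + 1, dtype=np.int64)
    base = list(range(1, _GRID_DENSE + 1))
    v = _GRID_DENSE
    while v < n:
        v = max(v + 1, int(round(v * _GRID_FACTOR)))
        base.append(v)
    base = np.asarray(base, dtype=np.int64)
    ks = np.unique(np.concatenate([base, n - base]))
    return ks[(ks >= lo) & (ks <= hi)]


@njit(cache=True)
def _arc_scan(Y, ks, min_width, i_step):  # pragma: no cover - via wrappers
    """Max squared two-sample t over candidate arcs, per row of Y.

    Rows are centred already.  Arc starts are scanned with stride ``i_step``
    (always including 0 and the right-flush start); candidate arc lengths are
    ``ks``.  Returns the per-row maxima plus the leftmost maximising arc
    (start i, length k) of row 0.  Degenerate pooled variance counts as a
    perfect split (+inf) when the group means differ and as 0 when they do
    not.
    """
    B, n = Y.shape
    best = np.full(B, -np.inf)
    best_i = -1
    best_k = -1
    cs = np.zeros(n + 1)
    cq = np.zeros(n + 1)
    dof = float(max(n - 2, 1))
    for b in range(B):
        s = 0.0
        q = 0.0
        for t in range(n):
            v = Y[b, t]
            s += v
            q += v * v
            cs[t + 1] = s
            cq[t + 1] = q
        S = cs[n]
        Q = cq[n]
        var_floor = 1e-18 * max(1.0, Q / n)
        bb = -np.inf
        bi = -1
        bk = -1
        for ki in range(ks.shape[0]):
            k = int(ks[ki])
            nc = n - k
            rk = 1.0 / k
            rc = 1.0 / nc
            ck = (rk + rc) / dof
            i = 0
            while i <= nc:
                r = nc - i
                if (i == 0 or i >= min_width) and (r == 0 or r >= min_width):
                    Sa = cs[i + k] - cs[i]
                    Sc = S - Sa
                    md = Sa * rk - Sc * rc
                    Qa = cq[i + k] - cq[i]
                    ss = (Qa - Sa * Sa * rk) + ((Q - Qa) - Sc * Sc * rc)
                    denom = ss * ck
                    if denom <= var_floor:
                        t2 = np.inf if md * md > var_floor else 0.0
                    else:
                        t2 = md * md / denom
                    if t2 > bb:
                        bb = t2
                        bi = i
                        bk = k
                    elif t2 == bb and i < bi:
                        bi = i
                        bk = k
                if i == nc:
                    break
                i = nc if i + i_step > nc else i + i_step
        best[b] = bb
        if b == 0:
            best_i = bi
            best_k = bk
    return best, best_i, best_k


def _start_stride(n: int) -> int:
    """Arc-start scan stride: exhaustive up to 256 points, then coarsened.

    Coarse boundaries placed at long intervals are refined implicitly: the
    recursion re-examines each piece at a finer stride, so residual slivers
    next to a misplaced boundary can still be split off.
    """
    return max(1, n // 256)


def _max_arc_stat(y: np.ndarray, ks: np.ndarray, min_width: int):
    """Max squared t statistic over arcs for a batch of series.

    Parameters
    ----------
    y : (B, n) array, each row one (permuted) series.

    Returns
    -------
    best : (B,) max t^2 per row
    arg : (i, k) of the leftmost maximising arc of row 0
    """
    y = np.ascontiguousarray(y - y.mean(axis=1, keepdims=True))
    best, best_i, best_k = _arc_scan(
        y, np.asarray(ks, dtype=np.int64), int(min_width), _start_stride(y.shape[1])
    )
    return best, (best_i, best_k)


def best_circular_split(series, min_width: int = 1):
    """Leftmost arc (i, j) maximising the circular two-sample t statistic.

    Returns ``(i, j, t2)`` where the arc is ``series[i:j]``, or ``None`` when
    no arc satisfies the width constraint.  Exposed mainly so the search can
    be validated against brute-force enumeration on small inputs.
    """
    y = np.asarray(series, dtype=np.float64)
    n = y.size
    ks = _arc_lengths(n, min_width)
    if ks.size == 0:
        return None
    best, (i, k) = _max_arc_stat(y[None, :], ks, min_width)
    if i < 0:
        return None
    return i, i + k, float(best[0])


def _refine_split(y, ks, i, k, min_width):
    """Re-localise an accepted split exhaustively around the grid optimum.

    Only the *placement* of the boundaries is refined (stride 1, arc lengths
    between the chosen grid length's neighbours); the accept/reject decision
    already happened on the shared grid, so this cannot bias the test.
    """
    n = y.size
    if n <= _EXHAUSTIVE_MAX and _start_stride(n) == 1:
        return i, k
    lo_w = max(min_width, 1)
    pos = int(np.searchsorted(ks, k))
    lo = int(ks[pos - 1]) + 1 if pos > 0 else lo_w
    hi = int(ks[pos + 1]) - 1 if pos + 1 < ks.size else n - lo_w
    kr = np.arange(max(lo, lo_w), min(hi, n - lo_w) + 1, dtype=np.int64)
    kr = np.union1d(kr, np.asarray([k], dtype=np.int64))
    y0 = np.ascontiguousarray(y - y.mean())[None, :]
    _, bi, bk = _arc_scan(y0, kr, int(min_width), 1)
    if bi < 0:
        return i, k
    return bi, bk


def _split_significant(y, alpha, min_width, n_perm, rng):
    """Return accepted split boundaries within y, or None."""
    n = y.size
    ks = _arc_lengths(n, min_width)
    if ks.size == 0:
        return None
    obs, (i, k) = _max_arc_stat(y[None, :], ks, min_width)
    t2_obs = float(obs[0])
    if not (t2_obs > 0):
        return None
    n_stop = ceil(alpha * n_perm - 1e-9)  # reaching this count rules out p < alpha
    count = 0
    done = 0
    chunk = 8  # grows geometrically: null splits stop after a handful of draws
    while done < n_perm and count < n_stop:
        c = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(y, (c, 1)), axis=1)
        pm, _ = _max_arc_stat(perms, ks, min_width)
        count += int(np.sum(pm >= t2_obs))
        done += c
        chunk = min(chunk * 2, 128)
    if count >= n_stop:  # p >= alpha certain
        return None
    i, k = _refine_split(y, ks, i, k, min_width)
    return i, i + k


def cbs_segment(series, alpha: float = 0.01, min_width: int = 2,
                n_perm: int = 200, seed=0) -> Segmentation:
    """Recursively segment ``series`` with permutation-tested circular splits.

    Parameters
    ----------
    series : 1-D array of finite values.
    alpha : per-split significance level of the permutation test.
    min_width : smallest block the recursion may create.
    n_perm : permutations per split test (stopped early when futile).
    seed : int seed or ``numpy.random.Generator``.
    """
    y = np.asarray(series, dtype=np.float64)
    if y.ndim != 1 or y.size < 1:
        raise ValueError("series must be a non-empty 1-D array")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    rng = _as_rng(seed)

    starts: list = []

    def recurse(lo: int, hi: int) -> None:
        starts.append(lo)
        if hi - lo < 2:
            return
        split = _split_significant(y[lo:hi], alpha, min_width, n_perm, rng)
        if split is None:
            return
        i, j = split
        starts.pop()  # replaced by the pieces
        for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
            if b > a:
                recurse(a, b)

    recurse(0, y.size)
    bp = np.asarray(sorted(starts), dtype=np.int64)
    ends = np.append(bp[1:], y.size)
    means = np.array([y[s:e].mean() for s, e in zip(bp, ends)])
    return Segmentation(bp, means, y.size)


def segment_subject(ratios, alpha: float = 0.01, min_width: int = 2,
                    n_perm: int = 200, seed=0) -> np.ndarray:
    """Segment one subject's raw ratios; return the piecewise-constant means."""
    return cbs_segment(ratios, alpha, min_width, n_perm, seed).expand()


def segment_cohort(values, alpha: float = 0.01, min_width: int = 2,
                   n_perm: int = 200, seed=0) -> np.ndarray:
    """Apply :func:`segment_subject` to every row of a subjects x markers array."""
    values = np.asarray(values, dtype=np.float64)
    rng = _as_rng(seed)
    out = np.empty_like(values)
    for i in range(values.shape[0]):
        out[i] = segment_subject(values[i], alpha, min_width, n_perm, rng)
    return out
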
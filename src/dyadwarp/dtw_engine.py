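"""Dynamic time warping with Rabiner–Juang step patterns.

Implements anchored (global) DTW over multivariate sequences under the
classical Rabiner–Juang taxonomy of local continuity constraints.  A step
pattern is a set of *chains*: composite moves made of elementary steps
``(di, dj)``, each step carrying a slope weight.  The accumulated cost of a
path is the weighted sum of local distances at every cell the path visits;
the reported distance is the accumulated cost normalized, by default, by the
number of aligned index pairs on the optimal path (the "average pairwise
distance at each aligned data point").

The taxonomy covers types I–VII with the four slope weightings

* ``a`` — min(di, dj) per elementary step
* ``b`` — max(di, dj)
* ``c`` — di (asymmetric: steps that do not advance the reference are free)
* ``d`` — di + dj (symmetric)

and the "smoothed" variants in which the total weight of a chain is spread
evenly over its steps.  The pipeline default is type VI with weighting c
(``RJ-VI-c``), whose slope is confined to [2/3, 3/2]: at most two diagonal
steps may be followed by one horizontal or vertical step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

__all__ = [
    "StepPattern",
    "WarpResult",
    "DtwError",
    "DtwInfeasibleError",
    "local_distance",
    "rj_step_pattern",
    "dtw_align",
    "brute_force_dtw",
    "max_path_offset",
]


class DtwError(ValueError):
    """Invalid input to the DTW engine."""


class DtwInfeasibleError(DtwError):
    """No legal path connects (1,1) to (N,M) under the step pattern."""


NORMALIZATION_RULES = ("aligned_pairs", "reference_length", "query_length", "sum_lengths")


@dataclass(frozen=True)
class StepPattern:
    """A weighted local-continuity constraint.

    ``chains`` is a tuple of composite moves; each chain is a tuple of
    elementary steps ``(di, dj, weight)`` listed from the start of the move
    to its end.  ``normalization_rule`` is the default rule applied by
    :func:`dtw_align` for this pattern.
    """

    id: str
    chains: tuple
    normalization_rule: str = "aligned_pairs"

    def __post_init__(self) -> None:
        if not self.chains:
            raise DtwError("step pattern must have at least one chain")
        if self.normalization_rule not in NORMALIZATION_RULES:
            raise DtwError(f"unknown normalization rule {self.normalization_rule!r}")
        for chain in self.chains:
            if not chain:
                raise DtwError("empty chain in step pattern")
            ti = sum(s[0] for s in chain)
            tj = sum(s[1] for s in chain)
            if (ti, tj) == (0, 0):
                raise DtwError("chain with zero total displacement")
            for di, dj, w in chain:
                if di < 0 or dj < 0 or w < 0:
                    raise DtwError("negative step component or weight")

    @property
    def totals(self) -> list:
        """Total (di, dj) displacement of each chain."""
        return [(sum(s[0] for s in c), sum(s[1] for s in c)) for c in self.chains]

    def transposed(self) -> "StepPattern":
        """The pattern with the roles of the two sequences swapped."""
        chains = tuple(tuple((dj, di, w) for di, dj, w in c) for c in self.chains)
        rule = {
            "reference_length": "query_length",
            "query_length": "reference_length",
        }.get(self.normalization_rule, self.normalization_rule)
        return StepPattern(self.id + "-T", chains, rule)

    def __str__(self) -> str:  # readable recursion, g = accumulated cost
        lines = [f"StepPattern {self.id} (normalization: {self.normalization_rule})"]
        lines.append("g[i,j] = min(")
        for chain, (ti, tj) in zip(self.chains, self.totals):
            terms = [f"g[i-{ti},j-{tj}]"]
            ri, rj = ti, tj
            for di, dj, w in chain:
                ri -= di
                rj -= dj
                if w != 0:
                    wtxt = "" if w == 1 else f"{w:g}*"
                    terms.append(f"{wtxt}d[i-{ri},j-{rj}]")
            lines.append("    " + " + ".join(terms) + " ,")
        lines.append(")")
        return "\n".join(lines).replace("-0", "")


# --- Rabiner–Juang taxonomy -------------------------------------------------
#
# Local continuity constraints, types I..VII.  Each chain is written from the
# start of the composite move to its end; the bare diagonal chain is listed
# first so that cost ties resolve toward the diagonal transition.

_RJ_CHAINS = {
    1: [[(1, 1)], [(1, 0)], [(0, 1)]],
    2: [[(1, 1)], [(1, 1), (1, 0)], [(1, 1), (0, 1)]],
    3: [[(1, 1)], [(2, 1)], [(1, 2)]],
    4: [[(1, 1)], [(1, 2)], [(1, 1), (1, 0)], [(1, 2), (1, 0)]],
    5: [
        [(1, 1)],
        [(1, 1), (1, 0)],
        [(1, 1), (1, 0), (1, 0)],
        [(1, 1), (0, 1)],
        [(1, 1), (0, 1), (0, 1)],
    ],
    6: [[(1, 1)], [(1, 1), (1, 1), (1, 0)], [(1, 1), (1, 1), (0, 1)]],
    7: [
        [(1, 1)],
        [(1, 1), (1, 0)],
        [(1, 1), (1, 0), (1, 0)],
        [(1, 1), (1, 0), (1, 0), (1, 0)],
    ],
}

_WEIGHTINGS = {
    "a": lambda di, dj: min(di, dj),
    "b": lambda di, dj: max(di, dj),
    "c": lambda di, dj: di,
    "d": lambda di, dj: di + dj,
}


def rj_step_pattern(type: int, weighting: str = "c", smoothed: bool = False) -> StepPattern:
    """Construct a step pattern from the Rabiner–Juang taxonomy.

    Parameters
    ----------
    type
        Local-continuity constraint type, 1..7 (printed I..VII).
    weighting
        Slope weighting: ``a`` min(di,dj), ``b`` max(di,dj), ``c`` di,
        ``d`` di+dj, applied per elementary step.
    smoothed
        If true, spread each chain's total weight evenly over its steps.

    The pipeline default is ``rj_step_pattern(6, "c", False)`` ("RJ-VI-c"),
    chosen because its slope bounds allow only moderate local time
    distortion and its geometry is symmetric in the two interactants.
    """
    if type not in _RJ_CHAINS:
        raise DtwError(
            f"undefined Rabiner–Juang type {type!r}; valid types: {sorted(_RJ_CHAINS)}"
        )
    if weighting not in _WEIGHTINGS:
        raise DtwError(
            f"undefined slope weighting {weighting!r}; valid weightings: "
            f"{sorted(_WEIGHTINGS)}"
        )
    wfun = _WEIGHTINGS[weighting]
    chains = []
    for raw in _RJ_CHAINS[type]:
        ws = [float(wfun(di, dj)) for di, dj in raw]
        if smoothed:
            mean_w = sum(ws) / len(ws)
            ws = [mean_w] * len(ws)
        chains.append(tuple((di, dj, w) for (di, dj), w in zip(raw, ws)))
    roman = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII"}
    pid = f"RJ-{roman[type]}-{weighting}" + ("-s" if smoothed else "")
    return StepPattern(pid, tuple(chains))


@dataclass(frozen=True)
class WarpResult:
    """Optimal anchored alignment of two sequences.

    ``path`` holds 1-based index pairs (i, j) for every visited cell, from
    (1, 1) to (N, M).  ``normalized_distance`` is ``accumulated_cost``
    normalized per ``norm_rule``.
    """

    path: np.ndarray
    accumulated_cost: float
    normalized_distance: float
    pattern_id: str
    N: int
    M: int
    norm_rule: str = "aligned_pairs"


def local_distance(x_frame: Sequence[float], y_frame: Sequence[float]) -> float:
    """Euclidean distance between two frames of equal dimensionality."""
    a = np.asarray(x_frame, dtype=float)
    b = np.asarray(y_frame, dtype=float)
    if a.shape != b.shape:
        raise DtwError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _as_matrix(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2 or a.shape[0] == 0:
        raise DtwError("input sequence must be a non-empty 1-D or 2-D array")
    return a


def _pattern_arrays(pattern: StepPattern):
    tot_i, tot_j, ptr, oi, oj, w = [], [], [0], [], [], []
    for chain in pattern.chains:
        ti = sum(s[0] for s in chain)
        tj = sum(s[1] for s in chain)
        tot_i.append(ti)
        tot_j.append(tj)
        ri, rj = ti, tj
        for di, dj, wt in chain:
            ri -= di
            rj -= dj
            oi.append(ri)  # landing cell offset back from chain end
            oj.append(rj)
            w.append(wt)
        ptr.append(len(oi))
    return (
        np.array(tot_i, dtype=np.int64),
        np.array(tot_j, dtype=np.int64),
        np.array(ptr, dtype=np.int64),
        np.array(oi, dtype=np.int64),
        np.array(oj, dtype=np.int64),
        np.array(w, dtype=np.float64),
    )


@njit(cache=True)
def _dp_kernel(D, tot_i, tot_j, ptr, oi, oj, w, win):  # pragma: no cover - jit
    N, M = D.shape
    g = np.full((N, M), np.inf)
    choice = np.full((N, M), -1, dtype=np.int64)
    g[0, 0] = D[0, 0]
    nc = tot_i.shape[0]
    for i in range(N):
        for j in range(M):
            if i == 0 and j == 0:
                continue
            if win >= 0 and abs(i - j) > win:
                continue
            best = np.inf
            bc = -1
            for c in range(nc):
                pi = i - tot_i[c]
                pj = j - tot_j[c]
                if pi < 0 or pj < 0:
                    continue
                prev = g[pi, pj]
                if not np.isfinite(prev):
                    continue
                cost = prev
                for k in range(ptr[c], ptr[c + 1]):
                    cost += w[k] * D[i - oi[k], j - oj[k]]
                if cost < best:
                    best = cost
                    bc = c
            g[i, j] = best
            choice[i, j] = bc
    return g, choice


def _traceback(choice: np.ndarray, pattern: StepPattern) -> np.ndarray:
    N, M = choice.shape
    totals = pattern.totals
    cells = [(N - 1, M - 1)]
    i, j = N - 1, M - 1
    while (i, j) != (0, 0):
        c = choice[i, j]
        chain = pattern.chains[c]
        ti, tj = totals[c]
        si, sj = i - ti, j - tj  # chain start cell
        inter = []
        ri, rj = si, sj
        for di, dj, _ in chain[:-1]:
            ri += di
            rj += dj
            inter.append((ri, rj))
        for cell in reversed(inter):
            cells.append(cell)
        cells.append((si, sj))
        i, j = si, sj
    cells.reverse()
    return np.array(cells, dtype=np.int64) + 1  # 1-based


def _normalize(cost: float, rule: str, n_pairs: int, N: int, M: int) -> float:
    if rule == "aligned_pairs":
        return cost / n_pairs
    if rule == "reference_length":
        return cost / N
    if rule == "query_length":
        return cost / M
    if rule == "sum_lengths":
        return cost / (N + M)
    raise DtwError(f"unknown normalization rule {rule!r}")


def _parse_window(window) -> int:
    if window is None:
        return -1
    if isinstance(window, str):
        kind, _, val = window.partition(":")
        if kind != "sakoechiba" or not val:
            raise DtwError(f"unknown window spec {window!r}; use 'sakoechiba:W'")
        return int(val)
    return int(window)


def dtw_align(
    x,
    y,
    pattern: StepPattern,
    window=None,
    norm: Optional[str] = None,
) -> WarpResult:
    """Optimal anchored alignment of ``x`` (reference) and ``y`` (query).

    Both inputs are (N, d) arrays (1-D accepted); the local metric is the
    Euclidean distance over frames.  ``window`` is an optional Sakoe–Chiba
    band, e.g. ``"sakoechiba:20"``.  Raises :class:`DtwInfeasibleError` when
    the pattern's slope bounds admit no path between the anchored endpoints.
    """
    X = _as_matrix(x)
    Y = _as_matrix(y)
    if X.shape[1] != Y.shape[1]:
        raise DtwError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    D = cdist(X, Y, metric="euclidean")
    return dtw_align_from_dist(D, pattern, window=window, norm=norm)


def dtw_align_from_dist(
    D: np.ndarray,
    pattern: StepPattern,
    window=None,
    norm: Optional[str] = None,
) -> WarpResult:
    """As :func:`dtw_align`, but from a precomputed local-distance matrix."""
    D = np.ascontiguousarray(D, dtype=np.float64)
    if D.ndim != 2 or D.size == 0:
        raise DtwError("empty input")
    N, M = D.shape
    win = _parse_window(window)
    arrays = _pattern_arrays(pattern)
    g, choice = _dp_kernel(D, *arrays, win)
    if not np.isfinite(g[N - 1, M - 1]):
        raise DtwInfeasibleError(
            f"no feasible path for lengths N={N}, M={M} under pattern "
            f"{pattern.id} (length ratio outside the pattern's slope bounds)"
        )
    path = _traceback(choice, pattern)
    cost = float(g[N - 1, M - 1])
    rule = norm or pattern.normalization_rule
    nd = _normalize(cost, rule, len(path), N, M)
    return WarpResult(
        path=path,
        accumulated_cost=cost,
        normalized_distance=nd,
        pattern_id=pattern.id,
        N=N,
        M=M,
        norm_rule=rule,
    )


_BRUTE_LIMIT = 10


def brute_force_dtw(x, y, pattern: StepPattern, norm: Optional[str] = None) -> WarpResult:
    """Exact DTW by exhaustive search over all legal paths.

    Independent oracle for :func:`dtw_align`: a top-down recursion over the
    pattern's chains that considers every legal path into each cell
    (memoized per cell), written without the bottom-up kernel.  Limited to
    sequences of length ≤ 10.
    """
    X = _as_matrix(x)
    Y = _as_matrix(y)
    N, M = X.shape[0], Y.shape[0]
    if N > _BRUTE_LIMIT or M > _BRUTE_LIMIT:
        raise DtwError(f"brute force limited to lengths ≤ {_BRUTE_LIMIT}")
    d = {}

    def dist(i, j):
        if (i, j) not in d:
            d[(i, j)] = math.dist(X[i], Y[j])
        return d[(i, j)]

    memo = {}

    def best(i, j):
        """Minimum accumulated cost into cell (i, j) and the path achieving it."""
        if (i, j) == (0, 0):
            return dist(0, 0), ((0, 0),)
        if (i, j) in memo:
            return memo[(i, j)]
        best_cost, best_path = math.inf, None
        for chain in pattern.chains:
            si = i - sum(s[0] for s in chain)
            sj = j - sum(s[1] for s in chain)
            if si < 0 or sj < 0:
                continue
            sub_cost, sub_path = best(si, sj)
            if sub_path is None:
                continue
            cost = sub_cost
            cells = []
            ci, cj = si, sj
            for di, dj, w in chain:
                ci += di
                cj += dj
                cells.append((ci, cj))
                cost += w * dist(ci, cj)
            if cost < best_cost:
                best_cost, best_path = cost, sub_path + tuple(cells)
        memo[(i, j)] = (best_cost, best_path)
        return memo[(i, j)]

    cost, path = best(N - 1, M - 1)
    if path is None:
        raise DtwInfeasibleError(
            f"no feasible path for lengths N={N}, M={M} under pattern "
            f"{pattern.id} (length ratio outside the pattern's slope bounds)"
        )
    path = np.array(path, dtype=np.int64) + 1
    rule = norm or pattern.normalization_rule
    nd = _normalize(cost, rule, len(path), N, M)
    return WarpResult(
        path=path,
        accumulated_cost=float(cost),
        normalized_distance=nd,
        pattern_id=pattern.id,
        N=N,
        M=M,
        norm_rule=rule,
    )


def max_path_offset(result: WarpResult) -> int:
    """Maximum |i - j| over the alignment path."""
    p = np.asarray(result.path)
    return int(np.max(np.abs(p[:, 0] - p[:, 1])))
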
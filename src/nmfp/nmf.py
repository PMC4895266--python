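"""Penalized KL-divergence NMF: V ~ W.H with conflicting-bin penalty.

The normalized bin-count matrix ``V`` (p bins x m samples) is factorized as
``V = W.H + eps`` with ``W >= 0`` (p x s, columns are candidate isoform bin
patterns, max-normalized to [0, 1]) and ``H >= 0`` (s x m, per-sample
pattern abundances).  The objective is the generalized Kullback-Leibler
divergence plus a penalty that discourages biologically incompatible bins
from co-occurring in one pattern::

    D(V, WH) = sum_ij [ V_ij log(V_ij/(WH)_ij) - V_ij + (WH)_ij ]
               + alpha * sum_{i conflicts j, unordered} (W W^T)_ij

From a fitted W, the per-bin bias diagonal is ``A_ii = max_k W_ik`` and the
binary bin-membership matrix is ``G_ij = I(W_ij / A_ii >= c)`` (default
``c = 0.4``); each column of G is one raw isoform candidate.

Minimization uses majorize-minimize multiplicative updates: the standard
Lee-Seung KL update for H, and for W a per-entry closed-form minimizer of
the majorized penalized objective (a scalar quadratic), which preserves
non-negativity, reduces to the Lee-Seung update when ``alpha = 0``, and
keeps the objective trace non-increasing.

The factorization rank s (number of patterns per run) is chosen by a gap
statistic: observed log reconstruction error per rank is compared with fits
on reference matrices whose entries are resampled uniformly within each
bin-row's observed range, and the smallest rank within one standard error
of the next rank's gap is taken.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .binning import NormalizedMatrix

__all__ = [
    "NMFConfig",
    "NMFResult",
    "objective",
    "kl_divergence",
    "fit",
    "estimate_A",
    "estimate_G",
    "select_rank",
]


@dataclass
class NMFConfig:
    """Tuning knobs of one NMF run.

    alpha:    weight of the conflicting-bin penalty.
    c:        binarization threshold on W_ij / A_ii for G.
    a_min:    optional minimum per-bin bias A_ii (on the [0, 1]
              peak-intensity scale) for a bin to count as observed.  The
              default 0 applies the binarization rule exactly as stated,
              where only A_ii = 0 rows are excluded; a small positive
              floor (e.g. 0.05) generalizes that degenerate case to noisy
              data, where a bin whose whole row is measurement noise is
              otherwise declared present in whichever pattern carries its
              row maximum.  See the methods note for the trade-off.
    max_iter: update-iteration cap.
    tol:      relative objective-change threshold over a ``window``-iteration
              span; iteration stops when the change falls below it.
    epsilon:  smoothing floor inside logs and divisions.
    seed:     base seed for the random initialization.
    B:        number of reference matrices per rank in the gap statistic.
    restarts: random restarts per gap-statistic fit; the best (lowest
              reconstruction error) restart is kept, which keeps the gap
              profile from being distorted by occasional poor local minima.
    """

    alpha: float = 0.1
    c: float = 0.4
    a_min: float = 0.0
    max_iter: int = 2000
    tol: float = 1e-6
    epsilon: float = 1e-10
    seed: int = 0
    B: int = 10
    restarts: int = 3
    window: int = 10

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 < self.c < 1:
            raise ValueError("c must be in (0, 1)")
        if self.tol <= 0 or self.epsilon <= 0:
            raise ValueError("tol and epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class NMFResult:
    """Fitted factors of one run plus the derived A diagonal and binary G."""

    W: np.ndarray
    H: np.ndarray
    A: np.ndarray
    G: np.ndarray
    objective_trace: np.ndarray
    rank: int
    converged: bool


def kl_divergence(V: np.ndarray, WH: np.ndarray, epsilon: float = 1e-10) -> float:
    """Generalized KL divergence sum(V log V/WH - V + WH), with 0 log 0 := 0."""
    WHc = np.maximum(WH, epsilon)
    pos = V > 0
    term = float((V[pos] * np.log(V[pos] / WHc[pos])).sum())
    return term - float(V.sum()) + float(WH.sum())


def _penalty(W: np.ndarray, conflicts: Optional[np.ndarray]) -> float:
    """sum over unordered conflicting bin pairs of (W W^T)_ij."""
    if conflicts is None or not conflicts.any():
        return 0.0
    return 0.5 * float((conflicts * (W @ W.T)).sum())


def objective(
    V: NormalizedMatrix | np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    alpha: float,
    conflicts: Optional[np.ndarray] = None,
    epsilon: float = 1e-10,
) -> float:
    """Penalized objective D(V, WH) (see module docstring)."""
    Vm = V.V if isinstance(V, NormalizedMatrix) else np.asarray(V, dtype=float)
    if (Vm < 0).any() or (W < 0).any() or (H < 0).any():
        raise ValueError("V, W and H must be non-negative")
    return kl_divergence(Vm, W @ H, epsilon) + alpha * _penalty(W, conflicts)


@njit(cache=True)
def _objective_nb(V, W, H, C, alpha, eps):  # pragma: no cover - exercised via fit
    p, m = V.shape
    WH = np.dot(W, H)
    total = 0.0
    for i in range(p):
        for j in range(m):
            wh = WH[i, j]
            whc = wh if wh > eps else eps
            v = V[i, j]
            if v > 0.0:
                total += v * np.log(v / whc) - v
            total += wh
    if alpha > 0.0:
        M = np.dot(W, W.T)
        pen = 0.0
        for i in range(p):
            for j in range(p):
                if C[i, j] > 0.0:
                    pen += M[i, j]
        total += 0.5 * alpha * pen
    return total


@njit(cache=True)
def _fit_loop(V, W, H, C, alpha, eps, max_iter, tol, window):  # pragma: no cover
    p, m = V.shape
    s = W.shape[1]
    trace = np.empty(max_iter + 1)
    trace[0] = _objective_nb(V, W, H, C, alpha, eps)
    use_pen = alpha > 0.0
    converged = False
    n = 0
    for it in range(1, max_iter + 1):
        # H update (Lee-Seung KL)
        WH = np.dot(W, H)
        for a in range(s):
            wsum = 0.0
            for i in range(p):
                wsum += W[i, a]
            if wsum < eps:
                wsum = eps
            for j in range(m):
                num = 0.0
                for i in range(p):
                    wh = WH[i, j]
                    if wh < eps:
                        wh = eps
                    num += W[i, a] * V[i, j] / wh
                H[a, j] *= num / wsum
        # W update: per-entry minimizer of the majorized penalized objective
        WH = np.dot(W, H)
        ratio = np.empty((p, m))
        for i in range(p):
            for j in range(m):
                wh = WH[i, j]
                if wh < eps:
                    wh = eps
                ratio[i, j] = V[i, j] / wh
        S = np.dot(ratio, H.T)
        if use_pen:
            CW = np.dot(C, W)
        for a in range(s):
            b = 0.0
            for j in range(m):
                b += H[a, j]
            for i in range(p):
                cterm = W[i, a] * S[i, a]
                if use_pen:
                    wa = W[i, a] if W[i, a] > eps else eps
                    aa = alpha * CW[i, a] / wa
                    denom = b + np.sqrt(b * b + 4.0 * aa * cterm)
                    if denom < eps:
                        denom = eps
                    W[i, a] = 2.0 * cterm / denom
                else:
                    bb = b if b > eps else eps
                    W[i, a] = cterm / bb
        trace[it] = _objective_nb(V, W, H, C, alpha, eps)
        n = it
        if it >= window:
            prev = trace[it - window]
            cur = trace[it]
            ref = abs(prev) if abs(prev) > 1.0 else 1.0
            if abs(prev - cur) <= tol * ref:
                converged = True
                break
    return trace[: n + 1], converged


def fit(
    V: NormalizedMatrix | np.ndarray,
    s: int,
    config: NMFConfig | None = None,
    conflicts: Optional[np.ndarray] = None,
) -> NMFResult:
    """Fit the penalized NMF at rank s from a seeded random initialization.

    Factors are initialized i.i.d. uniform(0, 1) scaled by ``mean(V)/s`` and
    refined by multiplicative majorize-minimize updates until the relative
    objective change over a 10-iteration window drops below ``tol`` or
    ``max_iter`` is reached.  On return W is column-max-normalized with the
    inverse scale folded into H, and A and G are derived from it.
    """
    config = config or NMFConfig()
    if isinstance(V, NormalizedMatrix):
        if conflicts is None:
            conflicts = V.scheme.conflicts
        V = V.V
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    if s < 1:
        raise ValueError("rank must be >= 1")
    p, m = V.shape
    eps = config.epsilon
    alpha = config.alpha

    if not (V > 0).any():
        W = np.zeros((p, s))
        H = np.zeros((s, m))
        return NMFResult(W, H, np.zeros(p), np.zeros((p, s), dtype=np.int8),
                         np.array([0.0]), s, True)

    if s > min(p, m):
        warnings.warn(
            f"rank {s} exceeds min(p, m) = {min(p, m)}; factorization is degenerate",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    scale = V.mean() / s
    W = rng.uniform(0.0, 1.0, size=(p, s)) * scale + eps
    H = rng.uniform(0.0, 1.0, size=(s, m)) * scale + eps

    if conflicts is not None and alpha > 0 and conflicts.any():
        C = np.ascontiguousarray(conflicts, dtype=np.float64)
        eff_alpha = alpha
    else:
        C = np.zeros((p, p), dtype=np.float64)
        eff_alpha = 0.0
    trace, converged = _fit_loop(
        np.ascontiguousarray(V, dtype=np.float64), W, H, C, float(eff_alpha),
        float(eps), int(config.max_iter), float(config.tol), int(config.window),
    )

    # fold column scales into H so each W column has max 1
    d = W.max(axis=0)
    nz = d > 0
    W[:, nz] /= d[nz]
    H[nz] *= d[nz, None]
    A = estimate_A(W)
    G = estimate_G(W, A, config.c, config.a_min)
    return NMFResult(W, H, A, G, np.asarray(trace), s, bool(converged))


def estimate_A(W: np.ndarray) -> np.ndarray:
    """Per-bin bias diagonal: A_ii = max_k W_ik (row maxima)."""
    if (W < 0).any():
        raise ValueError("W must be non-negative")
    return W.max(axis=1)


def estimate_G(W: np.ndarray, A: np.ndarray, c: float, a_min: float = 0.0) -> np.ndarray:
    """Binary bin membership: G_ij = I(W_ij / A_ii >= c).

    Rows with A_ii <= a_min yield all-zero G rows: a bin whose intensity
    never rises above the ``a_min`` fraction of the column peak anywhere is
    treated as containing no mapped reads (the degenerate A_ii = 0 case).
    """
    if not 0 < c < 1:
        raise ValueError("c must be in (0, 1)")
    denom = np.where(A > 0, A, 1.0)
    G = (W / denom[:, None]) >= c
    G[A <= max(a_min, 0.0), :] = False
    return G.astype(np.int8)


def select_rank(
    V: NormalizedMatrix | np.ndarray,
    candidate_ranks: Sequence[int],
    config: NMFConfig | None = None,
    conflicts: Optional[np.ndarray] = None,
) -> int:
    """Choose the NMF rank by the gap statistic.

    For each candidate rank the log reconstruction error (KL term only) of
    the fit on V is compared with fits on B reference matrices whose
    entries are drawn uniformly between each bin-row's min and max;
    ``Gap(s)`` is the mean reference log error minus the observed one.  The
    smallest rank whose gap reaches within one standard error of the
    maximum gap is returned (the ``globalSEmax`` decision rule), which
    guards both against the shallow-noise regime, where the gap profile
    starts flat, and against overfitting past the true rank, where it keeps
    creeping upward.
    """
    config = config or NMFConfig()
    if isinstance(V, NormalizedMatrix):
        if conflicts is None:
            conflicts = V.scheme.conflicts
        V = V.V
    V = np.asarray(V, dtype=float)
    ranks = sorted(set(int(s) for s in candidate_ranks))
    if not ranks or any(s < 1 for s in ranks):
        raise ValueError("candidate_ranks must be non-empty with every rank >= 1")
    if len(ranks) == 1:
        return ranks[0]
    p, m = V.shape
    if m == 1:
        warnings.warn("gap statistic is degenerate with a single sample; "
                      "returning the smallest candidate rank", stacklevel=2)
        return min(ranks)

    rng = np.random.default_rng(config.seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=(len(ranks), config.B + 1, config.restarts))
    lo = V.min(axis=1)[:, None]
    hi = V.max(axis=1)[:, None]
    refs = [lo + rng.uniform(0.0, 1.0, size=(p, m)) * (hi - lo)
            for _ in range(config.B)]

    floor = 1e-12

    def _log_fit(M: np.ndarray, s: int, seeds: np.ndarray) -> float:
        best = np.inf
        for seed in seeds:
            res = fit(M, s, dataclasses.replace(config, seed=int(seed)), conflicts)
            best = min(best, kl_divergence(M, res.W @ res.H, config.epsilon))
        return float(np.log(max(best, floor)))

    gap = np.empty(len(ranks))
    se = np.empty(len(ranks))
    for idx, s in enumerate(ranks):
        obs = _log_fit(V, s, sub_seeds[idx, 0, :])
        ref_logs = np.array(
            [_log_fit(refs[b], s, sub_seeds[idx, b + 1, :]) for b in range(config.B)]
        )
        gap[idx] = ref_logs.mean() - obs
        se[idx] = ref_logs.std(ddof=1) * np.sqrt(1.0 + 1.0 / config.B)

    best = int(np.argmax(gap))
    threshold = gap[best] - se[best]
    for idx in range(len(ranks)):
        if gap[idx] >= threshold:
            return ranks[idx]
    return ranks[best]
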
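"""Microstate discretization and Markov-state-model estimation/validation.

The conformational ensemble is discretized with k-means into microstates;
transitions between microstates at a chosen lag time are counted and
converted into a row-stochastic transition matrix.  Model quality is
assessed the standard way: VAMP-2 scoring of the discretization, implied
timescales across lag times (convergence signals Markovianity), and the
Chapman–Kolmogorov test comparing the propagated model T(τ)^k with a model
re-estimated at lag k·τ.

All estimators are deterministic given their inputs; k-means takes an
explicit seed for its k-means++ initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

__all__ = [
    "KMeansResult",
    "MarkovModel",
    "CKTestResult",
    "kmeans",
    "assign_microstates",
    "vamp2_score",
    "count_matrix",
    "estimate_transition_matrix",
    "implied_timescales",
    "ck_test",
    "select_hyperparameters",
    "lag_to_steps",
    "duration_to_frames",
]


# ---------------------------------------------------------------------------
# Lag-time bookkeeping

def lag_to_steps(lag_ns: float, frame_spacing_ns: float) -> int:
    """Convert a lag time in ns to an integer number of frames."""
    if lag_ns <= 0 or frame_spacing_ns <= 0:
        raise ValueError("lag and spacing must be positive")
    steps = round(lag_ns / frame_spacing_ns)
    if steps < 1:
        raise ValueError(f"lag {lag_ns} ns is below one frame at {frame_spacing_ns} ns")
    return steps


def duration_to_frames(duration_ns: float, frame_spacing_ns: float) -> int:
    """Number of saved frames in a run of given duration."""
    if duration_ns <= 0 or frame_spacing_ns <= 0:
        raise ValueError("duration and spacing must be positive")
    return round(duration_ns / frame_spacing_ns)


# ---------------------------------------------------------------------------
# k-means

@dataclass
class KMeansResult:
    centers: np.ndarray
    assignments: np.ndarray
    inertia: float
    n_iter: int


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def kmeans(samples: np.ndarray, k: int, seed: int = 0, max_iter: int = 300,
           tol: float = 1e-8) -> KMeansResult:
    """Lloyd's k-means with k-means++ initialization.

    Iterates until the largest center shift falls below ``tol`` or
    ``max_iter`` is reached.  Requires ``k`` <= number of distinct samples.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds number of distinct samples ({n_distinct})")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(X, k, rng)
    labels = np.zeros(X.shape[0], dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = np.sum((X[:, None, :] - centers[None]) ** 2, axis=2)
        labels = np.argmin(d2, axis=1)
        new_centers = centers.copy()
        for j in range(k):
            members = X[labels == j]
            if members.shape[0]:
                new_centers[j] = members.mean(axis=0)
        shift = np.max(np.linalg.norm(new_centers - centers, axis=1))
        centers = new_centers
        if shift < tol:
            break
    d2 = np.sum((X[:, None, :] - centers[None]) ** 2, axis=2)
    labels = np.argmin(d2, axis=1)
    inertia = float(np.sum(d2[np.arange(X.shape[0]), labels]))
    return KMeansResult(centers, labels, inertia, n_iter)


def assign_microstates(samples: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center microstate label per sample; ties -> lowest center index."""
    X = np.asarray(samples, dtype=float)
    C = np.asarray(centers, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if X.ndim == 1:
        X = X[:, None]
    if C.shape[0] == 0:
        raise ValueError("centers must be non-empty")
    if X.shape[1] != C.shape[1]:
        raise ValueError(
            f"dimensionality mismatch: samples d={X.shape[1]}, centers d={C.shape[1]}"
        )
    d2 = np.sum((X[:, None, :] - C[None]) ** 2, axis=2)
    return np.argmin(d2, axis=1)  # argmin picks the lowest index on ties


# ---------------------------------------------------------------------------
# Counting and estimation

def count_matrix(dtraj: np.ndarray, lag_steps: int, mode: str = "sliding",
                 n_states: int | None = None) -> np.ndarray:
    """Transition count matrix at the given lag.

    ``sliding`` counts every pair (t, t+lag); ``strided`` counts pairs at
    non-overlapping offsets t = 0, lag, 2·lag, ...
    """
    d = np.asarray(dtraj, dtype=int)
    if lag_steps < 1:
        raise ValueError("lag_steps must be >= 1")
    if lag_steps >= d.size:
        raise ValueError(f"lag {lag_steps} >= trajectory length {d.size}")
    if mode not in ("sliding", "strided"):
        raise ValueError(f"unknown mode {mode!r}; use 'sliding' or 'strided'")
    n = int(d.max()) + 1 if n_states is None else n_states
    if mode == "sliding":
        src, dst = d[:-lag_steps], d[lag_steps:]
    else:
        src, dst = d[:-lag_steps:lag_steps], d[lag_steps::lag_steps]
    C = np.zeros((n, n), dtype=np.int64)
    np.add.at(C, (src, dst), 1)
    return C


def _largest_scc(C: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly connected set of the count graph."""
    adj = csr_matrix((C > 0).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    # prefer the component with the most counts, tie-break by size then label
    weights = np.zeros(n_comp)
    for c in range(n_comp):
        idx = np.where(labels == c)[0]
        weights[c] = C[np.ix_(idx, idx)].sum()
    best = int(np.argmax(weights + 1e-9 * sizes))
    return np.where(labels == best)[0]


def _stationary_from_T(T: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(V[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _reversible_mle(C: np.ndarray, tol: float = 1e-10, max_iter: int = 100000):
    """Maximum-likelihood reversible transition matrix (fixed-point iteration).

    Iterates x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j) on the symmetric
    edge weights x; converges to the detailed-balance MLE.  Returns (T, pi).
    """
    C = C.astype(float)
    Csym = C + C.T
    x = Csym.copy()
    x[Csym == 0] = 0.0
    if x.sum() == 0:
        raise ValueError("no transitions to estimate from")
    x /= x.sum()
    c_row = C.sum(axis=1)
    for _ in range(max_iter):
        xi = x.sum(axis=1)
        q = c_row / xi
        denom = q[:, None] + q[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            x_new = np.where(Csym > 0, Csym / denom, 0.0)
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x))
        x = x_new
        if delta < tol:
            break
    xi = x.sum(axis=1)
    T = x / xi[:, None]
    return T, xi / xi.sum()


@dataclass
class MarkovModel:
    """Row-stochastic microstate transition matrix with spectral bookkeeping."""

    T: np.ndarray
    lag_steps: int
    lag_ns: float
    counts: np.ndarray
    stationary: np.ndarray
    eigenvalues: np.ndarray
    active_set: np.ndarray
    reversible: bool = False

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def to_dict(self) -> dict:
        return {
            "T": self.T.tolist(),
            "lag_steps": self.lag_steps,
            "lag_ns": self.lag_ns,
            "stationary": self.stationary.tolist(),
            "active_set": self.active_set.tolist(),
            "reversible": self.reversible,
        }


def _sorted_eigenvalues(T: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvals(T)
    # sort by real part descending; deterministic tie-break on imaginary part
    order = np.lexsort((w.imag, -w.real))
    return w[order]


def estimate_transition_matrix(counts: np.ndarray, reversible: bool = False,
                               prior_count: float = 0.0,
                               lag_steps: int = 1,
                               frame_spacing_ns: float = 0.1) -> MarkovModel:
    """Estimate a Markov model from a transition count matrix.

    The estimate is restricted to the largest strongly connected set of
    the count graph (``active_set``); states outside it are dropped.
    Non-reversible mode row-normalizes the counts (plus ``prior_count``);
    reversible mode runs the detailed-balance maximum-likelihood fixed
    point to tolerance 1e-10.
    """
    C = np.asarray(counts, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("counts must be square")
    if np.any(C < 0):
        raise ValueError("counts must be nonnegative")
    active = _largest_scc(C)
    if active.size == 0 or C[np.ix_(active, active)].sum() == 0:
        raise ValueError("no strongly connected set with transitions")
    Ca = C[np.ix_(active, active)] + prior_count
    if reversible:
        T, pi = _reversible_mle(Ca)
    else:
        T = Ca / Ca.sum(axis=1, keepdims=True)
        pi = _stationary_from_T(T)
    lam = _sorted_eigenvalues(T)
    return MarkovModel(
        T=T,
        lag_steps=lag_steps,
        lag_ns=lag_steps * frame_spacing_ns,
        counts=C[np.ix_(active, active)].astype(np.int64),
        stationary=pi,
        eigenvalues=lam,
        active_set=active,
        reversible=reversible,
    )


def estimate_msm(dtraj: np.ndarray, lag_steps: int, reversible: bool = False,
                 frame_spacing_ns: float = 0.1, mode: str = "sliding") -> MarkovModel:
    """Convenience: count at lag and estimate in one call."""
    C = count_matrix(dtraj, lag_steps, mode=mode)
    return estimate_transition_matrix(
        C, reversible=reversible, lag_steps=lag_steps,
        frame_spacing_ns=frame_spacing_ns,
    )


# ---------------------------------------------------------------------------
# VAMP-2

def vamp2_score(dtraj: np.ndarray, n_states_eval: int | None = None,
                lag_steps: int = 1) -> float:
    """VAMP-2 score of a discretization at the given lag.

    With indicator (one-hot) features the score is the squared Frobenius
    norm of the half-weighted transition operator
    C00^{-1/2} C01 C11^{-1/2}; the trivial stationary process contributes
    a unit singular value, so the score is always >= 1 and approaches
    1 + Σ λ_i² for a well-resolved Markov chain.
    """
    d = np.asarray(dtraj, dtype=int)
    n = int(d.max()) + 1 if n_states_eval is None else n_states_eval
    if d.size - lag_steps < n:
        raise ValueError(
            f"only {d.size - lag_steps} transitions for {n} states; need more data"
        )
    src, dst = d[:-lag_steps], d[lag_steps:]
    m = src.size
    C01 = np.zeros((n, n))
    np.add.at(C01, (src, dst), 1.0)
    C01 /= m
    p0 = np.bincount(src, minlength=n) / m
    p1 = np.bincount(dst, minlength=n) / m
    keep0 = p0 > 0
    keep1 = p1 > 0
    inv0 = np.zeros(n)
    inv1 = np.zeros(n)
    inv0[keep0] = 1.0 / np.sqrt(p0[keep0])
    inv1[keep1] = 1.0 / np.sqrt(p1[keep1])
    K = inv0[:, None] * C01 * inv1[None, :]
    s = np.linalg.svd(K, compute_uv=False)
    return float(np.sum(s ** 2))


def _cov_triplet(d: np.ndarray, n: int, lag: int):
    src, dst = d[:-lag], d[lag:]
    m = src.size
    C01 = np.zeros((n, n))
    np.add.at(C01, (src, dst), 1.0)
    C01 /= m
    C00 = np.diag(np.bincount(src, minlength=n) / m)
    C11 = np.diag(np.bincount(dst, minlength=n) / m)
    return C00, C01, C11


def _inv_sqrt_psd(M: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    w, V = np.linalg.eigh(M)
    w = np.where(w > eps, 1.0 / np.sqrt(w), 0.0)
    return V @ np.diag(w) @ V.T


def vamp2_score_cv(dtraj_train: np.ndarray, dtraj_test: np.ndarray,
                   n_states: int | None = None, lag_steps: int = 1) -> float:
    """Cross-validated VAMP-2: singular functions fit on one trajectory
    segment, score evaluated on another.

    Unlike the in-sample score, which never decreases under partition
    refinement, the held-out score drops once extra states only model
    noise — making it usable for selecting the microstate count.
    """
    dtr = np.asarray(dtraj_train, dtype=int)
    dte = np.asarray(dtraj_test, dtype=int)
    n = int(max(dtr.max(), dte.max())) + 1 if n_states is None else n_states
    C00, C01, C11 = _cov_triplet(dtr, n, lag_steps)
    K = _inv_sqrt_psd(C00) @ C01 @ _inv_sqrt_psd(C11)
    U, s, Vt = np.linalg.svd(K)
    A = _inv_sqrt_psd(C00) @ U
    B = _inv_sqrt_psd(C11) @ Vt.T
    t00, t01, t11 = _cov_triplet(dte, n, lag_steps)
    M = _inv_sqrt_psd(A.T @ t00 @ A) @ (A.T @ t01 @ B) @ _inv_sqrt_psd(B.T @ t11 @ B)
    return float(np.sum(np.linalg.svd(M, compute_uv=False) ** 2))


# ---------------------------------------------------------------------------
# Implied timescales

def implied_timescales(source, lag_list, frame_spacing_ns: float = 0.1,
                       n_timescales: int | None = None,
                       reversible: bool = False) -> dict[int, np.ndarray]:
    """Implied timescales t_i = −τ / ln λ_i (i >= 2) per lag, in ns.

    ``source`` is a discrete trajectory (a model is re-estimated at each
    lag) or a single :class:`MarkovModel` (one entry, its own lag).
    Eigenvalues outside (0, 1) yield NaN with a warning — they carry no
    relaxation timescale.
    """
    results: dict[int, np.ndarray] = {}
    if isinstance(source, MarkovModel):
        models = {source.lag_steps: source}
    else:
        d = np.asarray(source, dtype=int)
        models = {
            int(lag): estimate_msm(d, int(lag), reversible=reversible,
                                   frame_spacing_ns=frame_spacing_ns)
            for lag in lag_list
        }
    for lag, model in models.items():
        lam = model.eigenvalues[1:]
        if n_timescales is not None:
            lam = lam[:n_timescales]
        ts = np.full(lam.shape, np.nan)
        for i, l in enumerate(lam):
            if abs(l.imag) > 1e-12:
                warnings.warn(f"complex eigenvalue {l:.4g} at lag {lag}; timescale omitted")
                continue
            lr = l.real
            if lr <= 0 or lr >= 1:
                if lr <= 0:
                    warnings.warn(f"non-positive eigenvalue {lr:.4g} at lag {lag}")
                continue
            ts[i] = -model.lag_ns / np.log(lr)
        results[lag] = ts
    return results


# ---------------------------------------------------------------------------
# Chapman–Kolmogorov test

@dataclass
class CKTestResult:
    k: int
    predicted: np.ndarray
    estimated: np.ndarray
    per_set_agreement: np.ndarray
    agreement: float
    macrostate_sets: list


def _coarse_self_transitions(T: np.ndarray, pi: np.ndarray, sets: list) -> np.ndarray:
    out = np.empty(len(sets))
    for a, S in enumerate(sets):
        S = np.asarray(S, dtype=int)
        w = pi[S]
        out[a] = float(w @ T[np.ix_(S, S)].sum(axis=1) / w.sum())
    return out


def ck_test(dtraj: np.ndarray, lag_steps: int, k: int = 5,
            n_macro_for_test: int = 2, reversible: bool = False,
            frame_spacing_ns: float = 0.1,
            macrostate_sets: list | None = None) -> CKTestResult:
    """Chapman–Kolmogorov test: T(τ)^k against T estimated at lag k·τ.

    Both matrices are coarse-grained onto metastable macrostate sets
    (PCCA of the lag-τ model unless explicit sets are given) and compared
    on macrostate self-transition probabilities.  The agreement score is
    1 − mean(|predicted − estimated| / predicted), clamped to [0, 1]; a
    value of 1 at k = 1 is exact by construction, and ≥ 0.95 is the
    conventional adequacy threshold for the chosen lag.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(dtraj, dtype=int)
    if k * lag_steps >= d.size:
        raise ValueError(
            f"insufficient data: lag k·τ = {k * lag_steps} >= length {d.size}"
        )
    base = estimate_msm(d, lag_steps, reversible=reversible,
                        frame_spacing_ns=frame_spacing_ns)
    if macrostate_sets is None:
        from .tpt import pcca  # deferred: tpt depends on msm types

        part = pcca(base, n_macro_for_test)
        sets = [np.where(part.crisp_labels == a)[0] for a in range(n_macro_for_test)]
    else:
        sets = [np.asarray(S, dtype=int) for S in macrostate_sets]
    at_k = estimate_msm(d, k * lag_steps, reversible=reversible,
                        frame_spacing_ns=frame_spacing_ns)
    # map the k·τ model back onto the base active set
    pos = {s: i for i, s in enumerate(at_k.active_set)}
    n = base.n_states
    Tk_est = np.eye(n)
    for i, si in enumerate(base.active_set):
        for j, sj in enumerate(base.active_set):
            if si in pos and sj in pos:
                Tk_est[i, j] = at_k.T[pos[si], pos[sj]]
    Tk_est /= Tk_est.sum(axis=1, keepdims=True)
    Tk_pred = np.linalg.matrix_power(base.T, k)
    pred = _coarse_self_transitions(Tk_pred, base.stationary, sets)
    est = _coarse_self_transitions(Tk_est, base.stationary, sets)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(pred - est) / pred
    per_set = np.clip(1.0 - rel, 0.0, 1.0)
    return CKTestResult(
        k=k, predicted=pred, estimated=est, per_set_agreement=per_set,
        agreement=float(per_set.mean()), macrostate_sets=[list(map(int, S)) for S in sets],
    )


# ---------------------------------------------------------------------------
# Hyperparameter selection

def select_hyperparameters(samples: np.ndarray, k_grid, lag_grid,
                           seed: int = 0, frame_spacing_ns: float = 0.1,
                           vamp_lag_steps: int = 1, score_rel_tol: float = 0.01):
    """Pick the microstate count and lag time the standard way.

    ``k*`` is chosen by cross-validated VAMP-2 (singular functions fit on
    the first half of the data, scored on the second) of a k-means
    discretization at ``vamp_lag_steps``.  Because the score saturates at
    the resolved partition, the smallest k within ``score_rel_tol`` of
    the grid maximum is selected (parsimony at equal score).
    ``lag*`` is the smallest grid lag at which the
    slowest implied timescale varies by < 10% over the next two grid
    points (returns the largest lag with a warning if none converges).
    If ``samples`` is already a 1-D integer label sequence the k scan is
    skipped.

    Returns ``(k_star, lag_star, {"vamp2": {k: score}, "its": {lag: t2}})``.
    """
    k_grid = list(k_grid)
    lag_grid = sorted(int(l) for l in lag_grid)
    if not k_grid or not lag_grid:
        raise ValueError("k_grid and lag_grid must be non-empty")
    X = np.asarray(samples)
    vamp_table: dict[int, float] = {}
    if X.ndim == 1 and X.dtype.kind in "iu":
        dtraj = X.astype(int)
        k_star = int(dtraj.max()) + 1
    else:
        dtrajs: dict[int, np.ndarray] = {}
        half = X.shape[0] // 2
        for k in k_grid:
            res = kmeans(X[:half], k, seed=seed)
            full = assign_microstates(X, res.centers)
            dtrajs[k] = full
            vamp_table[k] = vamp2_score_cv(full[:half], full[half:], n_states=k,
                                           lag_steps=vamp_lag_steps)
        best = max(vamp_table.values())
        k_star = min(k for k, v in vamp_table.items()
                     if v >= best * (1.0 - score_rel_tol))
        dtraj = dtrajs[k_star]
    its = implied_timescales(dtraj, lag_grid, frame_spacing_ns=frame_spacing_ns)
    t2 = {lag: its[lag][0] if its[lag].size else np.nan for lag in lag_grid}
    lag_star = None
    for i, lag in enumerate(lag_grid[:-2]):
        window = [t2[lag], t2[lag_grid[i + 1]], t2[lag_grid[i + 2]]]
        if any(np.isnan(window)):
            continue
        ref = window[0]
        if ref > 0 and max(abs(v - ref) / ref for v in window[1:]) < 0.10:
            lag_star = lag
            break
    if lag_star is None:
        warnings.warn("no convergent lag in grid; returning the largest")
        lag_star = lag_grid[-1]
    return k_star, lag_star, {"vamp2": vamp_table, "its": t2}
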
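"""Supervised PLS denoising of the sensor matrix.

Each MEG channel is treated as a sample (row of X, an M x N channels-by-time
matrix) and labelled with its brain region through an M x C indicator matrix
Y.  Two-block PLS extracts score/weight pairs that maximize the squared
covariance between a linear combination of the time-point variables, X w, and
a linear combination of the region indicators, Y v, subject to unit-norm
weights and mutually uncorrelated scores.  Reconstructing X from the first K
score/loading pairs keeps the region-structured part of the data and discards
most of the sensor noise; the beamformer then estimates its covariance from
the reconstruction.

Both blocks are column-standardized before extraction and the reconstruction
is mapped back to the original physical units, so downstream covariances keep
the measured field scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import REGION_ORDER, RegionPartition

__all__ = [
    "ClassMatrix",
    "ColumnScaling",
    "PLSModel",
    "PLSConvergenceError",
    "build_class_matrix",
    "standardize_columns",
    "destandardize_columns",
    "fit_pls",
    "fit_pls_standardized",
    "reconstruct",
    "save_model",
    "load_model",
]


class PLSConvergenceError(RuntimeError):
    """Inner power iteration failed to converge at some extraction step."""


@dataclass
class ClassMatrix:
    """M x C one-hot region membership matrix (one row per channel)."""

    Y: np.ndarray
    region_order: tuple = REGION_ORDER

    def validate(self) -> None:
        if not np.all(np.isin(self.Y, (0, 1))):
            raise ValueError("class matrix entries must be 0/1")
        if not np.all(self.Y.sum(axis=1) == 1):
            raise ValueError("each channel must belong to exactly one region")


@dataclass
class ColumnScaling:
    """Per-column mean/sd used to standardize a matrix, kept for inversion."""

    means: np.ndarray
    sds: np.ndarray


@dataclass
class PLSModel:
    W: np.ndarray               # (N, K) predictor weights, unit columns
    V: np.ndarray               # (C, K) response weights (zero where Y exhausted)
    T: np.ndarray               # (M, K) scores ("intrinsic components")
    P_load: np.ndarray          # (N, K) predictor loadings
    K: int
    residual_norms: np.ndarray  # (K+1,) spectral norm of X before/after each step
    scaling: ColumnScaling
    region_order: tuple = REGION_ORDER
    threshold_rel: float | None = None
    meta: dict = field(default_factory=dict)


def build_class_matrix(partition: RegionPartition, channel_mask=None,
                       drop_empty: bool = False) -> ClassMatrix:
    """One-hot encode the region partition, optionally over a channel subset.

    A region left empty by the mask is an error by default (its standardized
    indicator column would be degenerate); with ``drop_empty`` the empty
    columns are removed instead, so e.g. a single-region mask yields a single
    column of ones.
    """
    labels = partition.labels
    if channel_mask is not None:
        labels = labels[np.asarray(channel_mask)]
    order = tuple(partition.region_order)
    Y = np.stack([(labels == r).astype(float) for r in order], axis=1)
    counts = Y.sum(axis=0)
    if np.any(counts == 0):
        if not drop_empty:
            empty = [r for r, c in zip(order, counts) if c == 0]
            raise ValueError(f"region(s) empty after channel masking: {empty}")
        keep = counts > 0
        Y = Y[:, keep]
        order = tuple(r for r, k in zip(order, keep) if k)
    cm = ClassMatrix(Y=Y, region_order=order)
    cm.validate()
    return cm


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, ColumnScaling]:
    """Zero-mean, unit-variance columns; raises on a constant column."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    bad = np.flatnonzero(sds <= 1e-12 * np.maximum(np.abs(means), 1e-300))
    if bad.size:
        raise ValueError(f"constant column(s) cannot be standardized: indices {bad.tolist()}")
    Xn = (X - means) / sds
    return Xn, ColumnScaling(means=means, sds=sds)


def destandardize_columns(Xn: np.ndarray, scaling: ColumnScaling) -> np.ndarray:
    return Xn * scaling.sds + scaling.means


def _spectral_norm(X: np.ndarray, v0: np.ndarray | None = None,
                   tol: float = 1e-6, maxit: int = 120) -> tuple[float, np.ndarray]:
    """Largest singular value by power iteration on X^T X (warm-startable).

    The Rayleigh-quotient estimate settles to within ``tol`` (relative) well
    before the iterate itself converges when leading singular values cluster,
    which is all the deflation stopping rule needs.
    """
    n = X.shape[1]
    v = np.full(n, 1.0 / np.sqrt(n)) if v0 is None else v0
    s = 0.0
    for _ in range(maxit):
        w = X.T @ (X @ v)
        nw = math.sqrt(w @ w)
        if nw == 0:
            return 0.0, v
        v_new = w / nw
        s_new = math.sqrt(nw)
        if abs(s_new - s) <= tol * max(s_new, 1.0):
            return s_new, v_new
        v, s = v_new, s_new
    return s, v


def _leading_pair(Mxy: np.ndarray, maxit: int, tol: float,
                  step: int) -> tuple[np.ndarray, np.ndarray]:
    """Leading singular pair of the N x C cross-product matrix.

    Power iteration on the small C x C Gram matrix; when two leading singular
    values nearly tie the iteration cannot settle within the cap, in which
    case the pair is computed by an exact thin SVD of the C-column matrix
    (deterministic, same fixed point).  Non-finite input is a hard error.
    """
    if not np.all(np.isfinite(Mxy)):
        raise PLSConvergenceError(f"non-finite cross-product at step {step}")
    C = Mxy.shape[1]
    # iterate on the tiny C x C Gram matrix; one matvec with Mxy at the end
    G = Mxy.T @ Mxy
    v = np.full(C, 1.0 / math.sqrt(C))
    v_prev = None
    converged = False
    for _ in range(maxit):
        u = G @ v
        nu = math.sqrt(u @ u)
        if nu == 0:
            v = np.zeros(C)
            v[0] = 1.0
            continue
        v = u / nu
        if v_prev is not None:
            d = v - v_prev
            if math.sqrt(d @ d) < tol:
                converged = True
                break
        v_prev = v
    if not converged:
        # near-tied leading singular values: finish with an exact thin SVD
        U, _, Vt = np.linalg.svd(Mxy, full_matrices=False)
        return U[:, 0], Vt[0]
    w = Mxy @ v
    w /= math.sqrt(w @ w)
    return w, v


def _fix_sign(w: np.ndarray) -> float:
    """Sign making the largest-magnitude entry of w positive."""
    i = int(np.argmax(np.abs(w)))
    return 1.0 if w[i] >= 0 else -1.0


def fit_pls(
    Xn: np.ndarray,
    Yn: np.ndarray,
    threshold_rel: float = 0.05,
    max_k: int = 30,
    deflate_y: bool = True,
    inner_tol: float = 1e-10,
    inner_maxit: int = 500,
) -> PLSModel:
    """Iterative two-block PLS extraction with both-block deflation.

    Per step the weight pair (w_k, v_k) maximizes Cov^2(X w, Y v) on the
    current deflated blocks (the leading singular pair of X^T Y); the score is
    t_k = X w_k, the loading p_k = X^T t_k / (t_k^T t_k), and both blocks are
    deflated (X by t p^T, Y by t c^T).  Extraction stops when the spectral
    norm of the deflated X falls to ``threshold_rel`` times its initial value
    or after ``max_k`` components.  Once the Y block is numerically exhausted
    (||X^T Y|| ~ 0) further components follow the leading principal direction
    of the deflated X, so K can reach rank(Xn) and full-K reconstruction is
    exact; those steps store v_k = 0.
    """
    X = np.array(Xn, dtype=float)
    Y = np.array(Yn, dtype=float)
    M, N = X.shape
    C = Y.shape[1]
    if Y.shape[0] != M:
        raise ValueError("X and Y must be row-aligned")
    if M < C:
        raise ValueError("need at least as many channels as classes")
    max_k = min(max_k, M, N)

    s0, v_power = _spectral_norm(X)
    xty_scale = np.linalg.norm(X.T @ Y)
    resid = [s0]
    Ws, Vs, Ts, Ps = [], [], [], []
    for k in range(max_k):
        if resid[-1] <= threshold_rel * s0:
            break
        Mxy = X.T @ Y
        if np.linalg.norm(Mxy) > 1e-12 * max(xty_scale, 1.0):
            w, v = _leading_pair(Mxy, inner_maxit, inner_tol, step=k)
        else:
            # response block exhausted: continue along X's principal direction
            _, w = _spectral_norm(X, v0=v_power)
            v = np.zeros(C)
        sgn = _fix_sign(w)
        w = sgn * w
        v = sgn * v
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-28:
            break
        p = X.T @ t / tt
        c = Y.T @ t / tt
        X -= np.outer(t, p)
        if deflate_y:
            Y -= np.outer(t, c)
        Ws.append(w); Vs.append(v); Ts.append(t); Ps.append(p)
        s_k, v_power = _spectral_norm(X, v0=v_power)
        resid.append(min(s_k, resid[-1]))

    K = len(Ws)
    if K == 0:
        raise ValueError("no component could be extracted (zero or constant input)")
    return PLSModel(
        W=np.column_stack(Ws), V=np.column_stack(Vs), T=np.column_stack(Ts),
        P_load=np.column_stack(Ps), K=K,
        residual_norms=np.array(resid),
        scaling=ColumnScaling(means=np.zeros(N), sds=np.ones(N)),
        threshold_rel=threshold_rel,
    )


def reconstruct(model: PLSModel, K_use: int | None = None) -> np.ndarray:
    """Rank-``K_use`` reconstruction X-hat = T P^T, de-standardized to the
    original data units via the scaling stored on the model."""
    K_use = model.K if K_use is None else K_use
    if not 1 <= K_use <= model.K:
        raise ValueError(f"K_use must be in [1, {model.K}]")
    Xn_hat = model.T[:, :K_use] @ model.P_load[:, :K_use].T
    return destandardize_columns(Xn_hat, model.scaling)


def fit_pls_standardized(X: np.ndarray, Y01: np.ndarray, **kwargs) -> PLSModel:
    """Standardize both blocks, fit, and attach X's scaling for reconstruction."""
    Xn, scaling = standardize_columns(X)
    Yn, _ = standardize_columns(Y01)
    model = fit_pls(Xn, Yn, **kwargs)
    model.scaling = scaling
    return model


def save_model(path, model: PLSModel) -> None:
    np.savez(
        path, W=model.W, V=model.V, T=model.T, P_load=model.P_load,
        K=model.K, residual_norms=model.residual_norms,
        means=model.scaling.means, sds=model.scaling.sds,
        region_order=np.array(model.region_order, dtype=object),
        threshold_rel=-1.0 if model.threshold_rel is None else model.threshold_rel,
        allow_pickle=True,
    )


def load_model(path) -> PLSModel:
    d = np.load(path, allow_pickle=True)
    thr = float(d["threshold_rel"])
    return PLSModel(
        W=d["W"], V=d["V"], T=d["T"], P_load=d["P_load"], K=int(d["K"]),
        residual_norms=d["residual_norms"],
        scaling=ColumnScaling(means=d["means"], sds=d["sds"]),
        region_order=tuple(d["region_order"]),
        threshold_rel=None if thr < 0 else thr,
    )
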
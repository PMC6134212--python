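"""Minimum-variance (LCMV) beamforming and the PLS-aided pLCMV pipeline.

The spatial filter for a scan point r0 minimizes the filter output power
tr(W' C W) subject to the unit-gain constraint W' L(r0) = I, giving

    W' = [L' C^-1 L]^-1 L' C^-1

and an output-power ("variance") map  Var(r0) = tr{[L(r0)' C^-1 L(r0)]^-1}
whose argmax is the estimated source location.  pLCMV runs the same scan on
the covariance of the PLS-reconstructed sensor matrix; because that
reconstruction has rank <= K << M, the covariance is inverted with relative
diagonal (Tikhonov) loading by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import LeadField
from .geometry import RegionPartition, SourceGrid
from .pls import PLSModel, build_class_matrix, fit_pls_standardized, reconstruct

__all__ = [
    "Covariance",
    "FilterWeights",
    "VarianceMap",
    "PipelineResult",
    "sample_covariance",
    "regularized_inverse",
    "lcmv_weights",
    "variance_map",
    "localize",
    "lcmv_localize",
    "pls_lcmv_localize",
]

#: Condition-number bound above which a 3x3 normal matrix counts as degenerate.
_DEGENERATE_COND = 1e12


@dataclass
class Covariance:
    """Channel covariance C = (X - rowmeans)(X - rowmeans)' / (N - 1)."""

    C: np.ndarray
    n_samples: int
    loading_lambda: float = 0.0

    def validate(self) -> None:
        if np.abs(self.C - self.C.T).max() > 1e-12 * max(np.abs(self.C).max(), 1.0):
            raise ValueError("covariance must be symmetric")


@dataclass
class FilterWeights:
    """Unit-gain spatial filter W (M x 3) for one scan point."""

    W: np.ndarray
    point_index: int | None = None


@dataclass
class VarianceMap:
    """Beamformer output power over the scan grid; NaN marks degenerate points."""

    values: np.ndarray
    grid: SourceGrid

    @property
    def n_valid(self) -> int:
        return int(np.sum(np.isfinite(self.values)))


@dataclass
class PipelineResult:
    """All intermediates of a localization run, for inspection."""

    index: int
    location: np.ndarray
    vmap: VarianceMap
    covariance: Covariance
    model: PLSModel | None = None
    K_used: int | None = None
    meta: dict = field(default_factory=dict)


def sample_covariance(X: np.ndarray) -> Covariance:
    """Unbiased sample covariance of the channel (row) vectors."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an M x N matrix with N >= 2 time samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / (X.shape[1] - 1)
    return Covariance(C=(C + C.T) / 2.0, n_samples=X.shape[1])


def regularized_inverse(cov: Covariance, lambda_rel: float = 1e-4) -> np.ndarray:
    """Inverse of C + lambda_rel * (trace(C)/M) * I, symmetrized.

    With ``lambda_rel = 0`` the plain inverse is returned; a singular C then
    raises with a hint to enable diagonal loading.
    """
    if lambda_rel < 0:
        raise ValueError("lambda_rel must be >= 0")
    C = cov.C
    M = C.shape[0]
    A = C + lambda_rel * (np.trace(C) / M) * np.eye(M)
    if lambda_rel == 0 and np.linalg.cond(A) > 1e14:
        raise np.linalg.LinAlgError(
            "covariance is singular or near-singular; use diagonal loading "
            "(lambda_rel > 0), e.g. the 1e-4 default"
        )
    Cinv = np.linalg.inv(A)
    cov.loading_lambda = lambda_rel
    return (Cinv + Cinv.T) / 2.0


def lcmv_weights(L0: np.ndarray, Cinv: np.ndarray,
                 point_index: int | None = None) -> FilterWeights:
    """Minimum-variance filter W' = [L' Cinv L]^-1 L' Cinv for one point."""
    G = Cinv @ L0
    A = L0.T @ G
    if np.linalg.cond(A) > _DEGENERATE_COND:
        raise np.linalg.LinAlgError(
            f"degenerate lead field at point {point_index}: L' Cinv L is singular"
        )
    W = G @ np.linalg.inv(A)
    return FilterWeights(W=W, point_index=point_index)


def variance_map(lead: LeadField, cov: Covariance,
                 lambda_rel: float = 1e-4, rank_rtol: float = 1e-8,
                 min_rank: int = 2) -> VarianceMap:
    """Output power tr{[L(p)' Cinv L(p)]^-1} at every grid point.

    In a spherical conductor the radially oriented moment is magnetically
    silent, so the 3x3 normal matrix L' Cinv L has (at most) rank 2
    everywhere; the trace is therefore taken over its non-silent eigenvalues
    (those above ``rank_rtol`` times the largest), the matrix analogue of the
    standard rank-2 lead-field reduction for MEG.  Points with fewer than
    ``min_rank`` usable directions (e.g. the sphere center, where the lead
    field vanishes entirely) get NaN and are excluded from localization.
    """
    Cinv = regularized_inverse(cov, lambda_rel)
    P, M, _ = lead.gains.shape
    L_flat = lead.gains.transpose(1, 0, 2).reshape(M, 3 * P)
    CL = (Cinv @ L_flat).reshape(M, P, 3).transpose(1, 0, 2)     # (P, M, 3)
    A = np.einsum("pmi,pmj->pij", lead.gains, CL)                # (P, 3, 3)
    A = (A + A.transpose(0, 2, 1)) / 2.0
    evals = np.linalg.eigvalsh(A)
    lam_max = evals[:, -1]
    usable = evals > rank_rtol * np.maximum(lam_max, 0.0)[:, None]
    degenerate = (lam_max <= 0) | (usable.sum(axis=1) < min_rank)
    values = np.full(P, np.nan)
    ok = ~degenerate
    with np.errstate(divide="ignore"):
        inv_ev = np.where(usable, 1.0 / evals, 0.0)
    values[ok] = inv_ev[ok].sum(axis=1)
    if not np.any(ok):
        raise ValueError("all grid points are degenerate for this lead field")
    return VarianceMap(values=values, grid=lead.grid)


def localize(vmap: VarianceMap) -> tuple[int, np.ndarray]:
    """Grid index and location of the map maximum (ties -> lowest index)."""
    if vmap.values.size == 0 or not np.any(np.isfinite(vmap.values)):
        raise ValueError("variance map has no valid values")
    idx = int(np.nanargmax(vmap.values))
    return idx, vmap.grid.points[idx].copy()


def lcmv_localize(X: np.ndarray, lead: LeadField,
                  lambda_rel: float = 1e-4) -> PipelineResult:
    """Plain LCMV scan: covariance of X -> variance map -> argmax."""
    cov = sample_covariance(X)
    vmap = variance_map(lead, cov, lambda_rel)
    idx, loc = localize(vmap)
    return PipelineResult(index=idx, location=loc, vmap=vmap, covariance=cov)


def pls_lcmv_localize(
    X: np.ndarray,
    partition: RegionPartition,
    lead: LeadField,
    pls_config: dict | None = None,
    lambda_rel: float = 1e-4,
    channel_mask=None,
    K_use: int | None = None,
) -> PipelineResult:
    """PLS-aided LCMV: denoise X via region-supervised PLS, then scan.

    ``X`` and ``lead`` must already be restricted to the same channel subset;
    ``channel_mask`` (indices into the full array) restricts the partition
    labels accordingly and defaults to ``lead.channel_index``.
    """
    if channel_mask is None:
        channel_mask = lead.channel_index
    if X.shape[0] != lead.n_channels:
        raise ValueError("X and lead field are not channel-aligned")
    cm = build_class_matrix(partition, channel_mask)
    model = fit_pls_standardized(X, cm.Y, **(pls_config or {}))
    K_used = model.K if K_use is None else K_use
    X_hat = reconstruct(model, K_used)
    cov = sample_covariance(X_hat)
    vmap = variance_map(lead, cov, lambda_rel)
    idx, loc = localize(vmap)
    return PipelineResult(index=idx, location=loc, vmap=vmap, covariance=cov,
                          model=model, K_used=K_used)
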
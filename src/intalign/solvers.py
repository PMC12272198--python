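"""Source-to-target alignment solvers and parcel-wise block-diagonal fitting.

All solvers estimate a square matrix ``R`` (vertices x vertices, within one
parcel) minimizing a discrepancy between ``R @ FX`` and ``FY``, where ``FX``
and ``FY`` are vertices x timepoints responses of the source and target to a
shared stimulus:

* **Procrustes** — ``R = s * M`` with ``M`` orthonormal (``M.T @ M = I``) and
  ``s > 0`` a scale, via SVD of ``FY @ FX.T``. Preserves vector norms (up to
  ``s``) and angles between activation maps. Reflections are allowed.
* **Entropic optimal transport** — ``R`` is a transport plan (nonnegative,
  uniform row and column marginals) minimizing ``<R, C> - eps * H(R)`` where
  ``C[i, j]`` is the Euclidean distance between the functional profiles of
  source vertex i and target vertex j and ``H`` is the discrete entropy
  ``-sum R_ij (log R_ij - 1)``. Solved by log-domain Sinkhorn iterations;
  the converged plan is rescaled so every row and column sums to 1.
* **Ridge** — closed-form Tikhonov solution
  ``R = FY @ FX.T @ inv(FX @ FX.T + alpha * I)``.
* **ProMises** — Procrustes with a spatial prior: the orthonormal ``M``
  maximizes ``trace(M.T @ (FY @ FX.T + k * Q))`` with location matrix
  ``Q = exp(-D)`` built from inter-vertex distances ``D``; ``k = 0`` reduces
  exactly to unscaled Procrustes.

Whole-cortex transforms are assembled block-diagonally: one ``R`` per parcel,
unassigned vertices mapped by identity, off-diagonal blocks implicitly zero
(signal never crosses parcel boundaries).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import (
    ContrastMap,
    Parcellation,
    SurfaceGeometry,
    TimeseriesImage,
    restrict_to_parcel,
)

__all__ = [
    "ParcelTransform",
    "FullTransform",
    "procrustes_fit",
    "optimal_transport_fit",
    "ridge_fit",
    "promises_fit",
    "fit_parcelwise",
    "apply_transform",
    "transport_entropy",
    "transport_cost",
    "ProcrustesAlignment",
    "OptimalTransportAlignment",
    "RidgeAlignment",
    "ProMisesAlignment",
    "ParcelwiseAlignment",
    "save_transform",
    "load_transform",
]

SOLVER_METHODS = ("procrustes", "optimal_transport", "ridge", "promises", "identity")


@dataclass
class ParcelTransform:
    """A square alignment matrix for one parcel."""

    parcel_id: int
    R: np.ndarray
    method: str
    scale_s: float | None = None
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("parcel transform must be square")
        if self.method not in SOLVER_METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def size(self) -> int:
        return self.R.shape[0]

    def validate(self) -> None:
        """Check the method-specific structural invariants."""
        if self.method == "procrustes":
            s = self.scale_s if self.scale_s is not None else 1.0
            M = self.R / s
            err = np.linalg.norm(M.T @ M - np.eye(self.size))
            if err > 1e-8:
                raise AssertionError(f"orthonormality violated: |M'M - I| = {err:.2e}")
            if s <= 0:
                raise AssertionError("procrustes scale must be positive")
        elif self.method == "optimal_transport":
            if (self.R < -1e-12).any():
                raise AssertionError("transport plan has negative entries")
            r = np.abs(self.R.sum(axis=1) - 1.0).max()
            c = np.abs(self.R.sum(axis=0) - 1.0).max()
            if max(r, c) > 1e-6:
                raise AssertionError(f"marginal violation {max(r, c):.2e} > 1e-6")
        elif self.method == "identity":
            if not np.array_equal(self.R, np.eye(self.size)):
                raise AssertionError("identity transform is not the identity matrix")


class FullTransform:
    """Block-diagonal whole-cortex transform: one ParcelTransform per parcel.

    Unassigned vertices (parcel label 0) are mapped by identity, so applying
    the transform always preserves the full vertex count.
    """

    def __init__(self, parcel_transforms: Sequence[ParcelTransform], parcellation: Parcellation):
        by_id = {t.parcel_id: t for t in parcel_transforms}
        missing = [pid for pid in parcellation.parcel_ids if pid not in by_id]
        if missing:
            raise ValueError(f"missing transforms for parcels {missing}")
        extra = [pid for pid in by_id if pid not in parcellation.parcel_ids]
        if extra:
            raise ValueError(f"transforms for unknown parcels {extra}")
        for pid, t in by_id.items():
            if t.size != parcellation.vertices_of(pid).size:
                raise ValueError(f"parcel {pid}: transform size {t.size} != parcel size")
        self.parcel_transforms = {pid: by_id[pid] for pid in parcellation.parcel_ids}
        self.parcellation = parcellation

    def __getitem__(self, parcel_id: int) -> ParcelTransform:
        return self.parcel_transforms[parcel_id]

    def apply_array(self, data: np.ndarray) -> np.ndarray:
        if data.shape[0] != self.parcellation.n_vertices:
            raise ValueError(
                f"data has {data.shape[0]} vertices, transform expects {self.parcellation.n_vertices}"
            )
        out = np.array(data, dtype=float, copy=True)
        vec = out.ndim == 1
        for pid, t in self.parcel_transforms.items():
            idx = self.parcellation.vertices_of(pid)
            block = data[idx] if vec else data[idx, :]
            out[idx] = t.R @ block
        return out

    def is_identity(self, atol: float = 0.0) -> bool:
        return all(
            np.allclose(t.R, np.eye(t.size), atol=atol, rtol=0.0)
            for t in self.parcel_transforms.values()
        )


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def _orthogonal_from_svd(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal polar factor of ``A`` via SVD, with deterministic signs.

    Sign ambiguity of paired singular vectors is fixed by requiring the
    largest-magnitude entry of each left singular vector to be positive,
    so outputs are reproducible across BLAS implementations.
    Returns (M, singular_values) with ``M = U @ Vt``.
    """
    U, sv, Vt = np.linalg.svd(A)
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    return U @ Vt, sv


def procrustes_fit(FX: np.ndarray, FY: np.ndarray, allow_scaling: bool = True, parcel_id: int = 0) -> ParcelTransform:
    """Scaled-orthogonal Procrustes solution of ``min ||R FX - FY||_F``.

    ``R = s * M`` with ``M = U @ Vt`` from the SVD of ``FY @ FX.T`` and
    ``s = sum(singular values) / ||FX||_F^2`` (``s = 1`` when scaling is off).
    Rank-deficient ``FX`` is accepted (the SVD formula remains a minimizer);
    a warning is issued when timepoints < vertices, where the fit is
    underdetermined.
    """
    FX = np.asarray(FX, dtype=float)
    FY = np.asarray(FY, dtype=float)
    if FX.shape != FY.shape:
        raise ValueError(f"shape mismatch: {FX.shape} vs {FY.shape}")
    v = FX.shape[0]
    fx_norm2 = float((FX**2).sum())
    if fx_norm2 == 0.0:
        warnings.warn("all-zero source block: scale undefined, returning identity", stacklevel=2)
        return ParcelTransform(parcel_id, np.eye(v), "procrustes", scale_s=1.0)
    if FX.shape[1] < v:
        warnings.warn(
            f"fewer timepoints ({FX.shape[1]}) than vertices ({v}): Procrustes fit is underdetermined",
            stacklevel=2,
        )
    M, sv = _orthogonal_from_svd(FY @ FX.T)
    s = float(sv.sum() / fx_norm2) if allow_scaling else 1.0
    if s == 0.0:
        s = 1.0  # FY all-zero: any orthonormal M is optimal; keep it unscaled
    return ParcelTransform(
        parcel_id, s * M, "procrustes", scale_s=s, hyperparams={"allow_scaling": allow_scaling}
    )


def _zscore_rows(F: np.ndarray) -> np.ndarray:
    mu = F.mean(axis=1, keepdims=True)
    sd = F.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (F - mu) / sd


def _functional_cost(FX: np.ndarray, FY: np.ndarray, zscore: bool) -> np.ndarray:
    """C[i, j] = Euclidean distance between source profile i and target profile j."""
    A = _zscore_rows(FX) if zscore else FX
    B = _zscore_rows(FY) if zscore else FY
    diff = A[:, None, :] - B[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def sinkhorn_plan(
    C: np.ndarray, epsilon: float, max_iter: int = 1000, tol: float = 1e-9
) -> np.ndarray:
    """Log-domain Sinkhorn for entropic OT with uniform marginals.

    Solves ``min <P, C> - eps * H(P)`` over plans with marginals ``1/v``
    (total mass 1, numerically stable), then rescales by ``v`` so each row
    and column sums to 1. Raises on non-convergence, reporting the final
    marginal violation.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    v = C.shape[0]
    log_a = -np.log(v) * np.ones(v)
    f = np.zeros(v)
    g = np.zeros(v)
    K = -C / epsilon
    violation = np.inf
    # violations below this are float64-floor territory for strongly peaked
    # plans; the plan is accepted and rounded to exact marginals
    floor_bound = 1e-4
    converged = False
    for _ in range(max_iter):
        f_old = f
        f = epsilon * (log_a - logsumexp(K + g[None, :] / epsilon, axis=1))
        g = epsilon * (log_a - logsumexp(K + f[:, None] / epsilon, axis=0))
        logP = K + (f[:, None] + g[None, :]) / epsilon
        P = np.exp(logP)
        # violation on the unit row/column-sum scale of the returned plan
        violation = v * max(
            np.abs(P.sum(axis=1) - 1.0 / v).max(), np.abs(P.sum(axis=0) - 1.0 / v).max()
        )
        if violation < tol:
            converged = True
            break
        if np.abs(f - f_old).max() < 1e-14 * max(1.0, np.abs(f).max()):
            break  # stagnated at the numerical floor
    if not converged and violation > floor_bound:
        raise RuntimeError(
            f"Sinkhorn did not converge in {max_iter} iterations "
            f"(marginal violation {violation:.3e})"
        )
    return _round_to_uniform_marginals(P, v) * v


def _round_to_uniform_marginals(P: np.ndarray, v: int) -> np.ndarray:
    """Project a near-feasible plan onto exact uniform 1/v marginals.

    Scale rows then columns down where they exceed 1/v, then distribute the
    remaining mass deficit as a rank-one nonnegative correction; the result
    is nonnegative with marginals exact to float precision.
    """
    target = 1.0 / v
    row = P.sum(axis=1)
    P = P * np.minimum(1.0, target / np.where(row > 0, row, 1.0))[:, None]
    col = P.sum(axis=0)
    P = P * np.minimum(1.0, target / np.where(col > 0, col, 1.0))[None, :]
    dr = target - P.sum(axis=1)
    dc = target - P.sum(axis=0)
    deficit = dr.sum()
    if deficit > 0:
        P = P + np.outer(np.maximum(dr, 0), np.maximum(dc, 0)) / deficit
    return P


def optimal_transport_fit(
    FX: np.ndarray,
    FY: np.ndarray,
    epsilon: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-9,
    zscore: bool = True,
    parcel_id: int = 0,
) -> ParcelTransform:
    """Entropic optimal transport plan between source and target vertices.

    The returned plan has every row and column summing to 1 (all vertices
    weighted equally); smaller ``epsilon`` gives sparser, lower-cost plans.
    Timeseries are z-scored per vertex before the cost computation by
    default, so the cost scale is comparable across datasets.
    """
    FX = np.asarray(FX, dtype=float)
    FY = np.asarray(FY, dtype=float)
    if FX.shape != FY.shape:
        raise ValueError(f"shape mismatch: {FX.shape} vs {FY.shape}")
    C = _functional_cost(FX, FY, zscore=zscore)
    plan = sinkhorn_plan(C, epsilon=epsilon, max_iter=max_iter, tol=tol)
    # the plan is indexed [source, target]; as an aligner we need
    # R @ FX ~ FY, i.e. output (target) rows drawing from source rows
    R = plan.T
    return ParcelTransform(
        parcel_id, R, "optimal_transport", hyperparams={"epsilon": epsilon, "zscore": zscore}
    )


def transport_entropy(R: np.ndarray) -> float:
    """Discrete entropy ``H(R) = -sum_ij R_ij (log R_ij - 1)`` with 0 log 0 = 0."""
    R = np.asarray(R, dtype=float)
    mask = R > 0
    return float(-(R[mask] * (np.log(R[mask]) - 1.0)).sum())


def transport_cost(R: np.ndarray, C: np.ndarray) -> float:
    """Elementwise (Frobenius) inner product ``<R, C> = sum_ij R_ij C_ij``."""
    return float((np.asarray(R) * np.asarray(C)).sum())


def ridge_fit(FX: np.ndarray, FY: np.ndarray, alpha: float = 1000.0, parcel_id: int = 0) -> ParcelTransform:
    """Closed-form ridge solution ``R = FY FX' (FX FX' + alpha I)^-1``.

    ``alpha = 0`` is permitted only when ``FX @ FX.T`` is invertible.
    """
    FX = np.asarray(FX, dtype=float)
    FY = np.asarray(FY, dtype=float)
    if FX.shape != FY.shape:
        raise ValueError(f"shape mismatch: {FX.shape} vs {FY.shape}")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    v = FX.shape[0]
    G = FX @ FX.T + alpha * np.eye(v)
    try:
        # R G = FY FX'  =>  G' R' = (FY FX')'
        R = np.linalg.solve(G, (FY @ FX.T).T).T
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"singular system at alpha={alpha}; use alpha > 0"
        ) from e
    if alpha == 0.0 and np.linalg.cond(G) > 1e12:
        raise np.linalg.LinAlgError("FX @ FX.T is numerically singular; use alpha > 0")
    return ParcelTransform(parcel_id, R, "ridge", hyperparams={"alpha": alpha})


def promises_fit(
    FX: np.ndarray,
    FY: np.ndarray,
    k: float,
    distances: np.ndarray,
    parcel_id: int = 0,
) -> ParcelTransform:
    """Spatially regularized Procrustes (ProMises model).

    Finds orthonormal ``M`` maximizing ``trace(M.T (FY FX.T + k Q))`` with
    location prior ``Q = exp(-D)`` built from inter-vertex distances ``D``
    (entries in (0, 1], diagonal 1), penalizing matches between spatially
    distant vertices. ``k = 0`` is bit-identical to unscaled Procrustes.
    """
    FX = np.asarray(FX, dtype=float)
    FY = np.asarray(FY, dtype=float)
    if FX.shape != FY.shape:
        raise ValueError(f"shape mismatch: {FX.shape} vs {FY.shape}")
    if k < 0:
        raise ValueError("k must be >= 0")
    D = np.asarray(distances, dtype=float)
    if D.shape != (FX.shape[0], FX.shape[0]):
        raise ValueError("distance matrix size must match vertex count")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    Q = np.exp(-D)
    M, _ = _orthogonal_from_svd(FY @ FX.T + k * Q)
    return ParcelTransform(parcel_id, M, "promises", scale_s=1.0, hyperparams={"k": k})


# ---------------------------------------------------------------------------
# Parcel-wise fitting and application
# ---------------------------------------------------------------------------

def _solver_for(method: str, hyperparams: Mapping | None, geometry: SurfaceGeometry | None):
    hp = dict(hyperparams or {})

    if method == "procrustes":
        def run(FX, FY, pid, idx):
            return procrustes_fit(FX, FY, allow_scaling=hp.get("allow_scaling", True), parcel_id=pid)
    elif method == "optimal_transport":
        def run(FX, FY, pid, idx):
            return optimal_transport_fit(
                FX,
                FY,
                epsilon=hp.get("epsilon", 1.0),
                max_iter=hp.get("max_iter", 1000),
                tol=hp.get("tol", 1e-9),
                zscore=hp.get("zscore", True),
                parcel_id=pid,
            )
    elif method == "ridge":
        def run(FX, FY, pid, idx):
            return ridge_fit(FX, FY, alpha=hp.get("alpha", 1000.0), parcel_id=pid)
    elif method == "promises":
        if geometry is None:
            raise ValueError("promises requires surface geometry for the distance prior")

        def run(FX, FY, pid, idx):
            return promises_fit(FX, FY, k=hp.get("k", 0.0), distances=geometry.distances(idx), parcel_id=pid)
    elif method == "identity":
        def run(FX, FY, pid, idx):
            return ParcelTransform(pid, np.eye(FX.shape[0]), "identity")
    else:
        raise ValueError(f"unknown solver method {method!r}")
    return run


def fit_parcelwise(
    source: TimeseriesImage | np.ndarray,
    target: TimeseriesImage | np.ndarray,
    parcellation: Parcellation,
    method: str = "procrustes",
    hyperparams: Mapping | None = None,
    geometry: SurfaceGeometry | None = None,
) -> FullTransform:
    """Fit one ParcelTransform per parcel from source to target.

    Alignment is computed separately within each parcel (no cross-parcel
    mixing); unassigned vertices get the identity implicitly.
    """
    src = source.data if isinstance(source, TimeseriesImage) else np.asarray(source, dtype=float)
    tgt = target.data if isinstance(target, TimeseriesImage) else np.asarray(target, dtype=float)
    if src.shape != tgt.shape:
        raise ValueError(f"source/target shape mismatch: {src.shape} vs {tgt.shape}")
    if src.shape[0] != parcellation.n_vertices:
        raise ValueError("vertex count does not match parcellation")
    run = _solver_for(method, hyperparams, geometry)
    transforms = []
    for pid in parcellation.parcel_ids:
        idx = parcellation.vertices_of(pid)
        try:
            transforms.append(run(src[idx, :], tgt[idx, :], pid, idx))
        except Exception as e:
            raise type(e)(f"parcel {pid}: {e}") from e
    return FullTransform(transforms, parcellation)


def apply_transform(transform: FullTransform, image):
    """Apply a block-diagonal transform to a timeseries or contrast map.

    Linearity holds exactly: ``apply(T, a x + b y) = a apply(T, x) + b apply(T, y)``.
    """
    if isinstance(image, TimeseriesImage):
        return image.with_data(transform.apply_array(image.data), alignment_state="functional")
    if isinstance(image, ContrastMap):
        return image.with_data(transform.apply_array(image.data))
    return transform.apply_array(np.asarray(image, dtype=float))


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------

class _PairAlignment(BaseEstimator, TransformerMixin):
    """Base for single-block aligners: fit(X, Y) learns ``R_``; transform maps X."""

    def fit(self, X, Y=None):  # pragma: no cover - overridden
        raise NotImplementedError

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "R_")
        X = np.asarray(X, dtype=float)
        return self.R_ @ X


class ProcrustesAlignment(_PairAlignment):
    """Scaled-orthogonal Procrustes aligner for one vertex block.

    Parameters
    ----------
    scaling : bool
        Estimate the positive scale ``s`` (True) or fix ``s = 1``.

    Attributes
    ----------
    R_ : ndarray (v, v)
        The fitted transform ``s * M``.
    scale_ : float
    """

    def __init__(self, scaling: bool = True):
        self.scaling = scaling

    def fit(self, X, Y=None):
        if Y is None:
            raise ValueError("fit requires both source X and target Y")
        t = procrustes_fit(X, Y, allow_scaling=self.scaling)
        self.R_ = t.R
        self.scale_ = t.scale_s
        return self


class OptimalTransportAlignment(_PairAlignment):
    """Entropic OT aligner for one vertex block (uniform marginals)."""

    def __init__(self, epsilon: float = 1.0, max_iter: int = 1000, tol: float = 1e-9, zscore: bool = True):
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.tol = tol
        self.zscore = zscore

    def fit(self, X, Y=None):
        if Y is None:
            raise ValueError("fit requires both source X and target Y")
        t = optimal_transport_fit(
            X, Y, epsilon=self.epsilon, max_iter=self.max_iter, tol=self.tol, zscore=self.zscore
        )
        self.R_ = t.R
        return self


class RidgeAlignment(_PairAlignment):
    """Ridge-regularized linear aligner for one vertex block."""

    def __init__(self, alpha: float = 1000.0):
        self.alpha = alpha

    def fit(self, X, Y=None):
        if Y is None:
            raise ValueError("fit requires both source X and target Y")
        self.R_ = ridge_fit(X, Y, alpha=self.alpha).R
        return self


class ProMisesAlignment(_PairAlignment):
    """Procrustes aligner with a spatial location prior exp(-D) weighted by k."""

    def __init__(self, k: float = 0.0, distances: np.ndarray | None = None):
        self.k = k
        self.distances = distances

    def fit(self, X, Y=None):
        if Y is None:
            raise ValueError("fit requires both source X and target Y")
        if self.distances is None:
            raise ValueError("ProMises requires an inter-vertex distance matrix")
        self.R_ = promises_fit(X, Y, k=self.k, distances=self.distances).R
        return self


class ParcelwiseAlignment(BaseEstimator, TransformerMixin):
    """Whole-cortex aligner: one solver fit per parcel, block-diagonal apply.

    Parameters
    ----------
    parcellation : Parcellation
    method : {"procrustes", "optimal_transport", "ridge", "promises", "identity"}
    scaling, epsilon, alpha, k, max_iter, tol, zscore
        Solver hyperparameters (each used only by the relevant method).
    geometry : SurfaceGeometry, optional
        Required for ``promises``.

    Attributes
    ----------
    transform_ : FullTransform
    """

    def __init__(
        self,
        parcellation: Parcellation | None = None,
        method: str = "procrustes",
        scaling: bool = True,
        epsilon: float = 1.0,
        alpha: float = 1000.0,
        k: float = 0.0,
        max_iter: int = 1000,
        tol: float = 1e-9,
        zscore: bool = True,
        geometry: SurfaceGeometry | None = None,
    ):
        self.parcellation = parcellation
        self.method = method
        self.scaling = scaling
        self.epsilon = epsilon
        self.alpha = alpha
        self.k = k
        self.max_iter = max_iter
        self.tol = tol
        self.zscore = zscore
        self.geometry = geometry

    def _hyperparams(self) -> dict:
        return {
            "allow_scaling": self.scaling,
            "epsilon": self.epsilon,
            "alpha": self.alpha,
            "k": self.k,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "zscore": self.zscore,
        }

    def fit(self, X, Y=None):
        if self.parcellation is None:
            raise ValueError("a parcellation is required")
        if Y is None:
            raise ValueError("fit requires both source X and target Y")
        self.transform_ = fit_parcelwise(
            X, Y, self.parcellation, method=self.method,
            hyperparams=self._hyperparams(), geometry=self.geometry,
        )
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "transform_")
        return apply_transform(self.transform_, X)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_transform(transform: FullTransform, path, manifest_path=None) -> None:
    """Write a FullTransform to the HDF5 container, with an optional text manifest."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["parcellation_checksum"] = transform.parcellation.checksum()
        f.create_dataset("labels", data=transform.parcellation.labels)
        grp = f.create_group("parcels")
        for pid, t in transform.parcel_transforms.items():
            g = grp.create_group(str(pid))
            g.create_dataset("R", data=t.R)
            g.attrs["method"] = t.method
            g.attrs["scale_s"] = t.scale_s if t.scale_s is not None else np.nan
            g.attrs["hyperparams"] = json.dumps(t.hyperparams)
    if manifest_path is not None:
        lines = [f"parcellation_checksum\t{transform.parcellation.checksum()}"]
        for pid, t in transform.parcel_transforms.items():
            lines.append(f"parcel\t{pid}\t{t.method}\t{t.size}x{t.size}")
        from pathlib import Path

        Path(manifest_path).write_text("\n".join(lines) + "\n")


def load_transform(path) -> FullTransform:
    import h5py

    with h5py.File(path, "r") as f:
        parc = Parcellation(f["labels"][()])
        transforms = []
        for key, g in f["parcels"].items():
            scale = float(g.attrs["scale_s"])
            transforms.append(
                ParcelTransform(
                    parcel_id=int(key),
                    R=g["R"][()],
                    method=str(g.attrs["method"]),
                    scale_s=None if np.isnan(scale) else scale,
                    hyperparams=json.loads(g.attrs["hyperparams"]),
                )
            )
    return FullTransform(transforms, parc)
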
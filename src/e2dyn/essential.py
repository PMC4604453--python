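"""Essential dynamics: superposition, positional-fluctuation covariance, PCA.

The covariance analysis follows the standard essential-dynamics recipe: frames
are least-squares fitted (Kabsch) to an iterated mean conformation, the
covariance matrix of the residual fluctuations is built over the mapped Cα
atoms, and its eigendecomposition yields the essential subspace.  Because the
analysis runs on Cα atoms of a single element by default, mass weighting is a
uniform scale factor there; the flag exists for all-atom use.
"""
from __future__ import annotations

import numpy as np

from .core import EssentialSubspace, ProjectionSeries, TrajectoryEnsemble
from .errors import ConsistencyError, InvalidArgumentError


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the weighted RMSD to the
    reference.  The rotation is proper (determinant +1).

    Parameters
    ----------
    mobile, reference:
        ``(N, 3)`` coordinate arrays, N >= 3.
    weights:
        Optional per-atom non-negative weights; uniform when omitted.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InvalidArgumentError("mobile and reference must both have shape (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise InvalidArgumentError("superposition requires at least 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise InvalidArgumentError("weights must be non-negative, not all zero")
        w = w / w.sum()

    cm_mob = w @ mobile
    cm_ref = w @ reference
    x = mobile - cm_mob
    y = reference - cm_ref
    rotation = _kabsch_rotation((w[:, None] * x).T @ y)
    translation = cm_ref - rotation @ cm_mob
    moved = x @ rotation.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - y) ** 2)))
    return rotation, translation, rmsd


def _kabsch_rotation(h: np.ndarray) -> np.ndarray:
    """Proper rotation maximising Tr(R @ H) for cross-covariance ``H = X^T Y``."""
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def superpose_frames(
    frames: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Fit every frame of ``(F, N, 3)`` onto the reference; batched Kabsch."""
    frames = np.asarray(frames, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    n = reference.shape[0]
    if n < 3:
        raise InvalidArgumentError("superposition requires at least 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    cm_mob = np.einsum("a,fax->fx", w, frames)
    cm_ref = w @ reference
    x = frames - cm_mob[:, None, :]
    y = reference - cm_ref
    h = np.einsum("fax,a,ay->fxy", x, w, y)          # (F, 3, 3) cross-covariances
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fxy,fyz->fxz", vt.transpose(0, 2, 1),
                                        u.transpose(0, 2, 1))))
    flip = np.repeat(np.eye(3)[None], frames.shape[0], axis=0)
    flip[:, 2, 2] = d
    rot = np.einsum("fxy,fyz,fzw->fxw", vt.transpose(0, 2, 1), flip, u.transpose(0, 2, 1))
    return np.einsum("fax,fyx->fay", x, rot) + cm_ref


# ---------------------------------------------------------------------------
# Covariance of positional fluctuations
# ---------------------------------------------------------------------------

def iterative_mean_fit(
    frames: np.ndarray,
    weights: np.ndarray | None = None,
    n_passes: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass superposition: fit to frame 0, average, refit to the mean.

    Returns ``(fitted_frames, mean)`` with ``mean`` of shape ``(N, 3)``.
    """
    fitted = superpose_frames(frames, frames[0], weights)
    mean = fitted.mean(axis=0)
    for _ in range(max(0, n_passes - 1)):
        fitted = superpose_frames(frames, mean, weights)
        mean = fitted.mean(axis=0)
    return fitted, mean


def build_covariance(
    ensemble: TrajectoryEnsemble,
    atom_indices: np.ndarray | None = None,
    mass_weighting: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Covariance matrix of positional fluctuations over the mapped atoms.

    Frames are fitted to the two-pass iterated mean before the fluctuations
    are accumulated.  With ``mass_weighting`` the fluctuation components are
    scaled by sqrt(mass) (units amu·nm²); over Cα atoms only this is a uniform
    scale and leaves eigenvectors and eigenvalue ratios unchanged.

    Returns ``(covariance, mean)``; ``covariance`` is ``(3M, 3M)`` symmetric
    PSD, ``mean`` is the ``(M, 3)`` iterated mean the fluctuations refer to.
    """
    if ensemble.n_frames < 2:
        raise InvalidArgumentError("covariance requires at least 2 frames")
    if atom_indices is None:
        sub = ensemble.coords
        masses = ensemble.topology.masses()
    else:
        atom_indices = np.asarray(atom_indices, dtype=int)
        sub = ensemble.coords[:, atom_indices, :]
        masses = ensemble.topology.masses()[atom_indices]
    fitted, mean = iterative_mean_fit(sub)
    fluct = (fitted - mean).reshape(fitted.shape[0], -1)      # (F, 3M)
    if mass_weighting:
        scale = np.sqrt(np.repeat(masses, 3))
        fluct = fluct * scale
    cov = (fluct.T @ fluct) / fluct.shape[0]
    cov = 0.5 * (cov + cov.T)
    return cov, mean


def pca_decompose(
    covariance: np.ndarray,
    mean: np.ndarray | None = None,
    atom_map: np.ndarray | None = None,
) -> EssentialSubspace:
    """Full eigendecomposition of a symmetric covariance matrix.

    Eigenvalues are sorted descending and clamped to zero within a -1e-10·λ₁
    tolerance; each eigenvector's largest-magnitude component is made positive
    so the decomposition is deterministic up to degeneracy.
    """
    covariance = np.asarray(covariance, dtype=np.float64)
    if covariance.ndim != 2 or covariance.shape[0] != covariance.shape[1]:
        raise InvalidArgumentError("covariance must be square")
    scale = max(1.0, float(np.abs(covariance).max()))
    if np.abs(covariance - covariance.T).max() > 1e-8 * scale:
        raise InvalidArgumentError("covariance is not symmetric")
    evals, evecs = np.linalg.eigh(0.5 * (covariance + covariance.T))
    order = np.argsort(evals, kind="stable")[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    lam1 = max(evals[0], 0.0)
    if np.any(evals < -1e-10 * max(lam1, 1e-300) - 1e-14):
        raise InvalidArgumentError("covariance has significantly negative eigenvalues")
    evals = np.clip(evals, 0.0, None)
    # deterministic sign: largest-|component| positive, first index on ties
    peak = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[peak, np.arange(evecs.shape[1])])
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    if mean is None:
        mean = np.zeros(covariance.shape[0])
    return EssentialSubspace(mean=np.asarray(mean).ravel(), eigenvectors=evecs,
                             eigenvalues=evals, atom_map=atom_map)


def essential_subspace(
    ensemble: TrajectoryEnsemble,
    atom_indices: np.ndarray | None = None,
    mass_weighting: bool = False,
) -> EssentialSubspace:
    """Convenience chain: covariance then PCA over the mapped atoms."""
    cov, mean = build_covariance(ensemble, atom_indices, mass_weighting)
    idx = None if atom_indices is None else np.asarray(atom_indices, dtype=int)
    return pca_decompose(cov, mean=mean, atom_map=idx)


def project_onto(
    ensemble: TrajectoryEnsemble,
    subspace: EssentialSubspace,
    k: int,
) -> list[ProjectionSeries]:
    """Projections p_i(t) = (x(t) - mean)·v_i for the first *k* PCs.

    Frames are restricted to the subspace's atom map (when present) and fitted
    to the subspace mean before projecting.
    """
    if k < 0 or k > subspace.n_modes:
        raise InvalidArgumentError(f"k={k} out of range (0..{subspace.n_modes})")
    if k == 0:
        return []
    if subspace.atom_map is not None:
        coords = ensemble.coords[:, subspace.atom_map, :]
    else:
        coords = ensemble.coords
    if coords.shape[1] * 3 != subspace.dim:
        raise ConsistencyError(
            f"ensemble maps to {coords.shape[1] * 3} coordinates, subspace has {subspace.dim}"
        )
    mean = subspace.mean.reshape(-1, 3)
    fitted = superpose_frames(coords, mean)
    fluct = (fitted - mean).reshape(coords.shape[0], -1)
    proj = fluct @ subspace.eigenvectors[:, :k]
    return [ProjectionSeries(pc_index=i + 1, values=proj[:, i]) for i in range(k)]


def variance_explained(subspace: EssentialSubspace, k: int) -> float:
    """Cumulative variance fraction carried by the first *k* PCs."""
    if not 1 <= k <= subspace.n_modes:
        raise InvalidArgumentError(f"k={k} out of range (1..{subspace.n_modes})")
    tot = subspace.total_variance
    if tot == 0.0:
        return 0.0
    return float(subspace.eigenvalues[:k].sum() / tot)


# ---------------------------------------------------------------------------
# Rigid-body modes (used by the generator to build internal-motion bases)
# ---------------------------------------------------------------------------

def rigid_body_modes(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N, 6) of infinitesimal rigid translations/rotations.

    Displacement fields x -> x + t and x -> ω × (x - centre); fluctuations
    orthogonal to these survive least-squares superposition to first order.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    centred = coords - coords.mean(axis=0)
    modes = np.zeros((3 * n, 6))
    for a in range(3):
        modes[a::3, a] = 1.0
    for a, axis in enumerate(np.eye(3)):
        modes[:, 3 + a] = np.cross(np.tile(axis, (n, 1)), centred).ravel()
    q, r = np.linalg.qr(modes)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]
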
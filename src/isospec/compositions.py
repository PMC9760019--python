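"""Isometric log-ratio (ILR) transform for diet compositions.

Diet proportions live on the J-simplex; the ILR transform maps them
bijectively to R^(J-1) so that Gaussian population means and individual
random effects can act on an unconstrained scale.  The basis used here is
the fixed sequential-binary-partition (Helmert-type) contrast matrix, built
by Gram–Schmidt orthonormalisation in clr space — the same convention as
scikit-bio's default basis.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

_SIMPLEX_TOL = 1e-6


def ilr_basis(J: int) -> np.ndarray:
    """Orthonormal (J, J-1) contrast matrix V with V^T V = I, V^T 1 = 0."""
    if J < 2:
        raise DomainError("ILR basis requires at least 2 parts")
    # Helmert contrasts, normalised: row space orthogonal to 1
    H = np.zeros((J, J - 1))
    for d in range(1, J):
        H[:d, d - 1] = 1.0 / d
        H[d, d - 1] = -1.0
        H[:, d - 1] *= np.sqrt(d / (d + 1.0))
    return H


def ilr(p: np.ndarray) -> np.ndarray:
    """Map simplex vectors (last axis, strictly positive) to R^(J-1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise DomainError("ILR requires strictly positive proportions")
    logp = np.log(p)
    clr = logp - logp.mean(axis=-1, keepdims=True)
    return clr @ ilr_basis(p.shape[-1])


def ilr_inv(z: np.ndarray, J: int | None = None) -> np.ndarray:
    """Inverse ILR: map R^(J-1) coordinates (last axis) back to the simplex."""
    z = np.asarray(z, dtype=float)
    J = z.shape[-1] + 1 if J is None else J
    clr = z @ ilr_basis(J).T
    # softmax of clr coordinates; stabilised
    clr = clr - clr.max(axis=-1, keepdims=True)
    e = np.exp(clr)
    return e / e.sum(axis=-1, keepdims=True)


def check_simplex(p: np.ndarray, tol: float = _SIMPLEX_TOL, what: str = "vector") -> np.ndarray:
    """Validate that rows of ``p`` lie on the simplex; returns the array."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -tol):
        raise DomainError(f"{what} has negative proportions")
    s = p.sum(axis=-1)
    if np.any(np.abs(s - 1.0) > tol):
        raise DomainError(f"{what} does not sum to 1 (max deviation {np.abs(s - 1).max():.2e})")
    return p
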
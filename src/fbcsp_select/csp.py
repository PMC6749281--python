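"""Common spatial patterns on the supporting channel set.

For each filter-bank band the class-mean normalised covariance matrices
E1 and E2 are formed and the spatial filter pair maximising /
minimising the variance ratio

    J(p) = (p' E1 p) / (p' E2 p)

is obtained as the extreme generalised eigenvectors of (E1, E2).  Each
band then contributes a two-dimensional log-variance feature per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .channel_select import VAR_FLOOR

#: condition-number limit beyond which a ridge is added to E2
_COND_LIMIT = 1e10
_RIDGE = 1e-10


def normalized_covariance(X: np.ndarray) -> np.ndarray:
    """Trace-normalised sample covariance ``X X' / trace(X X')`` of one trial."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a channels x samples matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("trial matrix contains non-finite values")
    G = X @ X.T
    tr = float(np.trace(G))
    if tr <= 0.0:
        raise ValueError("all-zero trial: covariance trace is zero")
    return G / tr


def class_mean_covariance(
    per_trial: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic class means of per-trial covariance matrices.

    ``per_trial`` is (trials, d, d); returns the (E1, E2) pair.
    """
    per_trial = np.asarray(per_trial, dtype=float)
    labels = np.asarray(labels).ravel()
    m1, m2 = labels == 1, labels == 2
    if not (m1.any() and m2.any()):
        raise ValueError("both classes (1 and 2) must be present")
    return per_trial[m1].mean(axis=0), per_trial[m2].mean(axis=0)


@dataclass(frozen=True)
class SpatialFilterPair:
    """Variance-ratio-extremising spatial filter pair for one band.

    ``p_max`` attains ``j_max = max_p J(p)`` and ``p_min`` attains
    ``j_min = min_p J(p)``.  Signs are fixed so the first non-negligible
    component of each filter is positive.
    """

    p_max: np.ndarray
    p_min: np.ndarray
    j_max: float
    j_min: float
    band: int = 0


@dataclass(frozen=True)
class BandFeature:
    """Per-trial log-variance feature pair of one band."""

    v_max: float
    v_min: float
    band: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.v_max, self.v_min])


def _fix_sign(v: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(v) > 1e-12 * np.abs(v).max())
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def _check_sym(E: np.ndarray, name: str) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[0] != E.shape[1]:
        raise ValueError(f"{name} must be square, got shape {E.shape}")
    scale = max(np.abs(E).max(), 1.0)
    if not np.allclose(E, E.T, atol=1e-8 * scale):
        raise ValueError(f"{name} is not symmetric")
    return 0.5 * (E + E.T)


def solve_csp(E1: np.ndarray, E2: np.ndarray, band: int = 0) -> SpatialFilterPair:
    """Extremise the variance ratio J(p) over spatial filters p.

    Solved as the symmetric-definite generalised eigenproblem
    ``E1 p = lambda E2 p``; the largest/smallest eigenvalues are exactly
    the attained ratios.  A small ridge (1e-10 x trace) is added to the
    diagonal of E2 when it is badly conditioned.
    """
    E1 = _check_sym(E1, "E1")
    E2 = _check_sym(E2, "E2")
    if E1.shape != E2.shape:
        raise ValueError(f"size mismatch: {E1.shape} vs {E2.shape}")
    cond = np.linalg.cond(E2)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        E2 = E2 + _RIDGE * np.trace(E2) * np.eye(E2.shape[0])
    try:
        w, V = linalg.eigh(E1, E2)
    except linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise ValueError(f"E2 is numerically singular beyond ridge tolerance: {exc}")
    if not np.all(np.isfinite(w)):
        raise ValueError("generalised eigenvalues are not finite; E2 is singular")
    return SpatialFilterPair(
        p_max=_fix_sign(V[:, -1].copy()),
        p_min=_fix_sign(V[:, 0].copy()),
        j_max=float(w[-1]),
        j_min=float(w[0]),
        band=band,
    )


def band_features(X: np.ndarray, pair: SpatialFilterPair) -> BandFeature:
    """Log-variance of the spatially filtered trial under both filters.

    Population variance, natural log, floored at :data:`VAR_FLOOR`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != pair.p_max.shape[0]:
        raise ValueError(
            f"trial shape {X.shape} does not match filter length {pair.p_max.shape[0]}"
        )
    v_max = float(np.log(max((pair.p_max @ X).var(), VAR_FLOOR)))
    v_min = float(np.log(max((pair.p_min @ X).var(), VAR_FLOOR)))
    return BandFeature(v_max=v_max, v_min=v_min, band=pair.band)
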
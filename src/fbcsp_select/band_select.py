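"""Mutual-information band selection (MIBIF) over filter-bank CSP features.

Each band's two CSP features are scored by their estimated mutual
information with the binary class label; the two highest-scoring bands
supply the final four-dimensional feature vector.  Densities are
estimated with a Parzen window (Gaussian kernel, Silverman bandwidth)
per class, and the MI is the sample average of the log posterior ratio,
expressed in bits.
"""

from __future__ import annotations

import numpy as np

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _silverman(x: np.ndarray, scale_floor: float) -> float:
    h = 1.06 * x.std() * x.size ** (-0.2)
    return max(h, scale_floor)


def _parzen(eval_at: np.ndarray, samples: np.ndarray, h: float) -> np.ndarray:
    z = (eval_at[:, None] - samples[None, :]) / h
    return np.exp(-0.5 * z * z).mean(axis=1) / (h * _SQRT2PI)


def mutual_information(feature_values: np.ndarray, labels: np.ndarray) -> float:
    """Estimated I(feature; class) in bits for a binary label.

    A constant feature carries no information and returns 0.  The
    estimate is clipped below at 0 (small-sample estimates can dip
    negative).
    """
    x = np.asarray(feature_values, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if x.size != y.size:
        raise ValueError("feature and label lengths differ")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    if x.size < 4:
        raise ValueError("need at least 4 trials for a density estimate")
    if np.ptp(x) == 0.0:
        return 0.0
    scale_floor = max(1e-3 * x.std(), 1e-12)
    cond = np.empty((x.size, 2))
    priors = np.empty(2)
    for j, c in enumerate(classes):
        xc = x[y == c]
        priors[j] = xc.size / x.size
        cond[:, j] = _parzen(x, xc, _silverman(xc, scale_floor))
    mix = cond @ priors
    own = np.where(y == classes[0], cond[:, 0], cond[:, 1])
    mi = float(np.mean(np.log2((own + 1e-300) / (mix + 1e-300))))
    return max(mi, 0.0)


def band_scores(per_band_features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-band MI score: sum of the MI of the band's two CSP features.

    ``per_band_features`` has shape (bands, trials, 2).
    """
    feats = np.asarray(per_band_features, dtype=float)
    if feats.ndim != 3 or feats.shape[-1] != 2:
        raise ValueError(f"expected (bands, trials, 2), got shape {feats.shape}")
    return np.array(
        [
            mutual_information(feats[m, :, 0], labels)
            + mutual_information(feats[m, :, 1], labels)
            for m in range(feats.shape[0])
        ]
    )


def select_bands(
    per_band_features: np.ndarray, labels: np.ndarray, n_bands: int = 2
) -> tuple[int, ...]:
    """Indices of the ``n_bands`` highest-scoring bands, best first.

    Ties break toward the lower band index.
    """
    scores = band_scores(per_band_features, labels)
    if scores.size < n_bands:
        raise ValueError(f"cannot pick {n_bands} bands out of {scores.size}")
    order = sorted(range(scores.size), key=lambda m: (-scores[m], m))
    return tuple(order[:n_bands])


def assemble(final_bands: tuple[int, int], per_band) -> np.ndarray:
    """Final 4-vector ``[v_max(m1), v_min(m1), v_max(m2), v_min(m2)]``.

    ``per_band`` is a sequence of :class:`~fbcsp_select.csp.BandFeature`
    (or 2-vectors) for one trial, indexed by band.
    """
    m1, m2 = final_bands
    if m1 == m2:
        raise ValueError("the two selected bands must differ")
    out = []
    for m in (m1, m2):
        try:
            entry = per_band[m]
        except (IndexError, KeyError):
            raise ValueError(f"band {m} missing from per-band features")
        vec = entry.as_array() if hasattr(entry, "as_array") else np.asarray(entry, dtype=float)
        out.append(vec)
    return np.concatenate(out)


def assemble_features(final_bands: tuple[int, int], per_band_features: np.ndarray) -> np.ndarray:
    """Vectorised :func:`assemble` over trials: returns (trials, 4)."""
    feats = np.asarray(per_band_features, dtype=float)
    m1, m2 = final_bands
    return np.concatenate([feats[m1], feats[m2]], axis=1)
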
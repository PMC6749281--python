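"""Principle-channel and supporting-set selection.

The most class-discriminative channel ("principle channel") is found by
ranking channels on the Fisher ratio of their three time-domain
parameters (TDPs) -- the log-variances of the signal and of its first
and second discrete derivatives, i.e. Hjorth-style activity, mobility
and complexity descriptors.  A supporting channel set is then built from
the channels whose class-mean Pearson correlation with the principle
channel exceeds a threshold in *both* classes; the CSP stage operates on
this subset.

Both the TDPs and the correlations are computed on broadband-filtered
epochs (0.5-40 Hz in the default pipeline), not per filter-bank band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import EpochSet

#: variance floor applied before taking logarithms, so constant or
#: linear-ramp channels produce finite TDPs instead of -inf.
VAR_FLOOR = 1e-12


class DegenerateChannelError(ValueError):
    """A channel whose TDPs carry no within-class variability at all."""


class SupportSetError(ValueError):
    """The supporting channel set came out too small for CSP."""


def tdp(x: np.ndarray, p: int) -> float:
    """Time-domain parameter of order ``p`` for one signal.

    Returns ``log(var(d^p x / dn^p))`` where the derivative is the
    ``p``-th forward difference and the variance uses population
    normalisation ``1/(N - p)``.  The variance is floored at
    :data:`VAR_FLOOR` before the (natural) log.
    """
    if p not in (0, 1, 2):
        raise ValueError(f"TDP order must be 0, 1 or 2, got {p}")
    x = np.asarray(x, dtype=float).ravel()
    if x.size - p < 2:
        raise ValueError(f"need at least {p + 2} samples for order-{p} TDP, got {x.size}")
    d = np.diff(x, n=p) if p else x
    return float(np.log(max(d.var(), VAR_FLOOR)))


def tdp_matrix(data: np.ndarray) -> np.ndarray:
    """TDPs for every trial and channel: (trials, channels, 3)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected trials x channels x samples, got shape {data.shape}")
    if data.shape[-1] < 4:
        raise ValueError("need at least 4 samples per trial for all three TDP orders")
    out = np.empty(data.shape[:2] + (3,))
    for p in range(3):
        d = np.diff(data, n=p, axis=-1) if p else data
        out[..., p] = np.log(np.maximum(d.var(axis=-1), VAR_FLOOR))
    return out


def _class_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).ravel()
    m1, m2 = labels == 1, labels == 2
    if not (m1.any() and m2.any()):
        raise ValueError("both classes (1 and 2) must be present")
    return m1, m2


def fisher_ratios(tdps: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Fisher ratio of the three TDP types for every channel.

    The numerator sums, over TDP types, the squared between-class mean
    differences; the denominator sums the within-class population
    variances over types and classes.  Channels with zero denominator
    are returned as NaN ("degenerate").
    """
    tdps = np.asarray(tdps, dtype=float)
    m1, m2 = _class_masks(labels)
    mu1, mu2 = tdps[m1].mean(axis=0), tdps[m2].mean(axis=0)  # (K, 3)
    num = ((mu1 - mu2) ** 2).sum(axis=-1)
    den = (tdps[m1].var(axis=0) + tdps[m2].var(axis=0)).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / den, np.nan)
    return ratio


def fisher_ratio(tdps: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Fisher ratio for channel ``k``; raises on a degenerate channel."""
    value = fisher_ratios(tdps, labels)[k]
    if not np.isfinite(value):
        raise DegenerateChannelError(
            f"channel {k} has zero within-class TDP variability"
        )
    return float(value)


def _principle_from_ratios(ratios: np.ndarray) -> int:
    finite = np.isfinite(ratios)
    if not finite.any():
        raise DegenerateChannelError("all channels are degenerate; cannot rank them")
    # np.argmax returns the first (lowest-index) maximiser, our tie rule
    return int(np.argmax(np.where(finite, ratios, -np.inf)))


def select_principle_channel(epoch_set: EpochSet) -> tuple[np.ndarray, int]:
    """Fisher ratios for all channels plus the argmax (ties -> lowest index).

    Expects broadband-filtered epochs.
    """
    ratios = fisher_ratios(tdp_matrix(epoch_set.data), epoch_set.require_labels())
    return ratios, _principle_from_ratios(ratios)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample correlation coefficient via centred cross/auto sums."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("inputs must share a length of at least 2")
    xc, yc = x - x.mean(), y - y.mean()
    px, py = float(xc @ xc), float(yc @ yc)
    if px == 0.0 or py == 0.0:
        raise ValueError("correlation undefined for a constant input vector")
    return float((xc @ yc) / np.sqrt(px * py))


def trial_correlations(data: np.ndarray, principle: int) -> np.ndarray:
    """Per-trial correlation of every channel with the principle channel.

    Returns (trials, channels); entries for channels that are constant
    within a trial come back NaN.
    """
    data = np.asarray(data, dtype=float)
    xc = data - data.mean(axis=-1, keepdims=True)
    power = np.einsum("ikn,ikn->ik", xc, xc)
    cross = np.einsum("ikn,in->ik", xc, xc[:, principle])
    denom = np.sqrt(power * power[:, [principle]])
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, cross / denom, np.nan)


def class_mean_correlations(rho: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Average per-trial correlations within each class: (channels, 2)."""
    m1, m2 = _class_masks(labels)
    return np.stack([rho[m1].mean(axis=0), rho[m2].mean(axis=0)], axis=1)


@dataclass(frozen=True)
class ChannelSelection:
    """Outcome of principle-channel and supporting-set selection.

    Attributes
    ----------
    fisher : (K,) Fisher ratios (NaN marks degenerate channels)
    principle : index of the highest-Fisher channel
    mean_corr : (K, 2) class-mean correlations with the principle channel
    threshold : the correlation threshold rho_thr used
    support : ascending channel indices of the supporting set (includes
        the principle channel, whose self-correlation is identically 1)
    """

    fisher: np.ndarray
    principle: int
    mean_corr: np.ndarray
    threshold: float
    support: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.principle not in self.support:
            raise ValueError("principle channel must belong to the supporting set")
        if len(self.support) < 2:
            raise SupportSetError("supporting set needs at least two channels")


def _support_from_corr(mean_corr: np.ndarray, principle: int, threshold: float) -> tuple[int, ...]:
    with np.errstate(invalid="ignore"):
        ok = (mean_corr[:, 0] >= threshold) & (mean_corr[:, 1] >= threshold)
    ok[principle] = True
    return tuple(int(q) for q in np.flatnonzero(ok))


def supporting_set(
    epoch_set: EpochSet,
    principle: int,
    threshold: float,
    fisher: np.ndarray | None = None,
) -> ChannelSelection:
    """Build the supporting channel set for a given principle channel.

    A channel ``q`` joins the set when its class-mean correlation with
    the principle channel is at least ``threshold`` in both classes
    (signed correlations; strongly anti-correlated channels do not
    qualify).  Expects broadband-filtered epochs.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    labels = epoch_set.require_labels()
    rho = trial_correlations(epoch_set.data, principle)
    mean_corr = class_mean_correlations(rho, labels)
    support = _support_from_corr(mean_corr, principle, threshold)
    if len(support) < 2:
        raise SupportSetError(
            f"supporting set holds only the principle channel at rho_thr={threshold}; "
            "lower the threshold (CSP needs at least 2 channels)"
        )
    if fisher is None:
        fisher = fisher_ratios(tdp_matrix(epoch_set.data), labels)
    return ChannelSelection(
        fisher=np.asarray(fisher, dtype=float),
        principle=int(principle),
        mean_corr=mean_corr,
        threshold=float(threshold),
        support=support,
    )


class TDPChannelSelector(TransformerMixin, BaseEstimator):
    """scikit-learn transformer that keeps only the supporting channel set.

    Operates on 3-D arrays (trials x channels x samples) that are
    already broadband-filtered.  ``fit`` picks the principle channel by
    TDP Fisher ratio and forms the supporting set at ``threshold``;
    ``transform`` subsets the channel axis accordingly.
    """

    def __init__(self, threshold: float = 0.7):
        self.threshold = threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        epochs = EpochSet(data=X, labels=np.asarray(y), fs=1.0)
        fisher, principle = select_principle_channel(epochs)
        self.selection_ = supporting_set(epochs, principle, self.threshold, fisher=fisher)
        self.n_channels_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_channels_:
            raise ValueError(
                f"expected {self.n_channels_} channels, got {X.shape[1]}"
            )
        return X[:, list(self.selection_.support), :]
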
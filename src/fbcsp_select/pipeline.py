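"""End-to-end classifier: channel selection -> filter-bank CSP -> SVM.

:class:`FBCSPClassifier` is a scikit-learn estimator over 3-D epoch
arrays (trials x channels x samples).  ``fit`` runs, in order: broadband
filtering, TDP Fisher ratios, principle-channel selection, class-mean
correlations, supporting-set construction, per-band CSP on the
supporting set, mutual-information band selection, and a linear
maximum-margin classifier on the standardised 4-dimensional feature
vector.  Every selection statistic is computed from the training trials
only.

:func:`cross_validate` runs seeded repeated stratified cross-validation
with an optional nested (inner-CV) choice of the correlation threshold
from a grid, mirroring how per-session thresholds are tuned in practice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from . import band_select, channel_select
from .channel_select import ChannelSelection, SupportSetError, VAR_FLOOR
from .csp import SpatialFilterPair, solve_csp
from .preprocess import (
    BandSpec,
    EpochSet,
    FilterBank,
    bandpass_array,
    default_filterbank,
)

logger = logging.getLogger("fbcsp_select")

DEFAULT_RHO_GRID = (0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, loadable from a YAML file.

    ``rho_threshold=None`` means the correlation threshold is chosen per
    training fold from ``rho_grid`` by an inner cross-validation
    ("individual threshold" mode); a float fixes it ("constant
    threshold" mode).
    """

    window: tuple[float, float] = (0.5, 2.5)
    broadband: tuple[float, float] = (0.5, 40.0)
    filter_order: int = 4
    filterbank: FilterBank | None = None
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    rho_threshold: float | None = None
    cv_folds: int = 5
    cv_repeats: int = 5
    seed: int = 0
    svm_c: float = 1.0
    n_bands: int = 2

    def __post_init__(self) -> None:
        if any(not 0.0 < t <= 1.0 for t in self.rho_grid):
            raise ValueError("rho_grid values must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 cross-validation folds")

    def bank(self) -> FilterBank:
        return self.filterbank if self.filterbank is not None else default_filterbank(self.filter_order)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        if "broadband" in raw:
            raw["broadband"] = tuple(raw["broadband"])
        if "rho_grid" in raw:
            raw["rho_grid"] = tuple(raw["rho_grid"])
        fb = raw.get("filterbank")
        if fb in (None, "default"):
            raw["filterbank"] = None
        else:
            order = raw.get("filter_order", 4)
            raw["filterbank"] = FilterBank(
                tuple(BandSpec(lo, hi, order=order) for lo, hi in fb)
            )
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["window"] = list(self.window)
        payload["broadband"] = list(self.broadband)
        payload["rho_grid"] = list(self.rho_grid)
        payload["filterbank"] = (
            "default"
            if self.filterbank is None
            else [[b.low_hz, b.high_hz] for b in self.filterbank]
        )
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


class _SessionCache:
    """Per-session precomputation shared across cross-validation fits.

    Filtering, TDPs, trial correlation matrices and per-trial band
    covariances are all per-trial quantities, so fold subsets can index
    into them without any information crossing trial boundaries.
    """

    def __init__(self, X: np.ndarray, fs: float, broadband, filter_order: int, bank: FilterBank):
        bb = BandSpec(broadband[0], broadband[1], order=filter_order)
        xb = bandpass_array(X, bb, fs)
        self.tdps = channel_select.tdp_matrix(xb)
        xc = xb - xb.mean(axis=-1, keepdims=True)
        power = np.einsum("ikn,ikn->ik", xc, xc)
        norm = np.sqrt(power)
        cross = np.einsum("ikn,iln->ikl", xc, xc)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.corr = cross / (norm[:, :, None] * norm[:, None, :])
        self.n_samples = X.shape[-1]
        self.covs: list[np.ndarray] = []
        self.sums: list[np.ndarray] = []
        for band in bank:
            xf = bandpass_array(X, band, fs)
            self.covs.append(np.einsum("ikn,iln->ikl", xf, xf))
            self.sums.append(xf.sum(axis=-1))


def _log_var_features(cov_sub: np.ndarray, sum_sub: np.ndarray, p: np.ndarray, n: int) -> np.ndarray:
    """Per-trial log population variance of the projected band signal.

    Uses the identity var(p'X) = (p'Cp - (p's)^2 / n) / n with C = XX'
    and s the per-channel sample sums; algebraically identical to
    projecting the filtered series and calling ``var``.
    """
    q = np.einsum("a,iab,b->i", p, cov_sub, p)
    mu = sum_sub @ p
    var = np.maximum(q / n - (mu / n) ** 2, VAR_FLOOR)
    return np.log(var)


class FBCSPClassifier(ClassifierMixin, BaseEstimator):
    """Filter-bank CSP classifier with TDP/correlation channel selection.

    Parameters
    ----------
    fs : float
        Sampling rate of the epoch arrays, Hz.
    rho_threshold : float
        Class-mean correlation threshold for the supporting channel set.
    broadband : (low, high)
        Broadband filter (Hz) feeding the TDP / correlation path.
    filter_order : int
        Butterworth order for broadband and bank filters.
    filterbank : FilterBank or None
        ``None`` selects the default eight 4-Hz bands over 4-36 Hz.
    n_bands : int
        Number of bands kept by mutual-information selection (2 gives
        the standard 4-dimensional feature vector).
    C : float
        Margin parameter of the linear SVM.

    Attributes (after ``fit``)
    --------------------------
    classes_ : the two label values, sorted
    selection_ : :class:`~fbcsp_select.channel_select.ChannelSelection`
    filters_ : per-band :class:`~fbcsp_select.csp.SpatialFilterPair`
    band_scores_ : per-band mutual information (bits)
    bands_ : indices of the selected bands, best first
    coef_, intercept_ : linear decision function on standardised features
    """

    def __init__(
        self,
        fs: float = 100.0,
        rho_threshold: float = 0.7,
        broadband: tuple[float, float] = (0.5, 40.0),
        filter_order: int = 4,
        filterbank: FilterBank | None = None,
        n_bands: int = 2,
        C: float = 1.0,
    ):
        self.fs = fs
        self.rho_threshold = rho_threshold
        self.broadband = broadband
        self.filter_order = filter_order
        self.filterbank = filterbank
        self.n_bands = n_bands
        self.C = C

    # -- helpers -----------------------------------------------------------

    def _bank(self) -> FilterBank:
        return self.filterbank if self.filterbank is not None else default_filterbank(self.filter_order)

    @staticmethod
    def _validate_X(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"expected trials x channels x samples, got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("epoch data contains non-finite samples")
        return X

    def _encode(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y).ravel()
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(f"need exactly two classes, got {self.classes_.size}")
        return np.where(y == self.classes_[0], 1, 2)

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X = self._validate_X(X)
        y12 = self._encode(y)
        if len(y12) != len(X):
            raise ValueError("X and y length mismatch")
        cache = _SessionCache(X, self.fs, self.broadband, self.filter_order, self._bank())
        self._fit_cached(cache, np.arange(len(y12)), y12)
        return self

    def _fit_cached(self, cache: _SessionCache, idx: np.ndarray, y12: np.ndarray) -> None:
        """Fit from precomputed per-trial statistics restricted to ``idx``."""
        bank = self._bank()
        tdps = cache.tdps[idx]
        fisher = channel_select.fisher_ratios(tdps, y12)
        principle = channel_select._principle_from_ratios(fisher)
        mean_corr = channel_select.class_mean_correlations(
            cache.corr[idx][:, :, principle], y12
        )
        support = channel_select._support_from_corr(mean_corr, principle, self.rho_threshold)
        if len(support) < 2:
            raise SupportSetError(
                f"supporting set holds only the principle channel at "
                f"rho_thr={self.rho_threshold}; lower the threshold"
            )
        self.selection_ = ChannelSelection(
            fisher=fisher,
            principle=principle,
            mean_corr=mean_corr,
            threshold=float(self.rho_threshold),
            support=support,
        )
        S = np.asarray(support)
        n = cache.n_samples
        n_trials = len(idx)
        filters: list[SpatialFilterPair] = []
        feats = np.empty((len(bank), n_trials, 2))
        for m in range(len(bank)):
            cov = cache.covs[m][np.ix_(idx, S, S)]
            sums = cache.sums[m][np.ix_(idx, S)]
            traces = np.einsum("iaa->i", cov)
            if np.any(traces <= 0):
                raise ValueError("all-zero trial encountered in band filtering")
            cov_norm = cov / traces[:, None, None]
            E1 = cov_norm[y12 == 1].mean(axis=0)
            E2 = cov_norm[y12 == 2].mean(axis=0)
            pair = solve_csp(E1, E2, band=m)
            filters.append(pair)
            feats[m, :, 0] = _log_var_features(cov, sums, pair.p_max, n)
            feats[m, :, 1] = _log_var_features(cov, sums, pair.p_min, n)
        self.filters_ = filters
        self.band_scores_ = band_select.band_scores(feats, y12)
        order = sorted(range(len(bank)), key=lambda m: (-self.band_scores_[m], m))
        self.bands_ = tuple(order[: self.n_bands])
        F = band_select.assemble_features(self.bands_[:2], feats) if self.n_bands == 2 else np.concatenate([feats[m] for m in self.bands_], axis=1)
        self.feat_mean_ = F.mean(axis=0)
        self.feat_std_ = np.maximum(F.std(axis=0), 1e-12)
        Fs = (F - self.feat_mean_) / self.feat_std_
        svm = SVC(kernel="linear", C=self.C)
        svm.fit(Fs, y12)
        self.coef_ = svm.coef_.ravel().copy()
        self.intercept_ = float(svm.intercept_[0])
        self.n_channels_ = cache.corr.shape[1]
        logger.info(
            "fit: principle=%d |S|=%d bands=%s", principle, len(support), self.bands_
        )

    # -- prediction --------------------------------------------------------

    def _features(self, X: np.ndarray) -> np.ndarray:
        """Standardised features of new epochs under the fitted model."""
        bank = self._bank()
        S = list(self.selection_.support)
        cols = []
        for m in self.bands_:
            xf = bandpass_array(X[:, S, :], bank[m], self.fs)
            pair = self.filters_[m]
            for p in (pair.p_max, pair.p_min):
                proj = np.einsum("a,ian->in", p, xf)
                cols.append(np.log(np.maximum(proj.var(axis=-1), VAR_FLOOR)))
        F = np.stack(cols, axis=1)
        return (F - self.feat_mean_) / self.feat_std_

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = self._validate_X(X)
        if X.shape[1] != self.n_channels_:
            raise ValueError(
                f"channel mismatch: model was fitted on {self.n_channels_} channels, "
                f"got {X.shape[1]}"
            )
        return self._features(X) @ self.coef_ + self.intercept_

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])

    def _predict_cached(self, cache: _SessionCache, idx: np.ndarray) -> np.ndarray:
        """Predict trials of the cached session by index (class codes 1/2)."""
        S = np.asarray(self.selection_.support)
        n = cache.n_samples
        cols = []
        for m in self.bands_:
            cov = cache.covs[m][np.ix_(idx, S, S)]
            sums = cache.sums[m][np.ix_(idx, S)]
            pair = self.filters_[m]
            cols.append(_log_var_features(cov, sums, pair.p_max, n))
            cols.append(_log_var_features(cov, sums, pair.p_min, n))
        F = (np.stack(cols, axis=1) - self.feat_mean_) / self.feat_std_
        d = F @ self.coef_ + self.intercept_
        return np.where(d > 0, 2, 1)


# -- thin functional wrappers ---------------------------------------------


def fit_model(
    epochs: EpochSet, config: PipelineConfig | None = None, threshold: float | None = None
) -> FBCSPClassifier:
    """Fit a classifier on a labelled epoch set using a config."""
    config = config or PipelineConfig()
    thr = threshold if threshold is not None else (config.rho_threshold or 0.7)
    est = FBCSPClassifier(
        fs=epochs.fs,
        rho_threshold=thr,
        broadband=config.broadband,
        filter_order=config.filter_order,
        filterbank=config.filterbank,
        n_bands=config.n_bands,
        C=config.svm_c,
    )
    return est.fit(epochs.data, epochs.require_labels())


def predict_labels(model: FBCSPClassifier, epochs: EpochSet) -> np.ndarray:
    """Predict one label in {1, 2} per trial of an (unlabelled) epoch set."""
    return model.predict(epochs.data)


# -- cross-validation ------------------------------------------------------


@dataclass
class CVResult:
    """Repeated stratified cross-validation outcome (accuracies in %)."""

    accuracies: np.ndarray
    mean: float
    std: float
    chosen_thresholds: tuple[float, ...]
    threshold_table: dict[float, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [{"fold": i, "accuracy_pct": a, "rho_thr": t}
                for i, (a, t) in enumerate(zip(self.accuracies, self.chosen_thresholds))]
        return pd.DataFrame(rows)


def _accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean(pred == truth))


def _make_estimator(fs: float, config: PipelineConfig, threshold: float) -> FBCSPClassifier:
    return FBCSPClassifier(
        fs=fs,
        rho_threshold=threshold,
        broadband=config.broadband,
        filter_order=config.filter_order,
        filterbank=config.filterbank,
        n_bands=config.n_bands,
        C=config.svm_c,
    )


def _fit_eval_cached(
    cache: _SessionCache,
    y12: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    fs: float,
    config: PipelineConfig,
    threshold: float,
) -> float:
    est = _make_estimator(fs, config, threshold)
    est.classes_ = np.array([1, 2])
    est._fit_cached(cache, train_idx, y12[train_idx])
    return _accuracy(est._predict_cached(cache, test_idx), y12[test_idx])


def _cv_cached(
    cache: _SessionCache,
    y12: np.ndarray,
    fs: float,
    config: PipelineConfig,
    threshold: float | None,
    grid_table: bool,
) -> CVResult:
    splitter = RepeatedStratifiedKFold(
        n_splits=config.cv_folds, n_repeats=config.cv_repeats, random_state=config.seed
    )
    placeholder = np.zeros((len(y12), 1))
    accs: list[float] = []
    chosen: list[float] = []
    table: dict[float, list[float]] = {t: [] for t in config.rho_grid} if grid_table else {}
    for f, (tr, te) in enumerate(splitter.split(placeholder, y12)):
        if threshold is None:
            inner = StratifiedKFold(
                n_splits=config.cv_folds, shuffle=True, random_state=config.seed + 104729 + f
            )
            best_thr, best_score = None, -np.inf
            for t in config.rho_grid:
                scores = []
                try:
                    for itr, iva in inner.split(placeholder[tr], y12[tr]):
                        scores.append(
                            _fit_eval_cached(cache, y12, tr[itr], tr[iva], fs, config, t)
                        )
                except SupportSetError:
                    continue
                score = float(np.mean(scores))
                if score > best_score:
                    best_thr, best_score = t, score
            if best_thr is None:
                raise SupportSetError(
                    "every grid threshold left the supporting set empty; lower the grid"
                )
            thr = best_thr
        else:
            thr = float(threshold)
        accs.append(_fit_eval_cached(cache, y12, tr, te, fs, config, thr))
        chosen.append(thr)
        if grid_table:
            for t in config.rho_grid:
                try:
                    table[t].append(_fit_eval_cached(cache, y12, tr, te, fs, config, t))
                except SupportSetError:
                    table[t].append(np.nan)
    acc_pct = 100.0 * np.asarray(accs)
    mean_table = {
        t: float(100.0 * np.nanmean(v)) if np.isfinite(v).any() else float("nan")
        for t, v in ((t, np.asarray(v)) for t, v in table.items())
    }
    return CVResult(
        accuracies=acc_pct,
        mean=float(acc_pct.mean()),
        std=float(acc_pct.std()),
        chosen_thresholds=tuple(chosen),
        threshold_table=mean_table,
    )


def cross_validate(
    epochs: EpochSet,
    config: PipelineConfig | None = None,
    threshold: float | None | str = "config",
    grid_table: bool = False,
) -> CVResult:
    """Seeded repeated stratified cross-validation of the full pipeline.

    With ``threshold=None`` (or ``config.rho_threshold=None``) the
    correlation threshold is selected within each training fold by an
    inner stratified cross-validation over ``config.rho_grid``, so the
    held-out trials never influence the choice.  With a float, that
    constant threshold is used everywhere.  ``grid_table=True``
    additionally reports the mean outer accuracy at every grid value.
    """
    config = config or PipelineConfig()
    thr = config.rho_threshold if threshold == "config" else threshold
    y = epochs.require_labels()
    counts = np.bincount(y)[1:3]
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} trials; need >= {config.cv_folds} "
            "for stratified folds"
        )
    cache = _SessionCache(
        epochs.data, epochs.fs, config.broadband, config.filter_order, config.bank()
    )
    return _cv_cached(cache, y, epochs.fs, config, thr, grid_table)


def permutation_baseline(
    epochs: EpochSet,
    config: PipelineConfig | None = None,
    threshold: float = 0.7,
    n_permutations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Mean CV accuracy (%) under label permutation, one entry per shuffle.

    Reuses the session's filtered data across permutations (labels play
    no role in filtering), so this is far cheaper than re-running
    :func:`cross_validate` from scratch.
    """
    config = config or PipelineConfig()
    y = epochs.require_labels()
    cache = _SessionCache(
        epochs.data, epochs.fs, config.broadband, config.filter_order, config.bank()
    )
    rng = np.random.default_rng(seed)
    means = []
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        res = _cv_cached(cache, yp, epochs.fs, config, threshold, grid_table=False)
        means.append(res.mean)
    return np.asarray(means)


# -- model persistence -----------------------------------------------------


def model_payload(model: FBCSPClassifier) -> dict:
    """JSON-serialisable snapshot of a fitted model."""
    check_is_fitted(model, "coef_")
    bank = model._bank()
    sel = model.selection_
    return {
        "format": "fbcsp-select-model",
        "version": 1,
        "params": {
            "fs": model.fs,
            "rho_threshold": model.rho_threshold,
            "broadband": list(model.broadband),
            "filter_order": model.filter_order,
            "n_bands": model.n_bands,
            "C": model.C,
        },
        "filterbank": [[b.low_hz, b.high_hz, b.order] for b in bank],
        "classes": [int(c) for c in model.classes_],
        "n_channels": int(model.n_channels_),
        "selection": {
            "fisher": np.nan_to_num(sel.fisher, nan=-1.0).tolist(),
            "principle": sel.principle,
            "mean_corr": np.nan_to_num(sel.mean_corr, nan=-2.0).tolist(),
            "threshold": sel.threshold,
            "support": list(sel.support),
        },
        "filters": [
            {
                "band": p.band,
                "p_max": p.p_max.tolist(),
                "p_min": p.p_min.tolist(),
                "j_max": p.j_max,
                "j_min": p.j_min,
            }
            for p in model.filters_
        ],
        "band_scores": model.band_scores_.tolist(),
        "bands": list(model.bands_),
        "feat_mean": model.feat_mean_.tolist(),
        "feat_std": model.feat_std_.tolist(),
        "coef": model.coef_.tolist(),
        "intercept": model.intercept_,
    }


def save_model(model: FBCSPClassifier, path) -> None:
    Path(path).write_text(json.dumps(model_payload(model), indent=1))


def load_model(path) -> FBCSPClassifier:
    raw = json.loads(Path(path).read_text())
    if raw.get("format") != "fbcsp-select-model":
        raise ValueError(f"{path} is not a model file of this package")
    p = raw["params"]
    bank = FilterBank(tuple(BandSpec(lo, hi, order=o) for lo, hi, o in raw["filterbank"]))
    model = FBCSPClassifier(
        fs=p["fs"],
        rho_threshold=p["rho_threshold"],
        broadband=tuple(p["broadband"]),
        filter_order=p["filter_order"],
        filterbank=bank,
        n_bands=p["n_bands"],
        C=p["C"],
    )
    sel = raw["selection"]
    model.classes_ = np.asarray(raw["classes"])
    model.n_channels_ = raw["n_channels"]
    model.selection_ = ChannelSelection(
        fisher=np.asarray(sel["fisher"]),
        principle=sel["principle"],
        mean_corr=np.asarray(sel["mean_corr"]),
        threshold=sel["threshold"],
        support=tuple(sel["support"]),
    )
    model.filters_ = [
        SpatialFilterPair(
            p_max=np.asarray(f["p_max"]),
            p_min=np.asarray(f["p_min"]),
            j_max=f["j_max"],
            j_min=f["j_min"],
            band=f["band"],
        )
        for f in raw["filters"]
    ]
    model.band_scores_ = np.asarray(raw["band_scores"])
    model.bands_ = tuple(raw["bands"])
    model.feat_mean_ = np.asarray(raw["feat_mean"])
    model.feat_std_ = np.asarray(raw["feat_std"])
    model.coef_ = np.asarray(raw["coef"])
    model.intercept_ = raw["intercept"]
    return model
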
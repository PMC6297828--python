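"""Two-stage classification on Clone-Attractor activity features.

Features are CA amplitudes per (sample, time point) data point.  The
pipeline is:

1. *Active-feature filter* — keep CAs with nonzero amplitude in strictly
   more than a fraction (default 95%) of the data points.
2. *Forward feature selection* — train Gaussian-kernel soft-margin SVMs
   on every feature pair, rank by leave-one-out cross-validation (LOOCV)
   accuracy, keep the top k (default 50); repeatedly extend the retained
   subsets by one unused feature until the best score stops improving or
   the dimension cap is reached.
3. *Ensemble averaging* — a committee of m machines (default 10), the
   i-th trained on the i-th ranked subset; the ensemble output is the mean
   of the members' continuous outputs (decision values squashed to [0, 1]
   by a logistic link).
4. *Noise-robust evaluation* — each data point is scored by an ensemble
   trained without it (leave-one-out), with multiplicative Gaussian noise
   ``x -> x * (1 + v)``, ``v ~ N(0, sigma^2)`` applied to the held-out
   copy; ROC/AUC per noise amplitude plus the noise-averaged ROC.  Model
   selection picks the dimension with the best noise-averaged AUC (ties
   go to the smaller dimension).

Stage 1 separates control from transgenic data points; stage 2 separates
pre-cancer from cancer points within the transgenic group.

LOOCV leaves out a single (sample, time point) data point, not a whole
mouse; scores can therefore be optimistic when a mouse's time points are
correlated.  Mouse-level hold-out is available via ``MLConfig.loocv_unit``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from tcranet.clustering import ActivityMatrix
from tcranet.errors import ConfigurationError, ValidationError
from tcranet.io import SampleMeta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MLConfig:
    """Tunable parameters of the classification pipeline."""

    active_fraction: float = 0.95
    top_k: int = 50
    dims: tuple[int, int] = (3, 8)  # reported model dimensions; selection starts at pairs
    ensemble_size: int = 10
    kernel: str = "gaussian"
    noise_amplitudes: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)
    seed: int = 0
    C: float = 1.0                 # soft-margin penalty
    gamma: str | float = "median"  # median-heuristic kernel bandwidth by default
    normalize: bool = False        # opt-in per-data-point relative abundance
    active_over: str = "points"    # "points" (sample x time) or "samples" (per mouse)
    convergence_tol: float = 1e-6
    operating_fpr: float = 0.1
    loocv_unit: str = "point"      # "point" or "sample" (hold out a whole mouse)

    def __post_init__(self) -> None:
        if not 0 < self.active_fraction <= 1:
            raise ConfigurationError("active_fraction must be in (0, 1]")
        if self.ensemble_size < 1 or self.top_k < 1:
            raise ConfigurationError("ensemble_size and top_k must be >= 1")
        if any(s < 0 for s in self.noise_amplitudes):
            raise ConfigurationError("noise amplitudes must be >= 0")
        if self.kernel != "gaussian":
            raise ConfigurationError(f"unsupported kernel {self.kernel!r}")
        if not 2 <= self.dims[0] <= self.dims[1]:
            raise ConfigurationError("dims must satisfy 2 <= low <= high")


@dataclass
class FeatureMatrix:
    """Data points (sample, time point) x CA features, with binary labels."""

    X: pd.DataFrame          # index (sample_id, time_point), columns ca_id
    y: pd.Series             # aligned string labels
    positive_label: str

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValidationError("feature matrix and labels are misaligned")
        if self.X.isna().any().any():
            raise ValidationError("feature matrix contains missing values")

    @property
    def y01(self) -> np.ndarray:
        return (self.y == self.positive_label).to_numpy(dtype=int)


@dataclass
class ClassifierEnsemble:
    """Committee of kernel machines over different feature subspaces."""

    machines: list[tuple[tuple, SVC]]  # (feature subset, fitted classifier)

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """Mean of the members' probability-like outputs in [0, 1]."""
        outs = [
            _logistic(clf.decision_function(X[list(subset)].to_numpy(dtype=float)))
            for subset, clf in self.machines
        ]
        return np.mean(outs, axis=0)


@dataclass
class RocResult:
    """ROC/AUC per (dimension, noise amplitude) and the selected model."""

    auc: dict[tuple[int, float], float]
    curves: dict[tuple[int, float], tuple[np.ndarray, np.ndarray]]  # (fpr, tpr)
    noise_avg_auc: dict[int, float]
    noise_avg_curve: dict[int, tuple[np.ndarray, np.ndarray]]
    chosen_dim: int
    operating_point: tuple[float, float]  # (fpr, tpr) on the chosen noise-avg curve


@dataclass
class StageResult:
    features: list                       # CA ids surviving the active filter
    subsets_by_dim: dict[int, list[tuple[tuple, float]]]
    roc: RocResult
    selected_features: list              # union of CA ids in the chosen-dim committee


@dataclass
class TwoStageResult:
    stage1: StageResult
    stage2: StageResult | None
    feature_jaccard: float | None        # overlap of the two selected lists


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def _median_gamma(X: np.ndarray) -> float:
    """Median-heuristic RBF bandwidth: gamma = 1 / median squared distance."""
    if X.shape[0] < 2:
        return 1.0
    d2 = pdist(X, "sqeuclidean")
    d2 = d2[d2 > 0]
    if d2.size == 0:
        return 1.0
    return float(1.0 / np.median(d2))


def _resolve_gamma(X: np.ndarray, cfg: MLConfig) -> float:
    return _median_gamma(X) if cfg.gamma == "median" else float(cfg.gamma)


def active_feature_filter(activity: ActivityMatrix, cfg: MLConfig = MLConfig()) -> list:
    """CAs active (amplitude > 0) in strictly more than ``active_fraction``
    of the data points (or of the samples, with ``active_over='samples'``)."""
    data = activity.data
    if data.size == 0:
        raise ConfigurationError("empty activity matrix")
    if cfg.active_over == "points":
        frac = (data > 0).mean(axis=1)
    elif cfg.active_over == "samples":
        frac = (data > 0).T.groupby(level="sample_id").any().mean(axis=0)
    else:
        raise ConfigurationError(f"unknown active_over {cfg.active_over!r}")
    kept = list(data.index[frac > cfg.active_fraction])
    if not kept:
        raise ConfigurationError(
            f"no feature is active in more than {cfg.active_fraction:.0%} of "
            f"{cfg.active_over}; lower active_fraction"
        )
    logger.info("active-feature filter kept %d of %d CAs", len(kept), len(data))
    return kept


def labels_from_metadata(metas: Sequence[SampleMeta]) -> pd.DataFrame:
    """(sample, time point) table of group and phenotype labels."""
    rows = [
        (m.sample_id, t, m.group, p)
        for m in metas
        for t, p in sorted(m.phenotype_by_time.items())
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "time_point", "group", "phenotype"])
    return df.set_index(["sample_id", "time_point"])


def feature_matrix(
    activity: ActivityMatrix,
    labels: pd.Series | Mapping,
    features: Sequence | None = None,
    positive_label: str = "transgenic",
    cfg: MLConfig = MLConfig(),
) -> FeatureMatrix:
    """Assemble the data-point x feature matrix restricted to labelled points.

    With ``cfg.normalize`` the amplitudes of each data point are divided by
    that point's total amplitude (relative abundance); default raw counts.
    """
    data = activity.data
    if cfg.normalize:
        totals = data.sum(axis=0).replace(0, 1.0)
        data = data / totals
        logger.info("feature values: per-data-point relative abundance")
    if features is None:
        features = active_feature_filter(activity, cfg)
    X = data.loc[list(features)].T
    if not isinstance(labels, pd.Series):
        labels = pd.Series(dict(labels))
        labels.index = pd.MultiIndex.from_tuples(labels.index, names=["sample_id", "time_point"])
    common = X.index.intersection(labels.index)
    X = X.loc[common]
    y = labels.loc[common]
    return FeatureMatrix(X, y, positive_label)


def _loocv_folds(index: pd.MultiIndex, unit: str) -> list[np.ndarray]:
    n = len(index)
    if unit == "point":
        return [np.array([i]) for i in range(n)]
    if unit == "sample":
        samples = index.get_level_values("sample_id")
        return [np.flatnonzero(samples == s) for s in samples.unique()]
    raise ConfigurationError(f"unknown loocv_unit {unit!r}")


def loocv_score(
    X: np.ndarray, y: np.ndarray, cfg: MLConfig = MLConfig(),
    folds: list[np.ndarray] | None = None,
) -> float:
    """Leave-one-out accuracy of a Gaussian-kernel soft-margin SVM.

    The kernel bandwidth follows the median heuristic on the full subset
    (deterministic given the data) and the kernel matrix is precomputed
    once.  Folds containing no support vector of the full-data solution
    reuse it unchanged — removing points with zero Lagrange multiplier
    leaves the SVM solution intact — so only support-vector folds refit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("LOOCV needs at least two classes")
    n = X.shape[0]
    gamma = _resolve_gamma(X, cfg)
    K = np.exp(-gamma * squareform(pdist(X, "sqeuclidean")))
    if folds is None:
        folds = [np.array([i]) for i in range(n)]
    full = SVC(kernel="precomputed", C=cfg.C, shrinking=False)
    full.fit(K, y)
    full_pred = full.predict(K)
    is_sv = np.zeros(n, dtype=bool)
    is_sv[full.support_] = True
    correct = 0
    for held in folds:
        if not is_sv[held].any():
            correct += int((full_pred[held] == y[held]).sum())
            continue
        rest = np.setdiff1d(np.arange(n), held)
        if len(np.unique(y[rest])) < 2:
            continue  # degenerate fold: the held-out points carry a whole class
        clf = SVC(kernel="precomputed", C=cfg.C, shrinking=False)
        clf.fit(K[np.ix_(rest, rest)], y[rest])
        pred = clf.predict(K[np.ix_(held, rest)])
        correct += int((pred == y[held]).sum())
    return correct / n


def forward_selection(
    fm: FeatureMatrix, cfg: MLConfig = MLConfig()
) -> dict[int, list[tuple[tuple, float]]]:
    """Bottom-up subset search: all pairs, then one-feature extensions.

    Returns, per dimension, the ``top_k`` subsets as ``(features, LOOCV
    score)`` sorted by (score desc, subset lexicographic).  The search
    stops when the best score fails to improve by more than
    ``convergence_tol`` or the upper dimension bound is reached.
    """
    cols = sorted(fm.X.columns)
    if len(cols) < 2:
        raise ConfigurationError("forward selection needs at least two features")
    Xall = fm.X[cols].to_numpy(dtype=float)
    col_ix = {c: i for i, c in enumerate(cols)}
    y = fm.y01
    folds = _loocv_folds(fm.X.index, cfg.loocv_unit)

    def score(subset: tuple) -> float:
        ix = [col_ix[c] for c in subset]
        return loocv_score(Xall[:, ix], y, cfg, folds)

    def rank(cands: set[tuple]) -> list[tuple[tuple, float]]:
        scored = [(sub, score(sub)) for sub in sorted(cands)]
        scored.sort(key=lambda t: (-t[1], t[0]))
        return scored[: cfg.top_k]

    results: dict[int, list[tuple[tuple, float]]] = {}
    results[2] = rank(set(itertools.combinations(cols, 2)))
    best = results[2][0][1]
    d = 2
    while d < cfg.dims[1]:
        cands = {
            tuple(sorted(set(sub) | {c}))
            for sub, _ in results[d]
            for c in cols
            if c not in sub
        }
        if not cands:
            break
        ranked = rank(cands)
        d += 1
        results[d] = ranked
        if ranked[0][1] <= best + cfg.convergence_tol and d >= cfg.dims[0]:
            logger.info("forward selection converged at dimension %d", d)
            break
        best = max(best, ranked[0][1])
    return results


def train_ensemble(
    fm: FeatureMatrix,
    subsets: Sequence[tuple],
    cfg: MLConfig = MLConfig(),
) -> ClassifierEnsemble:
    """Committee of up to ``ensemble_size`` machines, the i-th trained on
    the i-th ranked feature subset (all of them, with a warning, if fewer
    subsets are available)."""
    if len(subsets) < cfg.ensemble_size:
        warnings.warn(
            f"only {len(subsets)} subsets available for an ensemble of "
            f"{cfg.ensemble_size}; using all of them",
            stacklevel=2,
        )
    chosen = list(subsets)[: cfg.ensemble_size]
    machines = []
    y = fm.y01
    for subset in chosen:
        X = fm.X[list(subset)].to_numpy(dtype=float)
        clf = SVC(kernel="rbf", C=cfg.C, gamma=_resolve_gamma(X, cfg))
        clf.fit(X, y)
        machines.append((tuple(subset), clf))
    return ClassifierEnsemble(machines)


def perturb(X, sigma: float, rng: np.random.Generator | int = 0):
    """Multiplicative Gaussian perturbation ``x -> x * (1 + v)``,
    ``v ~ N(0, sigma^2)`` drawn independently per element."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    noise = rng.normal(0.0, sigma, size=np.shape(X))
    if isinstance(X, pd.DataFrame):
        return X * (1.0 + noise)
    return np.asarray(X, dtype=float) * (1.0 + noise)


def _heldout_scores(
    fm: FeatureMatrix, subsets: Sequence[tuple], cfg: MLConfig,
    noisy_X: Mapping[float, pd.DataFrame],
) -> dict[float, np.ndarray]:
    """Ensemble output for every data point from machines trained without it.

    One fit per (machine, fold); every noise level is scored with the same
    fitted machines on its own noisy copy of the held-out points.
    """
    y = fm.y01
    n = len(y)
    folds = _loocv_folds(fm.X.index, cfg.loocv_unit)
    chosen = list(subsets)[: cfg.ensemble_size]
    sums = {s: np.zeros(n) for s in noisy_X}
    sigmas = list(noisy_X)
    for subset in chosen:
        cols = list(subset)
        X = fm.X[cols].to_numpy(dtype=float)
        gamma = _resolve_gamma(X, cfg)
        noisy = {s: noisy_X[s][cols].to_numpy(dtype=float) for s in sigmas}
        full = SVC(kernel="rbf", C=cfg.C, gamma=gamma, shrinking=False)
        full.fit(X, y)
        is_sv = np.zeros(n, dtype=bool)
        is_sv[full.support_] = True
        # folds free of support vectors: the full solution is the held-out
        # solution, so score their noisy copies in one batch per sigma
        sv_free = [h for h in folds if not is_sv[h].any()]
        free = np.concatenate(sv_free) if sv_free else np.array([], dtype=int)
        for s in sigmas:
            if free.size:
                sums[s][free] += _logistic(full.decision_function(noisy[s][free]))
        for held in folds:
            if not is_sv[held].any():
                continue
            rest = np.setdiff1d(np.arange(n), held)
            if len(np.unique(y[rest])) < 2:
                for s in sigmas:
                    sums[s][held] += 0.5
                continue
            clf = SVC(kernel="rbf", C=cfg.C, gamma=gamma, shrinking=False)
            clf.fit(X[rest], y[rest])
            stacked = np.vstack([noisy[s][held] for s in sigmas])
            dec = _logistic(clf.decision_function(stacked))
            m = len(held)
            for j, s in enumerate(sigmas):
                sums[s][held] += dec[j * m : (j + 1) * m]
    return {s: v / len(chosen) for s, v in sums.items()}


def evaluate_roc(
    fm: FeatureMatrix,
    subsets_by_dim: Mapping[int, Sequence[tuple[tuple, float]]],
    cfg: MLConfig = MLConfig(),
) -> RocResult:
    """Noise-robustness ROC analysis across model dimensions.

    For every dimension the top-ranked subsets form the committee; every
    data point is scored held-out (machines refit without it) on copies
    perturbed at each noise amplitude.  The noise-averaged ROC averages
    the (FPR, TPR) points over amplitudes on a common threshold grid; the
    dimension with the highest noise-averaged AUC wins, ties going to the
    smaller dimension.
    """
    y = fm.y01
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC evaluation needs both classes present")
    rng = np.random.default_rng(cfg.seed)
    noisy_X = {s: perturb(fm.X, s, rng) for s in cfg.noise_amplitudes}
    thresholds = np.linspace(0.0, 1.0, 201)
    aucs: dict[tuple[int, float], float] = {}
    curves: dict[tuple[int, float], tuple[np.ndarray, np.ndarray]] = {}
    avg_auc: dict[int, float] = {}
    avg_curve: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for d in sorted(subsets_by_dim):
        subsets = [sub for sub, _ in subsets_by_dim[d]]
        scores = _heldout_scores(fm, subsets, cfg, noisy_X)
        fprs, tprs = [], []
        for s, sc in scores.items():
            fpr, tpr, _ = roc_curve(y, sc)
            aucs[(d, s)] = float(_trapezoid_auc(fpr, tpr))
            curves[(d, s)] = (fpr, tpr)
            grid_fpr = [np.mean(sc[y == 0] >= t) for t in thresholds]
            grid_tpr = [np.mean(sc[y == 1] >= t) for t in thresholds]
            fprs.append(grid_fpr)
            tprs.append(grid_tpr)
        avg_curve[d] = (np.mean(fprs, axis=0), np.mean(tprs, axis=0))
        avg_auc[d] = float(np.mean([aucs[(d, s)] for s in scores]))
    chosen = min(avg_auc, key=lambda d: (-round(avg_auc[d], 12), d))
    fpr_c, tpr_c = avg_curve[chosen]
    ok = fpr_c <= cfg.operating_fpr + 1e-12
    if ok.any():
        i = int(np.argmax(np.where(ok, fpr_c, -1.0)))
        operating = (float(fpr_c[i]), float(tpr_c[i]))
    else:
        operating = (float(fpr_c.min()), float(tpr_c[np.argmin(fpr_c)]))
    return RocResult(aucs, curves, avg_auc, avg_curve, int(chosen), operating)


def _run_stage(
    activity: ActivityMatrix,
    labels: pd.Series,
    positive_label: str,
    cfg: MLConfig,
) -> StageResult:
    features = active_feature_filter(activity, cfg)
    fm = feature_matrix(activity, labels, features, positive_label, cfg)
    if len(np.unique(fm.y01)) < 2:
        raise ValidationError(
            f"stage needs both classes; got only {set(fm.y.unique())}"
        )
    subsets = forward_selection(fm, cfg)
    eval_dims = {d: s for d, s in subsets.items() if d >= min(cfg.dims[0], max(subsets))}
    roc = evaluate_roc(fm, eval_dims, cfg)
    committee = [sub for sub, _ in subsets[roc.chosen_dim][: cfg.ensemble_size]]
    selected = sorted({c for sub in committee for c in sub})
    return StageResult(features, subsets, roc, selected)


def two_stage_classify(
    activity: ActivityMatrix,
    metas: Sequence[SampleMeta],
    cfg: MLConfig = MLConfig(),
) -> TwoStageResult:
    """Stage 1: control vs. transgenic on all data points.  Stage 2:
    pre-cancer vs. cancer on the transgenic points only.  Reports the two
    selected feature lists and their Jaccard overlap."""
    lab = labels_from_metadata(metas)
    stage1 = _run_stage(activity, lab["group"], "transgenic", cfg)

    mask = (lab["group"] == "transgenic") & lab["phenotype"].isin(["pre_cancer", "cancer"])
    pheno = lab.loc[mask, "phenotype"]
    stage2 = None
    jaccard = None
    if pheno.nunique() < 2:
        warnings.warn("stage 2 skipped: pre_cancer or cancer class absent", stacklevel=2)
    else:
        sub_activity = ActivityMatrix(activity.data[pheno.index])
        stage2 = _run_stage(sub_activity, pheno, "cancer", cfg)
        s1, s2 = set(stage1.selected_features), set(stage2.selected_features)
        jaccard = len(s1 & s2) / len(s1 | s2) if (s1 | s2) else 0.0
    return TwoStageResult(stage1, stage2, jaccard)
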
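"""Bootstrap/inner-CV model-selection harness with a meta-learner.

Evaluation scheme: in each of ``n_iter`` iterations, n patients are drawn
with replacement; all samples of drawn patients form the training set and
all remaining samples the test set (iterations with fewer than 5 test
samples of either class are redrawn). Within the training set, stratified
5-fold cross-validation selects one algorithm + hyperparameter combination
from

* linear SVM, C in [2^-5, 2^-3, 2^-1, 2^1, 2^3, 2^7, 2^9, 2^11, 2^13, 2^15];
* feed-forward neural network, two hidden layers of 200, rectifier
  activation, adaptive learning rate (optional — off by default so a full
  run stays fast);
* random forest, 200 trees;
* binomial elastic-net GLM, l1 ratio in [0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1].

For all but the SVM, the minority class is oversampled inside each
training fold by ceil(majority/minority) duplication. Selection is by mean
inner AUC; ties go to the simpler model family (GLM < SVM < RF < NN).

The meta-learner is a Gaussian (ordinary least squares) linear model over
the per-feature-set predicted probabilities; its training inputs are
out-of-fold predictions on the iteration's training set only, so no test
information leaks into it.

ROC curves are averaged vertically on a fixed 1001-point FPR grid; the
aggregate AUC is the trapezoid area under the mean curve.

Cross-dataset harmonization standardizes every feature per source dataset
using that source's healthy controls (mean 0, sd 1 on controls).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

SVM_C_GRID = [2.0 ** k for k in (-5, -3, -1, 1, 3, 7, 9, 11, 13, 15)]
ENET_ALPHA_GRID = [0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0]
ROC_GRID_POINTS = 1001
#: tie-break order, simplest first
FAMILY_ORDER = ("glm", "svm", "rf", "nn")


# ---------------------------------------------------------------------------
# Cross-dataset harmonization
# ---------------------------------------------------------------------------


def harmonize(
    X: pd.DataFrame, control_mask: np.ndarray, source_tags: np.ndarray
) -> pd.DataFrame:
    """Per-source, per-feature standardization on that source's controls.

    Every source must contribute >= 2 controls. Features with zero control
    spread in any source are dropped with a log message.
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    source_tags = np.asarray(source_tags)
    out = X.copy().astype(float)
    drop: set[str] = set()
    for source in np.unique(source_tags):
        in_source = source_tags == source
        ctrl = in_source & control_mask
        if ctrl.sum() < 2:
            raise ValueError(f"source {source!r} has < 2 controls")
        mean = X.loc[ctrl].mean(axis=0)
        sd = X.loc[ctrl].std(axis=0, ddof=1)
        zero = sd[sd == 0].index
        drop.update(zero)
        sd = sd.replace(0, np.nan)
        out.loc[in_source] = (X.loc[in_source] - mean) / sd
    if drop:
        logger.warning("dropping %d features with zero control spread: %s",
                       len(drop), sorted(drop)[:5])
        out = out.drop(columns=sorted(drop))
    return out


# ---------------------------------------------------------------------------
# Candidate models and inner selection
# ---------------------------------------------------------------------------


def _candidates(include_nn: bool, seed: int) -> list[tuple[str, dict, object, bool]]:
    """(family, params, estimator, oversample) in tie-break order."""
    cands: list[tuple[str, dict, object, bool]] = []
    for alpha in ENET_ALPHA_GRID:
        est = make_pipeline(
            StandardScaler(),
            LogisticRegression(solver="saga", l1_ratio=alpha, C=1.0,
                               max_iter=500, tol=1e-3, random_state=seed),
        )
        cands.append(("glm", {"l1_ratio": alpha}, est, True))
    for C in SVM_C_GRID:
        est = make_pipeline(StandardScaler(), LinearSVC(C=C, random_state=seed))
        cands.append(("svm", {"C": C}, est, False))
    cands.append(
        ("rf", {"n_trees": 200},
         RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1), True)
    )
    if include_nn:
        from sklearn.neural_network import MLPClassifier

        cands.append(
            ("nn", {"hidden": (200, 200)},
             MLPClassifier(hidden_layer_sizes=(200, 200), activation="relu",
                           learning_rate="adaptive", max_iter=500, random_state=seed),
             True)
        )
    return cands


def _oversample(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate the minority class by ceil(majority/minority)."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    factor = math.ceil(counts.max() / counts.min())
    idx = np.flatnonzero(y == minority)
    extra = np.tile(idx, factor - 1)
    keep = np.concatenate([np.arange(len(y)), extra])
    return X[keep], y[keep]


def _proba(est, X: np.ndarray) -> np.ndarray:
    """Predicted probability of the positive class; margin classifiers get
    a sigmoid link on their decision values (monotone, so ROC-identical)."""
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return expit(est.decision_function(X))


@dataclass
class SelectedModel:
    family: str
    params: dict
    estimator: object
    inner_auc: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _proba(self.estimator, X)


def inner_select(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    include_nn: bool = False,
    n_folds: int = 5,
) -> SelectedModel:
    """Stratified 5-fold inner CV over all candidates; refit the winner on
    the full training set.

    Oversampling happens inside each fold's training portion (and in the
    final refit) so duplicated samples never straddle a fold boundary.
    Ties in inner AUC go to the simpler family, then the earlier grid
    entry.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    n_folds = min(n_folds, int(counts.min()))
    if n_folds < 2:
        raise ValueError("too few samples of one class for inner CV")
    cands = _candidates(include_nn, seed)

    # one shared fold assignment keeps the comparison fair across candidates
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
    scores = []
    for family, params, est, oversample in cands:
        aucs = []
        for tr, va in folds:
            Xtr, ytr = X[tr], y[tr]
            if oversample:
                Xtr, ytr = _oversample(Xtr, ytr)
            m = clone(est)
            m.fit(Xtr, ytr)
            if len(np.unique(y[va])) == 2:
                aucs.append(roc_auc_score(y[va], _proba(m, X[va])))
        scores.append(float(np.mean(aucs)) if aucs else 0.5)

    best = int(np.argmax(scores))  # argmax keeps the first (simplest) on ties
    family, params, est, oversample = cands[best]
    Xf, yf = (X, y) if not oversample else _oversample(X, y)
    fitted = clone(est)
    fitted.fit(Xf, yf)
    return SelectedModel(family=family, params=params, estimator=fitted,
                         inner_auc=scores[best])


# ---------------------------------------------------------------------------
# ROC averaging
# ---------------------------------------------------------------------------


def average_roc(curves: list[tuple[np.ndarray, np.ndarray]]
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Vertical (per-FPR) average of ROC curves on a fixed 1001-point grid.

    Returns (fpr_grid, mean_tpr, auc of the mean curve). Grid endpoints
    (0, 0) and (1, 1) are always present.
    """
    if not curves:
        raise ValueError("no curves to average")
    grid = np.linspace(0.0, 1.0, ROC_GRID_POINTS)
    tprs = []
    for fpr, tpr in curves:
        fpr = np.concatenate([[0.0], np.asarray(fpr), [1.0]])
        tpr = np.concatenate([[0.0], np.asarray(tpr), [1.0]])
        tprs.append(np.interp(grid, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0] = 0.0
    mean_tpr[-1] = 1.0
    return grid, mean_tpr, float(np.trapezoid(mean_tpr, grid))


# ---------------------------------------------------------------------------
# Bootstrap evaluation
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Aggregate of the patient-level bootstrap evaluation."""

    fpr_grid: np.ndarray = field(repr=False)
    mean_tpr: np.ndarray = field(repr=False)
    auc: float
    per_iteration_auc: np.ndarray = field(repr=False)
    chosen: list[dict] = field(repr=False, default_factory=list)
    #: per-iteration (train patient ids, test patient ids) for leakage audits
    splits: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)

    @property
    def auc_ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.per_iteration_auc, [2.5, 97.5])
        return float(lo), float(hi)


def _draw_split(
    patients: np.ndarray, y: np.ndarray, rng: np.random.Generator,
    min_test_per_class: int = 5, max_redraws: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level bootstrap train/test index split with the test-set
    class-count rule; a patient's samples never straddle the split."""
    unique_patients = np.unique(patients)
    n = len(unique_patients)
    for _ in range(max_redraws):
        drawn = rng.choice(unique_patients, size=n, replace=True)
        train = np.isin(patients, drawn)
        test = ~train
        if test.sum() == 0:
            continue
        counts = [np.sum(y[test] == c) for c in np.unique(y)]
        if min(counts) >= min_test_per_class:
            return np.flatnonzero(train), np.flatnonzero(test)
    raise RuntimeError("could not satisfy the test-set class rule after redraws")


def _out_of_fold_predictions(
    X: np.ndarray, y: np.ndarray, model: SelectedModel, seed: int, n_folds: int = 5
) -> np.ndarray:
    """Out-of-fold probabilities on the training set using the selected
    model's family and hyperparameters (freshly refit per fold)."""
    n_folds = min(n_folds, int(np.unique(y, return_counts=True)[1].min()))
    oof = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=max(n_folds, 2), shuffle=True, random_state=seed)
    for tr, va in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            continue
        Xtr, ytr = _oversample(X[tr], y[tr]) if model.family != "svm" else (X[tr], y[tr])
        m = clone(model.estimator)
        m.fit(Xtr, ytr)
        oof[va] = _proba(m, X[va])
    oof[np.isnan(oof)] = float(np.mean(y))
    return oof


def bootstrap_evaluate(
    feature_sets: dict[str, pd.DataFrame] | pd.DataFrame,
    y: np.ndarray,
    patients: np.ndarray,
    n_iter: int = 100,
    seed: int = 0,
    include_nn: bool = False,
    meta: bool = True,
) -> dict[str, BootstrapResult]:
    """Patient-level bootstrap evaluation of one or several feature sets.

    With several feature sets the iterations share their train/test splits
    and a Gaussian linear meta-learner combines the per-set predicted
    probabilities (trained on out-of-fold training predictions only);
    its result appears under the key ``"meta"``.
    """
    if isinstance(feature_sets, pd.DataFrame):
        feature_sets = {"features": feature_sets}
        meta = False
    names = list(feature_sets)
    mats = {k: np.asarray(v, dtype=float) for k, v in feature_sets.items()}
    y = np.asarray(y)
    patients = np.asarray(patients)
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")

    rng = np.random.default_rng(seed)
    curves: dict[str, list] = {k: [] for k in names + (["meta"] if meta else [])}
    aucs: dict[str, list] = {k: [] for k in curves}
    chosen: dict[str, list] = {k: [] for k in curves}
    splits: list[tuple[np.ndarray, np.ndarray]] = []

    for it in range(n_iter):
        tr, te = _draw_split(patients, y, rng)
        splits.append((np.unique(patients[tr]), np.unique(patients[te])))
        it_seed = int(rng.integers(0, 2**31 - 1))
        test_probas = {}
        train_oof = {}
        for k in names:
            model = inner_select(mats[k][tr], y[tr], seed=it_seed, include_nn=include_nn)
            test_probas[k] = model.predict_proba(mats[k][te])
            chosen[k].append({"iteration": it, "family": model.family, **model.params})
            if meta:
                train_oof[k] = _out_of_fold_predictions(mats[k][tr], y[tr], model, it_seed)
        if meta:
            meta_model = LinearRegression()
            meta_model.fit(np.column_stack([train_oof[k] for k in names]), y[tr])
            test_probas["meta"] = np.clip(
                meta_model.predict(np.column_stack([test_probas[k] for k in names])),
                0.0, 1.0,
            )
            chosen["meta"].append({"iteration": it, "family": "gaussian_glm"})
        for k, proba in test_probas.items():
            fpr, tpr, _ = roc_curve(y[te], proba)
            curves[k].append((fpr, tpr))
            aucs[k].append(roc_auc_score(y[te], proba))

    out = {}
    for k in curves:
        grid, mean_tpr, auc = average_roc(curves[k])
        out[k] = BootstrapResult(
            fpr_grid=grid, mean_tpr=mean_tpr, auc=auc,
            per_iteration_auc=np.array(aucs[k]), chosen=chosen[k], splits=splits,
        )
    return out
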
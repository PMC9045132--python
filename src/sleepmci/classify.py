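"""Train and evaluate the SVM and Bi-GRU classifiers.

Both classifiers emit a per-segment MCI score in [0, 1]; 0.5 is the
decision threshold for the confusion matrix. Evaluation metrics follow
the standard confusion-matrix formulas:

    sensitivity = TP / (TP + FN) * 100%
    specificity = TN / (TN + FP) * 100%
    accuracy    = (TP + TN) / (TP + FN + TN + FP) * 100%
    F1          = 2 * precision * recall / (precision + recall) * 100%

with the ROC traced by sweeping the score threshold and the AUC computed
by the trapezoid rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureTable, standardize
from .gru import BiGRU, GruConfig


@dataclass
class SvmConfig:
    """Cubic-polynomial-kernel SVM. ``gamma``/``C`` None triggers a
    10-fold cross-validated grid search; the printed NREM preset is
    gamma = 2.15, C = 1 and the wake preset gamma = 13.2, C = 2."""

    degree: int = 3
    gamma: float | None = 2.15
    C: float | None = 1.0
    coef0: float = 1.0
    gamma_grid: tuple = (0.01, 0.1, 1.0, 2.15, 10.0, 13.2)
    C_grid: tuple = (0.1, 0.5, 1.0, 2.0, 10.0)

    def __post_init__(self) -> None:
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.C is not None and self.C <= 0:
            raise ValueError("C must be positive")


def wake_svm_config(**kw) -> SvmConfig:
    kw.setdefault("gamma", 13.2)
    kw.setdefault("C", 2.0)
    return SvmConfig(**kw)


@dataclass
class EvalReport:
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float     # %
    sensitivity: float  # %
    specificity: float  # %
    f1: float           # %
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    scores: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1,
                "auc": self.auc}


def split_data(table: FeatureTable, train_fraction: float = 0.8, seed: int = 0,
               grouping: str = "segment"):
    """Stratified random train/test split at segment or subject level.

    Returns (train_idx, test_idx) as integer row indices, deterministic
    per seed. Subject grouping guarantees no subject spans both sides.
    """
    y = table.y
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    if grouping == "segment":
        for cls in classes:
            rows = np.flatnonzero(y == cls)
            if rows.size < 2:
                raise ValueError("need >= 2 rows per class")
            rows = rng.permutation(rows)
            n_train = int(round(train_fraction * rows.size))
            n_train = min(max(n_train, 1), rows.size - 1)
            train_idx.extend(rows[:n_train])
            test_idx.extend(rows[n_train:])
    elif grouping == "subject":
        subjects = table.meta["subject"].to_numpy()
        for cls in classes:
            subj = np.unique(subjects[y == cls])
            subj = rng.permutation(subj)
            n_train = int(round(train_fraction * subj.size))
            n_train = min(max(n_train, 1), subj.size - 1)
            train_subj = set(subj[:n_train])
            for i in np.flatnonzero(y == cls):
                (train_idx if subjects[i] in train_subj else test_idx).append(i)
    else:
        raise ValueError("grouping must be 'segment' or 'subject'")
    return np.sort(train_idx), np.sort(test_idx)


def _cv_accuracy(model_factory, X, y, cv_folds, seed):
    accs = []
    for attempt in range(3):
        try:
            skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                                  random_state=seed + attempt)
            accs = []
            for tr, va in skf.split(X, y):
                if np.unique(y[tr]).size < 2:
                    raise ValueError("single-class fold")
                m = model_factory()
                m.fit(X[tr], y[tr])
                accs.append(float((m.predict(X[va]) == y[va]).mean()))
            return float(np.mean(accs))
        except ValueError:
            continue
    raise ValueError("could not build folds with both classes after 3 attempts")


def train_svm(X, y, config: SvmConfig | None = None, cv_folds: int = 10,
              seed: int = 0):
    """Fit the cubic-polynomial SVM on standardized features.

    When gamma or C is None, the pair is chosen from the config grids by
    10-fold cross-validated accuracy. Returns (model, cv_accuracy); the
    model's ``score01`` attribute maps decision values to [0, 1] MCI
    scores by a rank-preserving logistic squash.
    """
    config = config or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cv_folds = min(cv_folds, int(np.bincount(y).min()))
    if config.gamma is None or config.C is None:
        gammas = config.gamma_grid if config.gamma is None else (config.gamma,)
        cs = config.C_grid if config.C is None else (config.C,)
        best = (-1.0, None)
        for g in gammas:
            for c in cs:
                acc = _cv_accuracy(
                    lambda: SVC(kernel="poly", degree=config.degree, gamma=g,
                                C=c, coef0=config.coef0),
                    X, y, cv_folds, seed)
                if acc > best[0]:
                    best = (acc, (g, c))
        gamma, C = best[1]
        cv_acc = best[0]
    else:
        gamma, C = config.gamma, config.C
        cv_acc = _cv_accuracy(
            lambda: SVC(kernel="poly", degree=config.degree, gamma=gamma,
                        C=C, coef0=config.coef0),
            X, y, cv_folds, seed)
    model = SVC(kernel="poly", degree=config.degree, gamma=gamma, C=C,
                coef0=config.coef0)
    model.fit(X, y)
    model.score01 = lambda Z: 1.0 / (1.0 + np.exp(-model.decision_function(Z)))
    return model, cv_acc


def train_bigru(X, y, config: GruConfig | None = None, cv_folds: int = 10,
                seed: int = 0):
    """Train the Bi-GRU with cross-validated best-epoch selection.

    Per the training protocol, up to ``max_epochs`` epochs are run on each
    CV fold; the epoch with the best mean validation accuracy is selected
    and a final model is trained on all rows for that many epochs.
    Returns (model, {"best_epoch", "cv_accuracy"}).
    """
    config = config or GruConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[-1] != config.input_size:
        raise ValueError(
            f"feature width {X.shape[-1]} != configured input size "
            f"{config.input_size}")
    cv_folds = min(cv_folds, int(np.bincount(y).min()))
    if cv_folds >= 2:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        acc_curves = []
        for fold_i, (tr, va) in enumerate(skf.split(X, y)):
            cfg = GruConfig(**{**config.__dict__, "seed": seed * 1000 + fold_i})
            net = BiGRU(cfg)
            hist = net.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
            acc_curves.append(hist["val_acc"])
        mean_acc = np.mean(acc_curves, axis=0)
        best_epoch = int(np.argmax(mean_acc)) + 1
        cv_acc = float(mean_acc[best_epoch - 1])
    else:
        best_epoch = config.max_epochs
        cv_acc = float("nan")
    final_cfg = GruConfig(**{**config.__dict__, "seed": seed})
    model = BiGRU(final_cfg)
    model.fit(X, y, n_epochs=best_epoch)
    return model, {"best_epoch": best_epoch, "cv_accuracy": cv_acc}


def evaluate(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Confusion counts, the four %-metrics, ROC points and AUC."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if scores.size != y.size:
        raise ValueError("scores and labels must have the same length")
    if np.unique(y).size < 2:
        raise ValueError("both classes required: sensitivity or specificity "
                         "would be undefined")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sens = tp / (tp + fn) * 100.0
    spec = tn / (tn + fp) * 100.0
    acc = (tp + tn) / (tp + fn + tn + fp) * 100.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn)
    f1 = (2 * precision * recall / (precision + recall) * 100.0
          if precision + recall else 0.0)
    # ROC by sweeping the threshold over the observed scores
    thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    tpr = np.array([((scores >= t) & (y == 1)).sum() / n_pos for t in thresholds])
    fpr = np.array([((scores >= t) & (y == 0)).sum() / n_neg for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return EvalReport(tp=tp, fn=fn, tn=tn, fp=fp, accuracy=acc,
                      sensitivity=sens, specificity=spec, f1=f1,
                      roc_fpr=fpr, roc_tpr=tpr, auc=auc, scores=scores)


def run_split_and_train(table: FeatureTable, model: str = "svm",
                        train_fraction: float = 0.8, seed: int = 0,
                        grouping: str = "segment", cv_folds: int = 10,
                        svm_config: SvmConfig | None = None,
                        gru_config: GruConfig | None = None):
    """Convenience end-to-end: split, standardize on train rows, fit,
    score the test rows. Returns an EvalReport on the test partition."""
    train_idx, test_idx = split_data(table, train_fraction, seed, grouping)
    std = standardize(table, train_idx)
    Xtr, ytr = std.X[train_idx], std.y[train_idx]
    Xte, yte = std.X[test_idx], std.y[test_idx]
    if model == "svm":
        fitted, _ = train_svm(Xtr, ytr, svm_config, cv_folds, seed)
        scores = fitted.score01(Xte)
    elif model == "bigru":
        cfg = gru_config or GruConfig(input_size=std.X.shape[1])
        fitted, _ = train_bigru(Xtr, ytr, cfg, cv_folds, seed)
        scores = fitted.predict_scores(Xte)
    else:
        raise ValueError("model must be 'svm' or 'bigru'")
    return evaluate(scores, yte)
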
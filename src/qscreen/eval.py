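"""Maximum-margin classification on precomputed Gram matrices, metric
computation, exact McNemar paired comparison, and the benchmark suite.

The classifier is a soft-margin SVM solved on the precomputed kernel
matrix; evaluation follows the usual screening-test vocabulary (accuracy,
precision, recall/sensitivity, specificity, F1, ROC-AUC), and classifier
pairs are compared with the exact binomial McNemar test on their
discordant predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "PD"


@dataclass
class TrainedModel:
    """A fitted precomputed-kernel SVM, reconstructible from stored pieces."""

    support_indices: np.ndarray      # indices into the training rows
    dual_coefficients: np.ndarray    # alpha_i * y_i for support vectors
    bias: float
    C: float
    train_ids: list
    classes: tuple[str, str]         # (negative, positive)

    def __post_init__(self) -> None:
        if np.any(np.abs(self.dual_coefficients) > self.C + 1e-8):
            raise ValueError("|dual coefficients| must be <= C")


def svm_fit(train_gram: np.ndarray, labels, C: float = 1.0,
            train_ids: list | None = None) -> TrainedModel:
    """Solve the soft-margin dual on a precomputed kernel matrix.

    No kernel hyperparameters exist (the Gram matrix is the input); C is
    the only knob and defaults to the conventional 1.0.
    """
    from sklearn.svm import SVC

    K = np.asarray(train_gram, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("train Gram must be square")
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    # put the positive (PD) label last so sklearn's decision sign means PD
    neg, pos = sorted(classes, key=lambda c: c == POSITIVE_LABEL)
    clf = SVC(C=C, kernel="precomputed")
    clf.fit(K, np.where(y == pos, 1, -1))
    if train_ids is None:
        train_ids = list(range(K.shape[0]))
    return TrainedModel(
        support_indices=clf.support_.copy(),
        dual_coefficients=clf.dual_coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        C=C,
        train_ids=list(train_ids),
        classes=(str(neg), str(pos)),
    )


def svm_decision(model: TrainedModel, cross_gram: np.ndarray) -> np.ndarray:
    """Decision scores sum_i alpha_i y_i K(x, x_i) + b for test rows.

    ``cross_gram`` is test x train; its columns must align with the
    training rows the model was fitted on.
    """
    K = np.atleast_2d(np.asarray(cross_gram, dtype=float))
    if K.shape[1] != len(model.train_ids):
        raise ValueError("cross-Gram columns do not match training rows")
    return K[:, model.support_indices] @ model.dual_coefficients + model.bias


def svm_predict(model: TrainedModel, cross_gram: np.ndarray) -> np.ndarray:
    """Labels by decision-score sign; an exact zero ties to the positive."""
    scores = svm_decision(model, cross_gram)
    neg, pos = model.classes
    return np.where(scores >= 0.0, pos, neg)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Confusion counts with the derived screening metrics."""

    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float = field(init=False)
    precision: float = field(init=False)
    recall_sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    f1: float = field(init=False)
    roc_auc: float = float("nan")

    def __post_init__(self) -> None:
        tp, fn, fp, tn = self.tp, self.fn, self.fp, self.tn
        n = tp + fn + fp + tn
        self.accuracy = (tp + tn) / n if n else float("nan")
        self.precision = tp / (tp + fp) if tp + fp else float("nan")
        self.recall_sensitivity = tp / (tp + fn) if tp + fn else float("nan")
        self.specificity = tn / (tn + fp) if tn + fp else float("nan")
        p, r = self.precision, self.recall_sensitivity
        self.f1 = (2 * p * r / (p + r)
                   if np.isfinite(p) and np.isfinite(r) and (p + r) > 0
                   else float("nan"))

    @property
    def n_test(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def confusion(self) -> tuple[int, int, int, int]:
        return self.tp, self.fn, self.fp, self.tn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall_sensitivity": self.recall_sensitivity,
            "specificity": self.specificity, "f1": self.f1,
            "roc_auc": self.roc_auc, "n_test": self.n_test,
        }


def rank_auc(y_true: np.ndarray, scores: np.ndarray,
             positive=POSITIVE_LABEL) -> float:
    """ROC-AUC as the Mann-Whitney rank statistic (ties counted half)."""
    y = np.asarray(y_true) == positive
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def confusion_and_metrics(y_true, y_pred, scores=None,
                          positive=POSITIVE_LABEL) -> EvaluationReport:
    """Confusion counts and all metrics; undefined ratios come back NaN."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    t = y_true == positive
    p = y_pred == positive
    report = EvaluationReport(
        tp=int(np.sum(t & p)), fn=int(np.sum(t & ~p)),
        fp=int(np.sum(~t & p)), tn=int(np.sum(~t & ~p)),
    )
    if scores is not None:
        report.roc_auc = rank_auc(y_true, scores, positive)
    return report


def mcnemar_exact(b: int, c: int) -> float:
    """Two-sided exact McNemar p-value from the discordant-pair counts.

    Under the null the smaller discordant count is Binomial(b+c, 1/2);
    p = 2 * P(X <= min(b, c)), capped at 1.
    """
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))


def discordant_counts(y_true, pred_a, pred_b) -> tuple[int, int]:
    """(b, c): cases only model A got right, and only model B got right."""
    y_true = np.asarray(y_true)
    a_ok = np.asarray(pred_a) == y_true
    b_ok = np.asarray(pred_b) == y_true
    return int(np.sum(a_ok & ~b_ok)), int(np.sum(~a_ok & b_ok))


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------

def _classical_models(seed: int) -> dict:
    from sklearn.ensemble import (GradientBoostingClassifier,
                                  RandomForestClassifier)
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    return {
        "linear_svm": SVC(kernel="linear", C=1.0),
        "poly_svm": SVC(kernel="poly", C=1.0),
        "rbf_svm": SVC(kernel="rbf", C=1.0),
        "random_forest": RandomForestClassifier(random_state=seed),
        "gradient_boost": GradientBoostingClassifier(random_state=seed),
        "naive_bayes": GaussianNB(),
        "logistic_regression": LogisticRegression(max_iter=1000),
        "knn": KNeighborsClassifier(),
    }


def benchmark_suite(std_df: pd.DataFrame, kernel_spec, seed: int = 0,
                    C: float = 1.0, quantum_subset: tuple[int, int] | None
                    = (30, 15), zz_max_qubits: int = 20) -> pd.DataFrame:
    """Run the proposed kernel plus classical and feature-map baselines.

    All models share the same standardized split.  The Z/ZZ feature-map
    fidelity kernels optionally run on a reduced subset (default first 30
    train / 15 test rows) because full entangled statevector Grams are
    expensive.  Returns one row of metrics per model; per-model failures
    are logged and marked, not fatal.  Pairwise exact McNemar p-values
    against the proposed model are included where test sets coincide.
    """
    from .kernel import featuremap_gram, gram_matrix

    train = std_df[std_df["split"] == "train"]
    test = std_df[std_df["split"] == "test"]
    y_train = train["label"].to_numpy()
    y_test = test["label"].to_numpy()

    X_train = kernel_spec.transform(train)
    X_test = kernel_spec.transform(test)
    w = kernel_spec.softmax_weights

    results, predictions = [], {}

    # proposed quantum-inspired kernel
    K_train = gram_matrix(X_train, X_train, w).values
    K_cross = gram_matrix(X_test, X_train, w).values
    model = svm_fit(K_train, y_train, C=C)
    scores = svm_decision(model, K_cross)
    preds = svm_predict(model, K_cross)
    rep = confusion_and_metrics(y_test, preds, scores)
    results.append({"model": "proposed_qsvm", **rep.as_dict()})
    predictions["proposed_qsvm"] = (y_test, preds)

    # classical baselines on the full standardized feature set
    cols = [c for c in std_df.columns if c not in ("label", "split")]
    Xf_train = train[cols].to_numpy(dtype=float)
    Xf_test = test[cols].to_numpy(dtype=float)
    for name, clf in _classical_models(seed).items():
        try:
            clf.fit(Xf_train, y_train)
            preds = clf.predict(Xf_test)
            if hasattr(clf, "decision_function"):
                sc = clf.decision_function(Xf_test)
                if sc.ndim > 1:
                    sc = sc[:, -1]
                pos_last = list(clf.classes_).index(POSITIVE_LABEL)
                if pos_last == 0:
                    sc = -sc
            else:
                pos_idx = list(clf.classes_).index(POSITIVE_LABEL)
                sc = clf.predict_proba(Xf_test)[:, pos_idx]
            rep = confusion_and_metrics(y_test, preds, sc)
            results.append({"model": name, **rep.as_dict()})
            predictions[name] = (y_test, preds)
        except Exception as e:  # noqa: BLE001 - suite must continue
            logger.warning("baseline %s failed: %s", name, e)
            results.append({"model": name, "failed": True})

    # Z / ZZ feature-map fidelity kernels, optionally on a subset
    for kind in ("z", "zz"):
        try:
            Xq_train, Xq_test = X_train, X_test
            yq_train, yq_test = y_train, y_test
            if quantum_subset is not None:
                n_tr, n_te = quantum_subset
                Xq_train, yq_train = X_train[:n_tr], y_train[:n_tr]
                Xq_test, yq_test = X_test[:n_te], y_test[:n_te]
            if kind == "zz" and Xq_train.shape[1] > zz_max_qubits:
                raise ValueError(
                    f"ZZ map needs <= {zz_max_qubits} features; "
                    "pass a feature subset")
            Kq = featuremap_gram(Xq_train, Xq_train, kind=kind)
            Kq_cross = featuremap_gram(Xq_test, Xq_train, kind=kind)
            m = svm_fit(Kq, yq_train, C=C)
            sc = svm_decision(m, Kq_cross)
            preds = svm_predict(m, Kq_cross)
            rep = confusion_and_metrics(yq_test, preds, sc)
            results.append({"model": f"{kind}_featuremap", **rep.as_dict()})
            predictions[f"{kind}_featuremap"] = (yq_test, preds)
        except Exception as e:  # noqa: BLE001
            logger.warning("%s feature map failed: %s", kind, e)
            results.append({"model": f"{kind}_featuremap", "failed": True})

    table = pd.DataFrame(results).set_index("model")
    ref_y, ref_pred = predictions["proposed_qsvm"]
    pvals = {}
    for name, (yt, pr) in predictions.items():
        if name == "proposed_qsvm" or len(yt) != len(ref_y):
            continue
        b, c = discordant_counts(ref_y, ref_pred, pr)
        pvals[name] = mcnemar_exact(b, c)
    table["mcnemar_p_vs_proposed"] = pd.Series(pvals)
    return table


def report_table(table: pd.DataFrame) -> pd.DataFrame:
    """Comparison table in the conventional column order."""
    cols = ["accuracy", "roc_auc", "f1", "precision",
            "recall_sensitivity", "specificity"]
    out = table.reindex(columns=cols)
    out.columns = ["Accuracy", "ROC/AUC", "F1 Score", "Precision",
                   "Recall/Sensitivity", "Specificity"]
    return out
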
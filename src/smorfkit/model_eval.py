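"""Classifier training and evaluation for smORF coding potential.

The classifier roster is LR, SVM, RF and GTB (scikit-learn); RF with
``max_features='sqrt'`` is the default.  Evaluation follows the standard
binary-classification metric set — SN, SP, PRE, ACC, F1S, HM (harmonic mean
of SN and SP) and MCC — plus ROC/PR curves built by sweeping the score cutoff
over all distinct scores, with trapezoid AUC.

Cross-validation re-fits the feature probability tables on each fold's
training part only, so no test-fold record ever leaks into the encoders.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .features import FeatureSchema, FeatureTables, encode_dataset, fit_feature_tables
from .seqdata import Dataset

logger = logging.getLogger("smorfkit")

MODEL_FORMAT_VERSION = 1
METHODS = ("LR", "SVM", "RF", "GTB")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    TP: float = 0
    TN: float = 0
    FP: float = 0
    FN: float = 0
    SN: float = 0.0
    SP: float = 0.0
    PRE: float = 0.0
    ACC: float = 0.0
    F1S: float = 0.0
    HM: float = 0.0
    MCC: float = 0.0
    roc_auc: float = float("nan")
    pr_auc: float = float("nan")
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = list(self.flags)
        return d

    @classmethod
    def mean(cls, reports: Sequence["MetricsReport"]) -> "MetricsReport":
        """Element-wise mean across folds; flags are unioned."""
        if not reports:
            raise ValueError("no reports to average")
        fields = ["TP", "TN", "FP", "FN", "SN", "SP", "PRE", "ACC",
                  "F1S", "HM", "MCC", "roc_auc", "pr_auc"]
        out = cls()
        for f in fields:
            setattr(out, f, float(np.mean([getattr(r, f) for r in reports])))
        out.flags = tuple(sorted({f for r in reports for f in r.flags}))
        return out


def _labels01(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "positive").astype(int)
    return arr.astype(int)


def confusion(scores, labels, cutoff: float) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) at a cutoff; ties (score == cutoff) predict positive."""
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    s = np.asarray(scores, dtype=float)
    y = _labels01(labels)
    pred = s >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, tn, fp, fn


def _safe_div(num: float, den: float, flag: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(flag)
        return 0.0
    return num / den


def compute_metrics(TP: float, TN: float, FP: float, FN: float) -> MetricsReport:
    """Rate metrics from a confusion matrix.

    0/0 rates are reported as 0 with a flag naming the undefined metric; an
    MCC denominator of 0 yields MCC 0.
    """
    if min(TP, TN, FP, FN) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = TP + TN + FP + FN
    if total == 0:
        raise ValueError("all confusion counts are zero")
    flags: list[str] = []
    sn = _safe_div(TP, TP + FN, "SN undefined", flags)
    sp = _safe_div(TN, TN + FP, "SP undefined", flags)
    pre = _safe_div(TP, TP + FP, "PRE undefined", flags)
    acc = (TP + TN) / total
    f1s = _safe_div(2 * pre * sn, pre + sn, "F1S undefined", flags)
    hm = _safe_div(2 * sp * sn, sp + sn, "HM undefined", flags)
    mcc_den = math.sqrt((TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    mcc = (TP * TN - FP * FN) / mcc_den if mcc_den else 0.0
    if mcc_den == 0:
        flags.append("MCC undefined")
    return MetricsReport(TP=TP, TN=TN, FP=FP, FN=FN, SN=sn, SP=sp, PRE=pre,
                         ACC=acc, F1S=f1s, HM=hm, MCC=mcc, flags=tuple(flags))


def curve_and_auc(scores, labels, kind: str = "roc") -> tuple[np.ndarray, float]:
    """ROC or PR curve by sweeping the cutoff over all distinct scores (plus
    the 0/1 boundaries), with trapezoid AUC.

    ROC points are (FPR, TPR).  PR points are stored as (recall, precision);
    the published axis statement swaps the axes relative to the usual
    convention — this affects plotting labels only, not the AUC.
    """
    if kind not in ("roc", "pr"):
        raise ValueError("kind must be 'roc' or 'pr'")
    s = np.asarray(scores, dtype=float)
    y = _labels01(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    s = np.clip(s, 0.0, 1.0)
    # sweep the cutoff from strict to permissive so the curve is traversed in
    # path order (recall/TPR nondecreasing); trapezoid integrates that path
    thresholds = sorted(set(s) | {0.0, 1.0}, reverse=True)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    matrices = [(0, n_neg, 0, n_pos)]  # sentinel: nothing predicted positive
    matrices += [confusion(s, y, t) for t in thresholds]
    points = [(0.0, 1.0)] if kind == "pr" else []  # PR anchor at zero recall
    for tp, tn, fp, fn in matrices:
        if kind == "roc":
            fpr = fp / (fp + tn) if (fp + tn) else 0.0
            tpr = tp / (tp + fn) if (tp + fn) else 0.0
            points.append((fpr, tpr))
        elif tp + fp > 0:
            points.append((tp / (tp + fn), tp / (tp + fp)))
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "LR": {"C": 1.0, "max_iter": 2000},
    "SVM": {"C": 1.0, "kernel": "rbf", "gamma": "scale"},
    "RF": {"n_estimators": 200, "max_features": "sqrt"},
    "GTB": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
}


def _make_classifier(method: str, hyperparameters: dict, seed: int):
    if method == "LR":
        return LogisticRegression(random_state=seed, **hyperparameters)
    if method == "SVM":
        return SVC(probability=True, random_state=seed, **hyperparameters)
    if method == "RF":
        return RandomForestClassifier(random_state=seed, **hyperparameters)
    if method == "GTB":
        return GradientBoostingClassifier(random_state=seed, **hyperparameters)
    raise ValueError(f"unknown method {method!r}; known: {METHODS}")


@dataclass
class TrainedModel:
    """A fitted classifier bundled with everything needed to score raw ORFs:
    the feature probability tables, the feature schema and the per-start-codon
    score cutoffs."""

    method: str
    hyperparameters: dict
    classifier: object
    tables: Optional[FeatureTables] = None
    schema: Optional[FeatureSchema] = None
    cutoffs: dict[str, float] = field(default_factory=dict)
    seed: int = 42

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        if len(X) == 0:
            return np.zeros(0)
        return self.classifier.predict_proba(X)[:, 1]

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION,
                     "model": self}, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        doc = joblib.load(str(path))
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model bundle version in {path}")
        return doc["model"]


def train_classifier(X: np.ndarray, y, method: str = "RF",
                     hyperparameters: Optional[dict] = None,
                     seed: int = 42) -> TrainedModel:
    """Fit a classifier on an encoded matrix; scores are positive-class
    probabilities in [0, 1].  Reproducible under ``seed``."""
    y01 = _labels01(y)
    if len(X) != len(y01):
        raise ValueError("X and y lengths differ")
    if y01.min() == y01.max():
        raise ValueError("both classes must be present in y")
    hp = dict(DEFAULT_HYPERPARAMETERS.get(method, {}))
    if hyperparameters:
        hp.update(hyperparameters)
    clf = _make_classifier(method, hp, seed)
    clf.fit(X, y01)
    return TrainedModel(method=method, hyperparameters=hp, classifier=clf,
                        seed=seed)


def train_model(pos_train: Dataset, neg_train: Dataset, schema: FeatureSchema,
                method: str = "RF", hyperparameters: Optional[dict] = None,
                pseudocount: float = 1.0, seed: int = 42) -> TrainedModel:
    """End-to-end: fit tables on the training data, encode, fit classifier."""
    tables = fit_feature_tables(pos_train, neg_train, pseudocount)
    Xp = encode_dataset(pos_train, tables, schema)
    Xn = encode_dataset(neg_train, tables, schema)
    X = np.vstack([Xp, Xn])
    y = np.array([1] * len(Xp) + [0] * len(Xn))
    model = train_classifier(X, y, method, hyperparameters, seed)
    model.tables = tables
    model.schema = schema
    return model


def predict_scores(model: TrainedModel, records: Dataset) -> np.ndarray:
    """Score raw ORF records through the model's own tables and schema."""
    if model.tables is None or model.schema is None:
        raise ValueError("model has no feature tables/schema attached")
    X = encode_dataset(records, model.tables, model.schema)
    return model.score_matrix(X)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffled index modulo k — stratification is per class, so fold sizes
    within a class differ by at most 1."""
    idx = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[idx] = np.arange(n) % k
    return folds


def _evaluate_fold(scores: np.ndarray, y: np.ndarray, cutoff: float) -> MetricsReport:
    rep = compute_metrics(*confusion(scores, y, cutoff))
    try:
        _, rep.roc_auc = curve_and_auc(scores, y, "roc")
        _, rep.pr_auc = curve_and_auc(scores, y, "pr")
    except ValueError:
        pass
    return rep


def cross_validate(pos_train: Dataset, neg_train: Dataset, method: str = "RF",
                   hyperparameters: Optional[dict] = None,
                   schema: FeatureSchema | None = None, k: int = 10,
                   seed: int = 42, cutoff: float = 0.5,
                   feature_subset: Optional[Sequence[str]] = None,
                   pseudocount: float = 1.0) -> MetricsReport:
    """Stratified k-fold CV on raw records with leakage-free encoding.

    For every fold the FeatureTables are fitted on that fold's training part
    only, then both parts are encoded and the classifier trained/evaluated.
    ``feature_subset`` restricts the schema to the named scalar features.
    """
    from .features import FeatureSchema as FS, get_schema
    if schema is None:
        schema = get_schema("reduced33")
    if feature_subset is not None:
        schema = FS(schema.name + "+subset", schema.components,
                    tuple(feature_subset))
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pos_train) < k or len(neg_train) < k:
        raise ValueError(f"each class needs at least k={k} records")
    rng = np.random.default_rng(seed)
    pos_folds = _fold_assignment(len(pos_train), k, rng)
    neg_folds = _fold_assignment(len(neg_train), k, rng)
    reports = []
    for fold in range(k):
        pos_tr = Dataset([r for r, f in zip(pos_train.records, pos_folds) if f != fold])
        pos_te = [r for r, f in zip(pos_train.records, pos_folds) if f == fold]
        neg_tr = Dataset([r for r, f in zip(neg_train.records, neg_folds) if f != fold])
        neg_te = [r for r, f in zip(neg_train.records, neg_folds) if f == fold]
        tables = fit_feature_tables(pos_tr, neg_tr, pseudocount)
        Xtr = np.vstack([encode_dataset(pos_tr, tables, schema),
                         encode_dataset(neg_tr, tables, schema)])
        ytr = np.array([1] * len(pos_tr) + [0] * len(neg_tr))
        Xte = np.vstack([encode_dataset(Dataset(pos_te), tables, schema),
                         encode_dataset(Dataset(neg_te), tables, schema)])
        yte = np.array([1] * len(pos_te) + [0] * len(neg_te))
        model = train_classifier(Xtr, ytr, method, hyperparameters, seed)
        reports.append(_evaluate_fold(model.score_matrix(Xte), yte, cutoff))
    return MetricsReport.mean(reports)


def cross_validate_matrix(X: np.ndarray, y, method: str = "RF",
                          hyperparameters: Optional[dict] = None, k: int = 10,
                          seed: int = 42, cutoff: float = 0.5) -> MetricsReport:
    """Stratified k-fold CV on a pre-encoded matrix (no table re-fitting —
    use only for features that do not depend on fitted probability tables)."""
    y01 = _labels01(y)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y01), dtype=int)
    for cls in (0, 1):
        idx = np.where(y01 == cls)[0]
        if len(idx) < k:
            raise ValueError(f"class {cls} smaller than k={k}")
        folds[idx] = _fold_assignment(len(idx), k, rng)
    reports = []
    for fold in range(k):
        tr, te = folds != fold, folds == fold
        model = train_classifier(X[tr], y01[tr], method, hyperparameters, seed)
        reports.append(_evaluate_fold(model.score_matrix(X[te]), y01[te], cutoff))
    return MetricsReport.mean(reports)
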
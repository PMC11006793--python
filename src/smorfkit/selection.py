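"""Feature selection: component ablation, mRMR (MIQ) ranking, incremental
feature selection and precision-targeted score-cutoff calibration.

mRMR ranks features by mutual information with the label divided by the mean
mutual information with the already-selected features (the quotient scheme).
Features are discretized into 3 bins at mean +/- one standard deviation
before MI estimation; MI is in nats.  IFS then cross-validates every nested
top-i subset of the ranking and keeps the size maximizing mean MCC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import mutual_info_score

from .features import FeatureSchema, COMPONENTS
from .model_eval import (MetricsReport, confusion, cross_validate,
                         cross_validate_matrix, _labels01)
from .seqdata import Dataset

logger = logging.getLogger("smorfkit")


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AblationStep:
    removed_component: str
    remaining: tuple[str, ...]
    acc: float
    mcc: float


@dataclass
class AblationTrace:
    steps: list[AblationStep] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        return [{"step": i + 1, "removed": s.removed_component,
                 "remaining": ",".join(s.remaining), "ACC": s.acc, "MCC": s.mcc}
                for i, s in enumerate(self.steps)]


def ablate_components(pos_train: Dataset, neg_train: Dataset,
                      components: Sequence[str],
                      cv_config: Optional[dict] = None,
                      stop_size: int = 1) -> AblationTrace:
    """Stepwise leave-one-component-out ablation.

    Each round cross-validates every subset missing exactly one remaining
    component and permanently drops the component whose removal performed
    best (highest mean MCC, ties to higher ACC, then ascending name).
    """
    if len(components) < 2:
        raise ValueError("ablation needs at least 2 components")
    unknown = set(components) - set(COMPONENTS)
    if unknown:
        raise KeyError(f"unknown components {sorted(unknown)}")
    cfg = dict(cv_config or {})
    remaining = list(components)
    trace = AblationTrace()
    while len(remaining) > stop_size:
        best: tuple[float, float, str] | None = None
        best_report: MetricsReport | None = None
        for comp in sorted(remaining):
            subset = [c for c in remaining if c != comp]
            schema = FeatureSchema("ablation",
                                   tuple((c, COMPONENTS[c][0]) for c in subset))
            rep = cross_validate(pos_train, neg_train, schema=schema, **cfg)
            key = (-rep.MCC, -rep.ACC, comp)
            if best is None or key < best:
                best, best_report, best_comp = key, rep, comp
        remaining.remove(best_comp)
        trace.steps.append(AblationStep(best_comp, tuple(remaining),
                                        best_report.ACC, best_report.MCC))
        logger.info("ablation: removed %s (ACC %.3f, MCC %.3f)", best_comp,
                    best_report.ACC, best_report.MCC)
    return trace


# ---------------------------------------------------------------------------
# mRMR (MIQ) ranking
# ---------------------------------------------------------------------------

def discretize(X: np.ndarray) -> np.ndarray:
    """Per-feature 3-bin discretization at mean +/- one standard deviation."""
    X = np.asarray(X, dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    out = np.ones_like(X, dtype=int)
    out[X < mu - sd] = 0
    out[X > mu + sd] = 2
    return out


def mrmr_rank(X: np.ndarray, y, feature_names: Optional[Sequence[str]] = None,
              n_bins: int = 3) -> list[str]:
    """Full mRMR ranking under the mutual-information-quotient scheme.

    The first feature maximizes MI with the label; each subsequent pick
    maximizes MI(f; y) / mean MI(f; already selected).  Ties break on
    ascending feature name.  Returns a permutation of the feature names.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 features")
    y01 = _labels01(y)
    if y01.min() == y01.max():
        raise ValueError("both classes must be present")
    if n_bins != 3:
        raise NotImplementedError("only the 3-bin mean +/- sd scheme is supported")
    names = list(feature_names) if feature_names is not None else \
        [f"f{i}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")
    D = discretize(X)
    n = X.shape[1]
    relevance = np.array([mutual_info_score(y01, D[:, j]) for j in range(n)])
    pair_mi: dict[tuple[int, int], float] = {}

    def mi(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in pair_mi:
            pair_mi[key] = mutual_info_score(D[:, a], D[:, b])
        return pair_mi[key]

    selected: list[int] = []
    candidates = set(range(n))
    eps = 1e-12
    while candidates:
        scored = []
        for j in candidates:
            if not selected:
                q = relevance[j]
            else:
                red = float(np.mean([mi(j, s) for s in selected]))
                q = relevance[j] / max(red, eps)
            scored.append((-q, names[j], j))
        scored.sort()
        pick = scored[0][2]
        selected.append(pick)
        candidates.remove(pick)
    return [names[j] for j in selected]


# ---------------------------------------------------------------------------
# incremental feature selection
# ---------------------------------------------------------------------------

@dataclass
class RankingResult:
    ranked_features: list[str]
    ifs_curve: list[tuple[int, float, float]]  # (subset_size, ACC, MCC)
    best_size: int

    @property
    def best_features(self) -> list[str]:
        return self.ranked_features[:self.best_size]


def _ifs_from_reports(ranked: Sequence[str],
                      reports: Sequence[MetricsReport]) -> RankingResult:
    curve = [(i + 1, r.ACC, r.MCC) for i, r in enumerate(reports)]
    # ties toward the smaller subset
    best_size = max(range(len(curve)), key=lambda i: (curve[i][2], -i)) + 1
    return RankingResult(list(ranked), curve, best_size)


def ifs_select(ranked_features: Sequence[str], pos_train: Dataset,
               neg_train: Dataset, cv_config: Optional[dict] = None,
               schema: Optional[FeatureSchema] = None) -> RankingResult:
    """Cross-validate every nested top-i subset of a feature ranking on raw
    records (tables re-fitted per fold) and keep the MCC-optimal size."""
    cfg = dict(cv_config or {})
    reports = [cross_validate(pos_train, neg_train, schema=schema,
                              feature_subset=ranked_features[:i], **cfg)
               for i in range(1, len(ranked_features) + 1)]
    return _ifs_from_reports(ranked_features, reports)


def ifs_select_matrix(ranked_features: Sequence[str], X: np.ndarray, y,
                      feature_names: Sequence[str],
                      cv_config: Optional[dict] = None) -> RankingResult:
    """IFS over a pre-encoded matrix (columns named by ``feature_names``)."""
    cfg = dict(cv_config or {})
    col = {n: j for j, n in enumerate(feature_names)}
    X = np.asarray(X, dtype=float)
    reports = []
    for i in range(1, len(ranked_features) + 1):
        cols = [col[n] for n in ranked_features[:i]]
        reports.append(cross_validate_matrix(X[:, cols], y, **cfg))
    return _ifs_from_reports(ranked_features, reports)


# ---------------------------------------------------------------------------
# precision-targeted cutoff calibration
# ---------------------------------------------------------------------------

def choose_cutoff(scores, labels, target_precision: float) -> float:
    """Smallest candidate threshold (distinct scores plus {0, 1}) whose
    precision reaches the target with at least one predicted positive.

    Returns 1.0 — reject everything — when the target is unattainable, the
    behaviour used to exclude start codons that never reach the target.
    """
    if not 0 < target_precision <= 1:
        raise ValueError("target_precision must be in (0, 1]")
    s = np.clip(np.asarray(scores, dtype=float), 0.0, 1.0)
    y = _labels01(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    for t in sorted(set(s) | {0.0, 1.0}):
        tp, _, fp, _ = confusion(s, y, t)
        if tp + fp >= 1 and tp / (tp + fp) >= target_precision:
            return float(t)
    return 1.0
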
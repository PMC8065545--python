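"""Radiomic signature assembly and class-imbalanced SVM evaluation.

Signatures: per modality, the non-redundant representatives falling within
the first 10 features of the inter-reader stability rank (S_TOP-T2w,
S_TOP-ADC), their union (S_TOP), the mean-ADC single feature (S_ADCmean)
and S_TOP with mean ADC appended (S_TOP+ADCmean).

Evaluation: the class imbalance of each endpoint is handled by
undersampling — 10 random balanced subsets, each holding every
minority-class patient plus an equal-size draw of the majority class. In
each subset an RBF-kernel SVM (C = 1, kernel width 1/(d * var), i.e. the
library 'scale' convention; no tuning) is assessed by stratified 5-fold
cross-validation with per-fold z-scoring fit on the training folds.
Accuracy, sensitivity and specificity are pooled over folds per subset
and summarised as mean/SD/min/max over the 10 subsets; ROC curves pool
decision scores over all subsets, with trapezoidal AUC.

How performance was estimated *within* each balanced subset is the main
methodological free choice here (see docs); cross-validation is the
conservative option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .feature_selection import RedundancyResult, StabilityReport
from .preprocessing import logger
from .synthetic_cohort import PN_N1, PN_NX

#: endpoint -> (label column accessor, positive-class description)
ENDPOINTS = ("ggg", "pn", "ece")


@dataclass
class SignatureSpec:
    """A named list of (modality, feature-name) pairs."""

    name: str
    features: list[tuple[str, str]]

    def columns(self) -> list[str]:
        """Column names in a multi-modality feature table ('modality:feature')."""
        return [f"{mod}:{feat}" for mod, feat in self.features]


@dataclass
class SignatureEval:
    """Per-subset metrics and their summary for one signature x endpoint."""

    signature: str
    endpoint: str
    per_subset: pd.DataFrame           # columns accuracy, sensitivity, specificity
    roc: tuple[np.ndarray, np.ndarray]  # fpr, tpr (pooled scores)
    auc: float
    n_per_subset: int

    @property
    def summary(self) -> pd.DataFrame:
        return self.per_subset.agg(["mean", "std", "min", "max"])


# ---------------------------------------------------------------------------
# signature assembly
# ---------------------------------------------------------------------------

def build_signature(stability: dict[str, StabilityReport],
                    redundancy: dict[str, RedundancyResult],
                    modality_set: list[str], name: str,
                    top_k: int = 10,
                    append_adc_mean: bool = False) -> SignatureSpec:
    """Non-redundant features within the top-``top_k`` of the stability rank.

    Per modality, intersect the first ``top_k`` stable features (by rank)
    with that modality's redundancy representatives, keeping rank order;
    the signature is the union over ``modality_set``. Optionally append
    the mean-ADC feature if absent.
    """
    feats: list[tuple[str, str]] = []
    for mod in modality_set:
        top = stability[mod].top_stable(top_k)
        reps = set(redundancy[mod].representatives)
        feats.extend((mod, f) for f in top if f in reps)
    if append_adc_mean and ("adc", "fos_Mean") not in feats:
        feats.append(("adc", "fos_Mean"))
    if not feats:
        raise ValueError(f"signature {name!r} is empty "
                         "(no stable non-redundant features)")
    return SignatureSpec(name=name, features=feats)


def adc_mean_signature() -> SignatureSpec:
    """The single-feature mean-ADC baseline signature."""
    return SignatureSpec(name="S_ADCmean", features=[("adc", "fos_Mean")])


# ---------------------------------------------------------------------------
# undersampling and evaluation
# ---------------------------------------------------------------------------

def undersample_subsets(labels: np.ndarray, n_subsets: int = 10,
                        seed: int = 0) -> list[np.ndarray]:
    """Index sets of ``n_subsets`` balanced subsets of a binary label vector.

    Each subset keeps every minority-class sample and an equal-size uniform
    draw (without replacement, fresh per subset) from the majority class.
    Deterministic given the seed. Already-balanced labels yield the full
    index set ``n_subsets`` times.
    """
    labels = np.asarray(labels, dtype=bool)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be nonempty")
    minority, majority = (pos, neg) if pos.size <= neg.size else (neg, pos)
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n_subsets):
        draw = rng.choice(majority, size=minority.size, replace=False)
        subsets.append(np.sort(np.concatenate([minority, draw])))
    return subsets


def _pooled_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = tp + tn + fp + fn
    return {
        "accuracy": (tp + tn) / n if n else np.nan,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }


def eval_signature(table: pd.DataFrame, labels: np.ndarray, spec: SignatureSpec,
                   subsets: list[np.ndarray], cv_folds: int = 5, seed: int = 0,
                   svm_c: float = 1.0, svm_gamma="scale") -> SignatureEval:
    """Cross-validated RBF-SVM performance of a signature over balanced subsets.

    ``table`` columns are 'modality:feature'; ``labels`` is the binary
    endpoint (positive class = 1). Within each subset, stratified
    ``cv_folds``-fold CV with fold-wise standardization; subset metrics are
    pooled over the folds. Decision scores are pooled over all subsets for
    a single ROC/AUC.
    """
    cols = spec.columns()
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"signature {spec.name}: columns missing from table: {missing}")
    x_all = table[cols].to_numpy(dtype=float)
    y_all = np.asarray(labels, dtype=int)
    rows = []
    scores_pool: list[np.ndarray] = []
    truth_pool: list[np.ndarray] = []
    rng = np.random.default_rng(seed)
    for subset in subsets:
        x = x_all[subset]
        y = y_all[subset]
        n_folds = min(cv_folds, int(np.bincount(y, minlength=2).min()))
        if n_folds < 2:
            raise ValueError("need >= 2 patients per class per subset")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        y_pred = np.empty_like(y)
        score = np.empty(len(y), dtype=float)
        for tr, te in skf.split(x, y):
            model = make_pipeline(
                StandardScaler(),
                SVC(kernel="rbf", C=svm_c, gamma=svm_gamma))
            model.fit(x[tr], y[tr])
            y_pred[te] = model.predict(x[te])
            score[te] = model.decision_function(x[te])
        rows.append(_pooled_metrics(y, y_pred))
        scores_pool.append(score)
        truth_pool.append(y)
    per_subset = pd.DataFrame(rows)
    fpr, tpr, _ = roc_curve(np.concatenate(truth_pool), np.concatenate(scores_pool))
    return SignatureEval(signature=spec.name, endpoint="", per_subset=per_subset,
                         roc=(fpr, tpr), auc=float(auc(fpr, tpr)),
                         n_per_subset=int(len(subsets[0])))


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def endpoint_labels(labels: pd.DataFrame, endpoint: str) -> pd.Series:
    """Binary endpoint vector (positive class = 1); pN drops pNx patients."""
    if endpoint == "ggg":
        return labels["ggg_high"].astype(bool).astype(int)
    if endpoint == "ece":
        return labels["ece"].astype(bool).astype(int)
    if endpoint == "pn":
        assessable = labels["pn"] != PN_NX
        return (labels.loc[assessable, "pn"] == PN_N1).astype(int)
    raise ValueError(f"unknown endpoint {endpoint!r}")


def run_all_signatures(table: pd.DataFrame, labels: pd.DataFrame,
                       specs: list[SignatureSpec], n_subsets: int = 10,
                       cv_folds: int = 5, seed: int = 0,
                       min_minority: int = 4,
                       pz_subset: bool = True) -> pd.DataFrame:
    """Evaluate every signature for every endpoint, then repeat on PZ lesions.

    ``table`` is indexed by patient_id with 'modality:feature' columns;
    ``labels`` must carry patient_id, ggg_high, ece, pn, zone. Endpoints
    whose minority class falls below ``min_minority`` are skipped with a
    warning. Returns a long-format report (one row per signature x
    endpoint x cohort) with metric summaries and AUC.
    """
    lab = labels.set_index("patient_id") if "patient_id" in labels.columns else labels
    lab = lab.loc[table.index]
    cohorts = {"all": table.index}
    if pz_subset:
        cohorts["PZ"] = table.index[(lab["zone"] == "PZ").to_numpy()]
    rows = []
    rng = np.random.default_rng(seed)
    for cohort_name, idx in cohorts.items():
        sub_tab = table.loc[idx]
        sub_lab = lab.loc[idx]
        for endpoint in ENDPOINTS:
            y = endpoint_labels(sub_lab.reset_index(), endpoint)
            keep = sub_lab.index if endpoint != "pn" \
                else sub_lab.index[(sub_lab["pn"] != PN_NX).to_numpy()]
            y = y.to_numpy()
            counts = np.bincount(y, minlength=2)
            if counts.min() < min_minority:
                logger.warning("run_all_signatures: endpoint %s (%s) has minority "
                               "class %d < %d, skipped", endpoint, cohort_name,
                               counts.min(), min_minority)
                continue
            ep_seed = int(rng.integers(2 ** 31))
            subsets = undersample_subsets(y, n_subsets=n_subsets, seed=ep_seed)
            for spec in specs:
                ev = eval_signature(sub_tab.loc[keep], y, spec, subsets,
                                    cv_folds=cv_folds, seed=ep_seed)
                s = ev.summary
                row = {"signature": spec.name, "endpoint": endpoint,
                       "cohort": cohort_name, "auc": ev.auc,
                       "n_per_subset": ev.n_per_subset}
                for metric in ("accuracy", "sensitivity", "specificity"):
                    for stat in ("mean", "std", "min", "max"):
                        row[f"{metric}_{stat}"] = float(s.loc[stat, metric])
                rows.append(row)
    return pd.DataFrame(rows)
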
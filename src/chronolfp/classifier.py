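"""Leave-one-patient-out classification of daily clinical status.

Each classifier is a single-feature logistic regression (one metric's daily
or delta value) predicting symptom burdened vs. unburdened days.  Rows are
weighted so the two classes balance within every patient; evaluation is
leave-one-patient-out: each patient's days are scored by a model trained on
all other patients, held-out scores are pooled, and AUROC plus balanced
accuracy (mean of sensitivity and specificity at probability 0.5) are
reported.  Chance levels come from permutation nulls — global random label
shuffles and per-patient circular shifts of the day-ordered label sequence
(the latter preserves label contiguity) — with p = #(null > observed)/n_perm.
DeLong's test compares correlated AUROCs of two feature sets on the same
rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .types import BURDENED, UNBURDENED


# ---------------------------------------------------------------------------
# weighted logistic regression (Newton/IRLS, no penalty)

def fit_logistic(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None,
                 tol: float = 1e-8, max_iter: int = 100,
                 max_coef: float = 500.0) -> tuple[float, float]:
    """Maximum-likelihood logistic fit of a single feature plus intercept.

    Newton iterations on the weighted log-likelihood to ``tol`` on the
    coefficient change.  On (quasi-)separable data the likelihood has no
    finite maximiser; coefficients are capped at ``max_coef`` (predicted
    probabilities saturate, rankings unaffected).
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -500, 500)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w * (y - p))
        s = np.maximum(w * p * (1 - p), 1e-12)
        H = X.T @ (s[:, None] * X)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(beta).max() > max_coef:
            beta = np.clip(beta, -max_coef, max_coef)
            break
        if np.abs(step).max() < tol:
            break
    return float(beta[0]), float(beta[1])


def _predict_proba(intercept: float, coef: float, x: np.ndarray) -> np.ndarray:
    eta = np.clip(intercept + coef * np.asarray(x, dtype=float), -500, 500)
    return 1.0 / (1.0 + np.exp(-eta))


def patient_balanced_weights(patients: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row weights balancing the two classes within every patient.

    Row i of patient p with class c gets n_p / (2 · n_{p,c}), so each
    patient's two classes contribute equal total weight.
    """
    patients = np.asarray(patients)
    y = np.asarray(y)
    w = np.empty(len(y), dtype=float)
    for p in np.unique(patients):
        m = patients == p
        n_p = m.sum()
        for c in np.unique(y[m]):
            mc = m & (y == c)
            w[mc] = n_p / (2.0 * mc.sum())
    return w


# ---------------------------------------------------------------------------
# metrics

def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of sensitivity and specificity: (TP/(TP+FN) + TN/(TN+FP))/2."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present in the true labels")
    tp = np.sum((y_true == 1) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    tn = np.sum((y_true == 0) & (y_pred == 0))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    return float(0.5 * (tp / (tp + fn) + tn / (tn + fp)))


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUROC (ties get half credit) and the ROC points."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auroc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    return auroc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# leave-one-patient-out evaluation

@dataclass
class ClassifierResult:
    scores: pd.DataFrame          # patient, day, score, label
    auroc: float
    balanced_accuracy: float
    roc_points: pd.DataFrame

    def to_dict(self) -> dict:
        return {"auroc": self.auroc, "balanced_accuracy": self.balanced_accuracy}


def _encode_labels(labels) -> np.ndarray:
    """unburdened → 1 (positive class), burdened → 0."""
    mapping = {UNBURDENED: 1, BURDENED: 0, 1: 1, 0: 0, True: 1, False: 0}
    try:
        return np.asarray([mapping[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from None


def _lopo_scores(patient_codes: np.ndarray, x: np.ndarray, y: np.ndarray,
                 tol: float = 1e-8) -> np.ndarray:
    """Pooled held-out probabilities from leave-one-patient-out fits."""
    uniq = np.unique(patient_codes)
    if len(uniq) < 2:
        raise ValueError("need at least two patients for LOPO")
    scores = np.full(len(x), np.nan)
    for held in uniq:
        test = patient_codes == held
        train = ~test
        if y[train].min() == y[train].max():
            raise ValueError(f"training fold excluding patient {held} has a single class")
        w = patient_balanced_weights(patient_codes[train], y[train])
        b0, b1 = fit_logistic(x[train], y[train], w, tol=tol)
        scores[test] = _predict_proba(b0, b1, x[test])
    return scores


def _fast_auroc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney AUROC (half credit for ties) via midranks."""
    ranks = sps.rankdata(scores, method="average")
    m = int(y.sum())
    n = len(y) - m
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def _fast_balanced_accuracy(scores: np.ndarray, y: np.ndarray,
                            threshold: float = 0.5) -> float:
    pred = scores >= threshold
    pos, neg = y == 1, y == 0
    sens = np.count_nonzero(pred & pos) / np.count_nonzero(pos)
    spec = np.count_nonzero(~pred & neg) / np.count_nonzero(neg)
    return 0.5 * (sens + spec)


def lopo_logistic(features: pd.DataFrame, tol: float = 1e-8) -> ClassifierResult:
    """Leave-one-patient-out single-feature logistic classification.

    ``features`` has columns (patient, day, value, label); labels are the
    burdened/unburdened dichotomy (or 0/1).  Raises when a training fold
    holds a single class.
    """
    df = features.dropna(subset=["value"]).reset_index(drop=True)
    codes = pd.factorize(df["patient"])[0]
    x = df["value"].to_numpy(dtype=float)
    y = _encode_labels(df["label"])
    scores = _lopo_scores(codes, x, y, tol=tol)
    auroc, roc_points = roc_auc(scores, y)
    bal = balanced_accuracy(y, (scores >= 0.5).astype(int))
    out = df[["patient", "day"]].copy()
    out["score"] = scores
    out["label"] = y
    return ClassifierResult(scores=out, auroc=auroc, balanced_accuracy=bal,
                            roc_points=roc_points)


# ---------------------------------------------------------------------------
# permutation nulls

@dataclass
class PermutationResult:
    method: str
    n_perm: int
    observed_auroc: float
    observed_balanced_accuracy: float
    p_auroc: float
    p_balanced_accuracy: float
    null_auroc: np.ndarray = field(repr=False, default=None)
    null_balanced_accuracy: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "n_perm": self.n_perm,
            "auroc": self.observed_auroc,
            "balanced_accuracy": self.observed_balanced_accuracy,
            "p_auroc": self.p_auroc,
            "p_balanced_accuracy": self.p_balanced_accuracy,
        }


def _permute_encoded(y: np.ndarray, patient_orders: list[np.ndarray],
                     method: str, rng: np.random.Generator) -> np.ndarray:
    if method == "random":
        return rng.permutation(y)
    if method == "circular":
        out = y.copy()
        for order in patient_orders:
            if len(order) < 2:
                continue
            shift = int(rng.integers(0, len(order)))
            out[order] = np.roll(y[order], shift)
        return out
    raise ValueError(f"unknown permutation method {method!r}")


def permutation_test(features: pd.DataFrame, method: str = "circular",
                     n_perm: int = 10_000, seed: int = 0,
                     observed: ClassifierResult | None = None
                     ) -> PermutationResult:
    """Permutation null for the LOPO classifier (AUROC and balanced accuracy).

    ``method='random'`` shuffles labels globally; ``method='circular'``
    rotates each patient's day-ordered label sequence by a uniform offset
    (0 allowed).  Patients with < 2 days are left unshifted with their
    labels intact.  p = #(null > observed)/n_perm for each measure; a
    permutation whose training folds degenerate to one class is redrawn.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    df = features.dropna(subset=["value"]).reset_index(drop=True)
    obs = observed if observed is not None else lopo_logistic(df)
    codes = pd.factorize(df["patient"])[0]
    x = df["value"].to_numpy(dtype=float)
    y = _encode_labels(df["label"])
    days = df["day"].to_numpy()
    patient_orders = []
    for p in np.unique(codes):
        idx = np.flatnonzero(codes == p)
        order = idx[np.argsort(days[idx], kind="stable")]
        if len(order) < 2:
            warnings.warn(f"patient {df['patient'].iloc[idx[0]]!r} has < 2 days; "
                          "labels left unshifted")
        patient_orders.append(order)
    rng = np.random.default_rng(seed)
    null_auc = np.empty(n_perm)
    null_bal = np.empty(n_perm)
    for i in range(n_perm):
        for _attempt in range(100):
            yp = _permute_encoded(y, patient_orders, method, rng)
            try:
                scores = _lopo_scores(codes, x, yp)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not draw a usable permutation")
        null_auc[i] = _fast_auroc(scores, yp)
        null_bal[i] = _fast_balanced_accuracy(scores, yp)
    p_auc = float(np.sum(null_auc > obs.auroc) / n_perm)
    p_bal = float(np.sum(null_bal > obs.balanced_accuracy) / n_perm)
    return PermutationResult(method=method, n_perm=n_perm,
                             observed_auroc=obs.auroc,
                             observed_balanced_accuracy=obs.balanced_accuracy,
                             p_auroc=p_auc, p_balanced_accuracy=p_bal,
                             null_auroc=null_auc, null_balanced_accuracy=null_bal)


# ---------------------------------------------------------------------------
# DeLong's test for correlated AUROCs

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_test(scores1, scores2, labels) -> tuple[float, float]:
    """DeLong's test for two AUROCs computed on the same rows.

    Returns (z, two-tailed p).  Uses the structural-component formulation:
    per-observation placement values V10 (positives) and V01 (negatives)
    for each model, with the covariance of the paired AUROC estimates.
    """
    labels = np.asarray(labels, dtype=int)
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    if len(s1) != len(s2) or len(s1) != len(labels):
        raise ValueError("score vectors and labels must align row-for-row")
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((s1, s2)):
        rank_all = _midrank(s)
        rank_pos = _midrank(s[pos])
        rank_neg = _midrank(s[~pos])
        auc = (rank_all[pos].sum() - m * (m + 1) / 2.0) / (m * n)
        aucs[k] = auc
        v10[k] = (rank_all[pos] - rank_pos) / n
        v01[k] = 1.0 - (rank_all[~pos] - rank_neg) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = s10 / m + s01 / n
    delta = aucs[0] - aucs[1]
    denom = var[0, 0] + var[1, 1] - 2 * var[0, 1]
    if denom <= 0:
        return 0.0, 1.0
    z = delta / np.sqrt(denom)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))
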
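"""Kidney-outcome labelling and prognostic classification.

The binary outcome is a sustained loss of kidney function after biopsy:
the first follow-up time at which eGFR drops below 50% of its baseline
value, eGFR falls under 15 mL/min/1.73m2, or kidney replacement therapy
starts; otherwise the patient is censored at last follow-up.  Patients
with under six months of follow-up, or with no usable follow-up at all,
are excluded before modelling.

Five feature sets are assembled (image, clinical, image+clinical,
IIgAN-PT variables, image+IIgAN-PT) and fed to three classifier
families: gradient-boosted trees (XGBoost), random forest, and
L2-regularised logistic regression on standardised inputs.  Test AUCs
carry DeLong confidence intervals and models are compared pairwise with
DeLong's test for correlated ROC curves.  Time-to-event modelling is
deliberately out of scope; labels are binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .morphometry import FEATURE_COLUMNS

MIN_FOLLOWUP_MONTHS = 6.0

IMAGE_FEATURES = list(FEATURE_COLUMNS)  # 41 core features + 5 presence flags

CLINICAL_FEATURES = [
    "age",
    "sex_male",
    "bmi",
    "baseline_egfr",
    "upcr",
    "creatinine",
    "sbp",
    "dbp",
    "map",
    "hemoglobin",
    "diabetes",
    "hypertension",
    "isd",
    "rasb",
    "oxford_m",
    "oxford_e",
    "oxford_s",
    "oxford_t",
    "oxford_c",
]

#: Variables of the International IgAN Prediction Tool, kept as a plain
#: editable list (the published risk equation itself is not computed).
IIGAN_PT_FEATURES = [
    "age",
    "baseline_egfr",
    "map",
    "upcr",
    "oxford_m",
    "oxford_e",
    "oxford_s",
    "oxford_t",
    "rasb",
    "isd",
]

FEATURE_SETS: dict[str, list[str]] = {
    "image": IMAGE_FEATURES,
    "clinical": CLINICAL_FEATURES,
    "image+clinical": IMAGE_FEATURES + CLINICAL_FEATURES,
    "iigan_pt": IIGAN_PT_FEATURES,
    "image+iigan_pt": IMAGE_FEATURES + IIGAN_PT_FEATURES,
}

MODEL_FAMILIES = ("xgboost", "random_forest", "logistic_regression")


@dataclass
class OutcomeLabel:
    event: int
    time_months: float


def label_outcome(followup: pd.DataFrame, baseline_egfr: float) -> OutcomeLabel:
    """Label one patient from their ordered follow-up series.

    ``followup`` needs columns months, egfr, krt_flag.  The event fires
    at the first time eGFR < 0.5 x baseline, eGFR < 15, or KRT; else the
    patient is censored at last follow-up.
    """
    if len(followup) == 0:
        raise ValueError("at least one follow-up point is required")
    fu = followup.sort_values("months")
    for _, row in fu.iterrows():
        if row["egfr"] < 0.5 * baseline_egfr or row["egfr"] < 15.0 or bool(row["krt_flag"]):
            return OutcomeLabel(event=1, time_months=float(row["months"]))
    return OutcomeLabel(event=0, time_months=float(fu["months"].iloc[-1]))


def filter_cohort(
    patients: pd.DataFrame, followup: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the outcome-stage cohort filters.

    Drops patients with no follow-up (outcome indeterminable) or with
    last follow-up under six months.  Returns the kept patients with
    ``event`` and ``time_months`` columns attached, and an exclusion
    table with machine-readable reasons.
    """
    kept_rows, excluded = [], []
    fu_by_pid = dict(tuple(followup.groupby("patient_id")))
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        fu = fu_by_pid.get(pid)
        if fu is None or len(fu) == 0:
            excluded.append({"patient_id": pid, "reason": "no-outcome"})
            continue
        if fu["months"].max() < MIN_FOLLOWUP_MONTHS:
            excluded.append({"patient_id": pid, "reason": "follow-up<6m"})
            continue
        label = label_outcome(fu, float(row["baseline_egfr"]))
        out = dict(row)
        out["event"] = label.event
        out["time_months"] = label.time_months
        kept_rows.append(out)
    kept = pd.DataFrame(kept_rows).reset_index(drop=True)
    excl = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return kept, excl


def assemble_features(
    patients: pd.DataFrame,
    slide_features: pd.DataFrame,
    feature_set: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Join clinical records with slide features and select the columns
    of one feature set.

    Rows come back in stable patient_id order.  Raises when any patient
    cannot be joined to a slide feature vector.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; options: {sorted(FEATURE_SETS)}")
    merged = patients.merge(slide_features, on="slide_id", how="left", validate="one_to_one")
    probe = FEATURE_COLUMNS[0]
    if merged[probe].isna().any():
        bad = merged.loc[merged[probe].isna(), "patient_id"].tolist()
        raise ValueError(f"patients without slide features: {bad}")
    merged = merged.sort_values("patient_id").reset_index(drop=True)
    cols = FEATURE_SETS[feature_set]
    X = merged[cols].astype(float)
    y = merged["event"].astype(int)
    y.index = X.index
    return X, y


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney identity (equals the trapezoidal ROC area)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(fpr, tpr) sweep over all score thresholds, descending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    P, N = int(y.sum()), int((1 - y).sum())
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    distinct = np.append(np.diff(s) != 0, True)
    tpr = np.concatenate([[0.0], tps[distinct] / P])
    fpr = np.concatenate([[0.0], fps[distinct] / N])
    return np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# DeLong machinery (fast placement-value algorithm)
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(x)
    mid = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        mid[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n, dtype=float)
    out[order] = mid
    return out


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the structural components V10 (per positive) and V01
    (per negative)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance estimate."""
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def delong_ci(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Normal-approximation CI: AUC +/- z_{1-alpha/2} SE, truncated to [0,1]."""
    auc, var = delong_variance(scores, labels)
    z = norm.ppf(1 - alpha / 2)
    se = float(np.sqrt(max(var, 0.0)))
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Two-sided DeLong test for two correlated AUCs on the same labels.

    Returns (z, p).  A zero-variance difference with equal AUCs is the
    degenerate self-comparison and yields (0, 1); zero variance with
    unequal AUCs raises.
    """
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var_diff = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var_diff <= 0:
        if abs(auc_a - auc_b) < 1e-12:
            return 0.0, 1.0
        raise ValueError("zero variance with unequal AUCs (degenerate ties)")
    z = (auc_a - auc_b) / float(np.sqrt(var_diff))
    p = 2.0 * float(norm.sf(abs(z)))
    return float(z), p


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@dataclass
class PrognosisResult:
    model_family: str
    feature_set: str
    auc: float
    ci: tuple[float, float]
    roc: np.ndarray
    importances: list[tuple[str, float]]
    test_scores: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    test_labels: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _make_model(family: str, seed: int):
    if family == "xgboost":
        return XGBClassifier(
            n_estimators=300,
            max_depth=3,
            learning_rate=0.1,
            subsample=1.0,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    if family == "logistic_regression":
        return LogisticRegression(C=1.0, max_iter=5000, random_state=seed)
    raise ValueError(f"unknown model family {family!r}; options: {MODEL_FAMILIES}")


def fit_and_evaluate(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame,
    y_test: pd.Series,
    model_family: str = "xgboost",
    seed: int = 0,
    feature_set: str = "",
) -> PrognosisResult:
    """Fit one classifier and evaluate on the held-out set.

    Missing values are imputed by the training-set median with an
    indicator column added per affected feature.  AUC uses the
    Mann-Whitney identity; the 95% CI is DeLong-based.  Importances come
    from impurity gain for tree models and from absolute standardised
    coefficients for logistic regression.  Raises when the test set has
    a single class (AUC undefined).
    """
    if set(np.unique(y_train)) != {0, 1}:
        raise ValueError("training set must contain both classes")
    if len(np.unique(y_test)) < 2:
        raise ValueError("AUC undefined: test set has a single class")

    imputer = SimpleImputer(strategy="median", add_indicator=True)
    model = _make_model(model_family, seed)
    if model_family == "logistic_regression":
        pipe = Pipeline([("impute", imputer), ("scale", StandardScaler()), ("model", model)])
    else:
        pipe = Pipeline([("impute", imputer), ("model", model)])
    pipe.fit(X_train.to_numpy(), y_train.to_numpy())
    scores = pipe.predict_proba(X_test.to_numpy())[:, 1]

    names = list(X_train.columns)
    ind = pipe.named_steps["impute"].indicator_
    if ind is not None:
        names = names + [f"{names[i]}_missing" for i in ind.features_]
    fitted = pipe.named_steps["model"]
    if model_family == "logistic_regression":
        weights = np.abs(fitted.coef_.ravel())
    else:
        weights = np.asarray(fitted.feature_importances_, dtype=float)
    ranked = sorted(zip(names, weights), key=lambda t: (-t[1], t[0]))

    auc = mann_whitney_auc(scores, y_test.to_numpy())
    ci = delong_ci(scores, y_test.to_numpy())
    return PrognosisResult(
        model_family=model_family,
        feature_set=feature_set,
        auc=auc,
        ci=ci,
        roc=roc_points(scores, y_test.to_numpy()),
        importances=ranked,
        test_scores=scores,
        test_labels=y_test.to_numpy(),
    )


def run_model_grid(
    patients_train: pd.DataFrame,
    patients_test: pd.DataFrame,
    slide_features: pd.DataFrame,
    families: tuple[str, ...] = MODEL_FAMILIES,
    feature_sets: tuple[str, ...] = tuple(FEATURE_SETS),
    seed: int = 0,
) -> list[PrognosisResult]:
    """Fit every model family on every feature set (Table-5-style grid),
    with DeLong p-values computed afterwards via :func:`delong_test`."""
    results = []
    for fam in families:
        for fs in feature_sets:
            Xtr, ytr = assemble_features(patients_train, slide_features, fs)
            Xte, yte = assemble_features(patients_test, slide_features, fs)
            results.append(
                fit_and_evaluate(Xtr, ytr, Xte, yte, model_family=fam, seed=seed, feature_set=fs)
            )
    return results


def results_table(results: list[PrognosisResult], reference_set: str = "image") -> pd.DataFrame:
    """AUC (CI) per model x feature set, with the DeLong p-value of each
    feature set against the reference set within the same family."""
    rows = []
    by_family: dict[str, dict[str, PrognosisResult]] = {}
    for r in results:
        by_family.setdefault(r.model_family, {})[r.feature_set] = r
    for fam, group in by_family.items():
        ref = group.get(reference_set)
        for fs, r in group.items():
            p = None
            if ref is not None and fs != reference_set:
                try:
                    _, p = delong_test(r.test_scores, ref.test_scores, r.test_labels)
                except ValueError:
                    p = float("nan")
            rows.append(
                {
                    "model": fam,
                    "feature_set": fs,
                    "auc": r.auc,
                    "ci_lo": r.ci[0],
                    "ci_hi": r.ci[1],
                    "p_vs_reference": p,
                }
            )
    return pd.DataFrame(rows)


def importance_report(results: list[PrognosisResult], k: int = 5) -> pd.DataFrame:
    """Top-k features per model/feature-set combination, ties broken by
    feature name (k larger than the feature count returns everything)."""
    rows = []
    for r in results:
        for rank, (name, weight) in enumerate(r.importances[:k], start=1):
            rows.append(
                {
                    "model": r.model_family,
                    "feature_set": r.feature_set,
                    "rank": rank,
                    "feature": name,
                    "weight": float(weight),
                }
            )
    return pd.DataFrame(rows, columns=["model", "feature_set", "rank", "feature", "weight"])
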
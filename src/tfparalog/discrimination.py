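"""Penalized models discriminating two factors' binding preferences from
PWM-derived sequence features.

Each classified binding site contributes one 1001-bp sequence centered on
its peak summit. Features are the per-PWM maximum score ratios over the
sequence plus 12 strand-symmetric composition rates (2 mononucleotide +
10 dinucleotide classes). Two tasks share one protocol: an L1-penalized
logistic model separating PF1 from PF2 sites, and an L1-penalized linear
model for the log10 signal ratio at shared (F1F2) sites. Rows are split
70/30 into train/test; the penalty weight lambda is chosen by 10-fold
cross-validation on the training rows at the CV-error minimizer
(the glmnet "lambda.min" rule); evaluation uses held-out rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV, LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .annotation import ClassifiedPeak
from .intervals import GenomicInterval, extract_sequence
from .motif import (
    COMPOSITION_FEATURES,
    PWM,
    composition_features,
    encode,
    max_score_ratio_encoded,
)

__all__ = [
    "FeatureMatrix",
    "ModelSpec",
    "ModelEvaluation",
    "build_feature_matrix",
    "balance_classes",
    "fit_classifier",
    "single_feature_auc",
    "top_coefficients",
    "fit_ratio_regressor",
    "score_distribution_summary",
]

POSITIVE_CLASS = "PF1"  # positive coefficients point toward PF1


@dataclass
class FeatureMatrix:
    """Rows = peak-centered sequences; columns = PWM max score ratios plus
    composition rates; optional class label or real response per row."""

    features: pd.DataFrame
    labels: pd.Series | None = None
    response: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_tsv(self, path) -> None:
        out = self.features.copy()
        if self.labels is not None:
            out["label"] = self.labels
        if self.response is not None:
            out["response"] = self.response
        out.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = df.pop("label") if "label" in df else None
        response = df.pop("response") if "response" in df else None
        return cls(df, labels, response)


@dataclass
class ModelSpec:
    task: str = "classification"  # classification | regression
    cv_folds: int = 10
    train_fraction: float = 0.7
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    seed: int = 0


@dataclass
class ModelEvaluation:
    """Held-out evaluation: AUC for classification, Pearson r (with p-value)
    for regression, plus the selected-lambda coefficients (standardized
    scale; many exactly zero)."""

    coefficients: pd.Series
    auc: float | None = None
    pearson_r: float | None = None
    pearson_p: float | None = None
    lambda_selected: float | None = None
    n_train: int = 0
    n_test: int = 0


def build_feature_matrix(
    peaks: list[ClassifiedPeak],
    genome: dict[str, str],
    pwm_library: list[PWM],
    window: int = 1001,
) -> FeatureMatrix:
    """One row per peak: window-centered sequence scored against every PWM
    (maximum score ratio per PWM, both strands) plus composition rates.

    The window (default 1001 bp, odd) is centered on the peak summit; peaks
    whose window leaves the contig are dropped with a warning. Labels are
    the peak classes; the response, when both signals are positive, is
    log10(signal_a / signal_b).
    """
    if not pwm_library:
        raise ValueError("PWM library is empty")
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    half = window // 2
    names = [p.id for p in pwm_library] + list(COMPOSITION_FEATURES)
    rows, ids, labels, responses = [], [], [], []
    n_dropped = 0
    for i, pk in enumerate(peaks):
        center = pk.center
        start, end = center - half, center + half + 1
        contig = genome.get(pk.interval.chrom)
        if contig is None or start < 0 or end > len(contig):
            n_dropped += 1
            continue
        seq = extract_sequence(
            genome, GenomicInterval(pk.interval.chrom, start, end)
        )
        idx = encode(seq)
        feats = [max_score_ratio_encoded(p, idx) for p in pwm_library]
        comp = composition_features(seq)
        feats.extend(comp[k] for k in COMPOSITION_FEATURES)
        rows.append(feats)
        ids.append(f"{pk.interval.chrom}:{center}:{pk.label}:{i}")
        labels.append(pk.label)
        if pk.signal_a > 0 and pk.signal_b > 0:
            responses.append(np.log10(pk.signal_a / pk.signal_b))
        else:
            responses.append(np.nan)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} peaks whose {window}-bp window left the contig"
        )
    features = pd.DataFrame(rows, index=ids, columns=names)
    resp = pd.Series(responses, index=ids)
    return FeatureMatrix(features, pd.Series(labels, index=ids), resp)


def balance_classes(matrix: FeatureMatrix, seed: int = 0) -> FeatureMatrix:
    """Subsample every class without replacement down to the minority size."""
    if matrix.labels is None:
        raise ValueError("matrix has no labels")
    counts = matrix.labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 classes to balance")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for cls in sorted(counts.index):
        ids = matrix.labels.index[matrix.labels == cls].to_numpy()
        keep.extend(rng.choice(ids, size=n_min, replace=False))
    keep = sorted(keep, key=list(matrix.features.index).index)
    return FeatureMatrix(
        matrix.features.loc[keep],
        matrix.labels.loc[keep],
        matrix.response.loc[keep] if matrix.response is not None else None,
    )


def _train_test_split(ids, strata, train_fraction: float, seed: int):
    """Deterministic stratified split shared by model fits and
    single-feature evaluation."""
    rng = np.random.default_rng(seed)
    ids = np.asarray(ids)
    train_mask = np.zeros(len(ids), dtype=bool)
    for value in np.unique(strata):
        idx = np.nonzero(strata == value)[0]
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        train_mask[perm[:n_train]] = True
    return train_mask


def _standardize(train: np.ndarray, test: np.ndarray, names):
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    constant = std == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant feature(s): "
            f"{[n for n, c in zip(names, constant) if c][:5]}"
        )
    keep = ~constant
    std_safe = np.where(constant, 1.0, std)
    return (
        (train - mean)[:, keep] / std_safe[keep],
        (test - mean)[:, keep] / std_safe[keep],
        [n for n, c in zip(names, constant) if not c],
    )


def _logistic_lambda_path(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Decreasing lambda grid from lambda_max (all-zero coefficients) down
    to lambda_max * lambda_min_ratio, glmnet-style."""
    n = len(y)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-10)
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * spec.lambda_min_ratio), spec.n_lambda
    )


def fit_classifier(
    matrix: FeatureMatrix, spec: ModelSpec | None = None
) -> tuple[LogisticRegression, ModelEvaluation]:
    """L1-penalized logistic classification of PF1 vs PF2 rows.

    Features are standardized on the training rows; lambda is selected by
    10-fold CV (mean deviance) on the training split only, then the model is
    refit on all training rows at the selected lambda. AUC is computed from
    held-out predicted probabilities. Positive coefficients point toward
    the PF1 class.
    """
    spec = spec or ModelSpec()
    if matrix.labels is None:
        raise ValueError("matrix has no labels")
    classes = sorted(matrix.labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y = (matrix.labels == POSITIVE_CLASS).to_numpy().astype(float)
    if y.sum() == 0:  # POSITIVE_CLASS absent: first class alphabetically is positive
        y = (matrix.labels == classes[0]).to_numpy().astype(float)
    X = matrix.features.to_numpy(dtype=float)
    train = _train_test_split(
        matrix.features.index, matrix.labels.to_numpy(), spec.train_fraction, spec.seed
    )
    Xtr, Xte, names = _standardize(X[train], X[~train], list(matrix.features.columns))
    ytr, yte = y[train], y[~train]

    lambdas = _logistic_lambda_path(Xtr, ytr, spec)
    n_tr = len(ytr)
    cv = StratifiedKFold(spec.cv_folds, shuffle=True, random_state=spec.seed)
    # Fast CV scan over the path (the deviance curve is smooth, so a loose
    # per-fit tolerance does not move lambda.min materially), then a precise
    # refit on all training rows at the selected lambda.
    scan_model = LogisticRegressionCV(
        Cs=1.0 / (n_tr * lambdas),
        cv=cv,
        l1_ratios=[1.0],
        solver="liblinear",
        scoring="neg_log_loss",  # lambda.min by mean CV deviance
        tol=1e-2,
        max_iter=100,
        n_jobs=1,
        refit=True,  # C_ = argmin of the mean CV deviance across folds
        random_state=spec.seed,  # liblinear shuffles data internally
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        scan_model.fit(Xtr, ytr)
        lam_sel = 1.0 / (n_tr * float(np.ravel(scan_model.C_)[0]))
        model = LogisticRegression(
            l1_ratio=1.0,
            solver="liblinear",
            C=1.0 / (n_tr * lam_sel),
            tol=1e-4,
            max_iter=1000,
            random_state=spec.seed,
        )
        model.fit(Xtr, ytr)
    prob = model.predict_proba(Xte)[:, 1]
    auc = float(roc_auc_score(yte, prob))
    coefs = pd.Series(model.coef_[0], index=names)
    return model, ModelEvaluation(
        coefficients=coefs,
        auc=auc,
        lambda_selected=lam_sel,
        n_train=int(train.sum()),
        n_test=int((~train).sum()),
    )


def single_feature_auc(
    matrix: FeatureMatrix, feature_name: str, spec: ModelSpec | None = None
) -> float:
    """AUC of ranking the held-out rows by one raw feature value, using the
    same seeded 70/30 split as the paired classifier run. No model is fit."""
    spec = spec or ModelSpec()
    if feature_name not in matrix.features.columns:
        raise KeyError(f"unknown feature {feature_name!r}")
    y = (matrix.labels == POSITIVE_CLASS).to_numpy().astype(float)
    train = _train_test_split(
        matrix.features.index, matrix.labels.to_numpy(), spec.train_fraction, spec.seed
    )
    values = matrix.features[feature_name].to_numpy(dtype=float)
    auc = float(roc_auc_score(y[~train], values[~train]))
    # Report discriminative power regardless of the feature's direction.
    return max(auc, 1.0 - auc)


def top_coefficients(evaluation: ModelEvaluation, k: int = 10) -> pd.Series:
    """The k largest-|coefficient| features with signs (positive -> PF1,
    negative -> PF2, under the default label encoding). Fewer than k nonzero
    coefficients returns all nonzero ones."""
    nonzero = evaluation.coefficients[evaluation.coefficients != 0]
    ranked = nonzero.reindex(nonzero.abs().sort_values(ascending=False).index)
    return ranked.head(k)


def fit_ratio_regressor(
    matrix: FeatureMatrix, spec: ModelSpec | None = None
) -> tuple[LassoCV, ModelEvaluation]:
    """L1-penalized linear regression of log10(Y1/Y2) on the features.

    Same 70/30 split and 10-fold CV lambda.min protocol as the classifier
    (LassoCV's default path is 100 lambdas down to lambda_max * 1e-4).
    Evaluation is the Pearson correlation between predicted and observed
    ratios on the held-out rows, with its p-value.
    """
    spec = spec or ModelSpec(task="regression")
    if matrix.response is None:
        raise ValueError("matrix has no response")
    finite = matrix.response.notna().to_numpy()
    X = matrix.features.to_numpy(dtype=float)[finite]
    yr = matrix.response.to_numpy(dtype=float)[finite]
    if np.allclose(yr, yr[0]):
        raise ValueError("constant response")
    ids = matrix.features.index[finite]
    train = _train_test_split(ids, np.zeros(len(ids)), spec.train_fraction, spec.seed)
    Xtr, Xte, names = _standardize(X[train], X[~train], list(matrix.features.columns))
    ytr, yte = yr[train], yr[~train]
    model = LassoCV(
        alphas=spec.n_lambda,  # path length: lambda_max down to eps*lambda_max
        eps=spec.lambda_min_ratio,
        cv=KFold(spec.cv_folds, shuffle=True, random_state=spec.seed),
        random_state=spec.seed,
        max_iter=5000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xtr, ytr)
    pred = model.predict(Xte)
    if np.allclose(pred, pred[0]):
        r, p = 0.0, 1.0  # intercept-only model carries no ranking information
    else:
        r, p = stats.pearsonr(pred, yte)
    coefs = pd.Series(model.coef_, index=names)
    return model, ModelEvaluation(
        coefficients=coefs,
        pearson_r=float(r),
        pearson_p=float(p),
        lambda_selected=float(model.alpha_),
        n_train=int(train.sum()),
        n_test=int((~train).sum()),
    )


def score_distribution_summary(
    matrix: FeatureMatrix,
    feature_name: str,
    group_labels: list[str],
    bins: int = 15,
    value_range: tuple[float, float] = (0.85, 1.0),
) -> dict[str, dict]:
    """Per-group normalized histogram of one feature restricted to
    [0.85, 1] (fixed bin edges shared across groups) plus each group's
    median over the restricted range."""
    if feature_name not in matrix.features.columns:
        raise KeyError(f"unknown feature {feature_name!r}")
    edges = np.linspace(value_range[0], value_range[1], bins + 1)
    out: dict[str, dict] = {}
    for g in group_labels:
        vals = matrix.features.loc[matrix.labels == g, feature_name].to_numpy()
        if len(vals) == 0:
            raise ValueError(f"group {g!r} is empty")
        sel = vals[(vals >= value_range[0]) & (vals <= value_range[1])]
        if len(sel) == 0:
            out[g] = {"edges": edges, "density": np.zeros(bins), "median": np.nan,
                      "n": 0}
            continue
        hist, _ = np.histogram(sel, bins=edges)
        out[g] = {
            "edges": edges,
            "density": hist / hist.sum(),
            "median": float(np.median(sel)),
            "n": int(len(sel)),
        }
    return out
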
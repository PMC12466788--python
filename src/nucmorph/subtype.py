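"""Clinical subtype labels and transparent one-vs-all classifiers.

Subtype labels derive from HER2/ER/PR immunohistochemistry status.  The
three-class scheme is HER2+ (HER2 positive regardless of hormone
receptors), HR+ (HER2 negative with ER or PR positive) and TNBC (all three
negative).  The four-class scheme uses HER2 and ER only: TPBC (both
positive), HER2+ (HER2 only), HR+ (ER only), TNBC (neither).

Each subtype gets its own L1-penalized logistic regression trained
one-vs-all under 5x5 nested cross-validation: the outer folds produce
out-of-fold scores for unbiased evaluation, the inner folds pick the
regularization strength C by mean validation AUC (ties prefer the stronger
penalty).  Min-max scaling bounds are fit on training data only.  The five
outer-fold models are frozen into a :class:`ClassifierBundle`; applying a
bundle to external data scales each sample with every fold's stored bounds
(clamping out-of-range values), scores it with that fold's coefficients,
and averages the five logistic scores.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

SUBTYPES3 = ("HER2+", "HR+", "TNBC")
SUBTYPES4 = ("TPBC", "HER2+", "HR+", "TNBC")

#: Default regularization grid: 13 points, 1e-3 ... 1e3 (log-spaced).
DEFAULT_C_GRID = tuple(float(c) for c in np.logspace(-3, 3, 13))

POSITIVE, NEGATIVE, UNKNOWN = "positive", "negative", "unknown"


@dataclass(frozen=True)
class MarkerStatus:
    """HER2 / ER / PR immunohistochemistry status for one patient."""

    her2: str = UNKNOWN
    er: str = UNKNOWN
    pr: str = UNKNOWN


def derive_subtype3(m: MarkerStatus) -> str | None:
    """Three-class label, or None when a required marker is unknown."""
    if m.her2 == POSITIVE:
        return "HER2+"
    if m.her2 != NEGATIVE:
        logger.info("subtype unassignable: HER2 status unknown")
        return None
    if m.er == POSITIVE or m.pr == POSITIVE:
        return "HR+"
    if m.er == NEGATIVE and m.pr == NEGATIVE:
        return "TNBC"
    logger.info("subtype unassignable: ER/PR status unknown under HER2-negative")
    return None


def derive_subtype4(m: MarkerStatus) -> str | None:
    """Four-class label from HER2 and ER alone (PR ignored)."""
    if m.her2 not in (POSITIVE, NEGATIVE) or m.er not in (POSITIVE, NEGATIVE):
        logger.info("subtype unassignable: HER2 or ER status unknown")
        return None
    if m.her2 == POSITIVE:
        return "TPBC" if m.er == POSITIVE else "HER2+"
    return "HR+" if m.er == POSITIVE else "TNBC"


def derive_labels(clinical: pd.DataFrame, scheme: int = 3) -> pd.Series:
    """Vectorized label derivation from a clinical table.

    Expects lower-cased status strings in columns ``her2``, ``er``, ``pr``.
    Rows with unassignable labels come back as None.
    """
    fn = derive_subtype3 if scheme == 3 else derive_subtype4
    out = clinical.apply(
        lambda r: fn(
            MarkerStatus(
                her2=str(r.get("her2", UNKNOWN)).lower(),
                er=str(r.get("er", UNKNOWN)).lower(),
                pr=str(r.get("pr", UNKNOWN)).lower(),
            )
        ),
        axis=1,
    )
    return out


# ---------------------------------------------------------------------------
# Frozen fold models


@dataclass
class FoldModel:
    """Scaling bounds + logistic coefficients for one outer CV fold."""

    feature_min: np.ndarray
    feature_max: np.ndarray
    coef: np.ndarray
    intercept: float
    C: float

    def score(self, X: np.ndarray) -> np.ndarray:
        """Scale with the stored bounds (clamped to [0, 1]) and apply the
        logistic model."""
        span = self.feature_max - self.feature_min
        span = np.where(span == 0.0, 1.0, span)
        Z = np.clip((X - self.feature_min) / span, 0.0, 1.0)
        return 1.0 / (1.0 + np.exp(-(Z @ self.coef + self.intercept)))


@dataclass
class ClassifierBundle:
    """Five frozen fold models for one subtype, applied as-is externally."""

    subtype: str
    features: list[str]
    folds: list[FoldModel]
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtype": self.subtype,
            "features": self.features,
            "seed": self.seed,
            "folds": [
                {
                    "feature_min": f.feature_min.tolist(),
                    "feature_max": f.feature_max.tolist(),
                    "coef": f.coef.tolist(),
                    "intercept": f.intercept,
                    "C": f.C,
                }
                for f in self.folds
            ],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierBundle":
        payload = json.loads(Path(path).read_text())
        folds = [
            FoldModel(
                feature_min=np.asarray(f["feature_min"], dtype=float),
                feature_max=np.asarray(f["feature_max"], dtype=float),
                coef=np.asarray(f["coef"], dtype=float),
                intercept=float(f["intercept"]),
                C=float(f["C"]),
            )
            for f in payload["folds"]
        ]
        return cls(
            subtype=payload["subtype"],
            features=list(payload["features"]),
            folds=folds,
            seed=int(payload["seed"]),
        )


# ---------------------------------------------------------------------------
# Statistics


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: pairwise win fraction with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def associate_features(
    X: pd.DataFrame, in_group: Sequence[bool]
) -> pd.DataFrame:
    """Per-feature two-sided rank-sum test and rank-biserial effect size.

    The rank-biserial correlation is r = 2U/(n1*n2) - 1, where U counts
    pairs in which the in-group value exceeds the out-group value (ties
    half); r = +1 means the group dominates, -1 the reverse.
    """
    mask = np.asarray(in_group, dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in X.columns:
        a = X.loc[mask, col].to_numpy(dtype=float)
        b = X.loc[~mask, col].to_numpy(dtype=float)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        r = 2.0 * res.statistic / (len(a) * len(b)) - 1.0
        rows.append({"feature": col, "pvalue": float(res.pvalue), "rank_biserial": float(r)})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Nested cross-validation training


def _fit_lr(X: np.ndarray, y: np.ndarray, C: float) -> LogisticRegression:
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=0
    )
    model.fit(X, y)
    return model


def _minmax(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return X.min(axis=0), X.max(axis=0)


def _apply_minmax(X, lo, hi) -> np.ndarray:
    span = np.where(hi - lo == 0.0, 1.0, hi - lo)
    return np.clip((X - lo) / span, 0.0, 1.0)


def _valid_outer_split(y: np.ndarray, n_splits: int, seed: int):
    """Stratified outer folds with >= 2 samples of each class per test fold.

    Reseeds (with a warning) until the constraint holds; falls back to the
    last draw if only the weaker >= 1 constraint can be met.
    """
    last = None
    for attempt in range(100):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(np.zeros(len(y)), y))
        counts = [np.bincount(y[test], minlength=2) for _, test in splits]
        if all((c >= 2).all() for c in counts):
            if attempt:
                warnings.warn(
                    f"outer split reseeded {attempt} time(s) to keep >= 2 "
                    "samples of each class per fold",
                    UserWarning,
                    stacklevel=3,
                )
            return splits
        if all((c >= 1).all() for c in counts):
            last = splits
    if last is None:
        raise ValueError("cannot stratify: a class is too rare for 5 outer folds")
    warnings.warn(
        "outer folds contain classes with a single sample", UserWarning, stacklevel=3
    )
    return last


def nested_cv_train(
    X: pd.DataFrame,
    y: Sequence[int] | Sequence[bool],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    subtype: str = "target",
    n_outer: int = 5,
    n_inner: int = 5,
) -> tuple[ClassifierBundle, np.ndarray]:
    """Train one one-vs-all classifier under nested CV.

    Returns the frozen bundle of outer-fold models and the out-of-fold
    score vector aligned to the original sample order (each sample scored
    exactly once, by the model whose training fold excluded it).
    """
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y).astype(int)
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present in y")
    if len(yv) < 10:
        raise ValueError("need at least 10 samples for nested CV")
    C_grid = sorted(float(c) for c in C_grid)

    splits = _valid_outer_split(yv, n_outer, seed)
    oof = np.full(len(yv), np.nan)
    folds: list[FoldModel] = []
    for i, (train_idx, test_idx) in enumerate(splits):
        X_train, y_train = Xv[train_idx], yv[train_idx]
        # inner grid search on the outer-training data only
        inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed + 1000 + i)
        best_C, best_auc = C_grid[0], -np.inf
        for C in C_grid:
            inner_aucs = []
            for tr, va in inner.split(X_train, y_train):
                lo, hi = _minmax(X_train[tr])
                model = _fit_lr(_apply_minmax(X_train[tr], lo, hi), y_train[tr], C)
                s = model.decision_function(_apply_minmax(X_train[va], lo, hi))
                inner_aucs.append(auc(s, y_train[va]))
            mean_auc = float(np.mean(inner_aucs))
            if mean_auc > best_auc:  # ties keep the earlier (smaller) C
                best_auc, best_C = mean_auc, C
        lo, hi = _minmax(X_train)
        model = _fit_lr(_apply_minmax(X_train, lo, hi), y_train, best_C)
        fold = FoldModel(
            feature_min=lo,
            feature_max=hi,
            coef=model.coef_.ravel().copy(),
            intercept=float(model.intercept_[0]),
            C=best_C,
        )
        folds.append(fold)
        oof[test_idx] = fold.score(Xv[test_idx])

    bundle = ClassifierBundle(
        subtype=subtype, features=list(X.columns), folds=folds, seed=seed
    )
    return bundle, oof


def predict_external(bundle: ClassifierBundle, X: pd.DataFrame) -> np.ndarray:
    """Average the five frozen fold models' scores on new data."""
    missing = [f for f in bundle.features if f not in X.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {', '.join(missing)}")
    Xv = X[bundle.features].to_numpy(dtype=float)
    return np.mean([f.score(Xv) for f in bundle.folds], axis=0)


def assign_subtype(
    scores: Mapping[str, Sequence[float]], order: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Argmax subtype call per sample.

    ``order`` fixes the tie-break: on an exact score tie the earliest
    subtype in the declared order wins and the sample's tie flag is set.
    """
    order = list(order) if order is not None else list(scores)
    arrays = [np.asarray(scores[s], dtype=float) for s in order]
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise ValueError("score vectors must all have the same length")
    stacked = np.vstack(arrays)
    winner = stacked.argmax(axis=0)  # first maximum wins
    ties = (stacked == stacked.max(axis=0)).sum(axis=0) > 1
    return [order[i] for i in winner], ties


def feature_importance(bundle: ClassifierBundle) -> pd.DataFrame:
    """Mean fold coefficient per feature with a 95% t-interval (df = 4)."""
    coefs = np.vstack([f.coef for f in bundle.folds])
    n = coefs.shape[0]
    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    half = stats.t.ppf(0.975, df=n - 1) * sd / np.sqrt(n)
    return pd.DataFrame(
        {
            "mean": mean,
            "ci_lower": mean - half,
            "ci_upper": mean + half,
            "sign": np.sign(mean),
        },
        index=pd.Index(bundle.features, name="feature"),
    )
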
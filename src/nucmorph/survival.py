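"""Subtype-specific survival modelling and risk stratification.

The workflow: filter collinear features, fit a multivariate Cox
proportional-hazards model (features + patient age) under 5-fold
cross-validation where every test fold must contain at least one observed
event, concatenate the held-out linear-predictor risk scores, quantile
normalize them to [0, 1] between the 10th and 90th percentiles,

    r_scaled = 0                          if r <= p10
             = 1                          if r >= p90
             = (r - p10) / (p90 - p10)    otherwise,

stratify at a fixed 0.5 threshold into Low/High risk (exactly 0.5 -> Low),
and report Kaplan-Meier curves, the two-group log-rank test (significance
at P <= 0.1) and Harrell's C-index.  Overall and progression-free survival
share this code path; only the (time, event) columns differ.

Cox fitting, Kaplan-Meier, log-rank and the C-index delegate to lifelines
(Efron handling for tied event times).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import statistics as ll_stats
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index

#: Candidate |Pearson r| cutoffs scanned when optimizing the collinearity
#: filter (kept threshold = best cross-validated C-index).
DEFAULT_COLLINEARITY_CANDIDATES = (0.7, 0.8, 0.9, 0.95)


def collinearity_filter(X: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Iteratively drop the more-redundant member of the worst correlated pair.

    Zero-variance features are dropped first (with a warning).  While any
    feature pair exceeds ``threshold`` in absolute Pearson correlation, the
    member of the worst pair with the larger mean |r| to all other retained
    features is removed; exact ties drop the lexicographically later name.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    retained = list(X.columns)
    constant = [c for c in retained if X[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping zero-variance feature(s): {', '.join(constant)}",
            UserWarning,
            stacklevel=2,
        )
        retained = [c for c in retained if c not in constant]
    while len(retained) > 1:
        corr = X[retained].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.values.max()
        if worst <= threshold:
            break
        i, j = np.unravel_index(corr.values.argmax(), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        mean_a = corr.loc[a].drop(b).mean() if len(retained) > 2 else 0.0
        mean_b = corr.loc[b].drop(a).mean() if len(retained) > 2 else 0.0
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)  # deterministic tie-break by name
        retained.remove(drop)
    return retained


def cox_fit(
    df: pd.DataFrame,
    feature_cols: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    penalizer: float = 0.0,
) -> CoxPHFitter:
    """Fit a Cox PH model; fall back to a small ridge penalty on monotone
    likelihood / non-convergence (with a warning)."""
    if df[event_col].sum() < 1:
        raise ValueError("Cox fit requires at least one observed event")
    data = df[[duration_col, event_col, *feature_cols]]
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError:
        warnings.warn(
            "Cox partial likelihood did not converge (possible separation); "
            "refitting with ridge penalty 0.1",
            UserWarning,
            stacklevel=2,
        )
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    return cph


def cox_risk(cph: CoxPHFitter, df: pd.DataFrame) -> np.ndarray:
    """Linear-predictor risk score (log partial hazard) per row."""
    return cph.predict_log_partial_hazard(df).to_numpy(dtype=float)


def cv_risk_scores(
    df: pd.DataFrame,
    feature_cols: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    k: int = 5,
    seed: int = 0,
    max_tries: int = 100,
) -> np.ndarray:
    """Cross-validated risk scores: train on 80%, score the held-out 20%.

    Folds are re-drawn (new seed offset) until every test fold contains at
    least one observed event; held-out scores are concatenated in the
    original row order.
    """
    events = df[event_col].to_numpy(dtype=int)
    if events.sum() < k:
        raise ValueError(f"need at least {k} events for {k}-fold CV")
    n = len(df)
    rng_splits = None
    for attempt in range(max_tries):
        rng = np.random.default_rng(seed + attempt)
        order = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[order] = np.arange(n) % k
        if all(events[fold_of == f].sum() >= 1 for f in range(k)):
            rng_splits = fold_of
            break
    if rng_splits is None:
        raise ValueError(
            f"could not draw {k} folds with >= 1 event each in {max_tries} tries"
        )
    risk = np.full(n, np.nan)
    for f in range(k):
        test = rng_splits == f
        cph = cox_fit(
            df.loc[~test], feature_cols, duration_col=duration_col, event_col=event_col
        )
        risk[test] = cox_risk(cph, df.loc[test])
    return risk


def quantile_normalize_risk(r: Sequence[float]) -> np.ndarray:
    """Quantile-normalize raw risk to [0, 1] within the [p10, p90] interval."""
    r = np.asarray(r, dtype=float)
    if len(np.unique(r)) < 2:
        raise ValueError("need at least 2 distinct risk values")
    p10, p90 = np.percentile(r, [10, 90])
    if p90 <= p10:
        raise ValueError("degenerate risk spread: p90 <= p10")
    scaled = (r - p10) / (p90 - p10)
    scaled[r <= p10] = 0.0
    scaled[r >= p90] = 1.0
    return scaled


def stratify(r_scaled: Sequence[float], threshold: float = 0.5) -> np.ndarray:
    """Label scaled risks: > threshold -> 'High', <= threshold -> 'Low'."""
    r = np.asarray(r_scaled, dtype=float)
    return np.where(r > threshold, "High", "Low")


def km_curve(
    times: Sequence[float], events: Sequence[int], groups: Sequence[str]
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group as (time, survival) tables."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    curves = {}
    for g in np.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return curves


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence[str]
) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic (1 df) and p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    if events.sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    a, b = groups == labels[0], groups == labels[1]
    res = ll_stats.logrank_test(times[a], times[b], events[a], events[b])
    return float(res.test_statistic), float(res.p_value)


def c_index(
    risk: Sequence[float], times: Sequence[float], events: Sequence[int]
) -> float:
    """Harrell's concordance index for a risk score (higher risk = earlier
    event); ties in risk earn half credit."""
    try:
        return float(
            concordance_index(
                np.asarray(times, dtype=float),
                -np.asarray(risk, dtype=float),
                np.asarray(events, dtype=int),
            )
        )
    except ZeroDivisionError as exc:
        raise ValueError("no admissible pair for the C-index") from exc


@dataclass
class RiskStratification:
    """Cross-validated risk scores and the resulting Low/High stratification."""

    raw: np.ndarray
    scaled: np.ndarray
    groups: np.ndarray
    c_index: float
    logrank_stat: float
    logrank_p: float
    features_used: list[str]
    collinearity_threshold: float | None = None
    threshold: float = 0.5

    @property
    def significant(self) -> bool:
        return self.logrank_p <= 0.1


def choose_collinearity_threshold(
    df: pd.DataFrame,
    feature_cols: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    age_col: str | None = "age",
    candidates: Sequence[float] = DEFAULT_COLLINEARITY_CANDIDATES,
    seed: int = 0,
) -> tuple[float, list[str]]:
    """Scan candidate |r| cutoffs; keep the one maximizing CV C-index."""
    best = None
    for t in sorted(candidates):
        retained = collinearity_filter(df[list(feature_cols)], threshold=t)
        model_cols = retained + ([age_col] if age_col else [])
        risk = cv_risk_scores(
            df, model_cols, duration_col=duration_col, event_col=event_col, seed=seed
        )
        ci = c_index(risk, df[duration_col], df[event_col])
        if best is None or ci > best[0]:
            best = (ci, t, retained)
    return best[1], best[2]


def risk_stratification(
    df: pd.DataFrame,
    feature_cols: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    age_col: str | None = "age",
    seed: int = 0,
    threshold: float = 0.5,
    collinearity_candidates: Sequence[float] | None = DEFAULT_COLLINEARITY_CANDIDATES,
) -> RiskStratification:
    """End-to-end survival stratification for one cohort/subtype."""
    feature_cols = list(feature_cols)
    if collinearity_candidates and len(feature_cols) >= 2:
        chosen_t, retained = choose_collinearity_threshold(
            df,
            feature_cols,
            duration_col=duration_col,
            event_col=event_col,
            age_col=age_col,
            candidates=collinearity_candidates,
            seed=seed,
        )
    else:
        chosen_t, retained = None, feature_cols
    model_cols = retained + ([age_col] if age_col else [])
    raw = cv_risk_scores(
        df, model_cols, duration_col=duration_col, event_col=event_col, seed=seed
    )
    scaled = quantile_normalize_risk(raw)
    groups = stratify(scaled, threshold=threshold)
    ci = c_index(raw, df[duration_col], df[event_col])
    stat, p = logrank_test(df[duration_col], df[event_col], groups)
    return RiskStratification(
        raw=raw,
        scaled=scaled,
        groups=groups,
        c_index=ci,
        logrank_stat=stat,
        logrank_p=p,
        features_used=model_cols,
        collinearity_threshold=chosen_t,
        threshold=threshold,
    )


def plot_km(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
    path: str,
    title: str = "",
) -> None:
    """Save a Kaplan-Meier plot of the Low/High risk groups."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in np.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(times[mask], events[mask])
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
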
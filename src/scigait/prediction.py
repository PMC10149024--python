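"""Prediction of future improvement in walking capacity.

Subjects who repeated the six-minute walk test during rehabilitation
contribute one observation per consecutive pair of assessments.  The
binary label is whether the 6MWT distance increased by strictly more
than the test's standard error of measurement (16.5 m for this
population) — smaller changes are treated as measurement noise.
Subjects first measured deep in the chronic phase have their day axis
shifted so the first assessment sits at day 365, since further
time-since-injury carries little information once chronic.

Two predictor sets are compared with a random-forest classifier in
leave-one-subject-out cross-validation:

* set 1 — present 6MWT distance, days since injury, days until the
  next assessment;
* set 2 — set 1 plus all sensor-derived gait parameters, de-duplicated
  (|Pearson r| > 0.9) and reduced to the 10 most important features.

Feature scaling, redundancy removal and importance-based selection are
refit inside every training fold by default so no information from the
held-out subject leaks into model selection; a flag restores the
simpler whole-dataset variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kruskal
from sklearn.ensemble import RandomForestClassifier

log = logging.getLogger(__name__)


class PredictionError(ValueError):
    pass


@dataclass
class PredictionConfig:
    sem_m: float = 16.5  # standard error of measurement of the 6MWT, m
    chronic_day: float = 365.0  # days since injury marking the chronic phase
    n_top_features: int = 10
    corr_threshold: float = 0.9
    n_trees: int = 500
    max_depth: int | None = None
    seed: int = 0
    nested_selection: bool = True  # refit selection inside each LOSO fold

    def __post_init__(self) -> None:
        if self.sem_m <= 0:
            raise PredictionError("sem_m must be positive")
        if self.n_top_features < 1:
            raise PredictionError("n_top_features must be >= 1")


@dataclass
class ObservationPair:
    subject_id: str
    present_distance: float  # m
    days_since_injury: float  # after the chronic-shift rule
    days_until_next: float
    gait_features: pd.Series
    improved: bool  # future - present > SEM, strictly


@dataclass
class CvResult:
    predictions: np.ndarray
    labels: np.ndarray
    accuracy: float
    confusion: np.ndarray  # rows true, cols predicted; absolute counts
    confusion_normalized: np.ndarray  # rows sum to 1
    importances: pd.Series | None = None
    subject_ids: np.ndarray | None = None


# ---------------------------------------------------------------------------
# observation construction
# ---------------------------------------------------------------------------

def build_observations(trials: pd.DataFrame,
                       config: PredictionConfig | None = None
                       ) -> list[ObservationPair]:
    """One observation per consecutive trial pair of each subject.

    ``trials`` needs columns ``subject_id``, ``day``, ``distance`` plus
    any gait feature columns.  Subjects with a single trial contribute
    nothing.  The improvement label uses the strict inequality
    Δdistance > SEM.
    """
    config = config or PredictionConfig()
    feature_cols = [c for c in trials.columns
                    if c not in ("subject_id", "day", "distance")]
    obs: list[ObservationPair] = []
    for sid, grp in trials.groupby("subject_id", sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=float)
        if len(np.unique(days)) != len(days):
            raise PredictionError(f"duplicate trial dates for subject {sid}")
        if days[0] > config.chronic_day:
            days = days - (days[0] - config.chronic_day)  # chronic shift
        dist = grp["distance"].to_numpy(dtype=float)
        for j in range(len(grp) - 1):
            obs.append(ObservationPair(
                subject_id=str(sid),
                present_distance=float(dist[j]),
                days_since_injury=float(days[j]),
                days_until_next=float(days[j + 1] - days[j]),
                gait_features=grp.iloc[j][feature_cols].astype(float),
                improved=bool(dist[j + 1] - dist[j] > config.sem_m),
            ))
    return obs


def observations_frame(obs: list[ObservationPair]) -> pd.DataFrame:
    rows = []
    for o in obs:
        rows.append({"subject_id": o.subject_id,
                     "present_6mwt": o.present_distance,
                     "days_since_injury": o.days_since_injury,
                     "days_until_next": o.days_until_next,
                     **o.gait_features.to_dict(),
                     "improved": o.improved})
    return pd.DataFrame(rows)


SET1_COLUMNS = ["present_6mwt", "days_since_injury", "days_until_next"]


def make_feature_sets(obs: list[ObservationPair],
                      config: PredictionConfig | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Assemble (set1, set2, labels, subject_ids).

    Set 1 is exactly the three clinical predictors; set 2 additionally
    carries every gait parameter.  Standardisation and data-driven
    selection happen later (inside CV folds when nested selection is
    on), so the returned set 2 is the full candidate matrix.
    """
    if len(obs) < 2:
        raise PredictionError("need at least two observations")
    config = config or PredictionConfig()
    df = observations_frame(obs)
    labels = df.pop("improved").to_numpy(dtype=bool)
    if labels.all() or not labels.any():
        raise PredictionError("both improvement classes must be present")
    subjects = df.pop("subject_id").to_numpy()
    set1 = df[SET1_COLUMNS].copy()
    set2 = df.copy()
    return set1, set2, labels, subjects


# ---------------------------------------------------------------------------
# in-fold preprocessing
# ---------------------------------------------------------------------------

def _fit_selection(train_X: pd.DataFrame, train_y: np.ndarray,
                   config: PredictionConfig) -> tuple[list, pd.Series, pd.Series]:
    """Learn scaling parameters, drop redundant columns, rank by RF
    importance and keep the top ``n_top_features``.  Returns the kept
    column list and the (mean, sd) used for scaling."""
    mean = train_X.mean()
    sd = train_X.std(ddof=0).replace(0.0, 1.0)
    z = (train_X - mean) / sd
    # redundancy removal: keep the earlier column of each |r|>thr pair
    cols = list(z.columns)
    drop: set = set()
    corr = z.corr().abs().to_numpy()
    for i in range(len(cols)):
        if cols[i] in drop:
            continue
        for j in range(i + 1, len(cols)):
            if corr[i, j] > config.corr_threshold:
                drop.add(cols[j])
    kept = [c for c in cols if c not in drop]
    if len(kept) > config.n_top_features:
        rf = RandomForestClassifier(
            n_estimators=config.n_trees, max_depth=config.max_depth,
            random_state=config.seed)
        rf.fit(z[kept], train_y)
        imp = pd.Series(rf.feature_importances_, index=kept)
        kept = imp.sort_values(ascending=False).index[: config.n_top_features].tolist()
    return kept, mean, sd


# ---------------------------------------------------------------------------
# leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------

def loso_cv(features: pd.DataFrame, labels: np.ndarray, subject_ids,
            config: PredictionConfig | None = None) -> CvResult:
    """Leave-one-subject-out CV of a binary random forest.

    Every fold holds out all observations of one subject; the forest is
    trained on the rest (with scaling, redundancy removal and top-k
    importance selection refit on the training fold when
    ``config.nested_selection``) and predicts the held-out subject.
    Accuracy is (TP + TN) / N; the confusion matrix is reported both as
    absolute counts and normalised per true class.
    """
    config = config or PredictionConfig()
    labels = np.asarray(labels, dtype=bool)
    subject_ids = np.asarray(subject_ids)
    uniq = np.unique(subject_ids)
    if len(uniq) < 3:
        raise PredictionError("need at least 3 subjects for LOSO CV")

    if not config.nested_selection:
        global_kept, global_mean, global_sd = _fit_selection(features, labels, config)

    preds = np.zeros(len(labels), dtype=bool)
    importance_acc: list[pd.Series] = []
    for sid in uniq:
        test = subject_ids == sid
        train = np.nonzero(~test)[0]
        # canonical training-row order: results must not depend on how the
        # caller happened to order observations
        frame = features.iloc[train].reset_index(drop=True)
        order = frame.assign(_sid=subject_ids[train]).sort_values(
            ["_sid"] + list(features.columns), kind="mergesort").index.to_numpy()
        train = train[order]
        y_tr = labels[train]
        if y_tr.all() or not y_tr.any():
            majority = bool(y_tr.mean() >= 0.5)
            log.warning("fold %s: single-class training set, predicting majority", sid)
            preds[test] = majority
            continue
        X_tr = features.iloc[train]
        if config.nested_selection:
            kept, mean, sd = _fit_selection(X_tr, y_tr, config)
        else:
            kept, mean, sd = global_kept, global_mean, global_sd
        z_tr = ((X_tr - mean) / sd)[kept]
        z_te = ((features.loc[test] - mean) / sd)[kept]
        rf = RandomForestClassifier(
            n_estimators=config.n_trees, max_depth=config.max_depth,
            random_state=config.seed)
        rf.fit(z_tr, y_tr)
        preds[test] = rf.predict(z_te).astype(bool)
        importance_acc.append(pd.Series(rf.feature_importances_, index=kept))

    tp = int(np.sum(preds & labels))
    tn = int(np.sum(~preds & ~labels))
    fp = int(np.sum(preds & ~labels))
    fn = int(np.sum(~preds & labels))
    confusion = np.array([[tn, fp], [fn, tp]])
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = confusion / confusion.sum(axis=1, keepdims=True)
    importances = None
    if importance_acc:
        importances = (pd.concat(importance_acc, axis=1).fillna(0.0).mean(axis=1)
                       .sort_values(ascending=False))
    return CvResult(
        predictions=preds, labels=labels,
        accuracy=(tp + tn) / len(labels),
        confusion=confusion, confusion_normalized=norm,
        importances=importances, subject_ids=subject_ids,
    )


# ---------------------------------------------------------------------------
# improver vs non-improver statistics
# ---------------------------------------------------------------------------

def compare_improvers(features: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-feature Kruskal–Wallis comparison of improvers vs non-improvers.

    Returns a DataFrame with class medians, the p-value and significance
    stars at 0.05 / 0.01 / 0.001.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise PredictionError("both classes must be non-empty")
    from .clustering import significance_stars
    rows = []
    for col in features.columns:
        a = features[col].to_numpy()[labels]
        b = features[col].to_numpy()[~labels]
        try:
            p = kruskal(a, b).pvalue
        except ValueError:
            p = 1.0
        rows.append({"feature": col,
                     "median_improved": float(np.median(a)),
                     "median_not_improved": float(np.median(b)),
                     "p": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows).set_index("feature")
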
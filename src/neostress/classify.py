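"""Event-level stress classification with a subspace-LDA ensemble under
leave-one-patient-out (LOPO) evaluation.

Each hypoxic event contributes one feature row labelled by its subject's
stress status (any non-zero pain score the day before the recording).
Within every LOPO fold — all events of one subject held out — the
preprocessing is refit from scratch on the training subjects only:
median imputation of missing values, age correction (features with a
significant Pearson correlation against post-menstrual age are replaced by
the residuals of a linear fit), a greedy correlation filter keeping the
highest-F-score representative of any cluster of features correlated
above 0.9, and F-score ranking.  The classifier is a bagged ensemble of
linear discriminants, each trained on a stratified bootstrap and a random
feature subspace capped at one tenth of the training events; the ensemble
size is tuned by 10-fold cross-validation.  Test scores are pooled over
all folds before computing the AUC (rank statistic) and Cohen's kappa at
a 0.5 operating point.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .records import PipelineConfig, ValidationError

logger = logging.getLogger("neostress")

__all__ = [
    "META_COLUMNS", "assemble_features", "age_correct", "correlation_filter",
    "f_score", "SubspaceLDA", "train_subspace_lda", "lopo_evaluate",
    "cohens_kappa", "rank_auc", "ClassifierReport",
]

META_COLUMNS = ("subject_id", "group", "event_id", "label", "pma_weeks",
                "desat_threshold_pct")

#: Feature-name fragments marking power-like quantities (log-transformed
#: at assembly; HFnu is a bounded fraction and stays linear).
_POWER_TOKENS = ("_hf", "_lf", "_lfhf", "pdelta", "delta_power")


def is_power_feature(name: str) -> bool:
    if "_hfnu" in name:
        return False
    return any(tok in name for tok in _POWER_TOKENS)


def assemble_features(rows: list[dict]) -> pd.DataFrame:
    """One row per hypoxic event; power features natural-log transformed
    (ln(x + tiny)); missing values kept as NaN."""
    if not rows:
        logger.warning("assemble_features: no events")
        return pd.DataFrame(columns=list(META_COLUMNS))
    df = pd.DataFrame(rows)
    tiny = np.finfo(float).tiny
    for col in df.columns:
        if col in META_COLUMNS:
            continue
        if is_power_feature(col):
            vals = df[col].to_numpy(dtype=float)
            df[col] = np.log(np.clip(vals, 0.0, None) + tiny)
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in META_COLUMNS]


def feature_registry(columns) -> pd.DataFrame:
    """Tag table for feature names: modality group, epoch, log-transform flag.

    Names follow ``<signal>__<feature>__<epoch>``; modality groups are EEG
    (per-channel features), HR-SpO2 (tachogram / oximetry univariates) and
    B-H (brain-heart connectivity, the ``net_*`` partitions).
    """
    names = [c for c in columns if c not in META_COLUMNS]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate feature names in registry")
    rows = []
    for name in names:
        parts = name.split("__")
        epoch = parts[-1] if parts[-1] in ("pre", "during", "post", "whole") else ""
        if name.startswith("net_"):
            group = "B-H"
        elif name.startswith("eeg_"):
            group = "EEG"
        else:
            group = "HR-SpO2"
        rows.append({"name": name, "group": group, "epoch": epoch,
                     "log_transformed": is_power_feature(name)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Fold-local preprocessing
# --------------------------------------------------------------------------

def age_correct(table: pd.DataFrame, train_ids) -> pd.DataFrame:
    """Residualize features against PMA where the train-set Pearson
    correlation is significant (p < 0.05); coefficients are estimated on
    training rows and applied to all rows."""
    train_ids = set(train_ids)
    train = table["subject_id"].isin(train_ids).to_numpy()
    if table.loc[train, "subject_id"].nunique() < 3:
        raise ValidationError("age correction needs >= 3 training subjects")
    out = table.copy()
    pma = table["pma_weeks"].to_numpy(dtype=float)
    for col in feature_columns(table):
        x = out[col].to_numpy(dtype=float)
        m = train & np.isfinite(x)
        if m.sum() < 3 or np.ptp(x[m]) == 0 or np.ptp(pma[m]) == 0:
            continue
        r, p = stats.pearsonr(pma[m], x[m])
        if p < 0.05:
            slope, intercept = np.polyfit(pma[m], x[m], 1)
            out[col] = x - (slope * pma + intercept)
    return out


def f_score(feature_values, labels) -> float:
    """Two-class F-score: between-class separation over within-class spread,
    F = [(x+ - x)^2 + (x- - x)^2] / [var+ + var-]."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    m = np.isfinite(x)
    x, y = x[m], y[m]
    if not (np.any(y) and np.any(~y)):
        raise ValidationError("both classes must be present")
    xp, xn = x[y], x[~y]
    num = (xp.mean() - x.mean()) ** 2 + (xn.mean() - x.mean()) ** 2
    den = (xp.var(ddof=1) if xp.size > 1 else 0.0) + \
          (xn.var(ddof=1) if xn.size > 1 else 0.0)
    if den == 0:
        return 0.0
    return float(num / den)


def correlation_filter(table: pd.DataFrame, scores: dict[str, float],
                       cap: float = 0.9) -> list[str]:
    """Greedy pass in descending F-score order; drop any feature whose
    |Pearson r| with an already-retained feature exceeds the cap."""
    order = sorted(scores, key=lambda c: -scores[c])
    kept: list[str] = []
    X = {c: table[c].to_numpy(dtype=float) for c in order}
    for c in order:
        ok = True
        for k in kept:
            a, b = X[c], X[k]
            m = np.isfinite(a) & np.isfinite(b)
            if m.sum() < 3 or np.ptp(a[m]) == 0 or np.ptp(b[m]) == 0:
                continue
            if abs(np.corrcoef(a[m], b[m])[0, 1]) > cap:
                ok = False
                break
        if ok:
            kept.append(c)
    return kept


# --------------------------------------------------------------------------
# Subspace-LDA ensemble
# --------------------------------------------------------------------------

# sklearn warns when a bootstrap class collapses to one sample; the ensemble
# handles that case by design
warnings.filterwarnings("ignore", message="Only one sample available",
                        category=UserWarning)


def _fit_lda(X: np.ndarray, y: np.ndarray, shrinkage: float):
    # uniform priors: the LOPO folds have slightly different class ratios,
    # and prior-driven posterior shifts would bias the pooled scores
    try:
        model = LinearDiscriminantAnalysis(solver="lsqr", priors=(0.5, 0.5))
        model.fit(X, y)
        if not np.all(np.isfinite(model.coef_)):
            raise np.linalg.LinAlgError
        return model
    except (np.linalg.LinAlgError, ValueError):
        logger.info("degenerate within-class covariance; refit with shrinkage %.2f",
                    shrinkage)
        model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage,
                                           priors=(0.5, 0.5))
        model.fit(X, y)
        return model


class SubspaceLDA:
    """Bagged LDA ensemble over random feature subspaces.

    Each learner sees a stratified bootstrap of the training events and a
    uniformly random feature subset of ``subspace_dim`` columns; the
    ensemble score is the mean posterior probability of the positive class.
    """

    def __init__(self, n_learners: int = 30, subspace_dim: int | None = None,
                 shrinkage: float = 0.1, seed=0):
        self.n_learners = n_learners
        self.subspace_dim = subspace_dim
        self.shrinkage = shrinkage
        self.seed = seed
        self.learners_: list[tuple[np.ndarray, LinearDiscriminantAnalysis]] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SubspaceLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        if not (np.any(y) and np.any(~y)):
            raise ValidationError("training data must contain both classes")
        rng = np.random.default_rng(self.seed)
        n, p = X.shape
        dim = min(self.subspace_dim or p, p)
        pos = np.flatnonzero(y)
        neg = np.flatnonzero(~y)
        self.learners_ = []
        for _ in range(self.n_learners):
            rows = np.concatenate((rng.choice(pos, pos.size, replace=True),
                                   rng.choice(neg, neg.size, replace=True)))
            cols = rng.choice(p, size=dim, replace=False)
            Xb, yb = X[np.ix_(rows, cols)], y[rows]
            if np.any(yb) and np.any(~yb):
                self.learners_.append((cols, _fit_lda(Xb, yb, self.shrinkage)))
        if not self.learners_:
            raise ValidationError("no learner could be trained")
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        scores = np.zeros(X.shape[0])
        for cols, model in self.learners_:
            pos_col = int(np.flatnonzero(model.classes_)[0])
            scores += model.predict_proba(X[:, cols])[:, pos_col]
        return scores / len(self.learners_)


def _cv_auc(X, y, n_learners, dim, shrinkage, seed, n_folds) -> float:
    rng = np.random.default_rng(seed)
    n = y.size
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    scores = np.full(n, np.nan)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        ytr = y[train_idx]
        if not (np.any(ytr) and np.any(~ytr)) or test_idx.size == 0:
            continue
        model = SubspaceLDA(n_learners, dim, shrinkage,
                            seed=(seed * 131 + f) % 2**31).fit(X[train_idx], ytr)
        scores[test_idx] = model.predict_scores(X[test_idx])
    m = np.isfinite(scores)
    if not (np.any(y[m]) and np.any(~y[m])):
        return 0.5
    return rank_auc(scores[m], y[m])


def train_subspace_lda(X: np.ndarray, y: np.ndarray,
                       config: PipelineConfig | None = None,
                       seed=0) -> SubspaceLDA:
    """Fit the ensemble; when ``config.tune_ensemble`` the ensemble size is
    selected from ``config.ensemble_grid`` by 10-fold CV AUC (ties to the
    smaller ensemble).  The per-learner subspace is capped at
    ``floor(n_train / 10)`` features."""
    cfg = config or PipelineConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    dim = max(1, min(int(X.shape[0] * cfg.subspace_fraction), X.shape[1]))
    n_learners = cfg.ensemble_size
    if cfg.tune_ensemble and min(np.sum(y), np.sum(~y)) >= 2:
        n_folds = int(min(cfg.cv_folds, np.sum(y), np.sum(~y)))
        best = None
        for L in cfg.ensemble_grid:
            auc = _cv_auc(X, y, L, dim, cfg.lda_shrinkage, seed, n_folds)
            if best is None or auc > best[0] + 1e-12:
                best = (auc, L)
        n_learners = best[1]
    return SubspaceLDA(n_learners, dim, cfg.lda_shrinkage, seed=seed).fit(X, y)


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def rank_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney rank statistic (ties mid-ranked)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1, n0 = int(np.sum(y)), int(np.sum(~y))
    if n1 == 0 or n0 == 0:
        return math.nan
    r = stats.rankdata(s)
    return float((np.sum(r[y]) - n1 * (n1 + 1) / 2) / (n1 * n0))


def cohens_kappa(pred_labels, true_labels) -> float:
    """Chance-corrected agreement from the 2x2 confusion table; defined as
    0 when the expected agreement is 1."""
    yp = np.asarray(pred_labels, dtype=bool)
    yt = np.asarray(true_labels, dtype=bool)
    if yp.shape != yt.shape or yp.size == 0:
        raise ValidationError("prediction/truth must be equal-length, non-empty")
    n = yp.size
    po = np.mean(yp == yt)
    pe = (np.mean(yp) * np.mean(yt)) + (np.mean(~yp) * np.mean(~yt))
    if abs(1.0 - pe) < 1e-15:
        logger.info("kappa undefined (expected agreement 1); returning 0")
        return 0.0
    return float((po - pe) / (1.0 - pe))


# --------------------------------------------------------------------------
# Leave-one-patient-out evaluation
# --------------------------------------------------------------------------

@dataclass
class GroupResult:
    group: str
    threshold_pct: float
    auc: float
    kappa: float
    n_events: int
    n_subjects: int
    flags: list[str] = field(default_factory=list)
    scores: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"auc": self.auc, "kappa": self.kappa, "n_events": self.n_events,
                "n_subjects": self.n_subjects, "flags": self.flags}


@dataclass
class ClassifierReport:
    results: dict                      # (group, threshold) -> GroupResult
    seed: int
    config: PipelineConfig

    def to_dict(self) -> dict:
        out: dict = {}
        for (group, thr), res in self.results.items():
            out.setdefault(group, {})[f"{thr:g}"] = res.to_dict()
        return out

    def pooled_scores(self) -> pd.DataFrame:
        frames = [r.scores for r in self.results.values() if r.scores is not None]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _prepare_fold(table: pd.DataFrame, train_ids, cfg: PipelineConfig,
                  min_fscore_classes: bool = True):
    """Fold-local preprocessing: impute -> age-correct -> F-rank -> filter.

    Returns (feature list, imputation medians, corrected table).
    """
    train = table["subject_id"].isin(set(train_ids))
    cols = feature_columns(table)
    # median imputation with training medians; all-NaN training columns drop
    medians = table.loc[train, cols].median(numeric_only=True)
    usable = [c for c in cols if np.isfinite(medians.get(c, np.nan))]
    filled = table.copy()
    filled[usable] = filled[usable].fillna(medians[usable])
    filled = filled.drop(columns=[c for c in cols if c not in usable])
    corrected = age_correct(filled, train_ids)
    ytr = corrected.loc[train, "label"].to_numpy(dtype=bool)
    scores = {}
    for c in usable:
        x = corrected.loc[train, c].to_numpy(dtype=float)
        if np.ptp(x[np.isfinite(x)]) == 0:
            continue
        scores[c] = f_score(x, ytr)
    kept = correlation_filter(corrected.loc[train], scores, cfg.correlation_cap)
    n_keep = max(1, cfg.preselect_multiple * max(1, int(train.sum() * cfg.subspace_fraction)))
    kept = kept[:n_keep]
    return kept, medians, corrected


def lopo_evaluate(table: pd.DataFrame, config: PipelineConfig | None = None,
                  seed: int = 0, expected_groups=None) -> ClassifierReport:
    """Leave-one-patient-out evaluation per monitoring group and threshold.

    ``table`` must contain the META_COLUMNS plus feature columns; rows for
    several thresholds may coexist (column ``desat_threshold_pct``).
    ``expected_groups`` lists groups that must appear in the report even
    with zero detected events (flagged, not raised).
    """
    cfg = config or PipelineConfig()
    results: dict = {}
    groups = set(expected_groups or ())
    if not table.empty:
        groups |= set(table["group"].unique())
    if not groups:
        return ClassifierReport(results, seed, cfg)
    thr_values = (sorted(table["desat_threshold_pct"].unique())
                  if not table.empty else list(cfg.desat_thresholds_pct))
    for group in sorted(groups):
        for thr in thr_values:
            if table.empty:
                sub = table
            else:
                sub = table[(table["group"] == group)
                            & (table["desat_threshold_pct"] == thr)
                            ].reset_index(drop=True)
            res = _lopo_one(sub, group, float(thr), cfg, seed)
            results[(group, float(thr))] = res
            logger.info("lopo %s thr=%g: n=%d subjects=%d auc=%.3f kappa=%.3f %s",
                        group, thr, res.n_events, res.n_subjects,
                        res.auc, res.kappa, ";".join(res.flags))
    return ClassifierReport(results, seed, cfg)


def _lopo_one(sub: pd.DataFrame, group: str, thr: float,
              cfg: PipelineConfig, seed: int) -> GroupResult:
    subjects = sorted(sub["subject_id"].unique())
    n_events = len(sub)
    if n_events == 0:
        return GroupResult(group, thr, math.nan, math.nan, 0, 0, ["no events"])
    label_by_subject = sub.groupby("subject_id")["label"].first()
    if label_by_subject.nunique() < 2 or min(
            (label_by_subject).sum(), (~label_by_subject.astype(bool)).sum()) < 2:
        return GroupResult(group, thr, math.nan, math.nan, n_events,
                           len(subjects), ["single-class or <2 subjects per class"])
    rows = []
    for f, held_out in enumerate(subjects):
        train_ids = [s for s in subjects if s != held_out]
        train_labels = label_by_subject[train_ids]
        if train_labels.nunique() < 2:
            continue
        kept, medians, corrected = _prepare_fold(sub, train_ids, cfg)
        train = corrected["subject_id"].isin(train_ids)
        Xtr = corrected.loc[train, kept].to_numpy(dtype=float)
        ytr = corrected.loc[train, "label"].to_numpy(dtype=bool)
        Xte = corrected.loc[~train, kept].to_numpy(dtype=float)
        model = train_subspace_lda(Xtr, ytr, cfg, seed=(seed * 10007 + f) % 2**31)
        s = model.predict_scores(Xte)
        te = corrected.loc[~train]
        for (_, row), sc in zip(te.iterrows(), s):
            rows.append({"subject_id": row["subject_id"], "group": group,
                         "event_id": row["event_id"],
                         "desat_threshold_pct": thr,
                         "label": bool(row["label"]), "score": float(sc)})
    if not rows:
        return GroupResult(group, thr, math.nan, math.nan, n_events,
                           len(subjects), ["no testable folds"])
    pooled = pd.DataFrame(rows)
    y = pooled["label"].to_numpy(dtype=bool)
    s = pooled["score"].to_numpy(dtype=float)
    auc = rank_auc(s, y)
    kappa = cohens_kappa(s >= cfg.kappa_threshold, y)
    return GroupResult(group, thr, auc, kappa, n_events, len(subjects),
                       [], pooled)
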
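"""Presence/background ensemble modeling and evaluation.

Five base learners — a regularized logistic GLM with quadratic terms, a
spline-based GAM, a MaxEnt-style L1 logistic model on linear/quadratic/
product features, random forest, and gradient boosting — are fitted to
presence vs pseudo-absence data, evaluated by repeated stratified k-fold
cross-validation with AUC, TSS and the continuous Boyce index, and combined
by an AUC-weighted mean over all members whose AUC exceeds a cutoff
(0.7 by default). Binary habitat maps use the threshold that maximises the
sum of sensitivity and specificity (maxSSS).

Background points are down-weighted so the total presence and background
weights are equal, the standard correction for the gross presence/background
imbalance of presence-only data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import (
    FunctionTransformer,
    PolynomialFeatures,
    SplineTransformer,
    StandardScaler,
)
from xgboost import XGBClassifier

__all__ = [
    "ALGORITHMS",
    "BaseLearnerSpec",
    "FittedScorer",
    "ModelRun",
    "EnsembleModel",
    "auc",
    "tss_at",
    "tss_max",
    "max_sss_threshold",
    "boyce_index",
    "fit_base_learner",
    "cross_validate",
    "ensemble_weighted_mean",
    "build_ensemble",
    "variable_importance",
    "response_curve",
    "runs_table",
]

ALGORITHMS = ("GLM", "GAM", "MAXENT_LIKE", "RF", "XGB")
AUC_CUTOFF_DEFAULT = 0.7


@dataclass(frozen=True)
class BaseLearnerSpec:
    algorithm: str
    hyperparams: tuple = ()  # ((name, value), ...) so the spec stays hashable

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)


# ---------------------------------------------------------------------------
# threshold-free and threshold-dependent metrics
# ---------------------------------------------------------------------------

def auc(scores_presence, scores_background) -> float:
    """Rank (Mann-Whitney) AUC; ties count one half."""
    pos = np.asarray(scores_presence, dtype=float)
    neg = np.asarray(scores_background, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def tss_at(scores_presence, scores_background, threshold: float) -> float:
    """Sensitivity + specificity - 1 at the given threshold (score >= t is a
    predicted presence)."""
    pos = np.asarray(scores_presence, dtype=float)
    neg = np.asarray(scores_background, dtype=float)
    sens = float(np.mean(pos >= threshold))
    spec = float(np.mean(neg < threshold))
    return sens + spec - 1.0


def max_sss_threshold(scores_presence, scores_background) -> float:
    """Smallest threshold among the unique scores maximising sens + spec."""
    pos = np.asarray(scores_presence, dtype=float)
    neg = np.asarray(scores_background, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    candidates = np.unique(np.concatenate([pos, neg]))
    best_t, best_v = candidates[0], -np.inf
    for t in candidates:
        v = tss_at(pos, neg, t)
        if v > best_v + 1e-15:
            best_t, best_v = t, v
    return float(best_t)


def tss_max(scores_presence, scores_background) -> tuple[float, float]:
    """(max TSS, threshold attaining it) over the unique-score candidates."""
    t = max_sss_threshold(scores_presence, scores_background)
    return tss_at(scores_presence, scores_background, t), t


def boyce_index(
    scores_presence,
    scores_landscape,
    n_bins: int = 10,
    window_fraction: float = 0.1,
) -> float:
    """Continuous Boyce index.

    The landscape score range is covered by ``n_bins`` overlapping classes
    of width ``window_fraction`` of the range; for each class the
    predicted-to-expected ratio P/E (fraction of presence scores over
    fraction of landscape scores falling in the class) is computed, and the
    index is the Spearman rank correlation between P/E and the class
    midpoint over classes with non-zero expected frequency. Values lie in
    [-1, 1]; fewer than 3 usable classes is undefined and returns NaN with
    a warning.
    """
    pres = np.asarray(scores_presence, dtype=float)
    land = np.asarray(scores_landscape, dtype=float)
    mn, mx = land.min(), land.max()
    if mx <= mn:
        warnings.warn("landscape scores are constant; Boyce index undefined")
        return float("nan")
    width = window_fraction * (mx - mn)
    mids = np.linspace(mn + width / 2, mx - width / 2, n_bins)
    ratios, centers = [], []
    for m in mids:
        lo, hi = m - width / 2, m + width / 2
        e = np.mean((land >= lo) & (land <= hi))
        if e == 0:
            continue
        p = np.mean((pres >= lo) & (pres <= hi))
        ratios.append(p / e)
        centers.append(m)
    if len(ratios) < 3:
        warnings.warn("fewer than 3 non-empty suitability classes; Boyce undefined")
        return float("nan")
    rho = stats.spearmanr(centers, ratios).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------

def _append_squares(X):
    return np.hstack([X, X**2])


def _make_estimator(spec: BaseLearnerSpec, seed: int):
    p = spec.params
    if spec.algorithm == "GLM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("quad", FunctionTransformer(_append_squares)),
                ("clf", LogisticRegression(C=p.get("C", 1.0), max_iter=2000)),
            ]
        )
    if spec.algorithm == "GAM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "spline",
                    SplineTransformer(
                        n_knots=p.get("n_knots", 5), degree=p.get("degree", 3)
                    ),
                ),
                ("clf", LogisticRegression(C=p.get("C", 1.0), max_iter=2000)),
            ]
        )
    if spec.algorithm == "MAXENT_LIKE":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                (
                    "clf",
                    LogisticRegression(
                        l1_ratio=1.0,
                        solver="liblinear",
                        C=p.get("C", 1.0),
                        random_state=seed,
                        max_iter=2000,
                    ),
                ),
            ]
        )
    if spec.algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 200),
            max_depth=p.get("max_depth", None),
            min_samples_leaf=p.get("min_samples_leaf", 2),
            random_state=seed,
            n_jobs=1,
        )
    if spec.algorithm == "XGB":
        return XGBClassifier(
            n_estimators=p.get("n_estimators", 100),
            max_depth=p.get("max_depth", 3),
            learning_rate=p.get("learning_rate", 0.1),
            subsample=p.get("subsample", 0.8),
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(spec.algorithm)


@dataclass
class FittedScorer:
    """A fitted base learner mapping feature rows to suitability in [0, 1]."""

    algorithm: str
    estimator: object
    feature_names: list[str]

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        scores = self.estimator.predict_proba(X)[:, 1]
        return np.clip(scores, 0.0, 1.0)


def fit_base_learner(
    spec: BaseLearnerSpec,
    presences_features: pd.DataFrame,
    background_features: pd.DataFrame,
    seed: int = 0,
) -> FittedScorer:
    """Fit one algorithm on presence (1) vs background (0) rows.

    Background rows are down-weighted so total class weights are equal.
    """
    if list(presences_features.columns) != list(background_features.columns):
        raise ValueError("presence and background feature columns differ")
    n_pres, n_bg = len(presences_features), len(background_features)
    if n_pres < 2 or n_bg < 2:
        raise ValueError("need at least 2 presences and 2 background points")
    X = np.vstack(
        [presences_features.to_numpy(dtype=float), background_features.to_numpy(dtype=float)]
    )
    y = np.concatenate([np.ones(n_pres), np.zeros(n_bg)])
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class input")
    w = np.concatenate([np.ones(n_pres), np.full(n_bg, n_pres / n_bg)])
    est = _make_estimator(spec, seed)
    if isinstance(est, Pipeline):
        est.fit(X, y, clf__sample_weight=w)
    else:
        est.fit(X, y, sample_weight=w)
    return FittedScorer(
        algorithm=spec.algorithm,
        estimator=est,
        feature_names=list(presences_features.columns),
    )


# ---------------------------------------------------------------------------
# cross-validation and the ensemble
# ---------------------------------------------------------------------------

@dataclass
class ModelRun:
    """One fitted model with its held-out evaluation."""

    algorithm: str
    pa_set_id: int
    repeat_index: int
    fold_index: int
    auc: float
    tss: float
    boyce: float
    predictor: FittedScorer


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def cross_validate(
    presence_features: pd.DataFrame,
    background_sets: list[pd.DataFrame],
    specs: list[BaseLearnerSpec],
    k: int = 5,
    repeats: int = 3,
    seed: int = 0,
) -> list[ModelRun]:
    """Repeated stratified k-fold CV over algorithms x PA sets x repeats x folds.

    Presences and background are partitioned separately (so every fold holds
    presences), each record held out exactly once per repeat. Held-out AUC,
    TSS (at the held-out maxSSS threshold) and Boyce (held-out background as
    the landscape sample) are attached to each run.
    """
    n_pres = len(presence_features)
    if k > n_pres:
        raise ValueError(f"k={k} exceeds presence count {n_pres}")
    runs: list[ModelRun] = []
    for pa_id, bg in enumerate(background_sets):
        for rep in range(repeats):
            rng = np.random.default_rng([seed, pa_id, rep])
            pres_folds = _fold_indices(n_pres, k, rng)
            bg_folds = _fold_indices(len(bg), k, rng)
            for fold in range(k):
                pres_te = pres_folds[fold]
                bg_te = bg_folds[fold]
                pres_tr = np.setdiff1d(np.arange(n_pres), pres_te)
                bg_tr = np.setdiff1d(np.arange(len(bg)), bg_te)
                for spec in specs:
                    fit_seed = abs(hash((seed, pa_id, rep, fold, spec.algorithm))) % (2**31)
                    scorer = fit_base_learner(
                        spec,
                        presence_features.iloc[pres_tr],
                        bg.iloc[bg_tr],
                        seed=fit_seed,
                    )
                    s_pos = scorer.predict(presence_features.iloc[pres_te])
                    s_neg = scorer.predict(bg.iloc[bg_te])
                    run_auc = auc(s_pos, s_neg)
                    run_tss, _ = tss_max(s_pos, s_neg)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        run_boyce = boyce_index(s_pos, s_neg)
                    runs.append(
                        ModelRun(
                            algorithm=spec.algorithm,
                            pa_set_id=pa_id,
                            repeat_index=rep,
                            fold_index=fold,
                            auc=run_auc,
                            tss=run_tss,
                            boyce=run_boyce,
                            predictor=scorer,
                        )
                    )
    return runs


def ensemble_weighted_mean(
    member_scores: list[np.ndarray],
    member_aucs: list[float],
    auc_cutoff: float = AUC_CUTOFF_DEFAULT,
) -> np.ndarray:
    """AUC-weighted mean of the member scores above the cutoff.

    Weights are each included member's AUC divided by the included AUC sum,
    so the result is a convex combination bounded by the member extrema.
    """
    included = [
        (np.asarray(s, dtype=float), a)
        for s, a in zip(member_scores, member_aucs)
        if a > auc_cutoff
    ]
    if not included:
        raise ValueError(f"no member has AUC above the cutoff {auc_cutoff}")
    total = sum(a for _, a in included)
    out = np.zeros_like(included[0][0])
    for s, a in included:
        out = out + (a / total) * s
    return out


@dataclass
class EnsembleModel:
    """AUC-weighted ensemble of cross-validated members."""

    members: list[ModelRun]
    auc_cutoff: float = AUC_CUTOFF_DEFAULT
    threshold_maxsss: float | None = None
    variable_set: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble has no members above the AUC cutoff")

    @property
    def weights(self) -> np.ndarray:
        aucs = np.array([m.auc for m in self.members])
        return aucs / aucs.sum()

    def predict(self, X) -> np.ndarray:
        return ensemble_weighted_mean(
            [m.predictor.predict(X) for m in self.members],
            [m.auc for m in self.members],
            auc_cutoff=0.0,  # members were already filtered at build time
        )


def build_ensemble(
    runs: list[ModelRun],
    presence_features: pd.DataFrame,
    background_features: pd.DataFrame,
    auc_cutoff: float = AUC_CUTOFF_DEFAULT,
) -> EnsembleModel:
    """Filter runs at the AUC cutoff and compute the ensemble maxSSS threshold."""
    members = [r for r in runs if r.auc > auc_cutoff]
    model = EnsembleModel(
        members=members,
        auc_cutoff=auc_cutoff,
        variable_set=list(presence_features.columns),
    )
    s_pos = model.predict(presence_features)
    s_neg = model.predict(background_features)
    model.threshold_maxsss = max_sss_threshold(s_pos, s_neg)
    return model


# ---------------------------------------------------------------------------
# interpretation
# ---------------------------------------------------------------------------

def variable_importance(
    model,
    eval_features: pd.DataFrame,
    variable: str,
    n_perm: int = 5,
    seed: int = 0,
) -> float:
    """Permutation importance: 1 - |Pearson r| between predictions on the
    original features and on features with one column permuted, averaged
    over ``n_perm`` seeded permutations. Constant predictions give 0."""
    if variable not in eval_features.columns:
        raise KeyError(variable)
    base = model.predict(eval_features)
    if np.std(base) == 0:
        return 0.0
    vals = []
    for i in range(n_perm):
        rng = np.random.default_rng([seed, i])
        shuffled = eval_features.copy()
        shuffled[variable] = rng.permutation(shuffled[variable].to_numpy())
        perm = model.predict(shuffled)
        if np.std(perm) == 0:
            vals.append(1.0)
            continue
        r = np.corrcoef(base, perm)[0, 1]
        vals.append(1.0 - abs(float(r)))
    return float(np.mean(vals))


def response_curve(
    model,
    train_features: pd.DataFrame,
    variable: str,
    n_points: int = 100,
) -> pd.DataFrame:
    """Evaluation-strip response curve.

    The variable sweeps its observed training range; all other variables sit
    at their training medians. Returns columns (value, score).
    """
    if variable not in train_features.columns:
        raise KeyError(variable)
    med = train_features.median()
    sweep = np.linspace(
        train_features[variable].min(), train_features[variable].max(), n_points
    )
    strip = pd.DataFrame(
        {col: np.full(n_points, med[col]) for col in train_features.columns}
    )
    strip[variable] = sweep
    return pd.DataFrame({"value": sweep, "score": model.predict(strip)})


def runs_table(runs: list[ModelRun]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "algorithm": r.algorithm,
                "pa_set": r.pa_set_id,
                "repeat": r.repeat_index,
                "fold": r.fold_index,
                "auc": r.auc,
                "tss": r.tss,
                "boyce": r.boyce,
            }
            for r in runs
        ]
    )
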
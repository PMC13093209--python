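"""Learners, pseudo-absence sampling, fold construction, and skill scores.

Ten algorithm slots are exposed behind one contract — ``fit_model`` returns
a :class:`FittedModel` whose ``score`` maps predictor rows to [0, 1]:

=======  ==============================================================
ANN      multi-layer perceptron (one small hidden layer)
CTA      classification tree
FDA      discriminant analysis on a quadratic feature basis
GAM      logistic regression on per-variable cubic spline bases
GBM      stochastic gradient boosting
GLM      logistic regression with linear + quadratic terms
MARS     logistic regression on piecewise-linear hinge bases at
         quantile knots
MAXENT   presence/background logistic model on a polynomial feature
         expansion (the standard logistic surrogate)
RF       random forest
SRE      surface range envelope, implemented from its definition:
         suitable iff every continuous predictor lies within the
         central [q, 100-q] percentile interval of presence values
=======  ==============================================================

Class imbalance against the (much larger) pseudo-absence set is handled by
weighting so total presence weight equals total absence weight; learners
that cannot take sample weights receive integer-replicated presence rows
instead, which realizes the same weighting.

Skill scores follow the presence/absence conventions of the field: AUC in
its Mann-Whitney form (ties count one half) and the true skill statistic
TSS = sensitivity + specificity - 1, maximized over a threshold scanned at
midpoints of consecutive distinct scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .occurrences import OccurrenceSet
from .predictors import EnvStack, extract_values

ALGORITHMS = ["ANN", "CTA", "FDA", "GAM", "GBM", "GLM", "MARS", "MAXENT", "RF", "SRE"]

# learners whose fit() accepts no sample_weight: presence rows are replicated
_NEEDS_REPLICATION = {"ANN", "FDA"}


class _QuadraticBasis(BaseEstimator, TransformerMixin):
    """Per-feature (x, x^2) expansion without cross terms."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.hstack([X, X**2])


class _HingeBasis(BaseEstimator, TransformerMixin):
    """Piecewise-linear hinge pairs max(0, x-k), max(0, k-x) at quantile knots."""

    def __init__(self, quantiles=(0.25, 0.5, 0.75)):
        self.quantiles = quantiles

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.knots_ = np.quantile(X, self.quantiles, axis=0)  # (q, p)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        feats = [X]
        for k in self.knots_:
            feats.append(np.maximum(0.0, X - k))
            feats.append(np.maximum(0.0, k - X))
        return np.hstack(feats)


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "ANN":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    MLPClassifier(
                        hidden_layer_sizes=(8,), max_iter=800, random_state=seed
                    ),
                ),
            ]
        )
    if algorithm == "CTA":
        return DecisionTreeClassifier(min_samples_leaf=5, random_state=seed)
    if algorithm == "FDA":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("basis", _QuadraticBasis()),
                ("clf", LinearDiscriminantAnalysis()),
            ]
        )
    if algorithm == "GAM":
        return Pipeline(
            [
                ("basis", SplineTransformer(n_knots=5, degree=3)),
                ("clf", LogisticRegression(max_iter=2000)),
            ]
        )
    if algorithm == "GBM":
        return GradientBoostingClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1, random_state=seed
        )
    if algorithm == "GLM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("basis", _QuadraticBasis()),
                ("clf", LogisticRegression(max_iter=2000)),
            ]
        )
    if algorithm == "MARS":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("basis", _HingeBasis()),
                ("clf", LogisticRegression(max_iter=2000)),
            ]
        )
    if algorithm == "MAXENT":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("basis", PolynomialFeatures(degree=2, include_bias=False)),
                ("clf", LogisticRegression(max_iter=2000, C=0.5)),
            ]
        )
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=100, min_samples_leaf=2, random_state=seed, n_jobs=1
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; valid: {ALGORITHMS}")


@dataclass
class FittedModel:
    """A fitted learner honoring the uniform [0,1] score contract."""

    algorithm: str
    feature_names: list[str]
    continuous: list[str]
    estimator: object | None = None  # sklearn-style, or None for SRE
    envelope: tuple[np.ndarray, np.ndarray] | None = None  # SRE (lo, hi) per cont col
    categorical_levels: dict[str, list] = field(default_factory=dict)
    fold: int | None = None

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """Score predictor rows; values clipped to [0, 1]."""
        missing = [c for c in self.feature_names if c not in X.columns]
        if self.algorithm == "SRE":
            missing = [c for c in self.continuous if c not in X.columns]
        if missing:
            raise KeyError(f"missing predictor column(s): {missing}")
        if self.algorithm == "SRE":
            vals = X[self.continuous].to_numpy(dtype=float)
            lo, hi = self.envelope
            inside = np.all((vals >= lo) & (vals <= hi), axis=1)
            return inside.astype(float)
        mat = X[self.feature_names].to_numpy(dtype=float)
        proba = self.estimator.predict_proba(mat)[:, 1]
        return np.clip(proba, 0.0, 1.0)


@dataclass
class ModelEvaluation:
    """Held-out skill of one algorithm on one fold."""

    algorithm: str
    fold: int
    auc: float
    tss: float
    threshold: float
    sensitivity: float
    specificity: float
    model: FittedModel | None = None


@dataclass
class TrainingData:
    """Presence/pseudo-absence design matrix with a k-fold structure."""

    X: pd.DataFrame
    y: np.ndarray  # 1 presence, 0 pseudo-absence
    test_masks: np.ndarray  # (k, n) boolean; row f marks fold f's held-out rows
    fold: np.ndarray | None = None  # fold id per row when masks form a partition

    @property
    def k(self) -> int:
        return self.test_masks.shape[0]

    def split(self, f: int):
        """(X_train, y_train, X_test, y_test) for fold f (1-based)."""
        test = self.test_masks[f - 1]
        return (
            self.X[~test],
            self.y[~test],
            self.X[test],
            self.y[test],
        )


def encode_predictors(
    table: pd.DataFrame, categorical_levels: dict[str, list]
) -> pd.DataFrame:
    """One-hot encode categorical columns as '{layer}={level}' indicators."""
    out = table.copy()
    for col, levels in categorical_levels.items():
        if col not in out.columns:
            raise KeyError(f"missing predictor column(s): ['{col}']")
        for lev in levels:
            out[f"{col}={lev}"] = (out[col] == lev).astype(float)
        out = out.drop(columns=[col])
    return out


def sample_pseudo_absences(
    stack: EnvStack, occ: OccurrenceSet, n: int = 10000, seed: int = 0
) -> pd.DataFrame:
    """Draw n background cells uniformly without replacement.

    Cells carrying a presence record are excluded; results are returned as
    cell-center points with their grid indices.
    """
    rows, cols = np.nonzero(stack.mask)
    flat = rows.astype(np.int64) * stack.grid.n_cols + cols
    prow, pcol = stack.grid.cell_index(
        occ.frame["lon"].to_numpy(), occ.frame["lat"].to_numpy()
    )
    pres_flat = set((prow.astype(np.int64) * stack.grid.n_cols + pcol)[prow >= 0])
    eligible = flat[~np.isin(flat, list(pres_flat))]
    if n > eligible.size:
        raise ValueError(
            f"requested {n} pseudo-absences but only {eligible.size} eligible cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n, replace=False, shuffle=False)
    r, c = np.divmod(chosen, stack.grid.n_cols)
    lon, lat = stack.grid.cell_center(r, c)
    return pd.DataFrame({"lon": lon, "lat": lat, "grid_row": r, "grid_col": c})


def make_folds(
    presence_X: pd.DataFrame,
    absence_X: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    method: str = "cv",
) -> TrainingData:
    """Stratified fold structure over presences and pseudo-absences.

    ``method='cv'`` (default): disjoint stratified k-fold partition; each
    evaluation trains on k-1 folds and tests on one, so with k=4 the
    75/25 train/test split arises exactly. ``method='random_split'``: k
    independent stratified 75/25 splits (the alternative reading of
    repeated split evaluation).
    """
    n_p, n_a = len(presence_X), len(absence_X)
    if n_p < k or n_a < k:
        raise ValueError(f"need at least {k} rows of each class, got {n_p} / {n_a}")
    drop = ["lon", "lat", "grid_row", "grid_col", "masked"]
    Xp = presence_X.drop(columns=[c for c in drop if c in presence_X.columns])
    Xa = absence_X.drop(columns=[c for c in drop if c in absence_X.columns])
    X = pd.concat([Xp, Xa], ignore_index=True)
    y = np.concatenate([np.ones(n_p, dtype=int), np.zeros(n_a, dtype=int)])
    rng = np.random.default_rng(seed)
    n = n_p + n_a
    if method == "cv":
        fold = np.empty(n, dtype=int)
        fold[:n_p] = (np.arange(n_p) % k + 1)[rng.permutation(n_p)]
        fold[n_p:] = (np.arange(n_a) % k + 1)[rng.permutation(n_a)]
        masks = np.stack([fold == f for f in range(1, k + 1)])
        return TrainingData(X=X, y=y, test_masks=masks, fold=fold)
    if method == "random_split":
        masks = np.zeros((k, n), dtype=bool)
        for f in range(k):
            tp = rng.choice(n_p, size=max(1, n_p // 4), replace=False)
            ta = rng.choice(n_a, size=max(1, n_a // 4), replace=False)
            masks[f, tp] = True
            masks[f, n_p + ta] = True
        return TrainingData(X=X, y=y, test_masks=masks, fold=None)
    raise ValueError("method must be 'cv' or 'random_split'")


def _balanced_fit(est, X: np.ndarray, y: np.ndarray, replicate: bool):
    n_p = int((y == 1).sum())
    n_a = int((y == 0).sum())
    if replicate:
        reps = max(1, round(n_a / n_p))
        idx = np.concatenate([np.nonzero(y == 1)[0]] * reps + [np.nonzero(y == 0)[0]])
        est.fit(X[idx], y[idx])
        return est
    w = np.where(y == 1, n_a / n_p, 1.0)
    try:
        if isinstance(est, Pipeline):
            est.fit(X, y, clf__sample_weight=w)
        else:
            est.fit(X, y, sample_weight=w)
    except TypeError:  # estimator surprises us: fall back to replication
        return _balanced_fit(est, X, y, replicate=True)
    return est


def fit_model(
    algorithm: str,
    X: pd.DataFrame,
    y,
    continuous: list[str] | None = None,
    sre_quantile: float = 2.5,
    seed: int = 0,
    fold: int | None = None,
    categorical_levels: dict[str, list] | None = None,
) -> FittedModel:
    """Fit one algorithm on encoded training rows.

    ``X`` holds predictor columns (categoricals already as indicator
    columns); ``continuous`` names the continuous columns (default: all).
    SRE fits its percentile envelope on presence rows of the continuous
    predictors only; the other learners are class-balance weighted.
    """
    algorithm = algorithm.upper()
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; valid: {ALGORITHMS}")
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    feature_names = list(X.columns)
    continuous = list(continuous) if continuous is not None else feature_names

    if algorithm == "SRE":
        if not (0 <= sre_quantile < 50):
            raise ValueError("sre_quantile must be in [0, 50)")
        pres = X.loc[y == 1, continuous].to_numpy(dtype=float)
        lo = np.percentile(pres, sre_quantile, axis=0)
        hi = np.percentile(pres, 100.0 - sre_quantile, axis=0)
        return FittedModel(
            algorithm,
            feature_names,
            continuous,
            envelope=(lo, hi),
            fold=fold,
            categorical_levels=categorical_levels or {},
        )

    est = _make_estimator(algorithm, seed)
    mat = X.to_numpy(dtype=float)
    est = _balanced_fit(clone(est), mat, y, replicate=algorithm in _NEEDS_REPLICATION)
    return FittedModel(
        algorithm,
        feature_names,
        continuous,
        estimator=est,
        fold=fold,
        categorical_levels=categorical_levels or {},
    )


def predict_map(model: FittedModel, stack: EnvStack):
    """Project a fitted model over every unmasked cell of a stack."""
    from .ensemble import SuitabilityMap  # local import to avoid a cycle

    needed = set(model.continuous) | set(model.categorical_levels)
    missing = [n for n in needed if n not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing predictor layer(s): {missing}")
    table = stack.table()
    enc = encode_predictors(table, model.categorical_levels)
    scores = model.score(enc)
    values = np.full(stack.grid.shape, np.nan)
    values[table["row"].to_numpy(), table["col"].to_numpy()] = scores
    return SuitabilityMap(grid=stack.grid, values=values, mask=stack.mask.copy())


def auc(presence_scores, absence_scores) -> float:
    """Mann-Whitney AUC: P(presence score > absence score), ties count 1/2."""
    sp = np.asarray(presence_scores, dtype=float)
    sa = np.asarray(absence_scores, dtype=float)
    if sp.size == 0 or sa.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([sp, sa]))
    r_p = ranks[: sp.size].sum()
    return float((r_p - sp.size * (sp.size + 1) / 2) / (sp.size * sa.size))


def optimize_tss(scores, labels) -> tuple[float, float, float, float]:
    """Maximize TSS over thresholds; returns (tau, tss, sensitivity, specificity).

    Prediction is positive iff score >= tau. Candidate thresholds are the
    midpoints of consecutive distinct scores plus {0, 1}; the smallest
    maximizing tau is returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    cand = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    cand = np.unique(cand)
    pos = scores[:, None] >= cand[None, :]
    n_p = int((labels == 1).sum())
    n_a = int((labels == 0).sum())
    tp = pos[labels == 1].sum(axis=0)
    tn = (~pos[labels == 0]).sum(axis=0)
    sens = tp / n_p
    spec = tn / n_a
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax returns the first (smallest) maximizer
    return float(cand[best]), float(tss[best]), float(sens[best]), float(spec[best])


def evaluate_algorithms(
    algorithms: list[str],
    data: TrainingData,
    continuous: list[str] | None = None,
    sre_quantile: float = 2.5,
    seed: int = 0,
    categorical_levels: dict[str, list] | None = None,
) -> list[ModelEvaluation]:
    """Fit and score every algorithm on every fold.

    Each fold's model trains on the other folds and is evaluated on the
    held-out fold: AUC plus TSS maximized at the fold's own threshold.
    """
    evals: list[ModelEvaluation] = []
    for alg in algorithms:
        for f in range(1, data.k + 1):
            X_tr, y_tr, X_te, y_te = data.split(f)
            model = fit_model(
                alg,
                X_tr,
                y_tr,
                continuous=continuous,
                sre_quantile=sre_quantile,
                seed=seed,
                fold=f,
                categorical_levels=categorical_levels,
            )
            s = model.score(X_te)
            a = auc(s[y_te == 1], s[y_te == 0])
            tau, tss, sens, spec = optimize_tss(s, y_te)
            evals.append(
                ModelEvaluation(
                    algorithm=alg,
                    fold=f,
                    auc=a,
                    tss=tss,
                    threshold=tau,
                    sensitivity=sens,
                    specificity=spec,
                    model=model,
                )
            )
    return evals
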
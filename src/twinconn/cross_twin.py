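"""Cross-twin prediction of G-scores with leave-one-group-out CV (LOGOCV).

The central question: does a model trained on one member of every twin
pair predict the *co-twins'* intelligence?  Each bootstrap iteration
randomly sends one member of every pair to the training group and the
co-twin to the testing group (never both to the same group), screens
edges by univariate F test on the training group only, fits a partial
least squares regression (PLSR) whose component count is chosen by inner
cross-validation, and scores the Pearson correlation between predicted
and observed G-scores in the co-twin group.  Both fold directions
(A-group trains / B-group tests, and vice versa) are fitted; the
iteration's r is their mean, and each direction's selected edge set is
recorded for the downstream consensus analysis.

Significance comes from a full-pipeline permutation null: training
G-scores are shuffled and screening + fitting are rerun, pooling
``perms_per_model`` null draws per iteration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from sklearn.model_selection import KFold

from .cohort import Cohort
from .corrstats import permutation_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "SplitAssignment",
    "PredictiveModel",
    "PredictionResult",
    "split_pairs",
    "select_features_ftest",
    "fit_plsr",
    "predict_and_score",
    "build_model",
    "run_logocv_bootstrap",
]


@dataclass(frozen=True)
class SplitAssignment:
    """One twin-split: row indices of the two disjoint groups."""

    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("a subject appears in both groups")


@dataclass
class PredictiveModel:
    """A fitted screening + PLSR model.

    ``regressor`` is any object with fit/predict (PLSR by default; the
    hook exists so other learners can be plugged in).  A model with no
    selected edges degenerates to predicting the training mean.
    """

    selected_edge_indices: np.ndarray
    component_count: int
    regressor: object
    n_train: int
    train_mean: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.selected_edge_indices.size == 0 or self.regressor is None:
            return np.full(X.shape[0], self.train_mean)
        return np.asarray(
            self.regressor.predict(X[:, self.selected_edge_indices])
        ).ravel()


@dataclass
class PredictionResult:
    """Bootstrap LOGOCV output for one cohort condition."""

    per_iteration_r: np.ndarray
    null_draws: np.ndarray
    selections: list  # per iteration: (dir1 indices, dir2 indices)
    n_pairs: int
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.per_iteration_r))

    @property
    def p_perm(self) -> float:
        return permutation_pvalue(self.mean_r, self.null_draws)

    def as_dict(self) -> dict:
        return {
            "mean_r": self.mean_r,
            "p_perm": self.p_perm,
            "n_iterations": int(self.per_iteration_r.size),
            "n_null_draws": int(self.null_draws.size),
            "n_pairs": self.n_pairs,
            "seed": self.seed,
            "config": self.config,
        }


def split_pairs(
    cohort: Cohort, zygosity: str | None = None, rng_seed: int | np.random.Generator = 0
) -> SplitAssignment:
    """Randomly assign one member of every pair to each group (fair coin)."""
    sub = cohort.subset(zygosity)
    pairs = sub.pair_indices()
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to split")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    coin = rng.integers(0, 2, size=len(pairs))
    rows = np.arange(len(pairs))
    return SplitAssignment(pairs[rows, coin], pairs[rows, 1 - coin])


def _univariate_f(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column F statistic and p-value of the simple regression of y.

    ``F = r^2 (n-2) / (1 - r^2)`` on 1 and n-2 degrees of freedom (the
    statistic behind scikit-learn's f_regression, computed with the
    correlation clipped away from |r| = 1 so perfectly collinear columns
    get a huge finite F instead of a cancellation artefact).  Constant
    columns get F = 0.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    xnorm = np.linalg.norm(Xc, axis=0)
    ynorm = np.linalg.norm(yc)
    ok = (xnorm > 0) & (ynorm > 0)
    r = np.zeros(X.shape[1])
    np.divide(yc @ Xc, xnorm * ynorm, out=r, where=ok)
    r2 = np.clip(r * r, 0.0, 1.0 - 1e-14)
    fvals = r2 * (n - 2) / (1.0 - r2)
    pvals = np.where(ok, stats.f.sf(fvals, 1, n - 2), 1.0)
    return np.where(ok, fvals, 0.0), pvals


def select_features_ftest(
    X: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Edges univariately associated with y at ``p < alpha`` (F test).

    Constant edges get F = 0 and are never selected.
    """
    X = np.asarray(X, float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 training subjects for screening")
    _, pvals = _univariate_f(X, y)
    return np.flatnonzero(pvals < alpha)


def screening_f_statistics(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """The per-edge F statistics used by the screen (exposed for ranking)."""
    return _univariate_f(X, y)[0]


# ---------------------------------------------------------------------------
# PLSR with inner-CV component selection
#
# PLS1 (NIPALS) components are nested: the model with c components is the
# truncation of the model with c_max components.  The grid search therefore
# fits once per inner fold at c_max and evaluates every component count from
# the staged predictions, instead of refitting per grid point.


def _fit_pls(X: np.ndarray, y: np.ndarray, ncomp: int) -> PLSRegression:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PLSRegression(n_components=ncomp).fit(X, y.reshape(-1, 1))


def _staged_predictions(
    pls: PLSRegression,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
) -> np.ndarray:
    """(n_eval, c_max) predictions for every component count 1..c_max."""
    x_mean = X_train.mean(axis=0)
    x_std = X_train.std(axis=0, ddof=1)
    x_std[x_std == 0.0] = 1.0
    y_mean = y_train.mean()
    y_std = y_train.std(ddof=1) or 1.0
    scores = ((X_eval - x_mean) / x_std) @ pls.x_rotations_
    contrib = scores * pls.y_loadings_[0]
    return y_mean + y_std * np.cumsum(contrib, axis=1)


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    component_grid_max: int = 100,
    inner_folds: int = 5,
) -> tuple[PLSRegression, int]:
    """PLSR with the component count chosen by inner k-fold CV.

    The grid 1..``component_grid_max`` is clipped to what the data can
    support (min of training n - 1 and the feature count, warning when
    clipped); the criterion is the mean across inner folds of the Pearson
    correlation between held-out predictions and observations, ties going
    to the fewest components.  Returns the model refit on all rows with
    the chosen count.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, m = X.shape
    if n <= inner_folds:
        raise ValueError(f"need more than inner_folds={inner_folds} rows, have {n}")
    folds = list(KFold(n_splits=inner_folds).split(X))
    min_train = min(len(tr) for tr, _ in folds)
    cmax = min(component_grid_max, m, min_train - 1, n - 1)
    if cmax < component_grid_max:
        warnings.warn(
            f"component grid clipped from {component_grid_max} to {cmax}",
            stacklevel=2,
        )
    if cmax < 1:
        raise ValueError("cannot fit PLSR: no usable components")
    fold_scores = np.full((inner_folds, cmax), -np.inf)
    for f, (tr, te) in enumerate(folds):
        pls = _fit_pls(X[tr], y[tr], cmax)
        preds = _staged_predictions(pls, X[tr], y[tr], X[te])
        yc = y[te] - y[te].mean()
        denom_y = np.linalg.norm(yc)
        pc = preds - preds.mean(axis=0)
        denom_p = np.linalg.norm(pc, axis=0)
        ok = (denom_p > 0) & (denom_y > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rr = (yc @ pc) / (denom_p * denom_y)
        fold_scores[f, ok] = rr[ok]
    mean_scores = fold_scores.mean(axis=0)
    ncomp = int(np.argmax(mean_scores)) + 1  # first max -> fewest components
    return _fit_pls(X, y, ncomp), ncomp


def build_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    alpha_screen: float = 0.05,
    component_grid_max: int = 100,
    inner_folds: int = 5,
) -> PredictiveModel:
    """Screen edges on the training group, then fit PLSR on the survivors."""
    sel = select_features_ftest(X_train, y_train, alpha_screen)
    if sel.size == 0:
        return PredictiveModel(sel, 0, None, len(y_train), float(np.mean(y_train)))
    pls, ncomp = fit_plsr(
        X_train[:, sel], y_train, component_grid_max, inner_folds
    )
    return PredictiveModel(sel, ncomp, pls, len(y_train), float(np.mean(y_train)))


def predict_and_score(
    model: PredictiveModel, X_test: np.ndarray, y_test: np.ndarray
) -> float:
    """Pearson r between predicted and observed test G-scores.

    Zero-variance predictions (e.g. the empty-selection fallback) score 0
    by convention, with a warning.
    """
    preds = model.predict(X_test)
    if np.std(preds) == 0 or np.std(y_test) == 0:
        warnings.warn("zero-variance predictions; scoring r = 0", stacklevel=2)
        return 0.0
    return float(stats.pearsonr(preds, y_test)[0])


def run_logocv_bootstrap(
    cohort: Cohort,
    zygosity: str | None = None,
    B: int = 1000,
    perms_per_model: int = 100,
    alpha_screen: float = 0.05,
    component_grid_max: int = 100,
    inner_folds: int = 5,
    seed: int = 0,
) -> PredictionResult:
    """The twin-split bootstrap: B splits, a model per direction, pooled null.

    For every seeded split, both fold directions are fitted (screening is
    recomputed inside every iteration and every permutation — never on the
    full cohort) and the iteration's r is the mean of the two directions'
    test correlations.  The null pools ``B * perms_per_model`` draws, each
    obtained by shuffling the training G-scores and rerunning the entire
    screen-and-fit pipeline.  Deterministic given ``seed``: iteration
    ``it`` uses its own ``default_rng([seed, it])`` stream.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sub = cohort.subset(zygosity)
    X = sub.edges
    y = sub.g_adjusted
    pairs = sub.pair_indices()
    n_pairs = len(pairs)
    rows = np.arange(n_pairs)

    per_iter_r = np.empty(B)
    null_draws = np.empty(B * perms_per_model)
    selections = []
    for it in range(B):
        rng = np.random.default_rng([seed, it])
        coin = rng.integers(0, 2, size=n_pairs)
        groups = (pairs[rows, coin], pairs[rows, 1 - coin])
        assert np.intersect1d(*groups).size == 0, f"leaky split at iteration {it}"
        try:
            r_dirs, sel_dirs = [], []
            for tr, te in (groups, groups[::-1]):
                model = build_model(
                    X[tr], y[tr], alpha_screen, component_grid_max, inner_folds
                )
                r_dirs.append(predict_and_score(model, X[te], y[te]))
                sel_dirs.append(model.selected_edge_indices)
            per_iter_r[it] = np.mean(r_dirs)
            selections.append(tuple(sel_dirs))
            for j in range(perms_per_model):
                null_dirs = []
                for tr, te in (groups, groups[::-1]):
                    y_perm = rng.permutation(y[tr])
                    null_model = build_model(
                        X[tr], y_perm, alpha_screen, component_grid_max, inner_folds
                    )
                    null_dirs.append(predict_and_score(null_model, X[te], y[te]))
                null_draws[it * perms_per_model + j] = np.mean(null_dirs)
        except Exception as exc:  # annotate with the failing iteration
            raise RuntimeError(f"bootstrap iteration {it} failed: {exc}") from exc
        if (it + 1) % 100 == 0:
            logger.info("bootstrap iteration %d/%d", it + 1, B)

    return PredictionResult(
        per_iter_r,
        null_draws,
        selections,
        n_pairs,
        seed,
        config={
            "zygosity": zygosity,
            "B": B,
            "perms_per_model": perms_per_model,
            "alpha_screen": alpha_screen,
            "component_grid_max": component_grid_max,
            "inner_folds": inner_folds,
            "permutation_scheme": "shuffle training G-scores, refit full pipeline",
        },
    )
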
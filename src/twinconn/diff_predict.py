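"""Predicting within-pair G-score differences from FC differences.

The second analytical leg quantifies twin similarity directly: per pair,
the absolute G-score difference |G_a - G_b| is predicted from the vector
of per-edge absolute FC differences |x_a - x_b|, using k-fold
cross-validation (10 folds by default), within-fold ranking of edges by
the univariate F statistic with the top 400 retained, and the same
inner-CV PLSR as the cross-twin engine.  The evaluation correlates the
pooled out-of-fold predictions with the observed differences (one r per
cohort); significance comes from refitting under shuffled differences.
Network-specific variants restrict the features to one network's
intra-network edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from .atlas import NetworkAtlas, intra_network_edge_indices
from .cohort import Cohort
from .corrstats import permutation_pvalue
from .cross_twin import fit_plsr, screening_f_statistics


@dataclass
class DiffDataset:
    """Per-pair absolute differences: scalar dG, per-edge dFC vector."""

    d_g: np.ndarray
    d_fc: np.ndarray
    pair_ids: np.ndarray
    zygosity: str

    def __post_init__(self) -> None:
        self.d_g = np.asarray(self.d_g, float)
        self.d_fc = np.asarray(self.d_fc, float)
        if (self.d_g < 0).any() or (self.d_fc < 0).any():
            raise ValueError("absolute differences cannot be negative")
        if self.d_fc.shape[0] != self.d_g.size:
            raise ValueError("one dFC row per pair required")

    @property
    def n_pairs(self) -> int:
        return self.d_g.size


@dataclass
class DiffPredictionResult:
    """Pooled k-fold output of one difference model."""

    r: float
    null_draws: np.ndarray
    predictions: np.ndarray
    observed: np.ndarray
    fold_selections: list
    seed: int
    network: str | None = None
    config: dict = field(default_factory=dict)

    @property
    def p_perm(self) -> float:
        return permutation_pvalue(self.r, self.null_draws)

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "p_perm": self.p_perm if self.null_draws.size else None,
            "n_permutations": int(self.null_draws.size),
            "n_pairs": int(self.observed.size),
            "network": self.network,
            "seed": self.seed,
            "config": self.config,
        }


def pair_differences(cohort: Cohort, zygosity: str | None = None) -> DiffDataset:
    """Absolute within-pair differences of adjusted G and of every edge.

    Order-invariant: swapping co-twin order changes nothing.
    """
    sub = cohort.subset(zygosity)
    pairs = sub.pair_indices()
    g = sub.g_adjusted
    d_g = np.abs(g[pairs[:, 0]] - g[pairs[:, 1]])
    d_fc = np.abs(sub.edges[pairs[:, 0]] - sub.edges[pairs[:, 1]])
    pair_ids = sub.roster["pair_id"].to_numpy()[pairs[:, 0]]
    zy = sub.roster["zygosity"].iloc[0] if zygosity is None else zygosity
    return DiffDataset(d_g, d_fc, pair_ids, str(zy))


def _pooled_kfold_r(
    X: np.ndarray,
    y: np.ndarray,
    folds: list,
    top_m: int,
    component_grid_max: int,
    inner_folds: int,
    collect_selections: bool = False,
):
    """Pooled out-of-fold predictions; feature ranking inside folds only."""
    preds = np.empty_like(y)
    selections = []
    for tr, te in folds:
        fvals = screening_f_statistics(X[tr], y[tr])
        m = min(top_m, X.shape[1])
        sel = np.sort(np.argpartition(fvals, -m)[-m:])
        pls, _ = fit_plsr(X[tr][:, sel], y[tr], component_grid_max, inner_folds)
        preds[te] = np.asarray(pls.predict(X[te][:, sel])).ravel()
        if collect_selections:
            selections.append(sel)
    if np.std(preds) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance pooled predictions; r = 0", stacklevel=2)
        r = 0.0
    else:
        r = float(stats.pearsonr(preds, y)[0])
    return r, preds, selections


def run_kfold_diff_prediction(
    diffs: DiffDataset,
    k: int = 10,
    top_m: int = 400,
    n_perm: int = 5000,
    seed: int = 0,
    component_grid_max: int = 100,
    inner_folds: int = 5,
    feature_columns: np.ndarray | None = None,
    network: str | None = None,
) -> DiffPredictionResult:
    """k-fold prediction of dG from dFC with a shuffled-dG permutation null.

    Every pair is predicted exactly once (pooled out-of-fold).  The fold
    assignment and permutations are deterministic given ``seed``; the same
    folds are reused for every permutation so the null isolates the
    dG-to-dFC linkage.
    """
    if k > diffs.n_pairs:
        raise ValueError(f"k={k} exceeds {diffs.n_pairs} pairs")
    X = diffs.d_fc if feature_columns is None else diffs.d_fc[:, feature_columns]
    y = diffs.d_g
    folds = list(
        KFold(n_splits=k, shuffle=True, random_state=seed % (2**31)).split(X)
    )
    r, preds, sels = _pooled_kfold_r(
        X, y, folds, top_m, component_grid_max, inner_folds, True
    )
    rng = np.random.default_rng([seed, 1])
    null = np.empty(n_perm)
    for j in range(n_perm):
        y_perm = rng.permutation(y)
        null[j], _, _ = _pooled_kfold_r(
            X, y_perm, folds, top_m, component_grid_max, inner_folds
        )
    return DiffPredictionResult(
        r, null, preds, y, sels, seed, network,
        config={
            "k": k, "top_m": top_m, "n_perm": n_perm,
            "component_grid_max": component_grid_max,
            "inner_folds": inner_folds,
        },
    )


def network_specific_prediction(
    diffs: DiffDataset,
    atlas: NetworkAtlas,
    network: str,
    k: int = 10,
    top_m: int = 400,
    n_perm: int = 5000,
    seed: int = 0,
    component_grid_max: int = 100,
    inner_folds: int = 5,
) -> DiffPredictionResult:
    """The same difference model restricted to one network's intra-edges.

    With fewer intra-network edges than ``top_m`` the cap is inactive and
    all of the network's edges enter the ranking; otherwise screening is
    identical to the whole-brain model.
    """
    cols = intra_network_edge_indices(atlas, network)
    if cols.size < 1:
        raise ValueError(f"network {network} has no intra-network edges")
    return run_kfold_diff_prediction(
        diffs, k=k, top_m=top_m, n_perm=n_perm, seed=seed,
        component_grid_max=component_grid_max, inner_folds=inner_folds,
        feature_columns=cols, network=network,
    )
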
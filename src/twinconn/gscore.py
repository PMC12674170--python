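"""General-intelligence (G-score) statistics for twin cohorts.

Covers the behavioural leg of the analysis: regressing age and gender out
of the raw G-score, Pearson correlations of adjusted G-scores within
monozygotic (MZ) and dizygotic (DZ) twin pairs, and Falconer's classical
additive-heritability estimate ``h2 = 2 * (r_MZ - r_DZ)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort


@dataclass(frozen=True)
class HeritabilityEstimate:
    r_mz: float
    r_dz: float
    h2: float


def adjust_gscore(
    g_raw: np.ndarray, age: np.ndarray, gender: np.ndarray
) -> np.ndarray:
    """Residualise the raw G-score on age and gender.

    Ordinary least squares of ``g_raw`` on an intercept, age and a binary
    gender indicator; returns the residuals (mean zero).  If gender has a
    single level it is dropped from the design with a warning, since the
    column would make the design rank-deficient.
    """
    g_raw = np.asarray(g_raw, float)
    age = np.asarray(age, float)
    gender = np.asarray(gender, float)
    if not (g_raw.size == age.size == gender.size):
        raise ValueError("g_raw, age and gender must have equal length")
    if g_raw.size < 3:
        raise ValueError("need at least 3 subjects to adjust")
    cols = [age]
    if np.unique(gender).size < 2:
        warnings.warn(
            "gender has a single level; dropping it from the adjustment",
            stacklevel=2,
        )
    else:
        cols.append(gender)
    design = sm.add_constant(np.column_stack(cols), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear age/gender)")
    return np.asarray(sm.OLS(g_raw, design).fit().resid)


def adjust_cohort(cohort: Cohort) -> Cohort:
    """Return a cohort with ``g_adjusted`` filled in from ``g_raw``."""
    adj = adjust_gscore(
        cohort.roster["g_raw"].to_numpy(float),
        cohort.roster["age"].to_numpy(float),
        cohort.roster["gender"].to_numpy(float),
    )
    return cohort.with_adjusted(adj)


def twin_pair_correlation(
    cohort: Cohort, zygosity: str, *, double_entry: bool = False
) -> tuple[float, float]:
    """Pearson correlation of adjusted G-scores across co-twins.

    Member order within a pair follows the roster; because that order is
    arbitrary, ``double_entry=True`` computes the correlation on the
    doubled pairing {(a,b), (b,a)}, which is invariant to member order
    (the conventional intraclass-style treatment in twin research).

    Returns ``(r, p)``.
    """
    sub = cohort.subset(zygosity)
    pairs = sub.pair_indices()
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 {zygosity} pairs, have {len(pairs)}")
    g = sub.g_adjusted
    a, b = g[pairs[:, 0]], g[pairs[:, 1]]
    if double_entry:
        a, b = np.concatenate([a, b]), np.concatenate([b, a])
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def falconer_h2(r_mz: float, r_dz: float) -> HeritabilityEstimate:
    """Falconer's formula ``h2 = 2 * (r_mz - r_dz)``.

    The estimate is reported unclipped; values outside [0, 1] trigger a
    warning (they occur routinely from sampling noise in small cohorts).
    """
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    h2 = 2.0 * (r_mz - r_dz)
    if not 0.0 <= h2 <= 1.0:
        warnings.warn(
            f"Falconer h2={h2:.3f} outside [0, 1]; reporting unclipped",
            stacklevel=2,
        )
    return HeritabilityEstimate(float(r_mz), float(r_dz), float(h2))
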
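"""Comparison of two independent Pearson correlations, and permutation p-values.

Implements the classical Fisher-z machinery for testing whether two
correlations measured in independent groups differ: the z statistic with
standard error ``sqrt(1/(n1-3) + 1/(n2-3))``, Cohen's q effect size
(the difference on the Fisher-z scale), Zou's (2007) confidence interval
for ``r1 - r2`` built from the two back-transformed per-correlation
intervals, and the normal-approximation power of the two-tailed test.

Sample-size convention
----------------------
Pass the n that the correlations were computed over.  In a twin design
this differs by analysis: correlations across individuals use
per-individual counts (e.g. 178 and 100 subjects), correlations across
pairs (difference models) use per-pair counts (e.g. 89 and 50 pairs).
The choice is always an explicit argument here, never inferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CorrComparison:
    """Full comparison of two independent correlations."""

    r1: float
    n1: int
    r2: float
    n2: int
    z_stat: float
    p_two_tailed: float
    q: float
    ci_low: float
    ci_high: float
    power: float
    conf: float = 0.95
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher transformation ``z = atanh(r)``, clamping ``|r| >= 1``."""
    r = np.asarray(r, float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|r| >= 1 clamped to 1 - 1e-12 before atanh", stacklevel=2)
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _check_n(n1: int, n2: int) -> None:
    if n1 <= 3 or n2 <= 3:
        raise ValueError(f"sample sizes must exceed 3, got n1={n1}, n2={n2}")


def compare_independent_correlations(
    r1: float, n1: int, r2: float, n2: int,
    *, conf: float = 0.95, alpha: float = 0.05,
) -> CorrComparison:
    """Two-tailed Fisher z test of ``r1`` (group of ``n1``) vs ``r2``.

    Returns the z statistic, its two-tailed normal p-value, Cohen's
    ``q = atanh(r1) - atanh(r2)``, Zou's ``conf``-level interval for
    ``r1 - r2`` and the power of the ``alpha``-level test at effect q.
    """
    _check_n(n1, n2)
    q = float(fisher_z(r1) - fisher_z(r2))
    se = float(np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3)))
    z_stat = q / se
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    lo, hi = zou_ci(r1, n1, r2, n2, conf=conf)
    pw = power_two_correlations(q, n1, n2, alpha=alpha)
    return CorrComparison(
        float(r1), int(n1), float(r2), int(n2),
        float(z_stat), p, q, lo, hi, pw, conf, alpha,
    )


def zou_ci(
    r1: float, n1: int, r2: float, n2: int, *, conf: float = 0.95
) -> tuple[float, float]:
    """Zou's (2007) confidence interval for the difference ``r1 - r2``.

    Each correlation gets a Fisher-z interval back-transformed by tanh,
    ``(l_k, u_k)``; the bounds for the difference are then

    ``L = r1 - r2 - sqrt((r1 - l1)^2 + (u2 - r2)^2)``
    ``U = r1 - r2 + sqrt((u1 - r1)^2 + (r2 - l2)^2)``.
    """
    _check_n(n1, n2)
    if not 0.0 < conf < 1.0:
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    zc = stats.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    l1, u1 = np.tanh(fisher_z(r1) + np.array([-zc, zc]) / np.sqrt(n1 - 3))
    l2, u2 = np.tanh(fisher_z(r2) + np.array([-zc, zc]) / np.sqrt(n2 - 3))
    d = r1 - r2
    low = d - np.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2)
    high = d + np.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2)
    return float(low), float(high)


def power_two_correlations(
    q: float, n1: int, n2: int, *, alpha: float = 0.05
) -> float:
    """Approximate power to detect a correlation difference of effect ``q``.

    Normal approximation for the two-tailed Fisher z test:
    ``z_eff = q / sqrt(1/(n1-3) + 1/(n2-3))`` and
    ``power = Phi(z_eff - z_{alpha/2}) + Phi(-z_eff - z_{alpha/2})``.
    At q = 0 this reduces to the test size alpha.
    """
    _check_n(n1, n2)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_eff = q / se
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(z_eff - z_a) + stats.norm.cdf(-z_eff - z_a))


def permutation_pvalue(observed: float, null_draws: np.ndarray) -> float:
    """One-sided permutation p-value with the add-one convention.

    ``p = (1 + #{null >= observed}) / (1 + N)`` for a larger-is-better
    statistic; the add-one term counts the observed value as one member of
    the permutation distribution, so p can never be exactly zero.
    """
    null_draws = np.asarray(null_draws, float)
    if null_draws.size == 0:
        raise ValueError("empty null distribution")
    c = int(np.sum(null_draws >= observed))
    return (1 + c) / (1 + null_draws.size)
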
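"""Co-twin identification from connectivity profiles (fingerprinting).

For each individual, the candidate with the highest Pearson correlation
between (optionally edge-masked) connectivity vectors among all other
individuals of the same zygosity cohort is taken as the predicted
co-twin; identification accuracy is the percentage of individuals whose
top match is their true co-twin.  Run symmetrically for both members of
every pair, each attempt counting once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort


@dataclass
class IdentificationResult:
    matches: pd.DataFrame  # subject_id, true_cotwin, predicted, correct
    accuracy: float        # percent
    edge_mask: np.ndarray | None

    def as_dict(self) -> dict:
        return {
            "accuracy_percent": self.accuracy,
            "n_attempted": int(len(self.matches)),
            "n_correct": int(self.matches["correct"].sum()),
            "masked_edges": (
                int(self.edge_mask.size) if self.edge_mask is not None else "all"
            ),
        }


def _correlation_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-by-row Pearson correlations; flags zero-variance rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    ok = norms > 0
    Z = np.zeros_like(Xc)
    Z[ok] = Xc[ok] / norms[ok, None]
    return Z @ Z.T, ok


def _masked(cohort: Cohort, edge_mask: np.ndarray | None) -> np.ndarray:
    if edge_mask is None:
        return cohort.edges
    mask = np.asarray(edge_mask, int)
    if mask.size < 2:
        raise ValueError("edge mask needs at least 2 edges for a correlation")
    return cohort.edges[:, mask]


def identify_cotwin(
    subject_id: str,
    cohort: Cohort,
    edge_mask: np.ndarray | None = None,
    zygosity: str | None = None,
) -> str:
    """Predicted co-twin: the other individual most correlated with subject.

    Zero-variance masked vectors are excluded from candidacy with a
    warning; exact-tie candidates resolve to the lowest subject id.
    """
    sub = cohort.subset(zygosity)
    ids = sub.roster["subject_id"].to_numpy()
    where = np.flatnonzero(ids == subject_id)
    if where.size != 1:
        raise KeyError(f"subject {subject_id!r} not in cohort")
    corr, ok = _correlation_matrix(_masked(sub, edge_mask))
    return _best_match(int(where[0]), corr, ok, ids)


def _best_match(
    row: int, corr: np.ndarray, ok: np.ndarray, ids: np.ndarray
) -> str:
    if not ok[row]:
        raise ValueError(f"subject {ids[row]!r} has a zero-variance edge vector")
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} zero-variance candidate(s) excluded", stacklevel=2
        )
    scores = corr[row].copy()
    scores[row] = -np.inf
    scores[~ok] = -np.inf
    if np.isfinite(scores).sum() < 2:
        raise ValueError("need at least 2 candidates in the pool")
    best = scores.max()
    contenders = np.flatnonzero(scores == best)
    return str(min(ids[contenders]))


def identification_accuracy(
    cohort: Cohort,
    zygosity: str | None = None,
    edge_mask: np.ndarray | None = None,
) -> IdentificationResult:
    """Percent of individuals whose top match is the true co-twin."""
    sub = cohort.subset(zygosity)
    ids = sub.roster["subject_id"].to_numpy()
    pair_of = {}
    for a, b in sub.pair_indices():
        pair_of[ids[a]], pair_of[ids[b]] = ids[b], ids[a]
    corr, ok = _correlation_matrix(_masked(sub, edge_mask))
    records = []
    for row, sid in enumerate(ids):
        predicted = _best_match(row, corr, ok, ids)
        records.append(
            {
                "subject_id": sid,
                "true_cotwin": pair_of[sid],
                "predicted": predicted,
                "correct": predicted == pair_of[sid],
            }
        )
    matches = pd.DataFrame(records)
    accuracy = 100.0 * matches["correct"].mean()
    return IdentificationResult(matches, float(accuracy), edge_mask)
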
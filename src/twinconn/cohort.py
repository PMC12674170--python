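"""Twin-cohort container: roster plus per-subject edge vectors.

A cohort couples a roster table (subject id, pair id, zygosity, age,
gender, raw and adjusted general-intelligence scores) with the stacked
edge-vector matrix, one row per subject, aligned with the roster rows.
Twin structure is strict: every pair id occurs exactly twice and both
members share zygosity (same-sex pairs; gender is a single binary
indicator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fc import node_count_from_edges

ROSTER_COLUMNS = ["subject_id", "pair_id", "zygosity", "age", "gender", "g_raw"]


@dataclass
class Cohort:
    """Roster + aligned edge-vector matrix.

    Parameters
    ----------
    roster : pandas.DataFrame
        Columns ``subject_id, pair_id, zygosity, age, gender, g_raw`` and
        optionally ``g_adjusted``; one row per subject.
    edges : numpy.ndarray, shape (n_subjects, n_edges)
        Row ``s`` is subject ``s``'s Fisher-z edge vector.
    """

    roster: pd.DataFrame
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.roster = self.roster.reset_index(drop=True)
        missing = [c for c in ROSTER_COLUMNS if c not in self.roster.columns]
        if missing:
            raise ValueError(f"roster missing columns {missing}")
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 2 or self.edges.shape[0] != len(self.roster):
            raise ValueError(
                f"edges shape {self.edges.shape} does not match "
                f"{len(self.roster)} roster rows"
            )
        node_count_from_edges(self.edges.shape[1])  # validates triangularity
        counts = self.roster["pair_id"].value_counts()
        if not (counts == 2).all():
            bad = counts[counts != 2].index.tolist()
            raise ValueError(f"pair ids must occur exactly twice; bad: {bad}")
        zy_per_pair = self.roster.groupby("pair_id")["zygosity"].nunique()
        if not (zy_per_pair == 1).all():
            raise ValueError("co-twins must share zygosity")
        bad_zy = set(self.roster["zygosity"]) - {"MZ", "DZ"}
        if bad_zy:
            raise ValueError(f"zygosity must be MZ or DZ, got {sorted(bad_zy)}")

    # -- basic shape -------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.roster)

    @property
    def n_pairs(self) -> int:
        return self.n_subjects // 2

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    @property
    def node_count(self) -> int:
        return node_count_from_edges(self.n_edges)

    @property
    def g_adjusted(self) -> np.ndarray:
        if "g_adjusted" not in self.roster.columns:
            raise ValueError("cohort has no adjusted G-scores yet")
        return self.roster["g_adjusted"].to_numpy(float)

    # -- twin structure ----------------------------------------------------
    def subset(self, zygosity: str | None) -> "Cohort":
        """Rows of one zygosity (``None`` returns self)."""
        if zygosity is None:
            return self
        mask = (self.roster["zygosity"] == zygosity).to_numpy()
        if not mask.any():
            raise ValueError(f"no {zygosity} pairs in cohort")
        return Cohort(self.roster.loc[mask], self.edges[mask])

    def pair_indices(self) -> np.ndarray:
        """(n_pairs, 2) row indices of co-twins, members in roster order."""
        out = []
        for _, idx in self.roster.groupby("pair_id", sort=True).groups.items():
            a, b = sorted(idx)
            out.append((a, b))
        return np.array(sorted(out), dtype=int)

    def with_adjusted(self, g_adjusted: np.ndarray) -> "Cohort":
        roster = self.roster.copy()
        roster["g_adjusted"] = np.asarray(g_adjusted, float)
        return replace(self, roster=roster)

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write ``roster.csv`` and ``edges.tsv`` into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.roster.to_csv(directory / "roster.csv", index=False)
        edges = pd.DataFrame(
            self.edges, index=self.roster["subject_id"].to_numpy()
        )
        edges.index.name = "subject_id"
        edges.to_csv(directory / "edges.tsv", sep="\t")

    @classmethod
    def load(cls, directory: str | Path) -> "Cohort":
        directory = Path(directory)
        roster = pd.read_csv(directory / "roster.csv")
        edges = pd.read_csv(directory / "edges.tsv", sep="\t", index_col=0)
        edges = edges.loc[roster["subject_id"].to_numpy()]
        return cls(roster, edges.to_numpy(float))


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read a cohort roster table from delimited text (sniffed separator)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"roster {path} missing columns {missing}")
    return df


def save_ground_truth(path: str | Path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(
            {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in truth.items()},
            fh, indent=2,
        )
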
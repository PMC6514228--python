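"""Person-by-item ordinal response matrices.

Responses are 5-category Likert scores. Files use the 1-5 coding of the
source questionnaires; in memory every score is 0-4 (the coding used by the
likelihood machinery). Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix", "read_response_matrix", "write_response_matrix"]

#: Covariate columns recognized in response CSV files (besides diagnosis_*).
KNOWN_COVARIATES = ("gender", "age_group", "region")


@dataclass
class ResponseMatrix:
    """Ordinal scores for ``n_persons x n_items`` plus optional covariates.

    Attributes
    ----------
    item_ids : tuple of str
        Column identity of ``scores``.
    scores : ndarray of int, shape (n_persons, n_items)
        Internal 0-4 coding.
    covariates : DataFrame
        One row per person; may include two-level group codes
        (``gender``, ``age_group``, ``region``) and ``diagnosis_*`` labels.
    """

    item_ids: tuple[str, ...]
    scores: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    person_ids: tuple | None = None

    def __post_init__(self) -> None:
        self.item_ids = tuple(self.item_ids)
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.item_ids):
            raise ValueError(
                f"scores shape {self.scores.shape} inconsistent with "
                f"{len(self.item_ids)} item_ids"
            )
        if np.issubdtype(self.scores.dtype, np.floating) and np.isnan(self.scores).any():
            raise ValueError("missing responses are not supported")
        self.scores = self.scores.astype(np.int64)
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 4):
            raise ValueError("internal scores must lie in 0..4")
        if self.person_ids is None:
            self.person_ids = tuple(range(self.n_persons))
        if len(self.covariates) not in (0, self.n_persons):
            raise ValueError("covariates must have one row per person")

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def scores_1based(self) -> np.ndarray:
        """Scores in the 1-5 file coding."""
        return self.scores + 1

    def column(self, item_id: str) -> np.ndarray:
        try:
            j = self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"item {item_id!r} not in response matrix") from None
        return self.scores[:, j]

    def subset_items(self, item_ids: Iterable[str]) -> "ResponseMatrix":
        ids = list(item_ids)
        idx = [self.item_ids.index(i) for i in ids]
        return ResponseMatrix(
            tuple(ids), self.scores[:, idx], self.covariates.copy(), self.person_ids
        )

    def group_codes(self, name: str) -> np.ndarray:
        """Two-level 0/1 codes for a covariate column."""
        if name not in self.covariates.columns:
            raise KeyError(f"covariate {name!r} not present")
        col = self.covariates[name].to_numpy()
        levels = np.unique(col)
        if len(levels) != 2:
            raise ValueError(f"covariate {name!r} has {len(levels)} level(s), need 2")
        return (col == levels[1]).astype(int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"person_id": list(self.person_ids)})
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        for j, item in enumerate(self.item_ids):
            df[item] = self.scores[:, j] + 1
        return df


def _matrix_from_frame(df: pd.DataFrame, item_ids: Sequence[str] | None = None) -> ResponseMatrix:
    cov_cols = [
        c
        for c in df.columns
        if c in KNOWN_COVARIATES or c.startswith("diagnosis_")
    ]
    if item_ids is None:
        item_ids = [
            c for c in df.columns if c not in cov_cols and c != "person_id"
        ]
    raw = df[list(item_ids)].to_numpy()
    if np.isnan(raw.astype(float)).any():
        raise ValueError("missing responses are not supported")
    raw = raw.astype(np.int64)
    if raw.size and (raw.min() < 1 or raw.max() > 5):
        raise ValueError("file scores must lie in 1..5")
    persons = tuple(df["person_id"]) if "person_id" in df.columns else None
    return ResponseMatrix(tuple(item_ids), raw - 1, df[cov_cols].reset_index(drop=True), persons)


def read_response_matrix(path: str | Path, item_ids: Sequence[str] | None = None) -> ResponseMatrix:
    """Read a response CSV (person_id, covariates, item columns scored 1-5)."""
    return _matrix_from_frame(pd.read_csv(path), item_ids)


def write_response_matrix(matrix: ResponseMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index=False)
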
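"""Panel containers: subject x occasion tables of item responses or scores.

Both panels wrap a wide-format :class:`pandas.DataFrame` with the index
columns ``subject_id``, ``group`` (CA+/CA-) and ``occasion`` (t1/t2), one
row per subject-occasion. The complete-case contract is enforced at
construction: every subject appears at both occasions exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError

GROUPS = ("CA+", "CA-")
OCCASIONS = ("t1", "t2")
ID_COLUMNS = ["subject_id", "group", "occasion"]


@dataclass
class ItemMeta:
    """Metadata for one ordinal item."""

    scale: str
    n_categories: int
    reverse: bool = False


def _validate_ids(data: pd.DataFrame) -> None:
    for col in ID_COLUMNS:
        if col not in data.columns:
            raise DomainError(f"panel is missing required column {col!r}")
    bad_group = set(data["group"]) - set(GROUPS)
    if bad_group:
        raise DomainError(f"unknown group labels: {sorted(bad_group)}")
    bad_occ = set(data["occasion"]) - set(OCCASIONS)
    if bad_occ:
        raise DomainError(f"unknown occasion labels: {sorted(bad_occ)}")
    dup = data.duplicated(subset=["subject_id", "occasion"])
    if dup.any():
        key = data.loc[dup, ["subject_id", "occasion"]].iloc[0]
        raise DomainError(
            f"duplicate (subject, occasion) pair: ({key['subject_id']!r}, {key['occasion']!r})"
        )
    counts = data.groupby("subject_id", sort=False)["occasion"].nunique()
    incomplete = counts[counts != len(OCCASIONS)]
    if len(incomplete):
        raise DomainError(
            f"complete-case contract violated: subject {incomplete.index[0]!r} "
            f"has {int(incomplete.iloc[0])} occasion(s), expected {len(OCCASIONS)}"
        )


@dataclass
class ItemPanel:
    """Ordinal item responses per subject and occasion.

    ``data`` holds integer category codes in ``0..K-1`` where ``K`` is the
    per-item category count declared in ``item_meta``.
    """

    data: pd.DataFrame
    item_meta: dict[str, ItemMeta]

    def __post_init__(self) -> None:
        _validate_ids(self.data)
        missing = [c for c in self.item_meta if c not in self.data.columns]
        if missing:
            raise DomainError(f"items declared but absent from data: {missing}")
        for item, meta in self.item_meta.items():
            col = self.data[item]
            if col.isna().any():
                raise DomainError(f"missing values in item {item!r} (imputation is out of scope)")
            arr = col.to_numpy()
            if not np.all(arr == arr.astype(int)):
                raise DomainError(f"non-integer codes in item {item!r}")
            if arr.min() < 0 or arr.max() > meta.n_categories - 1:
                row = int(np.argmax((arr < 0) | (arr > meta.n_categories - 1)))
                raise DomainError(
                    f"out-of-range code in item {item!r} at row {row}: "
                    f"{arr[row]} not in 0..{meta.n_categories - 1}"
                )

    @property
    def items(self) -> list[str]:
        return list(self.item_meta)

    @property
    def scales(self) -> dict[str, list[str]]:
        """Mapping scale name -> ordered item list."""
        out: dict[str, list[str]] = {}
        for item, meta in self.item_meta.items():
            out.setdefault(meta.scale, []).append(item)
        return out

    def slice(self, group: str | None = None, occasion: str | None = None) -> pd.DataFrame:
        mask = pd.Series(True, index=self.data.index)
        if group is not None:
            mask &= self.data["group"] == group
        if occasion is not None:
            mask &= self.data["occasion"] == occasion
        return self.data[mask]


@dataclass
class ScorePanel:
    """Factor-score panel: continuous standardized scores plus binary nodes.

    ``binary_columns`` are coded 0/1 with 1 = protective (e.g. low
    aggression); continuous columns must be finite.
    """

    data: pd.DataFrame
    score_columns: list[str]
    binary_columns: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        _validate_ids(self.data)
        missing = [c for c in self.score_columns if c not in self.data.columns]
        if missing:
            raise DomainError(f"score columns absent from data: {missing}")
        unknown_binary = self.binary_columns - set(self.score_columns)
        if unknown_binary:
            raise DomainError(f"binary columns not among scores: {sorted(unknown_binary)}")
        for col in self.score_columns:
            arr = self.data[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(arr)):
                raise DomainError(f"non-finite values in score column {col!r}")
            if col in self.binary_columns and not np.isin(arr, (0.0, 1.0)).all():
                raise DomainError(f"binary column {col!r} contains values outside {{0, 1}}")

    @property
    def nodes(self) -> list[str]:
        return list(self.score_columns)

    def slice(self, group: str | None = None, occasion: str | None = None) -> pd.DataFrame:
        """Rows for one group/occasion cell, ordered by subject_id."""
        return self._slice_frame(group, occasion)

    def matrix(self, group: str | None = None, occasion: str | None = None) -> np.ndarray:
        """Score matrix (subjects x nodes) for one group/occasion slice,
        rows ordered by subject_id for reproducibility."""
        sl = self._slice_frame(group, occasion)
        return sl[self.score_columns].to_numpy(dtype=float)

    def subjects(self, group: str | None = None, occasion: str | None = None) -> np.ndarray:
        return self._slice_frame(group, occasion)["subject_id"].to_numpy()

    def _slice_frame(self, group: str | None, occasion: str | None) -> pd.DataFrame:
        mask = pd.Series(True, index=self.data.index)
        if group is not None:
            mask &= self.data["group"] == group
        if occasion is not None:
            mask &= self.data["occasion"] == occasion
        return self.data[mask].sort_values("subject_id", kind="stable")

    def paired_matrices(self, group: str | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Occasion-1 and occasion-2 score matrices with rows matched by
        subject_id; returns (X_t1, X_t2, subject_ids)."""
        a = self._slice_frame(group, OCCASIONS[0])
        b = self._slice_frame(group, OCCASIONS[1])
        ids_a = a["subject_id"].to_numpy()
        ids_b = b["subject_id"].to_numpy()
        if len(ids_a) != len(ids_b) or not np.array_equal(ids_a, ids_b):
            raise DomainError("occasions are not matched by subject_id")
        return (
            a[self.score_columns].to_numpy(dtype=float),
            b[self.score_columns].to_numpy(dtype=float),
            ids_a,
        )
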
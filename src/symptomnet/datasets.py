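"""Questionnaire datasets: loading, binarization, descriptive statistics.

The pipeline starts from a person x item table of Likert responses
(integers 1-5).  Incomplete rows are removed listwise at load time, the
way incomplete questionnaires are excluded in survey practice; there is
no imputation.  Responses are then dichotomized with the symptom-presence
rule: a score of 1 ("almost never") codes to 0 (absent), scores 2-5 code
to 1 (present).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class LikertParseError(ValueError):
    """A cell could not be parsed as an integer response."""


class LikertRangeError(ValueError):
    """A response lies outside the documented scale bounds."""


class CommunityMapError(KeyError):
    """The community map names an unknown item or misses one."""


@dataclass
class LikertDataset:
    """Person x item matrix of integer Likert responses with item metadata."""

    values: np.ndarray
    item_labels: list[str]
    community: dict[str, str] = field(default_factory=dict)
    scale: tuple[int, int] = (1, 5)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        self.item_labels = list(self.item_labels)
        lo, hi = self.scale
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D person x item matrix")
        if self.values.shape[1] != len(self.item_labels):
            raise ValueError("item_labels length must match the number of columns")
        if len(set(self.item_labels)) != len(self.item_labels):
            raise ValueError("item labels must be unique")
        if self.values.size and (self.values.min() < lo or self.values.max() > hi):
            raise LikertRangeError(
                f"responses must lie in [{lo}, {hi}]; "
                f"found range [{self.values.min()}, {self.values.max()}]"
            )
        _check_community(self.community, self.item_labels)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryDataset:
    """Person x item matrix in {0, 1} after the presence/absence coding."""

    values: np.ndarray
    item_labels: list[str]
    community: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        self.item_labels = list(self.item_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D person x item matrix")
        if self.values.shape[1] != len(self.item_labels):
            raise ValueError("item_labels length must match the number of columns")
        if len(set(self.item_labels)) != len(self.item_labels):
            raise ValueError("item labels must be unique")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary values must be 0 or 1")
        _check_community(self.community, self.item_labels)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.item_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown item label: {label!r}") from None
        return self.values[:, j]


def _check_community(community: dict[str, str], labels: list[str]) -> None:
    if not community:
        return
    known = set(labels)
    unknown = [k for k in community if k not in known]
    if unknown:
        raise CommunityMapError(f"community map names unknown items: {unknown}")


@dataclass
class LoadReport:
    rows_read: int
    rows_dropped: int


def load_likert_csv(
    path,
    label_row: bool = True,
    community_map: dict[str, str] | None = None,
    scale: tuple[int, int] = (1, 5),
) -> tuple[LikertDataset, LoadReport]:
    """Read a delimited person x item table of Likert responses.

    Rows with any missing cell are dropped listwise and counted in the
    returned :class:`LoadReport`.  Non-integer cells are an error (they
    indicate a corrupt file, not a skipped question); values outside
    ``scale`` are an error, never clamped.

    Returns
    -------
    (LikertDataset, LoadReport)
        The dataset (column order preserved) and the row accounting.
    """
    raw = pd.read_csv(
        path,
        header=0 if label_row else None,
        dtype=str,
        skipinitialspace=True,
        keep_default_na=False,
    )
    if label_row:
        labels = [str(c) for c in raw.columns]
    else:
        labels = [f"item{j + 1}" for j in range(raw.shape[1])]

    rows_read = raw.shape[0]
    cells = raw.to_numpy()
    missing = np.zeros(rows_read, dtype=bool)
    parsed = np.zeros_like(cells, dtype=int)
    na_tokens = {"", "na", "nan", "n/a", "."}
    for i in range(rows_read):
        for j in range(cells.shape[1]):
            s = str(cells[i, j]).strip()
            if s.lower() in na_tokens:
                missing[i] = True
                continue
            try:
                v = int(s)
            except ValueError:
                raise LikertParseError(
                    f"row {i + 1}, column {labels[j]!r}: non-integer cell {s!r}"
                ) from None
            parsed[i, j] = v

    keep = ~missing
    values = parsed[keep]
    lo, hi = scale
    if values.size:
        bad = (values < lo) | (values > hi)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise LikertRangeError(
                f"row {np.flatnonzero(keep)[i] + 1}, column {labels[j]!r}: "
                f"value {values[i, j]} outside [{lo}, {hi}]"
            )

    dataset = LikertDataset(
        values=values,
        item_labels=labels,
        community=dict(community_map or {}),
        scale=scale,
    )
    return dataset, LoadReport(rows_read=rows_read, rows_dropped=int(missing.sum()))


def binarize_likert(data: LikertDataset) -> BinaryDataset:
    """Dichotomize responses: scale minimum -> 0 (absent), anything above -> 1."""
    lo = data.scale[0]
    return BinaryDataset(
        values=(data.values > lo).astype(int),
        item_labels=list(data.item_labels),
        community=dict(data.community),
    )


def item_descriptives(likert: LikertDataset, binary: BinaryDataset) -> pd.DataFrame:
    """Per-item mean and sample SD of the Likert scores plus endorsement rate.

    Endorsement is the proportion coded present (1) after binarization.
    Sample SD uses denominator n - 1.
    """
    if likert.item_labels != binary.item_labels:
        raise ValueError("Likert and binary datasets must share item labels")
    if likert.values.shape != binary.values.shape:
        raise ValueError("Likert and binary datasets must share shape")
    n = likert.n_persons
    sd = likert.values.std(axis=0, ddof=1) if n > 1 else np.zeros(likert.n_items)
    return pd.DataFrame(
        {
            "M": likert.values.mean(axis=0),
            "SD": sd,
            "endorsement": binary.values.mean(axis=0),
        },
        index=pd.Index(likert.item_labels, name="Item"),
    )
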
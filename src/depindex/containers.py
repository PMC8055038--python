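"""Shared in-memory containers for the deprivation-index pipeline.

The central object is :class:`ItemResponseMatrix`: an N x J table of
dichotomous (0/1) deprivation indicators with an explicit missing mask and a
province label per participant. All pipeline stages consume and produce this
container, keeping person ids, province labels and item responses aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ItemResponseMatrix", "ExclusionReport"]


@dataclass
class ItemResponseMatrix:
    """Binary item responses with missingness and province labels.

    Parameters
    ----------
    responses : pandas.DataFrame
        N x J float frame with values in {0.0, 1.0, NaN}; NaN marks missing.
        Columns are item labels; the index holds participant ids.
    province : pandas.Series
        Province label per row, aligned with ``responses.index``.
    """

    responses: pd.DataFrame
    province: pd.Series

    def __post_init__(self) -> None:
        if not self.responses.index.equals(self.province.index):
            self.province = self.province.reindex(self.responses.index)
        if self.province.isna().any():
            raise ValueError("every row needs a province label")
        vals = self.responses.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            bad = self.responses.columns[np.where(~ok)[1][0]]
            raise ValueError(f"non-binary value in item column {bad!r}")

    # -- basic geometry -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def items(self) -> list[str]:
        return list(self.responses.columns)

    @property
    def provinces(self) -> list[str]:
        """Province labels in order of first appearance."""
        return list(dict.fromkeys(self.province))

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.responses.isna()

    def province_index(self, order: list[str] | None = None) -> np.ndarray:
        """Integer province code per row (0..K-1)."""
        order = order if order is not None else self.provinces
        codes = {p: k for k, p in enumerate(order)}
        return self.province.map(codes).to_numpy(dtype=int)

    def select_items(self, items: list[str]) -> "ItemResponseMatrix":
        missing = [c for c in items if c not in self.responses.columns]
        if missing:
            raise KeyError(f"unknown items: {missing}")
        return ItemResponseMatrix(self.responses[items].copy(), self.province.copy())

    def to_frame(self, outcome: pd.Series | None = None) -> pd.DataFrame:
        """Flatten to the CSV export layout (id, province, items[, outcome])."""
        out = pd.DataFrame({"id": self.responses.index, "province": self.province.values})
        for c in self.responses.columns:
            out[c] = self.responses[c].values
        if outcome is not None:
            out["outcome"] = np.asarray(outcome)
        return out


@dataclass
class ExclusionReport:
    """Bookkeeping for row exclusions (province filter, complete cases)."""

    n_input: int
    n_after_province_filter: int
    n_complete: int
    excluded_provinces: list[tuple[str, int]] = field(default_factory=list)
    per_item_missing: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.n_complete <= self.n_after_province_filter <= self.n_input):
            raise ValueError("exclusion counts must be non-increasing")

    @property
    def n_excluded_by_province(self) -> int:
        return self.n_input - self.n_after_province_filter
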
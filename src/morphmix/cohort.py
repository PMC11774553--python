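"""Cohort selection: demographic range filters, histograms, icicle levels.

Data logic behind interactive source selection — choose which segments to
replace and which source images to draw replacements from, narrowing the
source pool by successive demographic filters (e.g. restrict sources to
patients within the target's age band to control for age effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import SegmentSubset

__all__ = [
    "RangeFilter",
    "CategoryFilter",
    "SelectionState",
    "apply_filters",
    "icicle_levels",
    "histogram",
    "page_window",
]


@dataclass(frozen=True)
class RangeFilter:
    """Inclusive numeric range filter on one demographic variable."""

    variable: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(
                f"invalid range for {self.variable!r}: low {self.low} > high {self.high}"
            )

    def matches(self, values: pd.Series) -> pd.Series:
        # missing values fail the filter (conservative cohort definition)
        v = pd.to_numeric(values, errors="coerce")
        return v.ge(self.low) & v.le(self.high)

    def label(self) -> str:
        return f"{self.variable} ∈ [{self.low:g}, {self.high:g}]"


@dataclass(frozen=True)
class CategoryFilter:
    """Value-set membership filter for categorical variables."""

    variable: str
    values: Tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(self.values))
        if not self.values:
            raise ValueError(f"empty category set for {self.variable!r}")

    def matches(self, values: pd.Series) -> pd.Series:
        return values.isin(self.values) & values.notna()

    def label(self) -> str:
        return f"{self.variable} ∈ {{{', '.join(map(str, self.values))}}}"


Filter = Union[RangeFilter, CategoryFilter]


def _id_series(demographics: pd.DataFrame) -> pd.Series:
    if "id" not in demographics.columns:
        raise ValueError("demographics table must contain an 'id' column")
    return demographics["id"].astype(str)


def _check_variable(demographics: pd.DataFrame, variable: str) -> None:
    if variable not in demographics.columns:
        raise KeyError(f"unknown demographic variable {variable!r}")


def apply_filters(
    demographics: pd.DataFrame, filters: Sequence[Filter]
) -> List[str]:
    """Ids surviving every filter (conjunction), in original row order.

    Rows with a missing value for a filtered variable are excluded.  The
    final id set is order-independent in the filters; with no filters all
    ids are returned.
    """
    keep = pd.Series(True, index=demographics.index)
    for f in filters:
        _check_variable(demographics, f.variable)
        keep &= f.matches(demographics[f.variable])
    return _id_series(demographics)[keep].tolist()


def icicle_levels(
    demographics: pd.DataFrame, filters: Sequence[Filter]
) -> List[Tuple[str, int]]:
    """Cohort size after each successive filter, for an icicle-style display.

    Level 0 is the full cohort; level i the size after the first i filters.
    Sizes are non-increasing by construction.
    """
    levels = [("all", len(demographics))]
    keep = pd.Series(True, index=demographics.index)
    for f in filters:
        _check_variable(demographics, f.variable)
        keep &= f.matches(demographics[f.variable])
        levels.append((f.label(), int(keep.sum())))
    return levels


def histogram(
    demographics: pd.DataFrame, variable: str, n_bins: int = 20
) -> Tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of a numeric variable over [min, max].

    Returns ``(edges, counts)``; counts sum to the number of non-missing
    values.  A constant variable occupies a single bin.
    """
    _check_variable(demographics, variable)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = pd.to_numeric(demographics[variable], errors="raise").dropna().to_numpy(float)
    if values.size == 0:
        return np.array([0.0, 1.0]), np.zeros(1, dtype=int)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return np.array([lo, hi]), np.array([values.size])
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return edges, counts


def page_window(ids: Sequence[str], start: int, window: int = 50) -> List[str]:
    """A display page of ids: ``ids[start : start+window]``, shorter at the tail.

    The default window of 50 bounds how many images a tiled display renders
    at once.
    """
    if start < 0:
        raise ValueError("start index must be non-negative")
    if start > len(ids):
        raise ValueError(f"start {start} beyond end of id list ({len(ids)})")
    return list(ids[start : start + window])


@dataclass
class SelectionState:
    """A selection of segments to replace plus a filtered source pool.

    ``segments`` exposes the chosen segment codes and ``subset`` the ids
    surviving the filter chain — the two handles downstream recombination
    needs.
    """

    segment_subset: SegmentSubset
    filters: Tuple[Filter, ...] = ()
    demographics: Optional[pd.DataFrame] = None
    _selected_ids: Optional[List[str]] = field(default=None, repr=False)

    @property
    def segments(self) -> Tuple[int, ...]:
        return self.segment_subset.codes

    @property
    def subset(self) -> List[str]:
        if self._selected_ids is not None:
            return list(self._selected_ids)
        if self.demographics is None:
            raise ValueError("no demographics table attached to selection")
        return apply_filters(self.demographics, self.filters)

    def select(self, ids: Sequence[str]) -> "SelectionState":
        """Pin an explicit id selection (must survive the filter chain)."""
        if self.demographics is not None:
            surviving = set(apply_filters(self.demographics, self.filters))
            stray = [i for i in ids if i not in surviving]
            if stray:
                raise ValueError(f"ids not in filtered cohort: {stray}")
        self._selected_ids = list(ids)
        return self
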
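"""Shared domain types: segment maps, segmented instances, segment subsets.

The framework operates on grayscale images or fixed-length videos carried as
``(frames, height, width)`` arrays together with a per-pixel integer label
mask naming morphological segments.  Code ``0`` is reserved for background
and is never replaceable; every positive code must be declared in a
:class:`SegmentMap`.  Still images are treated as 1-frame videos so every
downstream operation is written once for the video case.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SegmentMap",
    "SegmentSubset",
    "SegmentedInstance",
    "validate_instance",
    "enumerate_segment_subsets",
]

BACKGROUND = 0


@dataclass(frozen=True)
class SegmentMap:
    """Ordered mapping of positive integer segment codes to segment names.

    The entry order is stable and defines the enumeration order of segment
    subsets (and therefore the row order of summary tables).
    """

    entries: Tuple[Tuple[int, str], ...]

    def __post_init__(self) -> None:
        entries = tuple((int(c), str(n)) for c, n in self.entries)
        object.__setattr__(self, "entries", entries)
        if not entries:
            raise ValueError("segment map must declare at least one segment")
        codes = [c for c, _ in entries]
        names = [n for _, n in entries]
        if any(c <= BACKGROUND for c in codes):
            raise ValueError("segment codes must be positive (0 is reserved for background)")
        if len(set(codes)) != len(codes):
            raise ValueError("segment codes must be unique")
        if any(not n for n in names):
            raise ValueError("segment names must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")

    @classmethod
    def from_dict(cls, mapping: Mapping[int, str]) -> "SegmentMap":
        return cls(tuple((int(c), str(n)) for c, n in mapping.items()))

    def to_dict(self) -> dict:
        return {c: n for c, n in self.entries}

    @property
    def codes(self) -> Tuple[int, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(n for _, n in self.entries)

    def name_of(self, code: int) -> str:
        for c, n in self.entries:
            if c == code:
                return n
        raise KeyError(f"segment code {code} not declared")

    def position_of(self, code: int) -> int:
        for i, (c, _) in enumerate(self.entries):
            if c == code:
                return i
        raise KeyError(f"segment code {code} not declared")

    def label(self, subset: "SegmentSubset") -> str:
        """Human-readable label of a subset, in segment-map order."""
        ordered = sorted(subset.codes, key=self.position_of)
        return " + ".join(self.name_of(c) for c in ordered)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SegmentSubset:
    """A non-empty set of segment codes selected for replacement."""

    codes: Tuple[int, ...]

    def __post_init__(self) -> None:
        codes = tuple(sorted({int(c) for c in self.codes}))
        if not codes:
            raise ValueError("segment subset must be non-empty")
        if any(c <= BACKGROUND for c in codes):
            raise ValueError("background (code 0) is never replaceable")
        object.__setattr__(self, "codes", codes)

    def key(self) -> str:
        """Stable textual key used in provenance tables, e.g. ``\"1+3\"``."""
        return "+".join(str(c) for c in self.codes)

    @classmethod
    def from_key(cls, key: str) -> "SegmentSubset":
        return cls(tuple(int(tok) for tok in str(key).split("+")))

    def __contains__(self, code: int) -> bool:
        return code in self.codes

    def __iter__(self):
        return iter(self.codes)

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class SegmentedInstance:
    """An image or video plus its label mask — the unit the framework recombines.

    ``pixels`` and ``mask`` are stored as ``(frames, height, width)`` arrays;
    2-D input is promoted to a single frame.  ``demographics`` optionally maps
    variable names to numbers or categories for cohort filtering.
    """

    id: str
    pixels: np.ndarray
    mask: np.ndarray
    demographics: Optional[dict] = field(default=None)

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        mask = np.asarray(self.mask)
        if pixels.ndim == 2:
            pixels = pixels[np.newaxis]
        if mask.ndim == 2:
            mask = mask[np.newaxis]
        if pixels.ndim != 3 or mask.ndim != 3:
            raise ValueError(
                f"pixels/mask must be 2-D stills or 3-D (frames, height, width) stacks, "
                f"got pixels.ndim={pixels.ndim}, mask.ndim={mask.ndim}"
            )
        if pixels.size == 0 or mask.size == 0:
            raise ValueError("pixels and mask must be non-empty arrays")
        if not np.issubdtype(mask.dtype, np.integer):
            if not np.all(mask == np.round(mask)):
                raise ValueError("mask must hold integer segment codes")
            mask = mask.astype(np.int64)
        self.pixels = pixels
        self.mask = mask

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.pixels.shape[1:]


def validate_instance(instance: SegmentedInstance, segmap: SegmentMap) -> SegmentedInstance:
    """Check a segmented instance against a segment map and return it unchanged.

    Raises :class:`ValueError` on a pixels/mask shape mismatch or on mask
    values not declared in the segment map (background 0 is always allowed).
    Idempotent: validating a valid instance twice is a no-op.
    """
    if instance.pixels.shape != instance.mask.shape:
        raise ValueError(
            f"shape mismatch: pixels {instance.pixels.shape} vs mask {instance.mask.shape}"
        )
    present = np.unique(instance.mask)
    allowed = set(segmap.codes) | {BACKGROUND}
    undeclared = [int(v) for v in present if int(v) not in allowed]
    if undeclared:
        raise ValueError(
            f"undeclared segment code(s) {undeclared} in mask of instance {instance.id!r}; "
            f"declared codes: {sorted(allowed)}"
        )
    return instance


def enumerate_segment_subsets(segmap: SegmentMap) -> list:
    """All non-empty subsets of the segment map's codes, 2^k − 1 of them.

    Deterministic order: by subset size ascending, then lexicographically by
    segment position in the map — singles first, then pairs, then the full
    set, matching the layout of per-subset summary tables.
    """
    codes = segmap.codes
    if not codes:
        raise ValueError("cannot enumerate subsets of an empty segment map")
    out = []
    for size in range(1, len(codes) + 1):
        for combo in itertools.combinations(codes, size):
            out.append(SegmentSubset(combo))
    return out
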
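"""Counterfactual experiment engine.

Runs the full recombination experiment: every target × source × segment
subset, in both role assignments, re-classifies the recombined images with
the user's model, flags the ones whose predicted label flipped relative to
the *target's predicted label* (never the ground truth), and aggregates a
per-subset summary of counterfactual counts and proportions.

The engine is classifier-agnostic: any object exposing
``predict(batch) -> labels`` over a ``(n, frames, height, width)`` array
plugs in, including sklearn-style classifiers wrapped to accept pixel
stacks.  Predictions must be deterministic for fixed input; when the model
also exposes scores in [0, 1], label 1 corresponds to score >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import SegmentMap, SegmentSubset, SegmentedInstance, enumerate_segment_subsets
from .recombine import Direction, RecombinedInstance, morphmix

__all__ = [
    "CounterfactualRecord",
    "CombinationSummary",
    "generate_recombinations",
    "flag_counterfactuals",
    "summarize_by_subset",
    "run_experiment",
    "resegment_and_score",
    "records_to_frame",
    "summaries_to_frame",
]


@dataclass
class CounterfactualRecord:
    """A recombined instance with its label comparison.

    ``is_counterfactual`` is true iff the model's label for the recombined
    image differs from its label for the original target image.
    """

    recombined: RecombinedInstance
    target_label: int
    recombined_label: int

    @property
    def is_counterfactual(self) -> bool:
        return self.recombined_label != self.target_label


@dataclass
class CombinationSummary:
    """One per-subset row of the counterfactual summary table."""

    subset: SegmentSubset
    n_counterfactual: int
    n_unchanged: int

    @property
    def total(self) -> int:
        return self.n_counterfactual + self.n_unchanged

    @property
    def proportion(self) -> float:
        """Counterfactual fraction, rounded half-up to 3 decimals."""
        if self.total == 0:
            return 0.0
        frac = Decimal(self.n_counterfactual) / Decimal(self.total)
        return float(frac.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def generate_recombinations(
    group_a: Sequence[SegmentedInstance],
    group_b: Sequence[SegmentedInstance],
    subsets: Sequence[SegmentSubset],
    bidirectional: bool = True,
    materialize: bool = True,
) -> Iterator[RecombinedInstance]:
    """Stream all |A|·|B|·|subsets| recombinations per direction.

    Direction ``A_TO_B`` pastes group-A source segments into group-B targets;
    ``B_TO_A`` swaps the roles.  Iteration order is deterministic:
    direction, then target index, then source index, then subset index.

    With ``materialize=False`` only provenance is produced (no pixel
    computation), which enumerates even tens of thousands of combinations
    in well under a second.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not subsets:
        raise ValueError("subset list must be non-empty")
    directions = [Direction.A_TO_B, Direction.B_TO_A] if bidirectional else [Direction.A_TO_B]
    for direction in directions:
        if direction is Direction.A_TO_B:
            targets, sources = group_b, group_a
        else:
            targets, sources = group_a, group_b
        for target in targets:
            for source in sources:
                for subset in subsets:
                    if materialize:
                        yield morphmix(target, source, subset, direction=direction)
                    else:
                        yield RecombinedInstance(
                            target_id=target.id,
                            source_id=source.id,
                            subset=subset,
                            direction=direction,
                        )


def flag_counterfactuals(
    labeled: Iterable[Tuple[RecombinedInstance, int]],
    target_labels: Mapping[str, int],
) -> List[CounterfactualRecord]:
    """Flag recombinations whose label differs from the target's predicted label.

    ``target_labels`` maps every target id to the model's prediction for the
    original, unmodified target image.
    """
    records = []
    for rec, label in labeled:
        if rec.target_id not in target_labels:
            raise KeyError(f"no predicted label for target {rec.target_id!r}")
        records.append(
            CounterfactualRecord(
                recombined=rec,
                target_label=int(target_labels[rec.target_id]),
                recombined_label=int(label),
            )
        )
    return records


def summarize_by_subset(
    records: Sequence[CounterfactualRecord],
    subset_order: Optional[Sequence[SegmentSubset]] = None,
) -> List[CombinationSummary]:
    """Aggregate counterfactual counts per segment subset.

    Rows follow ``subset_order`` when given (typically the enumeration order
    of the segment map), otherwise first-appearance order in ``records``.
    """
    if not records:
        raise ValueError("no records to summarize")
    counts: Dict[SegmentSubset, List[int]] = {}
    order: List[SegmentSubset] = []
    for r in records:
        s = r.recombined.subset
        if s not in counts:
            counts[s] = [0, 0]
            order.append(s)
        counts[s][0 if r.is_counterfactual else 1] += 1
    if subset_order is not None:
        order = [s for s in subset_order if s in counts]
    return [CombinationSummary(s, counts[s][0], counts[s][1]) for s in order]


def _predict_batches(classifier, stack_iter, batch_size: int):
    """Yield per-item labels from batched classifier calls."""
    batch = []
    for pixels in stack_iter:
        batch.append(pixels)
        if len(batch) == batch_size:
            yield from np.asarray(classifier.predict(np.stack(batch))).astype(int).tolist()
            batch = []
    if batch:
        yield from np.asarray(classifier.predict(np.stack(batch))).astype(int).tolist()


def run_experiment(
    cohort: Sequence[SegmentedInstance],
    classifier,
    segmap: SegmentMap,
    subsets: Optional[Sequence[SegmentSubset]] = None,
    batch_size: int = 16,
    keep_pixels: bool = False,
) -> Tuple[List[CounterfactualRecord], List[CombinationSummary]]:
    """End-to-end counterfactual experiment on a cohort.

    Predicts a label for every cohort member, partitions the cohort into the
    two predicted classes, recombines every cross-class pair in both
    directions over every subset (default: all 2^k − 1), re-classifies the
    recombinations in batches, flags counterfactuals, and summarizes per
    subset.  Pixel arrays are dropped from the returned records unless
    ``keep_pixels`` is set, so large runs keep only provenance in memory.
    """
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least two instances")
    if subsets is None:
        subsets = enumerate_segment_subsets(segmap)

    labels = np.asarray(classifier.predict(np.stack([x.pixels for x in cohort]))).astype(int)
    target_labels = {x.id: int(l) for x, l in zip(cohort, labels)}
    group_pos = [x for x, l in zip(cohort, labels) if l == 1]
    group_neg = [x for x, l in zip(cohort, labels) if l == 0]
    if not group_pos or not group_neg:
        raise ValueError(
            "cohort is entirely one predicted class; no source/target split possible"
        )

    records: List[CounterfactualRecord] = []
    batch: List[RecombinedInstance] = []

    def _flush():
        preds = np.asarray(classifier.predict(np.stack([r.pixels for r in batch]))).astype(int)
        for rec, label in zip(batch, preds):
            if not keep_pixels:
                rec.pixels = None
                rec.mask = None
            records.append(
                CounterfactualRecord(
                    recombined=rec,
                    target_label=target_labels[rec.target_id],
                    recombined_label=int(label),
                )
            )
        batch.clear()

    for rec in generate_recombinations(group_pos, group_neg, subsets, bidirectional=True):
        batch.append(rec)
        if len(batch) == batch_size:
            _flush()
    if batch:
        _flush()

    summaries = summarize_by_subset(records, subset_order=subsets)
    return records, summaries


def resegment_and_score(
    recombined: RecombinedInstance,
    expected_mask: np.ndarray,
    segmenter: Callable[[np.ndarray], np.ndarray],
) -> Dict[int, float]:
    """Score a segmenter's recovery of the recombined image's segments.

    Runs ``segmenter`` on the recombined pixels and returns the Dice
    coefficient ``2|X∩Y| / (|X|+|Y|)`` per segment code against
    ``expected_mask`` (the target mask with the subset region replaced by
    translated source labels; ``RecombinedInstance.mask`` provides it).
    Codes absent from both masks score 1.0; a code present in exactly one
    scores 0.0.
    """
    if recombined.pixels is None:
        raise ValueError("recombined instance is not materialized (no pixels)")
    expected_mask = np.asarray(expected_mask)
    predicted = np.asarray(segmenter(recombined.pixels))
    if predicted.shape != expected_mask.shape:
        raise ValueError(
            f"segmenter output shape {predicted.shape} does not match "
            f"expected mask shape {expected_mask.shape}"
        )
    codes = sorted(set(np.unique(expected_mask)) | set(np.unique(predicted)))
    scores: Dict[int, float] = {}
    for code in codes:
        if code == 0:
            continue
        x = expected_mask == code
        y = predicted == code
        denom = int(x.sum()) + int(y.sum())
        scores[int(code)] = 1.0 if denom == 0 else 2.0 * int((x & y).sum()) / denom
    return scores


def records_to_frame(records: Sequence[CounterfactualRecord]) -> pd.DataFrame:
    """Flatten records to a provenance table (one CSV row per recombination)."""
    rows = []
    for r in records:
        rec = r.recombined
        offsets = ";".join(
            "" if o is None else f"{o.drow}:{o.dcol}" for o in rec.offsets
        )
        rows.append(
            {
                "target_id": rec.target_id,
                "source_id": rec.source_id,
                "direction": rec.direction.value,
                "subset": rec.subset.key(),
                "offsets": offsets,
                "hole_fraction": rec.hole_fraction,
                "target_label": r.target_label,
                "recombined_label": r.recombined_label,
                "is_counterfactual": r.is_counterfactual,
            }
        )
    return pd.DataFrame(rows)


def summaries_to_frame(
    summaries: Sequence[CombinationSummary], segmap: Optional[SegmentMap] = None
) -> pd.DataFrame:
    """Summary table with counts and 3-decimal proportions, one row per subset."""
    rows = []
    for s in summaries:
        label = segmap.label(s.subset) if segmap is not None else s.subset.key()
        rows.append(
            {
                "segments_replaced": label,
                "subset": s.subset.key(),
                "n_counterfactual": s.n_counterfactual,
                "n_unchanged": s.n_unchanged,
                "proportion": f"{s.proportion:.3f}",
            }
        )
    return pd.DataFrame(rows)
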
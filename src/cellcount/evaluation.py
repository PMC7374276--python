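"""Counting-error metrics.

Per image: absolute error ``|predicted - true|`` and relative error
``100 * |predicted - true| / true`` (the true expert count is always the
denominator).  Aggregates over a test series: the mean of per-image
relative errors, the totals, the overall difference
``100 * |total_true - total_predicted| / total_true``, and the share of
images whose relative error stays under a chosen cutoff.  Because the
counting method is real-valued and its per-image errors have both signs,
the overall difference over a series is typically smaller than the mean
per-image error — pooling fields of view buys precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

#: Published benchmark of the redundant-count-map method on 26 held-out
#: phase-contrast frames of cultured 293A cells: (predicted, true) expert
#: count pairs.  Feeding these to :func:`summarize` reproduces the
#: benchmark's printed error statistics exactly.
REFERENCE_VALIDATION_PAIRS: tuple[tuple[int, int], ...] = (
    (400, 416),
    (411, 437),
    (432, 432),
    (430, 432),
    (453, 446),
    (243, 245),
    (262, 257),
    (265, 248),
    (255, 262),
    (257, 262),
    (256, 264),
    (259, 264),
    (399, 406),
    (426, 447),
    (235, 229),
    (255, 256),
    (453, 446),
    (420, 429),
    (402, 429),
    (251, 263),
    (415, 443),
    (419, 452),
    (258, 269),
    (468, 472),
    (259, 269),
    (454, 472),
)


@dataclass(frozen=True)
class EvalRecord:
    """Counting error of one image against its expert ground truth."""

    image_id: str
    predicted: float
    true_count: int

    def __post_init__(self) -> None:
        if self.true_count <= 0:
            raise ValueError(f"true_count must be positive, got {self.true_count}")

    @property
    def absolute_error(self) -> float:
        return abs(self.predicted - self.true_count)

    @property
    def relative_error_pct(self) -> float:
        return 100.0 * self.absolute_error / self.true_count


@dataclass(frozen=True)
class EvalSummary:
    """Aggregate error statistics over a test series."""

    n_images: int
    mean_relative_error_pct: float
    max_relative_error_pct: float
    total_predicted: float
    total_true: int
    overall_difference_pct: float
    records: tuple[EvalRecord, ...]

    def fraction_below(self, threshold_pct: float) -> float:
        """Share of images with relative error strictly below the cutoff."""
        return sum(r.relative_error_pct < threshold_pct for r in self.records) / self.n_images


def evaluate_image(predicted: float, true_count: int, image_id: str = "") -> EvalRecord:
    """Error record for a single image (true count must be positive)."""
    return EvalRecord(image_id=image_id, predicted=predicted, true_count=true_count)


def summarize(records: list[EvalRecord]) -> EvalSummary:
    """Aggregate a nonempty list of per-image records."""
    if not records:
        raise ValueError("cannot summarize an empty record list")
    rel = [r.relative_error_pct for r in records]
    total_pred = sum(r.predicted for r in records)
    total_true = sum(r.true_count for r in records)
    return EvalSummary(
        n_images=len(records),
        mean_relative_error_pct=sum(rel) / len(rel),
        max_relative_error_pct=max(rel),
        total_predicted=total_pred,
        total_true=total_true,
        overall_difference_pct=100.0 * abs(total_true - total_pred) / total_true,
        records=tuple(records),
    )


def evaluate_pairs(pairs, ids=None) -> EvalSummary:
    """Convenience: summarize (predicted, true) pairs directly."""
    ids = ids or [str(i + 1) for i in range(len(pairs))]
    return summarize(
        [evaluate_image(p, t, image_id=i) for (p, t), i in zip(pairs, ids)]
    )


def records_to_frame(summary: EvalSummary) -> pd.DataFrame:
    """Tidy per-image table with the error columns (2-decimal display is
    left to the caller)."""
    return pd.DataFrame(
        {
            "image_id": [r.image_id for r in summary.records],
            "predicted": [r.predicted for r in summary.records],
            "true_count": [r.true_count for r in summary.records],
            "absolute_error": [r.absolute_error for r in summary.records],
            "relative_error_pct": [r.relative_error_pct for r in summary.records],
        }
    )


def evaluate_csv(predictions_csv: str | Path, truth_csv: str | Path) -> EvalSummary:
    """Join a predictions CSV (``image_id,predicted``) with a truth CSV
    (``image_id,true_count``) on image_id and summarize."""
    pred = pd.read_csv(predictions_csv)
    truth = pd.read_csv(truth_csv)
    merged = pred.merge(truth, on="image_id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping image_id between predictions and truth")
    return summarize(
        [
            evaluate_image(row.predicted, int(row.true_count), image_id=str(row.image_id))
            for row in merged.itertuples()
        ]
    )
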
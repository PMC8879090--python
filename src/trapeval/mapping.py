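"""Mapping multi-class top-5 outputs to a binary detection per (image, model).

A detection fires when any of a model's top-5 synsets belongs to the target
set, regardless of rank or confidence. The two default targets are the
ImageNet categories whose labels cover the lynx ("lynx, catamount" and the
cougar category that also carries "catamount").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .store import ImageTruth, PredictionRecord, ValidationError

__all__ = [
    "DEFAULT_TARGET_SYNSETS",
    "DetectionMatrix",
    "detect_one",
    "build_detection_matrix",
]

#: ImageNet categories accepted as a lynx detection
DEFAULT_TARGET_SYNSETS = frozenset({"n02127052", "n02125311"})


def detect_one(
    top5_synsets: Sequence[str],
    targets: frozenset[str] | set[str] = DEFAULT_TARGET_SYNSETS,
) -> bool:
    """True iff any top-5 entry is a target synset (rank-independent)."""
    if len(top5_synsets) == 0:
        raise ValidationError("model produced no output (empty top-5 list)")
    if len(top5_synsets) > 5:
        raise ValidationError(f"more than 5 entries in top-5 list: {len(top5_synsets)}")
    return not targets.isdisjoint(top5_synsets)


@dataclass(frozen=True)
class DetectionMatrix:
    """Boolean detections, one row per image and one column per model,
    aligned with the per-row ground truth."""

    detections: pd.DataFrame  # bool, index image_id, columns model ids
    truth: pd.Series  # bool, same index

    def __post_init__(self) -> None:
        if not self.detections.index.equals(self.truth.index):
            raise ValidationError("detection rows and truth rows are misaligned")
        if self.detections.isna().any().any():
            raise ValidationError("detection matrix has missing cells")

    @property
    def models(self) -> list[str]:
        return list(self.detections.columns)

    @property
    def n_images(self) -> int:
        return len(self.detections)

    def to_csv(self, path: str | Path) -> None:
        out = self.detections.astype(int).copy()
        out.insert(0, "truth", self.truth.astype(int))
        out.to_csv(path, index_label="image_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DetectionMatrix":
        df = pd.read_csv(path, index_col="image_id")
        if "truth" not in df.columns:
            raise ValidationError(f"{path}: wide matrix CSV needs a 'truth' column")
        truth = df.pop("truth").astype(bool)
        return cls(detections=df.astype(bool), truth=truth)


def _as_frame(records: Iterable[PredictionRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        [(r.image_id, r.model_id, r.synset_id) for r in records],
        columns=["image_id", "model_id", "synset_id"],
    )


def build_detection_matrix(
    records: Iterable[PredictionRecord] | pd.DataFrame,
    truths: Iterable[ImageTruth] | pd.Series,
    targets: frozenset[str] | set[str] = DEFAULT_TARGET_SYNSETS,
    *,
    models: Optional[Sequence[str]] = None,
    allow_missing: bool = False,
) -> DetectionMatrix:
    """Aggregate per-rank records into one boolean per (image, model).

    Every image carrying predictions must have a truth row; by default every
    (image, model) cell must be backed by at least one record. With
    ``allow_missing=True`` uncovered cells become non-detections.
    """
    frame = _as_frame(records)
    if isinstance(truths, pd.Series):
        truth = truths.astype(bool)
    else:
        truths = list(truths)
        truth = pd.Series(
            [t.is_positive for t in truths],
            index=pd.Index([t.image_id for t in truths], name="image_id"),
            dtype=bool,
        )
    if truth.index.has_duplicates:
        raise ValidationError("duplicate image ids in ground truth")

    orphans = sorted(set(frame["image_id"].unique()) - set(truth.index))
    if orphans:
        raise ValidationError(
            f"{len(orphans)} image(s) have predictions but no truth: {orphans[:10]}"
        )

    frame = frame.assign(hit=frame["synset_id"].isin(targets))
    wide = (
        frame.groupby(["image_id", "model_id"], sort=False)["hit"]
        .any()
        .unstack("model_id")
    )
    if models is not None:
        missing_models = [m for m in models if m not in wide.columns]
        for m in missing_models:
            wide[m] = pd.NA
        wide = wide[list(models)]
    wide = wide.reindex(truth.index)

    if wide.isna().any().any():
        if not allow_missing:
            holes = int(wide.isna().sum().sum())
            raise ValidationError(
                f"{holes} (image, model) cell(s) have no prediction records; "
                "pass allow_missing=True to treat them as non-detections"
            )
        wide = wide.fillna(False).infer_objects(copy=False)
    return DetectionMatrix(detections=wide.astype(bool), truth=truth)
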
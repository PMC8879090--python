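"""Canonical data model and I/O for prediction records, ground truth and the model catalog.

Three interchangeable on-disk representations are supported: flat CSV, JSON
Lines, and a single SQLite database holding ``predictions``, ``truth`` and
``models`` tables. All readers validate; malformed rows raise, they are never
silently dropped.
"""

from __future__ import annotations

import csv
import json
import re
import sqlite3
import warnings
from dataclasses import dataclass, fields
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "PredictionRecord",
    "ImageTruth",
    "ModelCatalogEntry",
    "SchemaError",
    "ValidationError",
    "UnknownModelWarning",
    "read_predictions",
    "write_predictions",
    "read_truth",
    "write_truth",
    "load_model_catalog",
    "load_study_counts",
    "load_study_ensemble_counts",
    "validate_records",
    "validate_truth_coverage",
]

SYNSET_RE = re.compile(r"^n\d{8}$")

PREDICTION_COLUMNS = ("image_id", "model_id", "rank", "synset_id", "confidence")
TRUTH_COLUMNS = ("image_id", "is_positive", "camera_id", "timestamp")


class SchemaError(ValueError):
    """A file does not conform to the declared column schema."""


class ValidationError(ValueError):
    """Structurally valid input whose content violates an invariant."""


class UnknownModelWarning(UserWarning):
    """A model id not present in the bundled catalog was encountered."""


@dataclass(frozen=True, slots=True)
class PredictionRecord:
    """One rank of one model's top-5 output for one image."""

    image_id: str
    model_id: str
    rank: int
    synset_id: str
    confidence: float

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= 5:
            raise ValidationError(
                f"rank must be in 1..5, got {self.rank!r} "
                f"(image {self.image_id!r}, model {self.model_id!r})"
            )
        if not SYNSET_RE.match(self.synset_id):
            raise ValidationError(f"malformed synset id {self.synset_id!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence outside [0,1]: {self.confidence!r}")


@dataclass(frozen=True, slots=True)
class ImageTruth:
    """Human-assigned binary label for one image."""

    image_id: str
    is_positive: bool
    camera_id: Optional[str] = None
    timestamp: Optional[str] = None


@dataclass(frozen=True, slots=True)
class ModelCatalogEntry:
    model_id: str
    full_name: str
    input_size_px: int
    top1_imagenet: float
    top5_imagenet: Optional[float]
    origin_library: str
    n_params: Optional[int]
    flop_millions: Optional[float]


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "jsonl", "sqlite"):
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    return {
        ".csv": "csv",
        ".jsonl": "jsonl",
        ".db": "sqlite",
        ".sqlite": "sqlite",
        ".sqlite3": "sqlite",
    }.get(suffix, "csv")


# ---------------------------------------------------------------------------
# predictions


def validate_records(
    records: Sequence[PredictionRecord], *, check_catalog: bool = False
) -> None:
    """Check cross-record invariants: unique (image, model, rank), at most
    5 ranks per group, confidence non-increasing with rank."""
    by_group: dict[tuple[str, str], dict[int, float]] = {}
    for rec in records:
        key = (rec.image_id, rec.model_id)
        ranks = by_group.setdefault(key, {})
        if rec.rank in ranks:
            raise ValidationError(
                f"duplicate (image, model, rank) = "
                f"({rec.image_id!r}, {rec.model_id!r}, {rec.rank})"
            )
        ranks[rec.rank] = rec.confidence
    for (image_id, model_id), ranks in by_group.items():
        ordered = [conf for _, conf in sorted(ranks.items())]
        if any(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValidationError(
                f"confidence increases with rank for image {image_id!r}, "
                f"model {model_id!r}"
            )
    if check_catalog:
        known = {entry.model_id for entry in load_model_catalog()}
        for model_id in sorted({m for _, m in by_group}):
            if model_id not in known:
                warnings.warn(
                    f"model id {model_id!r} is not in the bundled catalog",
                    UnknownModelWarning,
                    stacklevel=2,
                )


def _records_from_frame(df: pd.DataFrame, source: str) -> list[PredictionRecord]:
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        try:
            records.append(
                PredictionRecord(
                    image_id=str(row.image_id),
                    model_id=str(row.model_id),
                    rank=int(row.rank),
                    synset_id=str(row.synset_id),
                    confidence=float(row.confidence),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{source}: bad row {tuple(row)!r}: {exc}") from exc
    return records


def read_predictions(
    path: str | Path,
    format: Optional[str] = None,
    *,
    validate: bool = True,
    check_catalog: bool = False,
) -> list[PredictionRecord]:
    """Read prediction records from CSV, JSONL or an SQLite store."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        df = pd.read_csv(
            path,
            dtype={"image_id": str, "model_id": str, "synset_id": str},
            float_precision="round_trip",
        )
    elif fmt == "jsonl":
        rows = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
        df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS if not rows else None)
    else:
        with sqlite3.connect(path) as con:
            df = pd.read_sql_query("SELECT * FROM predictions", con)
    if df.empty:
        return []
    records = _records_from_frame(df, str(path))
    if validate:
        validate_records(records, check_catalog=check_catalog)
    return records


_SQLITE_SCHEMA = """
CREATE TABLE IF NOT EXISTS predictions (
    image_id   TEXT NOT NULL,
    model_id   TEXT NOT NULL,
    rank       INTEGER NOT NULL CHECK (rank BETWEEN 1 AND 5),
    synset_id  TEXT NOT NULL,
    confidence REAL NOT NULL,
    PRIMARY KEY (image_id, model_id, rank)
);
CREATE TABLE IF NOT EXISTS truth (
    image_id    TEXT PRIMARY KEY,
    is_positive INTEGER NOT NULL,
    camera_id   TEXT,
    timestamp   TEXT
);
CREATE TABLE IF NOT EXISTS models (
    model_id       TEXT PRIMARY KEY,
    full_name      TEXT,
    input_size_px  INTEGER,
    top1_imagenet  REAL,
    top5_imagenet  REAL,
    origin_library TEXT,
    n_params       INTEGER,
    flop_millions  REAL
);
"""


def _ensure_sqlite_schema(con: sqlite3.Connection) -> None:
    con.executescript(_SQLITE_SCHEMA)


def write_predictions(
    records: Iterable[PredictionRecord],
    path: str | Path,
    format: Optional[str] = None,
    *,
    validate: bool = True,
    include_catalog: bool = True,
) -> None:
    """Write records; the result re-reads to the identical multiset.

    The SQLite route also creates ``truth`` and ``models`` tables and, by
    default, populates ``models`` from the bundled catalog.
    """
    path = Path(path)
    records = list(records)
    if validate:
        validate_records(records)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(PREDICTION_COLUMNS)
            for r in records:
                writer.writerow([r.image_id, r.model_id, r.rank, r.synset_id, repr(r.confidence)])
    elif fmt == "jsonl":
        with path.open("w") as fh:
            for r in records:
                fh.write(json.dumps({f.name: getattr(r, f.name) for f in fields(r)}))
                fh.write("\n")
    else:
        with sqlite3.connect(path) as con:
            _ensure_sqlite_schema(con)
            con.executemany(
                "INSERT OR REPLACE INTO predictions VALUES (?, ?, ?, ?, ?)",
                [(r.image_id, r.model_id, r.rank, r.synset_id, r.confidence) for r in records],
            )
            if include_catalog:
                con.executemany(
                    "INSERT OR REPLACE INTO models VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                    [
                        (
                            e.model_id,
                            e.full_name,
                            e.input_size_px,
                            e.top1_imagenet,
                            e.top5_imagenet,
                            e.origin_library,
                            e.n_params,
                            e.flop_millions,
                        )
                        for e in load_model_catalog()
                    ],
                )


# ---------------------------------------------------------------------------
# ground truth


def _truth_from_frame(df: pd.DataFrame, source: str) -> list[ImageTruth]:
    if "image_id" not in df.columns or "is_positive" not in df.columns:
        raise SchemaError(f"{source}: truth table needs image_id and is_positive columns")
    if df["image_id"].duplicated().any():
        dupes = df.loc[df["image_id"].duplicated(), "image_id"].tolist()
        raise ValidationError(f"{source}: duplicate truth rows for images {dupes[:5]}")
    out = []
    for row in df.itertuples(index=False):
        flag = row.is_positive
        if isinstance(flag, str):
            flag = flag.strip().lower() in ("1", "true", "yes")
        camera = getattr(row, "camera_id", None)
        stamp = getattr(row, "timestamp", None)
        out.append(
            ImageTruth(
                image_id=str(row.image_id),
                is_positive=bool(flag),
                camera_id=None if camera is None or pd.isna(camera) else str(camera),
                timestamp=None if stamp is None or pd.isna(stamp) else str(stamp),
            )
        )
    return out


def read_truth(path: str | Path, format: Optional[str] = None) -> list[ImageTruth]:
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"image_id": str})
    elif fmt == "jsonl":
        with path.open() as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
        df = pd.DataFrame(rows, columns=TRUTH_COLUMNS if not rows else None)
    else:
        with sqlite3.connect(path) as con:
            df = pd.read_sql_query("SELECT * FROM truth", con)
    if df.empty:
        return []
    return _truth_from_frame(df, str(path))


def write_truth(
    truths: Iterable[ImageTruth], path: str | Path, format: Optional[str] = None
) -> None:
    path = Path(path)
    truths = list(truths)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(TRUTH_COLUMNS)
            for t in truths:
                writer.writerow(
                    [t.image_id, int(t.is_positive), t.camera_id or "", t.timestamp or ""]
                )
    elif fmt == "jsonl":
        with path.open("w") as fh:
            for t in truths:
                fh.write(json.dumps({f.name: getattr(t, f.name) for f in fields(t)}))
                fh.write("\n")
    else:
        with sqlite3.connect(path) as con:
            _ensure_sqlite_schema(con)
            con.executemany(
                "INSERT OR REPLACE INTO truth VALUES (?, ?, ?, ?)",
                [(t.image_id, int(t.is_positive), t.camera_id, t.timestamp) for t in truths],
            )


def validate_truth_coverage(
    records: Iterable[PredictionRecord], truths: Iterable[ImageTruth]
) -> None:
    """Reject prediction sets referencing images absent from the truth table."""
    known = {t.image_id for t in truths}
    orphans = sorted({r.image_id for r in records} - known)
    if orphans:
        shown = ", ".join(orphans[:10])
        raise ValidationError(
            f"{len(orphans)} image(s) have predictions but no ground truth: {shown}"
        )


# ---------------------------------------------------------------------------
# bundled fixtures


def _data_path(name: str):
    return resources.files("trapeval.data").joinpath(name)


@lru_cache(maxsize=1)
def load_model_catalog() -> tuple[ModelCatalogEntry, ...]:
    """The 36-model catalog (abbreviation, reference accuracies, complexity)."""
    with resources.as_file(_data_path("model_catalog.csv")) as p:
        df = pd.read_csv(p)
    entries = tuple(
        ModelCatalogEntry(
            model_id=str(row.model_id),
            full_name=str(row.full_name),
            input_size_px=int(row.input_size_px),
            top1_imagenet=float(row.top1_imagenet),
            top5_imagenet=None if pd.isna(row.top5_imagenet) else float(row.top5_imagenet),
            origin_library=str(row.origin_library),
            n_params=None if pd.isna(row.n_params) else int(row.n_params),
            flop_millions=None if pd.isna(row.flop_millions) else float(row.flop_millions),
        )
        for row in df.itertuples(index=False)
    )
    if len(entries) != 36:
        raise RuntimeError(f"corrupted catalog fixture: {len(entries)} entries, expected 36")
    return entries


def load_study_counts() -> pd.DataFrame:
    """Published per-model confusion counts for the lynx label, indexed by model id.

    These are the study's reported TP/TN/FP/FN over 293,604 camera-trap
    images (1630 positives) — the raw CNN inference outputs themselves are
    not redistributable.
    """
    with resources.as_file(_data_path("study_confusion_counts.csv")) as p:
        df = pd.read_csv(p, index_col="model_id")
    return df.astype(int)


def load_study_ensemble_counts() -> pd.DataFrame:
    """Published confusion counts of the Multi-3/4/5 voting ensembles."""
    with resources.as_file(_data_path("study_ensemble_counts.csv")) as p:
        df = pd.read_csv(p, index_col="ensemble_id")
    for col in ("tp", "tn", "fp", "fn", "threshold"):
        df[col] = df[col].astype(int)
    return df
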
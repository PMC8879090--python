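"""Confusion counts and the twelve derived evaluation parameters.

All metrics are computed from integer TP/TN/FP/FN counts in full floating
point precision; display rounding is left to the caller. A metric whose
denominator vanishes (e.g. precision of an all-negative detector) is flagged
as NaN with a warning rather than silently coerced to zero.

The discriminant-power coefficient defaults to ``sqrt(3)/3.14``: the
published reference tables were evidently produced with pi truncated to two
decimals, and only this coefficient reproduces them. Pass
``dp_coef=DP_COEF_EXACT`` for the textbook constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .mapping import DetectionMatrix

__all__ = [
    "ConfusionCounts",
    "MetricVector",
    "UndefinedMetricWarning",
    "DP_COEF_PUBLISHED",
    "DP_COEF_EXACT",
    "METRIC_NAMES",
    "TABLE_COLUMNS",
    "confusion_counts",
    "compute_metrics",
    "metric_table",
    "metric_table_from_counts",
    "rank_models",
]

#: coefficient used in the published tables (pi ~ 3.14)
DP_COEF_PUBLISHED = math.sqrt(3) / 3.14
#: textbook discriminant-power coefficient
DP_COEF_EXACT = math.sqrt(3) / math.pi

METRIC_NAMES = (
    "tpr", "tnr", "ppv", "acc", "err", "bac", "gm", "yi", "dp", "f1", "mcc", "kappa",
)
TABLE_COLUMNS = (
    "TP", "TN", "FP", "FN",
    "TPR", "TNR", "PPV", "ACC", "ERR", "BAC", "GM", "YI", "DP", "F1", "MCC", "KAPPA",
)


class UndefinedMetricWarning(UserWarning):
    """A metric is undefined for the given counts (zero denominator)."""


@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    """TP/TN/FP/FN image tallies for one detector on one dataset."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("empty confusion matrix (total = 0)")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True, slots=True)
class MetricVector:
    """The twelve derived evaluation parameters; NaN marks an undefined value."""

    tpr: float
    tnr: float
    ppv: float
    acc: float
    err: float
    bac: float
    gm: float
    yi: float
    dp: float
    f1: float
    mcc: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def rounded(self, ndigits: int) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", UndefinedMetricWarning, stacklevel=3)
        return math.nan
    return num / den


def compute_metrics(c: ConfusionCounts, *, dp_coef: float = DP_COEF_PUBLISHED) -> MetricVector:
    """Derive the full metric vector from one set of confusion counts."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    tpr = _ratio(tp, tp + fn, "tpr")
    tnr = _ratio(tn, tn + fp, "tnr")
    ppv = _ratio(tp, tp + fp, "ppv")
    acc = (tp + tn) / c.total
    err = 1.0 - acc
    bac = (tpr + tnr) / 2.0
    gm = math.sqrt(tpr * tnr) if not (math.isnan(tpr) or math.isnan(tnr)) else math.nan
    yi = tpr + tnr - 1.0

    if math.isnan(tpr) or math.isnan(tnr) or tpr in (0.0, 1.0) or tnr in (0.0, 1.0):
        warnings.warn(
            "dp undefined: tpr or tnr at 0 or 1", UndefinedMetricWarning, stacklevel=2
        )
        dp = math.nan
    else:
        dp = dp_coef * (math.log10(tpr / (1.0 - tpr)) + math.log10(tnr / (1.0 - tnr)))

    if math.isnan(ppv) or math.isnan(tpr) or ppv + tpr == 0:
        warnings.warn("f1 undefined", UndefinedMetricWarning, stacklevel=2)
        f1 = math.nan
    else:
        f1 = 2.0 * ppv * tpr / (ppv + tpr)

    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        warnings.warn("mcc undefined: zero denominator", UndefinedMetricWarning, stacklevel=2)
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den)

    # closed count form, algebraically identical to (p_o - p_e) / (1 - p_e)
    kappa_den = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    if kappa_den == 0:
        warnings.warn("kappa undefined: zero denominator", UndefinedMetricWarning, stacklevel=2)
        kappa = math.nan
    else:
        kappa = 2.0 * (tp * tn - fp * fn) / kappa_den

    return MetricVector(
        tpr=tpr, tnr=tnr, ppv=ppv, acc=acc, err=err, bac=bac,
        gm=gm, yi=yi, dp=dp, f1=f1, mcc=mcc, kappa=kappa,
    )


def confusion_counts(matrix: DetectionMatrix, model_id: str) -> ConfusionCounts:
    """Tally TP/TN/FP/FN for one model column of a detection matrix."""
    if model_id not in matrix.models:
        raise KeyError(f"unknown model id {model_id!r}")
    detected = matrix.detections[model_id].to_numpy(dtype=bool)
    truth = matrix.truth.to_numpy(dtype=bool)
    tp = int(np.sum(detected & truth))
    tn = int(np.sum(~detected & ~truth))
    fp = int(np.sum(detected & ~truth))
    fn = int(np.sum(~detected & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _table_row(model_id: str, c: ConfusionCounts, dp_coef: float) -> dict:
    m = compute_metrics(c, dp_coef=dp_coef)
    row = {"model_id": model_id, "TP": c.tp, "TN": c.tn, "FP": c.fp, "FN": c.fn}
    row.update({name.upper(): value for name, value in m.as_dict().items()})
    return row


def metric_table(matrix: DetectionMatrix, *, dp_coef: float = DP_COEF_PUBLISHED) -> pd.DataFrame:
    """One row per model: counts plus all twelve derived metrics."""
    if not matrix.models:
        raise ValueError("empty detection matrix: no model columns")
    rows = [
        _table_row(model_id, confusion_counts(matrix, model_id), dp_coef)
        for model_id in matrix.models
    ]
    return pd.DataFrame(rows).set_index("model_id")[list(TABLE_COLUMNS)]


def metric_table_from_counts(
    counts: pd.DataFrame, *, dp_coef: float = DP_COEF_PUBLISHED
) -> pd.DataFrame:
    """Same as :func:`metric_table` but starting from a tp/tn/fp/fn frame
    (e.g. the bundled study counts)."""
    rows = [
        _table_row(
            str(model_id),
            ConfusionCounts(tp=int(r.tp), tn=int(r.tn), fp=int(r.fp), fn=int(r.fn)),
            dp_coef,
        )
        for model_id, r in zip(counts.index, counts.itertuples(index=False))
    ]
    return pd.DataFrame(rows).set_index("model_id")[list(TABLE_COLUMNS)]


def rank_models(
    table: pd.DataFrame, metric_name: str, k: Optional[int] = 5
) -> tuple[list[str], list[str]]:
    """Top-k and bottom-k model ids by one metric column.

    Deterministic tie-break: the metric, then MCC, then model id. NaNs sort
    last for the top list and are excluded from the bottom list.
    """
    col = metric_name.upper()
    if col not in table.columns:
        raise KeyError(f"unknown metric {metric_name!r}")
    if k is None:
        k = len(table)
    if k > len(table):
        raise ValueError(f"k={k} exceeds number of models ({len(table)})")
    ordered = table.reset_index().sort_values(
        by=[col, "MCC", "model_id"],
        ascending=[False, False, True],
        na_position="last",
    )["model_id"].tolist()
    top = ordered[:k]
    bottom = list(reversed(ordered[-k:])) if k else []
    return top, bottom
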
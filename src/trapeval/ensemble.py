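"""Threshold-voting ensembles of binary detectors.

Members are drawn from the per-model metric table by a kappa cutoff (and
optionally a sharp-drop truncation); the ensemble flags an image positive
when at least ``threshold`` member models flag it. A brute-force sweep over
all thresholds 1..N is provided since the optimal vote count depends on the
objective metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .mapping import DetectionMatrix
from .metrics import (
    DP_COEF_PUBLISHED,
    ConfusionCounts,
    MetricVector,
    compute_metrics,
)

__all__ = [
    "EnsembleSpec",
    "SelectionRule",
    "select_members",
    "ensemble_detections",
    "evaluate_ensemble",
    "threshold_search",
    "relative_improvement",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Member model ids (descending kappa order) and the vote threshold."""

    members: tuple[str, ...]
    threshold: int = 3

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("ensemble members must be unique")
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if not 1 <= self.threshold <= len(self.members):
            raise ValueError(
                f"threshold {self.threshold} out of range 1..{len(self.members)}"
            )


@dataclass(frozen=True)
class SelectionRule:
    """Kappa-based member selection: keep models with kappa >= cutoff, in
    descending kappa order, optionally truncated before the first adjacent
    relative drop exceeding ``drop_fraction``, then capped at
    ``max_members``."""

    kappa_cutoff: float = 0.2
    max_members: int = 5
    drop_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.kappa_cutoff < 1.0:
            raise ValueError("kappa_cutoff must be in (0, 1)")
        if self.max_members < 1:
            raise ValueError("max_members must be >= 1")
        if self.drop_fraction is not None and not 0.0 < self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must be in (0, 1)")


def select_members(table: pd.DataFrame, rule: SelectionRule = SelectionRule()) -> list[str]:
    """Choose ensemble members from a metric table (needs KAPPA/MCC columns)."""
    if "KAPPA" not in table.columns:
        raise KeyError("metric table lacks a KAPPA column")
    passing = table[table["KAPPA"] >= rule.kappa_cutoff]
    if passing.empty:
        raise ValueError(
            f"no model reaches the kappa cutoff {rule.kappa_cutoff}"
        )
    ordered = passing.reset_index().sort_values(
        by=["KAPPA", "MCC", "model_id"], ascending=[False, False, True]
    )
    ids = ordered["model_id"].tolist()
    kappas = ordered["KAPPA"].tolist()
    if rule.drop_fraction is not None:
        keep = len(ids)
        for i in range(1, len(ids)):
            if (kappas[i - 1] - kappas[i]) / kappas[i - 1] > rule.drop_fraction:
                keep = i
                break
        ids = ids[:keep]
    return ids[: rule.max_members]


def ensemble_detections(matrix: DetectionMatrix, spec: EnsembleSpec) -> pd.Series:
    """Per-image vote: detected iff >= threshold member models detect."""
    missing = [m for m in spec.members if m not in matrix.models]
    if missing:
        raise KeyError(f"members absent from detection matrix: {missing}")
    votes = matrix.detections[list(spec.members)].sum(axis=1)
    return (votes >= spec.threshold).rename("ensemble")


def evaluate_ensemble(
    matrix: DetectionMatrix,
    spec: EnsembleSpec,
    *,
    dp_coef: float = DP_COEF_PUBLISHED,
) -> tuple[ConfusionCounts, MetricVector]:
    detected = ensemble_detections(matrix, spec).to_numpy()
    truth = matrix.truth.to_numpy(dtype=bool)
    counts = ConfusionCounts(
        tp=int((detected & truth).sum()),
        tn=int((~detected & ~truth).sum()),
        fp=int((detected & ~truth).sum()),
        fn=int((~detected & truth).sum()),
    )
    return counts, compute_metrics(counts, dp_coef=dp_coef)


def threshold_search(
    matrix: DetectionMatrix,
    members: Sequence[str],
    objective: str = "KAPPA",
    *,
    dp_coef: float = DP_COEF_PUBLISHED,
) -> tuple[pd.DataFrame, int]:
    """Brute-force evaluation of every vote threshold 1..len(members).

    Returns the per-threshold table (counts + metrics) and the argmax
    threshold by ``objective``, tie-broken by MCC and then the smaller
    threshold.
    """
    objective = objective.upper()
    rows = []
    for t in range(1, len(members) + 1):
        counts, mv = evaluate_ensemble(
            matrix, EnsembleSpec(members=tuple(members), threshold=t), dp_coef=dp_coef
        )
        row = {"threshold": t, "TP": counts.tp, "TN": counts.tn, "FP": counts.fp, "FN": counts.fn}
        row.update({k.upper(): v for k, v in mv.as_dict().items()})
        rows.append(row)
    table = pd.DataFrame(rows).set_index("threshold")
    if objective not in table.columns:
        raise KeyError(f"unknown objective metric {objective!r}")
    best = (
        table.reset_index()
        .sort_values(by=[objective, "MCC", "threshold"], ascending=[False, False, True])
        .iloc[0]["threshold"]
    )
    return table, int(best)


def relative_improvement(ensemble_value: float, standalone_value: float) -> float:
    """Percent by which the ensemble exceeds the standalone model, expressed
    relative to the ensemble value."""
    if ensemble_value == 0:
        raise ZeroDivisionError("ensemble value is zero")
    return (ensemble_value - standalone_value) / ensemble_value * 100.0
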
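"""Synthetic top-5 prediction records with the statistical structure the
analysis assumes: rare positives, heterogeneous per-model sensitivity and
specificity, and positively correlated detections across models.

Detections follow a Gaussian-copula latent-difficulty model. Each image i
draws a latent standard normal z_i; model m detects the target iff

    rho * z_i + sqrt(1 - rho^2) * eps_im  <=  Phi^-1(p_m)

with eps_im iid standard normal, p_m = tpr_m on positive images and
1 - tnr_m on negatives. The copula preserves each model's marginal TPR/FPR
exactly for any rho, while rho controls how strongly models agree on the
same image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.stats import norm

from .mapping import DEFAULT_TARGET_SYNSETS
from .store import ImageTruth, PredictionRecord, load_study_counts

__all__ = [
    "SyntheticConfig",
    "default_model_profiles",
    "simulate",
    "simulate_detections",
]

# arbitrary non-target ImageNet animal categories used to pad the top-5
DEFAULT_DISTRACTOR_POOL = (
    "n02123045", "n02123159", "n02123394", "n02123597", "n02124075",
    "n02128385", "n02128757", "n02128925", "n02129165", "n02129604",
    "n02130308", "n02105162", "n02106662", "n02110341", "n02089867",
    "n02096294", "n02099601", "n02100735", "n02108089", "n02109961",
    "n02114367", "n02114548", "n02117135", "n02119022", "n02132136",
    "n02134084", "n02437616", "n02441942", "n02443484", "n02510455",
)


def default_model_profiles() -> list[tuple[str, float, float]]:
    """(model_id, tpr, tnr) for all 36 models, derived from the bundled
    study confusion counts, so the default simulation resembles the study."""
    counts = load_study_counts()
    return [
        (str(m), float(r.tp / (r.tp + r.fn)), float(r.tn / (r.tn + r.fp)))
        for m, r in zip(counts.index, counts.itertuples(index=False))
    ]


@dataclass
class SyntheticConfig:
    n_images: int = 10_000
    prevalence: float = 1630 / 293_604
    model_profiles: Sequence[tuple[str, float, float]] = field(
        default_factory=default_model_profiles
    )
    correlation: float = 0.5
    seed: int = 0
    target_synsets: frozenset[str] = DEFAULT_TARGET_SYNSETS
    distractor_pool: Sequence[str] = DEFAULT_DISTRACTOR_POOL
    fixed_positive_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_images <= 0:
            raise ValueError("n_images must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")
        if not self.model_profiles:
            raise ValueError("model_profiles must be non-empty")
        ids = [m for m, _, _ in self.model_profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("model ids in model_profiles must be unique")
        for m, tpr, tnr in self.model_profiles:
            if not (0.0 <= tpr <= 1.0 and 0.0 <= tnr <= 1.0):
                raise ValueError(f"rates for {m!r} must lie in [0, 1]")
        targets = set(self.target_synsets)
        if targets & set(self.distractor_pool):
            raise ValueError("distractor_pool must be disjoint from target_synsets")
        if len(self.distractor_pool) < 20:
            raise ValueError("distractor_pool needs at least 20 synsets")
        if self.fixed_positive_count is None and self.prevalence * self.n_images < 1:
            warnings.warn(
                "expected number of positives is below 1; the simulation will "
                "likely contain no positive images",
                UserWarning,
                stacklevel=2,
            )

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticConfig":
        if "model_profiles" in payload:
            payload = dict(payload)
            payload["model_profiles"] = [
                (str(m), float(tpr), float(tnr)) for m, tpr, tnr in payload["model_profiles"]
            ]
        if "target_synsets" in payload:
            payload["target_synsets"] = frozenset(payload["target_synsets"])
        return cls(**payload)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(payload)


def _image_ids(n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"img_{i:0{width}d}" for i in range(n)]


def simulate_detections(
    config: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Fast path: boolean detection matrix (n_images x n_models), the truth
    vector, and the model id order — no per-rank records materialised."""
    rng = np.random.default_rng(config.seed)
    n = config.n_images
    ids = [m for m, _, _ in config.model_profiles]
    tpr = np.array([p for _, p, _ in config.model_profiles])
    tnr = np.array([p for _, _, p in config.model_profiles])

    if config.fixed_positive_count is not None:
        k = config.fixed_positive_count
        if not 0 <= k <= n:
            raise ValueError("fixed_positive_count out of range")
        truth = np.zeros(n, dtype=bool)
        truth[rng.permutation(n)[:k]] = True
    else:
        truth = rng.random(n) < config.prevalence

    rho = config.correlation
    z = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(ids)))
    latent = rho * z[:, None] + np.sqrt(1.0 - rho * rho) * eps
    # detection probability per cell: tpr on positives, fpr = 1 - tnr on negatives
    p = np.where(truth[:, None], tpr[None, :], 1.0 - tnr[None, :])
    with np.errstate(divide="ignore"):
        cutoff = norm.ppf(p)
    detected = latent <= cutoff
    return detected, truth, ids


def _fill_top5(
    rng: np.random.Generator,
    detected: np.ndarray,
    pool: np.ndarray,
    targets: np.ndarray,
    chunk: int = 200_000,
) -> np.ndarray:
    """Synset id per (cell, rank): detected cells carry one random target at a
    random rank, the remaining ranks hold distinct distractors."""
    n_cells = detected.shape[0]
    out = np.empty((n_cells, 5), dtype=object)
    for start in range(0, n_cells, chunk):
        stop = min(start + chunk, n_cells)
        m = stop - start
        # 5 distinct distractors per cell via partial random permutation
        scores = rng.random((m, len(pool)))
        picks = np.argpartition(scores, 5, axis=1)[:, :5]
        out[start:stop] = pool[picks]
        det = detected[start:stop]
        hits = np.flatnonzero(det)
        if hits.size:
            ranks = rng.integers(0, 5, size=hits.size)
            synsets = targets[rng.integers(0, len(targets), size=hits.size)]
            out[start + hits, ranks] = synsets
    return out


def simulate(config: SyntheticConfig) -> tuple[list[PredictionRecord], list[ImageTruth]]:
    """Generate the full per-rank record set plus ground truth.

    Fully reproducible from ``config.seed``: detection structure, synset
    placement and confidences all derive from one seeded generator.
    """
    detected, truth, model_ids = simulate_detections(config)
    n, m = detected.shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    flat = detected.reshape(-1)  # cell order: image-major, model-minor
    pool = np.asarray(config.distractor_pool, dtype=object)
    targets = np.asarray(sorted(config.target_synsets), dtype=object)
    synsets = _fill_top5(rng, flat, pool, targets)
    confidences = -np.sort(-rng.random((n * m, 5)), axis=1)

    image_ids = _image_ids(n)
    records: list[PredictionRecord] = []
    cell = 0
    for i in range(n):
        img = image_ids[i]
        for j in range(m):
            model = model_ids[j]
            syn_row = synsets[cell]
            conf_row = confidences[cell]
            for rank in range(5):
                records.append(
                    PredictionRecord(
                        image_id=img,
                        model_id=model,
                        rank=rank + 1,
                        synset_id=syn_row[rank],
                        confidence=float(conf_row[rank]),
                    )
                )
            cell += 1
    truths = [
        ImageTruth(image_id=image_ids[i], is_positive=bool(truth[i])) for i in range(n)
    ]
    return records, truths
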
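"""Sliding-window ensemble inference over variable-depth volumes.

A fixed-depth window (default 32 slices) slides along the
superior-inferior axis with a stride (default 16); each window is scored
by every ensemble member and the member probabilities averaged. The
per-window scores are then aggregated into one patient-level
classification by one of four rules: average, majority vote, median, or
a weighted average that linearly down-weights the most superior windows
(where the high-uptake brain dominates the field of view).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from petmri3d.metrics import confusion, roc_auc, sens_spec_acc
from petmri3d.training import Ensemble

__all__ = [
    "SlidingWindowConfig", "WindowScores", "CasePrediction",
    "window_starts", "score_windows", "aggregate", "classify_dataset",
    "AGGREGATION_METHODS",
]

AGGREGATION_METHODS = ("average", "majority", "median", "weighted")
TailPolicy = Literal["floor", "end_aligned"]


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Window geometry. ``end_aligned`` appends a final window flush
    with the inferior end when the stride grid does not reach it."""

    window: int = 32
    stride: int = 16
    tail_policy: TailPolicy = "end_aligned"

    def __post_init__(self) -> None:
        if not 1 <= self.stride <= self.window:
            raise ValueError(f"need 1 <= stride <= window, got stride={self.stride}, window={self.window}")
        if self.tail_policy not in ("floor", "end_aligned"):
            raise ValueError(f"unknown tail_policy {self.tail_policy!r}")


@dataclass(frozen=True)
class WindowScores:
    """Per-window ensemble probabilities for one case; ``starts`` are
    0-based superior->inferior slice indices, strictly increasing."""

    starts: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.probs) or len(self.starts) == 0:
            raise ValueError("starts and probs must have equal length >= 1")
        if any(b <= a for a, b in zip(self.starts, self.starts[1:])):
            raise ValueError("starts must be strictly increasing")


@dataclass(frozen=True)
class CasePrediction:
    case_id: str
    method: str
    score: float  # NaN for majority vote (no score, hence no ROC/AUC)
    decision: int


def window_starts(depth: int, config: SlidingWindowConfig) -> tuple[int, ...]:
    """Window start indices for a volume of ``depth`` slices.

    ``floor``: multiples of the stride while the window fits.
    ``end_aligned``: the same plus a final start at ``depth - window``
    when the last floor window stops short of the volume end. A volume
    shallower than one window is an error (no padding is invented).
    """
    w, s = config.window, config.stride
    if depth < w:
        raise ValueError(f"depth {depth} < window {w}: cannot place a window")
    starts = list(range(0, depth - w + 1, s))
    if config.tail_policy == "end_aligned" and starts[-1] + w < depth:
        starts.append(depth - w)
    return tuple(starts)


def score_windows(
    ensemble: Ensemble, volume: np.ndarray, config: SlidingWindowConfig
) -> WindowScores:
    """Score every window of a preprocessed (x, y, z, c) volume.

    Each of the member models produces a probability per window; the
    window score is their arithmetic mean. The volume must be scaled and
    harmonised but NOT depth-cropped.
    """
    from petmri3d.model import forward

    if volume.ndim != 4:
        raise ValueError(f"expected (x, y, z, channel) volume, got shape {volume.shape}")
    depth = volume.shape[2]
    starts = window_starts(depth, config)
    probs = []
    for wi, start in enumerate(starts):
        sub = volume[:, :, start : start + config.window, :]
        try:
            member_probs = [forward(m.model, sub) for m in ensemble.members]
        except ValueError as e:
            raise ValueError(f"window {wi} (slices {start}..{start + config.window}): {e}") from e
        probs.append(float(np.mean(member_probs)))
    return WindowScores(starts=starts, probs=tuple(probs))


def _weights(n: int) -> np.ndarray:
    """Linear ramp w_i = i / sum(1..n) for windows i = 1..n ordered
    superior -> inferior; sums to 1 and down-weights the brain-heavy
    top of the stack."""
    i = np.arange(1, n + 1, dtype=float)
    return i / i.sum()


def aggregate(
    ws: WindowScores,
    method: str,
    threshold: float,
    case_id: str = "",
) -> CasePrediction:
    """Collapse window scores into one patient-level prediction.

    ``average``/``median``/``weighted`` produce a score compared against
    the ensemble threshold (decision = score >= threshold). ``majority``
    thresholds each window first and votes; a strict majority of
    positive windows is required, so an even split is negative, and no
    score (hence no ROC/AUC) is defined for this method.
    """
    p = np.asarray(ws.probs, dtype=float)
    if method == "average":
        score = float(p.mean())
    elif method == "median":
        score = float(np.median(p))
    elif method == "weighted":
        score = float(np.dot(_weights(len(p)), p))
    elif method == "majority":
        n_pos = int((p >= threshold).sum())
        return CasePrediction(case_id, method, math.nan, int(n_pos > len(p) / 2))
    else:
        raise ValueError(f"unknown aggregation method {method!r}; choose from {AGGREGATION_METHODS}")
    return CasePrediction(case_id, method, score, int(score >= threshold))


def classify_dataset(
    ensemble: Ensemble,
    cases: Sequence[tuple[str, np.ndarray, Optional[int]]],
    config: SlidingWindowConfig,
    methods: Sequence[str] = AGGREGATION_METHODS,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Predict every case under every aggregation method.

    ``cases`` are (case_id, preprocessed full-depth volume, label or
    None) triples. Returns a predictions table (one row per case and
    method) and, when labels are available, per-method metrics:
    confusion-derived accuracy/sensitivity/specificity at the ensemble
    threshold, plus ROC AUC for the score-producing methods (majority
    vote has no score, so its AUC is NaN).
    """
    if len(cases) == 0:
        raise ValueError("classify_dataset requires at least one case")
    rows = []
    for case_id, volume, label in cases:
        ws = score_windows(ensemble, volume, config)
        for method in methods:
            pred = aggregate(ws, method, ensemble.threshold, case_id=case_id)
            rows.append({"case_id": case_id, "method": method, "score": pred.score,
                         "decision": pred.decision, "label": label})
    table = pd.DataFrame.from_records(rows)
    metrics: dict[str, dict[str, float]] = {}
    if all(label is not None for _, _, label in cases):
        for method in methods:
            sub = table[table.method == method]
            c = confusion(sub.decision.to_numpy(), sub.label.to_numpy())
            sens, spec, acc = sens_spec_acc(c)
            entry = {"accuracy": acc, "sensitivity": sens, "specificity": spec,
                     "TN": c.TN, "FP": c.FP, "FN": c.FN, "TP": c.TP}
            if method != "majority" and len(set(sub.label)) == 2:
                entry["auc"] = roc_auc(sub.score.to_numpy(), sub.label.to_numpy()).auc
            else:
                entry["auc"] = math.nan
            metrics[method] = entry
    return table, metrics
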
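"""Per-instance scores and spatial heatmaps.

A trained model with the mean-based head admits an exact per-instance
read-out: each column of the measurement matrix is pushed through the
head's MLP and softmax on its own (skipping the instance-axis mean), so
every patch receives a positive-class probability. Scores are min-max
normalized to [0, 1] and painted onto a downsampled raster at the patch
coordinates; patches sharing a raster cell average their scores, and
cells with no patch are NaN (absent), never zero. The per-instance
pathway is defined for the mean head only; other heads raise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autograd import Tensor, softmax
from .bags import FeatureBag
from .errors import DataError, ParameterError, UnsupportedHeadError
from .model import ModelState, _measurement_t, _mlp, forward
from .synthetic import Cohort

__all__ = [
    "HeatmapResult",
    "per_instance_probabilities",
    "normalize_scores",
    "render_heatmap",
    "prototype_score_table",
]


@dataclass
class HeatmapResult:
    bag_id: str
    scores: np.ndarray  # normalized, length n, in [0, 1]
    raw: np.ndarray  # raw probabilities, length n
    coords: np.ndarray  # (n, 2)
    grid: np.ndarray  # 2-D raster; NaN where no patch painted
    downsample: int
    top_k: list[tuple[tuple[int, int], float]]  # ((x, y), raw probability)


def per_instance_probabilities(bag: FeatureBag, state: ModelState) -> np.ndarray:
    """Positive-class probability per instance (full bag, no sampling).

    Each measurement column (an L-vector) goes through the mean head's
    MLP and softmax individually; averaging the per-column logits
    recovers the bag-level pathway whenever the MLP acts affinely.
    """
    if state.config.head != "mean":
        raise UnsupportedHeadError(
            "per-instance probabilities are defined for the mean head only"
        )
    M = _measurement_t(Tensor(bag.features), state)
    if state.config.prototype_mode == "none":
        M = M.mean(axis=0, keepdims=True)
    cols = M.T  # (n, L): one row per instance
    probs = softmax(_mlp(cols, state), axis=-1).data
    return probs[:, 1]


def normalize_scores(raw: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to 0.5 everywhere."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 1 or raw.size < 1:
        raise ParameterError("normalize_scores expects a non-empty 1-D vector")
    if not np.isfinite(raw).all():
        raise DataError("normalize_scores: non-finite input")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def render_heatmap(
    scores: np.ndarray,
    coords: np.ndarray,
    patch_size: int = 256,
    downsample: int = 1,
    raw: np.ndarray | None = None,
    top_k: int = 3,
    bag_id: str = "",
) -> HeatmapResult:
    """Paint per-patch scores onto a raster at 1/downsample scale.

    Each patch covers [x, x + patch_size) x [y, y + patch_size); cells
    covered by several patches hold the mean of their scores. Painting
    is order-independent (sum/count accumulation).
    """
    scores = np.asarray(scores, dtype=np.float64)
    coords = np.asarray(coords, dtype=np.int64)
    if downsample < 1:
        raise ParameterError("downsample must be >= 1")
    if (coords < 0).any():
        raise DataError("coords: negative coordinates")
    if scores.shape[0] != coords.shape[0]:
        raise DataError("scores: length does not match coords")
    raw = scores if raw is None else np.asarray(raw, dtype=np.float64)

    x0 = coords[:, 0] // downsample
    y0 = coords[:, 1] // downsample
    x1 = (coords[:, 0] + patch_size - 1) // downsample + 1
    y1 = (coords[:, 1] + patch_size - 1) // downsample + 1
    W, H = int(x1.max()), int(y1.max())
    acc = np.zeros((H, W))
    cnt = np.zeros((H, W))
    for s, xa, xb, ya, yb in zip(scores, x0, x1, y0, y1):
        acc[ya:yb, xa:xb] += s
        cnt[ya:yb, xa:xb] += 1.0
    grid = np.full((H, W), np.nan)
    mask = cnt > 0
    grid[mask] = acc[mask] / cnt[mask]

    k = min(top_k, len(raw))
    top_idx = np.argsort(-raw, kind="stable")[:k]
    tops = [((int(coords[i, 0]), int(coords[i, 1])), float(raw[i])) for i in top_idx]
    return HeatmapResult(
        bag_id=bag_id,
        scores=scores,
        raw=raw,
        coords=coords,
        grid=grid,
        downsample=downsample,
        top_k=tops,
    )


def bag_heatmap(
    bag: FeatureBag, state: ModelState, downsample: int = 32, top_k: int = 3
) -> HeatmapResult:
    """Convenience: per-instance probabilities -> normalized heatmap."""
    raw = per_instance_probabilities(bag, state)
    return render_heatmap(
        normalize_scores(raw),
        bag.coords,
        patch_size=bag.patch_size,
        downsample=downsample,
        raw=raw,
        top_k=top_k,
        bag_id=bag.bag_id,
    )


def prototype_score_table(cohort: Cohort, state: ModelState) -> pd.DataFrame:
    """Per-bag prediction plus per-prototype mean measurement.

    One row per bag: bag_id, label, predicted positive probability, and
    for each prototype k the instance-axis mean of measurement row k —
    the plain-table export of the phenotype-vs-prediction analysis.
    """
    if state.config.prototype_mode != "cluster":
        raise UnsupportedHeadError("prototype score table requires cluster prototype mode")
    rows = []
    for bag in cohort.bags:
        res = forward(bag, state)
        row = {"bag_id": bag.bag_id, "label": bag.label, "prob": res.prob_positive}
        means = res.measurement.values.mean(axis=1)
        for k, v in enumerate(means):
            row[f"proto_{k}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)
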
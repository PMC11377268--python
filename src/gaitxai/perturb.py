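"""Greedy MoRF ("most relevant first") perturbation analysis.

Validates relevance heatmaps and compares classifiers / explanation
methods: the input window is tiled into fixed regions (default 7 x 7
frames x channels), regions are ranked per sample by their summed
relevance, and at each step the top-ranked regions accumulated so far are
replaced with Gaussian noise before re-predicting the test set. A steep
early decline in accuracy relative to random-order removal indicates a
well-localized explanation; after all regions are replaced the classifier
can only guess at chance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import TrainedModel
from .lrp import RelevanceMap

__all__ = [
    "RegionGrid", "MoRFResult", "tile_regions", "region_scores",
    "morf_curve", "decay_statistic", "select_model", "select_xai_method",
]


@dataclass(frozen=True)
class RegionGrid:
    """Row-major tiling of a (frames x channels) window into blocks."""

    window_shape: Tuple[int, int]
    region_shape: Tuple[int, int] = (7, 7)
    regions: Tuple[Tuple[slice, slice], ...] = field(default=(), compare=False)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def tile_regions(window_shape: Tuple[int, int], region_shape: Tuple[int, int] = (7, 7)) -> RegionGrid:
    """Tile the window row-major with ``region_shape`` blocks.

    Partial blocks at the bottom/right edges are kept, so the block count
    is ``ceil(H/rh) * ceil(W/rw)``.
    """
    H, W = window_shape
    rh, rw = region_shape
    if rh < 1 or rw < 1:
        raise ValueError("region shape must be positive")
    if rh > H and rw > W:
        raise ValueError(f"region {region_shape} larger than window {window_shape} in both dims")
    regions = []
    for i in range(0, H, rh):
        for j in range(0, W, rw):
            regions.append((slice(i, min(i + rh, H)), slice(j, min(j + rw, W))))
    return RegionGrid(tuple(window_shape), tuple(region_shape), tuple(regions))


def region_scores(rmap: RelevanceMap, grid: RegionGrid) -> np.ndarray:
    """Summed relevance per region; shape (..., n_regions)."""
    scores = np.asarray(rmap.scores if isinstance(rmap, RelevanceMap) else rmap)
    if scores.shape[-2:] != grid.window_shape:
        raise ValueError(
            f"map shape {scores.shape[-2:]} does not match grid window {grid.window_shape}"
        )
    out = np.empty(scores.shape[:-2] + (grid.n_regions,))
    for r, (si, sj) in enumerate(grid.regions):
        out[..., r] = scores[..., si, sj].sum(axis=(-2, -1))
    return out


@dataclass
class MoRFResult:
    """Accuracy-vs-perturbation-step curve for one removal order."""

    order: str  # "morf" | "random"
    step_accuracies: np.ndarray  # length n_steps + 1; step 0 = unperturbed
    n_steps: int
    noise_params: Tuple[float, float]
    seed: int
    region_order: np.ndarray  # (n_samples, n_regions_used) region ids per sample

    def __post_init__(self):
        self.step_accuracies = np.asarray(self.step_accuracies, dtype=float)
        if self.step_accuracies.shape != (self.n_steps + 1,):
            raise ValueError("step_accuracies must have length n_steps + 1")
        if np.any((self.step_accuracies < 0) | (self.step_accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")


def morf_curve(
    model: TrainedModel,
    X: np.ndarray,
    labels: Sequence,
    maps: Optional[np.ndarray],
    grid: RegionGrid,
    n_steps: int = 30,
    order: str = "morf",
    noise: Tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
    batch_size: int = 256,
) -> MoRFResult:
    """Accuracy after cumulatively noising the top-t regions, t = 0..n_steps.

    ``maps`` holds one relevance map per sample (shape like ``X``); it is
    ignored for the random order, where each sample gets an independent
    random region permutation. Region ordering is computed per sample from
    that sample's own map; ties and the random order are seeded. Noise is
    redrawn for the accumulated region set at every step (mean/sd in
    standardized input units).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    y_idx = np.array([model.classes.index(l) for l in labels])
    if order not in ("morf", "random"):
        raise ValueError(f"unknown order {order!r}")
    n_regions = grid.n_regions
    if n_steps > n_regions:
        import warnings

        warnings.warn(f"n_steps {n_steps} exceeds region count {n_regions}; clipped")
        n_steps = n_regions
    rng = np.random.default_rng(seed)
    if order == "morf":
        if maps is None:
            raise ValueError("morf order requires relevance maps")
        scores = region_scores(np.asarray(maps), grid)
        # descending score; numpy argsort is stable, so ties keep region order
        region_order = np.argsort(-scores, axis=-1, kind="stable")
    else:
        region_order = np.stack([rng.permutation(n_regions) for _ in range(n)])

    accs = [float(np.mean(_predict_idx(model, X, batch_size) == y_idx))]
    Xp = X.copy()
    for t in range(1, n_steps + 1):
        # perturbations accumulate: redraw noise for all t chosen regions
        Xp = X.copy()
        for s in range(n):
            for r in region_order[s, :t]:
                si, sj = grid.regions[r]
                block = Xp[s, si, sj]
                Xp[s, si, sj] = rng.normal(noise[0], noise[1], block.shape)
        accs.append(float(np.mean(_predict_idx(model, Xp, batch_size) == y_idx)))
    return MoRFResult(order, np.array(accs), n_steps, tuple(noise), seed,
                      region_order[:, :n_steps])


def _predict_idx(model: TrainedModel, X: np.ndarray, batch_size: int) -> np.ndarray:
    return model.predict_indices(X, batch_size=batch_size)


@dataclass
class DecayStatistic:
    """Mean per-step decline and step-wise baseline differences."""

    mean_decline: float
    baseline_minus_curve: np.ndarray


def decay_statistic(result: MoRFResult, baseline: Optional[MoRFResult] = None,
                    early_window: Optional[int] = None) -> DecayStatistic:
    """Rate of accuracy decline, mean-centered, vs a baseline curve.

    ``mean_decline`` is the average per-step drop of the curve (the mean
    of the negated first differences; centering the curve leaves the
    differences unchanged). ``baseline_minus_curve`` is the step-wise
    (baseline - curve) difference of the mean-centered curves; a larger
    value means the explanation-ordered removal hurts accuracy more than
    the baseline at that step. ``early_window`` restricts both statistics
    to steps 1..early_window.
    """
    curve = result.step_accuracies
    if baseline is not None and baseline.step_accuracies.shape != curve.shape:
        raise ValueError("curves have mismatched lengths")
    if early_window is not None:
        curve = curve[: early_window + 1]
    decline = float(np.mean(-np.diff(curve)))
    if baseline is None:
        diff = np.zeros_like(curve)
    else:
        base = baseline.step_accuracies[: curve.shape[0]]
        diff = (base - base.mean()) - (curve - curve.mean())
    return DecayStatistic(decline, diff)


def select_model(
    candidates: Sequence[Tuple[object, MoRFResult]],
    early_window: int = 15,
) -> object:
    """The candidate whose curve decays fastest over the early steps."""
    if not candidates:
        raise ValueError("empty candidate list")
    n_steps = {r.n_steps for _, r in candidates}
    if len(n_steps) != 1:
        raise ValueError("candidates must share an identical protocol")
    best, best_stat = None, -np.inf
    for cand, res in candidates:
        stat = decay_statistic(res, early_window=early_window).mean_decline
        if stat > best_stat:
            best, best_stat = cand, stat
    return best


def select_xai_method(
    per_method: Dict[str, MoRFResult],
    baseline: MoRFResult,
    early_window: int = 15,
) -> str:
    """The method with the largest baseline-subtracted early decline.

    The score is the mean of (baseline - curve) over steps 1..early_window
    with both curves mean-centered, so adding a constant to every curve
    does not change the ranking.
    """
    if not per_method:
        raise ValueError("no methods to select from")
    scores = {}
    for name, res in per_method.items():
        diff = decay_statistic(res, baseline).baseline_minus_curve
        scores[name] = float(diff[1 : early_window + 1].mean())
    return max(scores, key=scores.get)
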
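"""Fillet segmentation, patch extraction, label inheritance and grouped splits.

The foreground fillet is segmented by thresholding the mean grayscale image
(band-averaged reflectance), cleaned with a 3x3 morphological opening, and
tiled into non-overlapping 64x64 patches.  A patch whose window contains more
than 5 % background pixels is discarded.  Every surviving patch inherits the
TVB-N / TVC labels of its source fillet, and train/validation/prediction
splits are drawn at the fillet level so no biological sample leaks across
subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage

from salmonhsi.hypercube import Hypercube

__all__ = [
    "SpoilageLabels",
    "RoiMask",
    "Patch",
    "SplitAssignment",
    "mean_grayscale",
    "threshold_segment",
    "morphological_open",
    "extract_patches",
    "split_by_sample",
    "SAMPLING_DAYS",
]

#: Storage-day sampling grid of the emulated study design.
SAMPLING_DAYS = (0, 1, 2, 3, 5, 7, 9, 11)


@dataclass(frozen=True)
class SpoilageLabels:
    """Freshness indices of one fillet, inherited by all its patches.

    tvbn: total volatile basic nitrogen, mg/100 g.
    tvc:  total viable count, lg CFU/g.
    """

    tvbn: float
    tvc: float
    temperature_c: int
    day: int

    def __post_init__(self) -> None:
        if self.tvbn < 0 or self.tvc < 0:
            raise ValueError("freshness indices must be non-negative")
        if self.temperature_c not in (4, 8):
            raise ValueError("storage temperature must be 4 or 8 degC")
        if self.day not in SAMPLING_DAYS:
            raise ValueError(f"day {self.day} not in sampling grid {SAMPLING_DAYS}")


@dataclass
class RoiMask:
    mask: np.ndarray          # binary, rows x cols
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass
class Patch:
    data: np.ndarray          # window x window x bands
    sample_id: str
    side: str
    origin: tuple[int, int]   # (row, col) of top-left corner
    labels: SpoilageLabels | None = None


@dataclass
class SplitAssignment:
    """sample_id -> split name; all patches of a sample share its split."""

    mapping: dict[str, str]
    ratios: tuple[float, float, float]
    seed: int

    def counts(self) -> dict[str, int]:
        out = {"train": 0, "validation": 0, "prediction": 0}
        for v in self.mapping.values():
            out[v] += 1
        return out

    def __getitem__(self, sample_id: str) -> str:
        return self.mapping[sample_id]


def mean_grayscale(cube: Hypercube) -> np.ndarray:
    """Per-pixel mean over all bands, on the reflectance scale."""
    return cube.data.mean(axis=2)


def threshold_segment(gray: np.ndarray, threshold: float) -> RoiMask:
    """Foreground where gray strictly exceeds the threshold.

    The strict inequality puts a boundary pixel equal to the threshold in the
    background, which makes masks at nested thresholds themselves nested.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    gray = np.asarray(gray)
    return RoiMask(gray > threshold, float(threshold))


_SQUARE3 = np.ones((3, 3), dtype=bool)


def morphological_open(mask: RoiMask, element: np.ndarray | None = None) -> RoiMask:
    """Binary opening (erosion then dilation), 3x3 square element by default."""
    element = _SQUARE3 if element is None else np.asarray(element, dtype=bool)
    opened = ndimage.binary_opening(mask.mask, structure=element)
    return RoiMask(opened, mask.threshold)


def extract_patches(
    cube: Hypercube,
    mask: RoiMask,
    labels: SpoilageLabels | None = None,
    window: int = 64,
    max_bg_fraction: float = 0.05,
) -> list[Patch]:
    """Tile the ROI with a non-overlapping window and keep pure patches.

    The grid is anchored at the top-left of the mask bounding box with stride
    equal to the window; trailing partial windows are dropped, and any window
    whose background fraction exceeds ``max_bg_fraction`` is discarded.
    """
    rows, cols = cube.spatial_shape
    if window > rows or window > cols:
        raise ValueError(f"window {window} exceeds spatial dims {rows}x{cols}")
    if mask.mask.shape != (rows, cols):
        raise ValueError("mask shape does not match cube")
    fg = np.argwhere(mask.mask)
    patches: list[Patch] = []
    if fg.size:
        r0, c0 = fg.min(axis=0)
        for r in range(r0, rows - window + 1, window):
            for c in range(c0, cols - window + 1, window):
                win = mask.mask[r:r + window, c:c + window]
                bg_fraction = 1.0 - win.mean()
                if bg_fraction <= max_bg_fraction:
                    patches.append(Patch(
                        data=cube.data[r:r + window, c:c + window, :],
                        sample_id=cube.sample_id,
                        side=cube.side,
                        origin=(int(r), int(c)),
                        labels=labels,
                    ))
    if not patches:
        warnings.warn(
            f"no patch of {cube.sample_id}/{cube.side} survived the "
            f"{max_bg_fraction:.0%} background-purity rule",
            stacklevel=2,
        )
    return patches


def split_by_sample(
    sample_ids,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    stratify_by: dict | None = None,
) -> SplitAssignment:
    """Grouped shuffle split of unique sample ids into train/validation/prediction.

    Validation and prediction counts are floored; the remainder goes to train
    (train is never starved).  Deterministic given the seed.

    ``stratify_by`` optionally maps each sample id to a stratum (e.g. its
    temperature x day design cell); held-out samples are then drawn
    round-robin across strata so every storage stage is represented in every
    split — essential when there are only a few replicates per cell.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    unique = sorted(set(map(str, sample_ids)))
    n = len(unique)
    if n < 3:
        raise ValueError("need at least 3 samples to form 3 splits")
    n_val = max(int(np.floor(n * ratios[1])), 1)
    n_pred = max(int(np.floor(n * ratios[2])), 1)
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        order = rng.permutation(n)
        shuffled = [unique[i] for i in order]
    else:
        pools: dict = {}
        for sid in unique:
            pools.setdefault(stratify_by[sid], []).append(sid)
        for stratum in pools:
            pools[stratum] = [pools[stratum][i]
                              for i in rng.permutation(len(pools[stratum]))]
        strata = sorted(pools, key=str)
        shuffled = []
        while any(pools.values()):          # round-robin across strata
            for stratum in strata:
                if pools[stratum]:
                    shuffled.append(pools[stratum].pop())
    mapping: dict[str, str] = {}
    if stratify_by is None:
        held = shuffled[n - n_val - n_pred:]
        val_ids, pred_ids = held[:n_val], held[n_val:]
    else:
        # alternate the stratum-interleaved head between the two held-out
        # splits so both cover the stratum range
        head = shuffled[: 2 * max(n_val, n_pred)]
        val_ids = head[0::2][:n_val]
        pred_ids = [s for s in head[1::2] if s not in val_ids][:n_pred]
        still = [s for s in shuffled if s not in val_ids and s not in pred_ids]
        pred_ids += still[len(still) - (n_pred - len(pred_ids)):] \
            if len(pred_ids) < n_pred else []
    held = set(val_ids) | set(pred_ids)
    for sid in shuffled:
        if sid not in held:
            mapping[sid] = "train"
    for sid in val_ids:
        mapping[sid] = "validation"
    for sid in pred_ids:
        mapping[sid] = "prediction"
    return SplitAssignment(mapping, tuple(ratios), int(seed))
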
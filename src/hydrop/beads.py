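"""Fluorescence image QC for barcoded hydrogel beads.

After split-pool barcoding, hybridising a FAM probe against a single one of
the 96 sub-barcodes should light up roughly 1/96 of beads; the measured
positive-bead fraction is therefore a direct check that barcoding was
faithful.  The pipeline: Otsu foreground/background segmentation, circle
detection by Hough transform restricted to the foreground, per-bead scoring
as center intensity minus mean background intensity (center scoring is
preferred over whole-bead integration because slight focus differences
mostly perturb intensity near the bead edge), and an exact binomial
confidence interval on the positive fraction with the denominator taken
from the brightfield image (or a manual count).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import beta as _beta
from skimage.filters import threshold_otsu
from skimage.morphology import erosion
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "BeadDetection",
    "segment_foreground",
    "detect_beads",
    "score_beads",
    "positive_fraction",
    "intensity_threshold_from_background",
]


@dataclass(frozen=True)
class BeadDetection:
    """One detected bead: center (row, col) in pixels, radius in pixels,
    background-subtracted center intensity (may be negative), positive flag."""

    center: tuple[int, int]
    radius: float
    center_intensity: float | None = None
    positive: bool | None = None


def segment_foreground(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Otsu segmentation: returns (mask, threshold).

    The threshold maximises the between-class variance of the grayscale
    histogram; the mask is the pixels strictly above it.  A constant image
    has no threshold and is an error.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    if np.unique(image).size < 2:
        raise ValueError("constant image: no Otsu threshold exists")
    thr = float(threshold_otsu(image))
    return image > thr, thr


def detect_beads(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    radius_range: tuple[int, int] = (5, 30),
    min_radius: int = 5,
    accumulator_threshold: float = 0.4,
) -> list[BeadDetection]:
    """Detect circular beads with a circle Hough transform on the foreground.

    The Hough accumulator is built from the foreground boundary; peaks are
    kept with non-maximum suppression so centers are at least one (minimum)
    radius apart.  ``min_radius`` gates out small punctate artifacts
    (~1 um debris); the effective lower radius bound is
    ``max(radius_range[0], min_radius)``.
    """
    image = np.asarray(image)
    if mask is None:
        mask, _ = segment_foreground(image)
    if not mask.any():
        return []
    lo = max(int(radius_range[0]), int(min_radius))
    hi = int(radius_range[1])
    if hi < lo:
        raise ValueError("radius_range upper bound below the minimum radius")
    edges = mask & ~erosion(mask)
    radii = np.arange(lo, hi + 1)
    hspaces = hough_circle(edges, radii, normalize=True)
    accums, cx, cy, found_r = hough_circle_peaks(
        hspaces,
        radii,
        min_xdistance=lo,
        min_ydistance=lo,
        threshold=accumulator_threshold,
        total_num_peaks=np.inf,
    )
    out: list[BeadDetection] = []
    h, w = image.shape
    for x, y, r in zip(cx, cy, found_r):
        if 0 <= y < h and 0 <= x < w:
            out.append(BeadDetection(center=(int(y), int(x)), radius=float(r)))
    return out


def score_beads(
    fluorescence_image: np.ndarray,
    detections: list[BeadDetection],
    background_mask: np.ndarray,
    center_radius: int = 2,
) -> list[BeadDetection]:
    """Attach background-subtracted center intensities.

    ``center_intensity`` is the mean over a small disc (default radius
    2 px, damping shot noise relative to the single center pixel) minus the
    mean intensity over ``background_mask`` (the complement of the
    foreground).  Values may be negative.
    """
    img = np.asarray(fluorescence_image, dtype=float)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not background_mask.any():
        raise ValueError("empty background mask")
    bg = img[background_mask].mean()
    h, w = img.shape
    yy, xx = np.ogrid[-center_radius : center_radius + 1, -center_radius : center_radius + 1]
    disc = yy**2 + xx**2 <= center_radius**2
    scored = []
    for det in detections:
        r, c = det.center
        r0, r1 = max(0, r - center_radius), min(h, r + center_radius + 1)
        c0, c1 = max(0, c - center_radius), min(w, c + center_radius + 1)
        sub = img[r0:r1, c0:c1]
        d = disc[
            r0 - (r - center_radius) : disc.shape[0] - ((r + center_radius + 1) - r1),
            c0 - (c - center_radius) : disc.shape[1] - ((c + center_radius + 1) - c1),
        ]
        scored.append(replace(det, center_intensity=float(sub[d].mean() - bg)))
    return scored


def intensity_threshold_from_background(
    fluorescence_image: np.ndarray, background_mask: np.ndarray, k: float = 3.0
) -> float:
    """Default positive/negative cut on background-subtracted intensity:
    ``k`` background standard deviations above zero (background mean cancels
    in the subtraction)."""
    img = np.asarray(fluorescence_image, dtype=float)
    bg = img[np.asarray(background_mask, dtype=bool)]
    if bg.size == 0:
        raise ValueError("empty background mask")
    return float(k * bg.std())


def positive_fraction(
    detections_fluo: list[BeadDetection],
    total_beads: int | list[BeadDetection],
    intensity_threshold: float,
    confidence: float = 0.95,
) -> dict:
    """Positive-bead fraction with an exact (Clopper-Pearson) binomial CI.

    ``detections_fluo`` must be scored; a bead is positive when its
    background-subtracted center intensity reaches the threshold.
    ``total_beads`` is the denominator: the brightfield detection list or a
    manually counted integer.
    """
    total = total_beads if isinstance(total_beads, int) else len(total_beads)
    if total <= 0:
        raise ValueError("total bead count must be positive")
    positives = sum(
        1
        for d in detections_fluo
        if d.center_intensity is not None and d.center_intensity >= intensity_threshold
    )
    frac = positives / total
    alpha = 1.0 - confidence
    lo = _beta.ppf(alpha / 2, positives, total - positives + 1) if positives > 0 else 0.0
    hi = (
        _beta.ppf(1 - alpha / 2, positives + 1, total - positives)
        if positives < total
        else 1.0
    )
    return {
        "n_positive": positives,
        "n_total": total,
        "fraction": frac,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "confidence": confidence,
        "intensity_threshold": float(intensity_threshold),
    }


def write_detections_csv(detections: list[BeadDetection], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "center_row": d.center[0],
                "center_col": d.center[1],
                "radius": d.radius,
                "intensity": d.center_intensity,
                "positive": d.positive,
            }
            for d in detections
        ]
    ).to_csv(path, index=False)


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
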
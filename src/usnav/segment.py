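"""Vessel mask post-processing: confidence threshold, region-size filter, IoU.

The intraoperative recognizer emits a per-pixel vessel confidence map.  Only
pixels with confidence strictly above the cutoff (default 0.5) count as
vessel, and 8-connected regions smaller than 40 or larger than 50,000 pixels
are discarded as misidentifications.  A classical intensity-based segmenter
stands in for the trained network on synthetic frames, where vessels are
hypoechoic (dark).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from .reconstruct import UltrasoundFrame

#: default recognizer filters
CONFIDENCE_CUTOFF = 0.5
MIN_REGION_PX = 40
MAX_REGION_PX = 50_000

_STRUCT8 = np.ones((3, 3), dtype=bool)


def threshold_confidence(prob: np.ndarray, cutoff: float = CONFIDENCE_CUTOFF) -> np.ndarray:
    """Binary vessel mask: pixel labelled 1 iff confidence strictly > cutoff."""
    prob = np.asarray(prob)
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    if prob.size and (prob.min() < 0.0 or prob.max() > 1.0):
        raise ValueError("confidence values must lie in [0, 1]")
    return (prob > cutoff).astype(np.uint8)


def filter_regions(mask: np.ndarray,
                   min_px: int = MIN_REGION_PX,
                   max_px: int = MAX_REGION_PX) -> np.ndarray:
    """Drop 8-connected components with < min_px or > max_px pixels.

    Surviving components are preserved bit-exactly; the operation is
    idempotent and never adds pixels.
    """
    if min_px > max_px:
        raise ValueError("min_px must not exceed max_px")
    mask = (np.asarray(mask) > 0)
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask.astype(np.uint8)
    sizes = np.bincount(labels.ravel())
    keep = (sizes >= min_px) & (sizes <= max_px)
    keep[0] = False
    return keep[labels].astype(np.uint8)


def segment_intensity(frame: UltrasoundFrame,
                      dark_cutoff: float = 0.5) -> np.ndarray:
    """Vessel confidence from intensity alone (vessels are dark).

    Confidence decreases monotonically with pixel intensity and crosses the
    0.5 decision level exactly at intensity ``dark_cutoff``, so the classical
    stand-in plugs into the same thresholding rule as a learned recognizer.
    """
    img = np.asarray(frame.image, dtype=float)
    if img.size == 0:
        raise ValueError("frame image is empty")
    if img.max() > 1.0:        # 8-bit raster
        img = img / 255.0
    return np.clip(0.5 + dark_cutoff - img, 0.0, 1.0)


def compute_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary masks; 1.0 when both are empty."""
    pred = np.asarray(pred) > 0
    truth = np.asarray(truth) > 0
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    union = np.logical_or(pred, truth).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, truth).sum() / union)


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Inner boundary (pixels with a background 8-neighbour) of a binary mask.

    The registration pipeline reconstructs from boundary pixels so the
    ultrasound cloud samples the vessel *surface*, matching the CT operand.
    """
    mask = np.asarray(mask) > 0
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT8, border_value=0)
    return (mask & ~eroded).astype(np.uint8)


def segment_frame(frame: UltrasoundFrame,
                  dark_cutoff: float = 0.5,
                  confidence_cutoff: float = CONFIDENCE_CUTOFF,
                  min_px: int = MIN_REGION_PX,
                  max_px: int = MAX_REGION_PX) -> np.ndarray:
    """Full per-frame chain: intensity confidence -> threshold -> size filter."""
    prob = segment_intensity(frame, dark_cutoff)
    return filter_regions(threshold_confidence(prob, confidence_cutoff),
                          min_px, max_px)
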
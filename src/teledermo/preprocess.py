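"""Artifact removal and lesion segmentation.

Turns an RGB dermoscopy image into a cleaned image (hair strokes removed,
median-filtered) and a single-component binary lesion mask with the geometry
needed downstream: centroid, area, an ordered perimeter trace and its length.

Hair removal follows the classic razor approach: thin dark curvilinear
structures are detected as pixels where a grayscale morphological closing
with line structuring elements (orientations 0/45/90/135 degrees) exceeds
the original by a threshold, then repaired from the closing response.
Segmentation thresholds the approximation band of a single-level 2-D
wavelet decomposition (Otsu), reconstructs to full resolution and keeps the
largest connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, perimeter_crofton
from skimage.morphology import disk

from .errors import FormatError, SegmentationError


@dataclass
class CleanImage:
    """Artifact-free image: RGB, grayscale (0-255 float) and the hair mask."""

    rgb: np.ndarray        # (H, W, 3) uint8
    gray: np.ndarray       # (H, W) float, 0..255
    hair_mask: np.ndarray  # (H, W) bool


@dataclass
class LesionMask:
    """Single-component lesion mask and its boundary geometry.

    ``perimeter_points`` is the ordered, closed, subpixel boundary trace in
    0-based (row, col) coordinates (first point not repeated at the end);
    ``perimeter_length`` is the Crofton perimeter estimate of the mask
    (the traced polygon itself hugs the pixel staircase and would
    overestimate smooth boundaries by ~6 %).
    """

    mask: np.ndarray             # (H, W) bool
    centroid: tuple[float, float]
    area: int
    perimeter_points: np.ndarray  # (n, 2) float
    perimeter_length: float


def _line_footprints(length: int) -> list[np.ndarray]:
    return [
        np.ones((1, length), dtype=bool),
        np.ones((length, 1), dtype=bool),
        np.eye(length, dtype=bool),
        np.fliplr(np.eye(length, dtype=bool)),
    ]


def remove_hairs(image: np.ndarray, hair_threshold: float = 15.0,
                 line_length: int = 9) -> CleanImage:
    """Detect and repair dark hair strokes, then median-filter the image.

    A pixel belongs to a hair when both the maximal directional closing of
    the grayscale image and a 7x7 median filter exceed the original by more
    than ``hair_threshold`` gray levels: the closing finds dark structures
    thinner than the line element, and the median response (edge-preserving
    but line-erasing) rejects the lesion's own boundary. Flagged pixels are
    replaced, per channel, by the maximal directional closing (the
    orientation crossing the stroke), after which a 3x3 median filter is
    applied to the whole image.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError("expected an RGB raster of shape (H, W, 3)")
    if min(image.shape[:2]) < 32:
        raise FormatError("image must be at least 32x32")

    gray = rgb2gray(image) * 255.0
    footprints = _line_footprints(line_length)
    closings = np.stack(
        [ndimage.grey_closing(gray, footprint=fp) for fp in footprints])
    max_resp = closings.max(axis=0) - gray
    # a 7x7 median erases thin dark lines but preserves region edges, so
    # requiring a median response too rejects the lesion's own boundary ring
    median_resp = ndimage.median_filter(gray, size=7) - gray
    hair_mask = (max_resp > hair_threshold) & (median_resp > hair_threshold)
    if hair_mask.any():
        hair_mask = ndimage.binary_dilation(hair_mask, iterations=1)

    repaired = image.astype(float).copy()
    if hair_mask.any():
        for ch in range(3):
            ch_clos = np.stack([
                ndimage.grey_closing(image[:, :, ch].astype(float),
                                     footprint=fp) for fp in footprints
            ]).max(axis=0)
            plane = repaired[:, :, ch]
            plane[hair_mask] = ch_clos[hair_mask]

    for ch in range(3):
        repaired[:, :, ch] = ndimage.median_filter(repaired[:, :, ch], size=3)

    rgb = np.clip(np.rint(repaired), 0, 255).astype(np.uint8)
    return CleanImage(rgb=rgb, gray=rgb2gray(rgb) * 255.0,
                      hair_mask=hair_mask)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected component (ties: first in raster order)."""
    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        raise SegmentationError("no lesion detected")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))  # argmax -> lowest label on ties


def trace_perimeter(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Ordered closed subpixel boundary of a binary mask and its length.

    Uses the marching-squares contour at level 0.5; the longest closed
    contour is taken as the outer boundary.
    """
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("mask has no traceable boundary")
    contour = max(contours, key=len)
    closed = np.allclose(contour[0], contour[-1])
    points = contour[:-1] if closed else contour
    steps = np.diff(np.vstack([points, points[:1]]), axis=0)
    length = float(np.sqrt((steps**2).sum(axis=1)).sum())
    return points, length


def mask_geometry(mask: np.ndarray) -> LesionMask:
    """Build a :class:`LesionMask` (centroid, area, trace) from a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask")
    coords = np.argwhere(mask)
    centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    points, _ = trace_perimeter(mask)
    # the traced polygon hugs the pixel staircase and overestimates smooth
    # boundaries by ~6 %; the Crofton estimate is unbiased for blobs
    length = float(perimeter_crofton(mask, directions=4))
    return LesionMask(mask=mask, centroid=centroid, area=int(mask.sum()),
                      perimeter_points=points, perimeter_length=length)


def segment_lesion(clean: CleanImage, wavelet: str = "db4",
                   opening_radius: int = 2) -> LesionMask:
    """Wavelet-threshold segmentation of the (dark) lesion.

    Single-level 2-D decomposition of the grayscale image; Otsu threshold
    on the approximation band (lesion = below threshold, i.e. pigmented);
    the half-resolution mask is mapped back to full resolution with the
    analysis filter's phase offset compensated, holes filled, a
    morphological opening applied, and the largest component kept.
    """
    gray = clean.gray
    wav = pywt.Wavelet(wavelet)
    cA, _ = pywt.dwt2(gray, wav, mode="symmetric")
    if float(cA.max() - cA.min()) < 1e-9:
        raise SegmentationError("no lesion detected (uniform image)")
    t = threshold_otsu(cA)
    small = cA < t
    if not small.any() or small.all():
        raise SegmentationError("no lesion detected")

    # upsample x2; symmetric padding shifts the approximation band by
    # (dec_len - 2) / 2 coefficients, i.e. dec_len - 2 full-res pixels
    up = np.kron(small, np.ones((2, 2), dtype=bool))
    shift = wav.dec_len - 2
    h, w = gray.shape
    coarse = np.zeros((h, w), dtype=bool)
    src = up[shift:shift + h, shift:shift + w]
    coarse[:src.shape[0], :src.shape[1]] = src

    coarse = ndimage.binary_fill_holes(coarse)
    if opening_radius > 0:
        coarse = ndimage.binary_opening(coarse,
                                        structure=disk(opening_radius))
    if not coarse.any():
        raise SegmentationError("no lesion detected")
    coarse = _largest_component(coarse)

    # full-resolution refinement: the approximation-band mask locates the
    # lesion; re-thresholding the grayscale image restores the boundary
    # detail the half-resolution band cannot represent
    t_full = (threshold_otsu(gray) if float(gray.max() - gray.min()) > 1e-9
              else None)
    if t_full is not None:
        fine = ndimage.binary_fill_holes(gray < t_full)
        lab = label(fine, connectivity=2)
        overlap = np.bincount(lab[coarse].ravel(), minlength=lab.max() + 1)
        overlap[0] = 0
        if overlap.any():
            refined = lab == int(np.argmax(overlap))
            if refined.sum() >= 0.25 * coarse.sum():
                coarse = refined
    return mask_geometry(coarse)
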
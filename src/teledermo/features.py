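"""Texture and morphological lesion features, and the 7-element profile vector.

The seven selected features that populate a DermoFeature Profile are the
weighted intensity-difference frequency (WIDF) at inter-sample distance 10
and orientations 0/45/90/135 degrees, the maximum Feret diameter, the
box-counting geometric index of the boundary, and the contour steepness
(variance of the radial distances normalized by their mean). Solidity and
the pigment-deviation statistics are computed alongside as extras.

WIDF weights the relative frequency of each absolute intensity difference
``i`` between pixel pairs at offset (delta, theta) by ``(xi - i)``, so small
differences (smooth texture) score close to 1::

    WIDF = sum_i (xi - i) * f_i / xi,   sum_i f_i = 1.

Both endpoints of a pair must lie inside the lesion mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.color import rgb2hsv
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.morphology import disk

from .errors import InsufficientPairsError, ParameterError, ScalingError
from .preprocess import CleanImage, LesionMask

#: Fixed column order of the seven selected features.
FEATURE_NAMES = (
    "widf_10_0",
    "widf_10_45",
    "widf_10_90",
    "widf_10_135",
    "diameter",
    "geometric_index",
    "contour_steepness",
)

#: The four WIDF orientations (degrees) at inter-sample distance 10.
WIDF_THETAS = (0, 45, 90, 135)
WIDF_DELTA = 10


@dataclass(frozen=True)
class WIDFConfig:
    """Offset and quantization of one WIDF measurement."""

    delta: int = WIDF_DELTA
    theta: int = 0          # degrees, counterclockwise from the row axis
    xi: int = 256           # number of intensity levels

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ParameterError("delta must be >= 1")
        if self.xi < 2:
            raise ParameterError("xi must be >= 2")

    @property
    def offset(self) -> tuple[int, int]:
        """(d_row, d_col) pixel offset of the pair."""
        th = np.deg2rad(self.theta)
        return (int(round(self.delta * np.cos(th))),
                int(round(self.delta * np.sin(th))))


@dataclass
class FeatureVector:
    """Scaled 7-feature vector plus raw values and unscaled extras."""

    values: np.ndarray                 # 7 floats in [0, 1], FEATURE_NAMES order
    raw: dict[str, float]              # unscaled selected features
    extras: dict[str, float] = field(default_factory=dict)  # S_I, V_M, V_V


def widf(gray: np.ndarray, mask: np.ndarray, cfg: WIDFConfig) -> float:
    """Weighted intensity-difference frequency inside *mask* at one offset."""
    g = np.clip(np.rint(np.asarray(gray, dtype=float)), 0,
                cfg.xi - 1).astype(np.int64)
    mask = np.asarray(mask, dtype=bool)
    dr, dc = cfg.offset
    h, w = g.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise InsufficientPairsError("offset exceeds image extent")

    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = np.s_[r0:r1, c0:c1]
    b = np.s_[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = mask[a] & mask[b]
    if not valid.any():
        raise InsufficientPairsError(
            f"no in-mask pixel pair at offset ({dr}, {dc})")
    diffs = np.abs(g[a] - g[b])[valid]
    counts = np.bincount(diffs, minlength=cfg.xi)[:cfg.xi]
    f = counts / counts.sum()
    weights = cfg.xi - np.arange(cfg.xi)
    return float((weights * f).sum() / cfg.xi)


def solidity_index(lesion: LesionMask) -> float:
    """PP^2 / (4 pi A_t): 1 for a circle, larger for irregular outlines."""
    if lesion.perimeter_length <= 0 or lesion.area <= 0:
        raise ParameterError("degenerate mask")
    return float(lesion.perimeter_length ** 2 / (4.0 * np.pi * lesion.area))


def radial_distances(lesion: LesionMask) -> np.ndarray:
    """Centroid-to-perimeter distances, in trace order."""
    pts = np.asarray(lesion.perimeter_points, dtype=float)
    if pts.shape[0] < 3:
        raise ParameterError("need at least 3 perimeter points")
    c = np.asarray(lesion.centroid, dtype=float)
    return np.sqrt(((pts - c) ** 2).sum(axis=1))


def contour_steepness(lesion: LesionMask) -> float:
    """Population variance of the radial distances over their mean."""
    d = radial_distances(lesion)
    m = d.mean()
    if m <= 0:
        raise ParameterError("mean radial distance is zero")
    return float(d.var() / m)


def geometric_index(lesion: LesionMask) -> float:
    """Box-counting complexity of the lesion boundary, in [0, 2].

    The boundary pixels are covered with dyadic grids (box side halving
    from half the boundary's bounding-box side down to 2 px, grids anchored
    at the bounding-box origin); the index is the least-squares slope of
    log N_B against log L_B, where L_B is the inverse box side in units of
    the bounding-box side. ~1 for smooth curves, larger for fractal borders.
    """
    mask = lesion.mask
    boundary = mask & ~binary_erosion(mask, structure=disk(1))
    coords = np.argwhere(boundary)
    if coords.shape[0] < 4:
        raise ParameterError("boundary too small for box counting")
    origin = coords.min(axis=0)
    extent = coords.max(axis=0) - origin + 1
    side = float(extent.max())

    scales, counts = [], []
    s = side / 2.0
    while s >= 2.0:
        boxes = np.unique(np.floor((coords - origin) / s), axis=0)
        scales.append(s)
        counts.append(len(boxes))
        s /= 2.0
    if len(counts) < 2:
        raise ParameterError("boundary bounding box too small")
    # the two coarsest grids are area-dominated (a handful of boxes covers
    # everything); fit the scaling law over the genuinely fine grids
    fine = [i for i, sc in enumerate(scales) if sc <= side / 8.0]
    if len(fine) < 2:
        fine = list(range(len(scales)))
    log_l = [np.log(side / scales[i]) for i in fine]
    log_n = [np.log(counts[i]) for i in fine]
    slope = np.polyfit(log_l, log_n, 1)[0]
    return float(np.clip(slope, 0.0, 2.0))


def pigment_deviation(rgb: np.ndarray, lesion: LesionMask) -> tuple[float, float]:
    """Mean and population variance of the V-channel gradient magnitude
    sampled on a ~2-px-wide band around the lesion boundary."""
    v = rgb2hsv(rgb)[:, :, 2]
    gy, gx = np.gradient(v)
    gm = np.hypot(gy, gx)
    band = binary_dilation(lesion.mask, structure=disk(1)) & ~binary_erosion(
        lesion.mask, structure=disk(1))
    vals = gm[band]
    if vals.size == 0:
        raise ParameterError("empty boundary band")
    return float(vals.mean()), float(vals.var())


def diameter(lesion: LesionMask) -> float:
    """Maximum Feret diameter: max pairwise distance of perimeter points."""
    pts = np.asarray(lesion.perimeter_points, dtype=float)
    if pts.shape[0] < 2:
        raise ParameterError("need at least 2 perimeter points")
    if pts.shape[0] > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) point sets
            pass
    return float(pdist(pts).max())


class FeatureScaler:
    """Per-feature min-max scaler fit on a reference corpus.

    Profile values share a single watermark-strength weight, so the seven
    features must live on one [0, 1] scale; the scaler is fit on the
    training corpus and serialized with the classifier.
    """

    def __init__(self, mins: np.ndarray | None = None,
                 maxs: np.ndarray | None = None) -> None:
        self.mins = None if mins is None else np.asarray(mins, dtype=float)
        self.maxs = None if maxs is None else np.asarray(maxs, dtype=float)

    def fit(self, table: pd.DataFrame | np.ndarray) -> "FeatureScaler":
        if isinstance(table, pd.DataFrame):
            table = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
        table = np.asarray(table, dtype=float)
        self.mins = table.min(axis=0)
        self.maxs = table.max(axis=0)
        if np.any(self.maxs <= self.mins):
            raise ScalingError("constant feature column; max must exceed min")
        return self

    def transform(self, values: np.ndarray, clip: bool = True) -> np.ndarray:
        if self.mins is None:
            raise ScalingError("scaler has not been fit")
        scaled = (np.asarray(values, dtype=float) - self.mins) / (
            self.maxs - self.mins)
        return np.clip(scaled, 0.0, 1.0) if clip else scaled

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "feature_names": list(FEATURE_NAMES),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureScaler":
        doc = json.loads(Path(path).read_text())
        return cls(np.array(doc["mins"]), np.array(doc["maxs"]))


def compute_raw_features(clean: CleanImage, lesion: LesionMask) -> dict[str, float]:
    """All selected features (unscaled) plus the recorded extras."""
    raw = {}
    for theta in WIDF_THETAS:
        cfg = WIDFConfig(delta=WIDF_DELTA, theta=theta)
        raw[f"widf_{WIDF_DELTA}_{theta}"] = widf(clean.gray, lesion.mask, cfg)
    raw["diameter"] = diameter(lesion)
    raw["geometric_index"] = geometric_index(lesion)
    raw["contour_steepness"] = contour_steepness(lesion)
    v_m, v_v = pigment_deviation(clean.rgb, lesion)
    raw["solidity"] = solidity_index(lesion)
    raw["pigment_mean"] = v_m
    raw["pigment_var"] = v_v
    return raw


def extract_feature_vector(clean: CleanImage, lesion: LesionMask,
                           scaler: FeatureScaler) -> FeatureVector:
    """Compute, select and min-max scale the seven profile features."""
    raw = compute_raw_features(clean, lesion)
    selected = np.array([raw[name] for name in FEATURE_NAMES])
    scaled = scaler.transform(selected)
    return FeatureVector(
        values=scaled,
        raw={name: raw[name] for name in FEATURE_NAMES},
        extras={k: raw[k] for k in ("solidity", "pigment_mean", "pigment_var")},
    )


def feature_table(rows: list[dict[str, float]],
                  labels: list[str]) -> pd.DataFrame:
    """Assemble raw-feature dicts into the canonical CSV column order."""
    df = pd.DataFrame(rows)[list(FEATURE_NAMES)]
    df["label"] = labels
    return df
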
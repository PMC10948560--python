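"""Deterministic generators of synthetic dermoscopy data and carrier audio.

Every downstream stage of the store-and-forward pipeline (hair removal,
segmentation, feature extraction, watermarking, classification) is exercised
against data produced here, so each generator is a pure function of its
parameters and an integer seed.

Two kinds of objects are produced:

* pigmented-lesion images with ground-truth masks, in four class regimes
  (benign keratoses, basal cell carcinoma, melanoma, melanocytic nevi) whose
  texture, border irregularity, edge sharpness and size are chosen so that
  the seven selected lesion features separate the classes;
* speech-like one-dimensional carrier signals ("recorded patient-information
  signals", RPS) of configurable length and sample rate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import signal as sp_signal
from scipy.io import wavfile
from scipy.ndimage import binary_dilation, gaussian_filter

from .errors import ParameterError

#: Names of the four lesion classes, in canonical order.
CLASS_LABELS = (
    "melanocytic_nevus",
    "benign_keratosis",
    "basal_cell_carcinoma",
    "melanoma",
)

#: Per-class parameter regimes. Means are spread so that the seven selected
#: features (four texture statistics, diameter, border-complexity index and
#: contour steepness) are separable; the per-sample jitter applied by
#: :func:`generate_class_set` is small relative to the between-class spread.
CLASS_REGIMES: dict[str, dict[str, float]] = {
    "melanocytic_nevus": dict(
        lesion_radius=28.0, border_irregularity=0.04,
        texture_contrast=8.0, edge_sharpness=2.0,
    ),
    "benign_keratosis": dict(
        lesion_radius=33.0, border_irregularity=0.12,
        texture_contrast=20.0, edge_sharpness=1.2,
    ),
    "basal_cell_carcinoma": dict(
        lesion_radius=38.0, border_irregularity=0.22,
        texture_contrast=32.0, edge_sharpness=0.7,
    ),
    "melanoma": dict(
        lesion_radius=40.0, border_irregularity=0.30,
        texture_contrast=46.0, edge_sharpness=0.4,
    ),
}

_SKIN_RGB = np.array([205.0, 175.0, 155.0])
_LESION_RGB = np.array([95.0, 62.0, 52.0])
#: Column-to-row semi-axis ratio of the base ellipse.
_ASPECT = 0.85


@dataclass(frozen=True)
class LesionParams:
    """Parameters of one synthetic lesion image.

    ``border_irregularity`` is the dimensionless amplitude of the radial
    perturbation of the base ellipse; ``texture_contrast`` is the standard
    deviation (gray levels) of the interior texture field;
    ``edge_sharpness`` controls the steepness of the boundary luminance
    transition (larger = sharper); ``hair_count`` dark curvilinear strokes
    are overlaid.
    """

    class_label: str = "melanocytic_nevus"
    image_size: tuple[int, int] = (160, 160)
    lesion_radius: float = 35.0
    border_irregularity: float = 0.1
    texture_contrast: float = 20.0
    edge_sharpness: float = 1.0
    hair_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.lesion_radius <= 0:
            raise ParameterError("lesion_radius must be positive")
        for name in ("border_irregularity", "texture_contrast",
                     "edge_sharpness"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.hair_count < 0:
            raise ParameterError("hair_count must be >= 0")
        # lesion (including worst-case radial excursion) must fit with margin
        reach = self.lesion_radius * (1.0 + 2.0 * self.border_irregularity)
        if reach + 5.0 > min(h, w) / 2.0:
            raise ParameterError(
                "lesion does not fit inside the image with a 5-pixel margin"
            )


@dataclass
class SyntheticSample:
    """One generated image with its ground truth."""

    image: np.ndarray            # (H, W, 3) uint8
    truth_mask: np.ndarray       # (H, W) bool, one connected component
    hair_mask: np.ndarray        # (H, W) bool, union of overlaid strokes
    class_label: str
    params: LesionParams = field(repr=False, default=None)


def _radial_modulation(rng: np.random.Generator, phi: np.ndarray,
                       irregularity: float,
                       n_harmonics: int = 6) -> np.ndarray:
    """Zero-mean, unit-RMS harmonic mix g(phi) used to perturb the border.

    Harmonics start at wavenumber 2 so the perturbed boundary stays
    star-shaped (a single connected blob) and the centroid barely moves.
    More irregular regimes receive extra high-wavenumber harmonics, so the
    boundary's box-counting complexity grows with its amplitude.
    """
    amps = rng.uniform(0.3, 1.0, size=n_harmonics)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harmonics)
    g = np.zeros_like(phi)
    for k, (a, p) in enumerate(zip(amps, phases), start=2):
        g += a * np.cos(k * phi + p)
    n_fine = int(round(40.0 * irregularity))  # 0 for near-elliptic lesions
    fine_amps = rng.uniform(0.2, 0.45, size=max(n_fine, 1))
    fine_phases = rng.uniform(0.0, 2.0 * np.pi, size=max(n_fine, 1))
    for j in range(n_fine):
        g += fine_amps[j] * np.cos((9 + 2 * j) * phi + fine_phases[j])
    rms = np.sqrt(np.mean(g[::7] ** 2)) if g.size > 50 else np.sqrt(np.mean(g**2))
    return g / max(rms, 1e-12)


def _bezier_stroke(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one quadratic Bezier arc as a boolean stroke mask."""
    h, w = shape
    pts = rng.uniform([0, 0], [h - 1, w - 1], size=(3, 2))
    t = np.linspace(0.0, 1.0, 4 * (h + w))[:, None]
    curve = ((1 - t) ** 2 * pts[0] + 2 * (1 - t) * t * pts[1] + t**2 * pts[2])
    rr = np.clip(np.rint(curve[:, 0]).astype(int), 0, h - 1)
    cc = np.clip(np.rint(curve[:, 1]).astype(int), 0, w - 1)
    stroke = np.zeros(shape, dtype=bool)
    stroke[rr, cc] = True
    width = int(rng.integers(1, 4))  # 1-3 px
    if width >= 3:
        stroke = binary_dilation(stroke, iterations=1)
    elif width == 2:
        stroke = binary_dilation(stroke, structure=np.ones((2, 2), bool))
    return stroke


def generate_lesion(params: LesionParams) -> SyntheticSample:
    """Render one pigmented blob on a skin-toned background.

    The boundary is a radially perturbed ellipse; the interior carries a
    smooth texture field scaled by ``texture_contrast``; ``hair_count``
    dark curvilinear strokes (40-60 % darker than the underlying pixel) are
    overlaid last. Identical parameters and seed give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    b_ax = params.lesion_radius * _ASPECT   # row semi-axis
    a_ax = params.lesion_radius             # col semi-axis

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    rho = np.sqrt(((yy - cy) / b_ax) ** 2 + ((xx - cx) / a_ax) ** 2)
    if params.border_irregularity > 0:
        phi = np.arctan2(yy - cy, xx - cx)
        g = np.clip(_radial_modulation(rng, phi,
                                       params.border_irregularity),
                    -2.0, 2.0)
        boundary = 1.0 + params.border_irregularity * g
        boundary = np.maximum(boundary, 0.25)
    else:
        rng.spawn(1)  # keep stream alignment with the perturbed branch
        boundary = np.ones_like(rho)

    truth_mask = rho <= boundary

    # signed distance from the (perturbed) boundary, in approximate pixels
    d = (boundary - rho) * params.lesion_radius
    blend = 1.0 / (1.0 + np.exp(-np.clip(d * params.edge_sharpness, -40, 40)))

    skin = _SKIN_RGB[None, None, :] + rng.normal(0.0, 2.0, size=(h, w, 1))
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
    texture = texture / max(texture.std(), 1e-12) * params.texture_contrast
    lesion = _LESION_RGB[None, None, :] + texture[:, :, None] * np.array(
        [1.0, 0.9, 0.9]
    )
    image = skin * (1.0 - blend[:, :, None]) + lesion * blend[:, :, None]

    hair_mask = np.zeros((h, w), dtype=bool)
    for _ in range(params.hair_count):
        stroke = _bezier_stroke(rng, (h, w))
        darkness = rng.uniform(0.4, 0.6)
        image[stroke] *= 1.0 - darkness
        hair_mask |= stroke

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return SyntheticSample(image=image, truth_mask=truth_mask,
                           hair_mask=hair_mask, class_label=params.class_label,
                           params=params)


def generate_class_set(n_per_class: int, seed: int = 0,
                       image_size: tuple[int, int] = (160, 160),
                       hair_count: int = 3) -> list[SyntheticSample]:
    """Generate ``4 * n_per_class`` samples, grouped class by class.

    Each sample jitters its class regime by ~5 % so that within-class
    variance stays well below the between-class spread of the regimes.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    master = np.random.default_rng(seed)
    samples: list[SyntheticSample] = []
    for label in CLASS_LABELS:
        regime = CLASS_REGIMES[label]
        for _ in range(n_per_class):
            jit = np.clip(master.normal(1.0, 0.05, size=4), 0.9, 1.1)
            params = LesionParams(
                class_label=label,
                image_size=image_size,
                lesion_radius=regime["lesion_radius"] * jit[0],
                border_irregularity=max(
                    regime["border_irregularity"] * jit[1], 0.0),
                texture_contrast=max(regime["texture_contrast"] * jit[2], 0.0),
                edge_sharpness=max(regime["edge_sharpness"] * jit[3], 0.05),
                hair_count=hair_count,
                seed=int(master.integers(0, 2**31 - 1)),
            )
            samples.append(generate_lesion(params))
    return samples


def generate_rps(n_samples: int, sample_rate: float = 8000.0,
                 seed: int = 0) -> np.ndarray:
    """Synthesize a speech-like carrier signal.

    A stack of amplitude-modulated harmonics of a randomly drawn pitch,
    plus band-limited noise; zero-mean, peak amplitude < 1. The spectral
    envelope mimics voiced speech (energy below ~3 kHz, syllabic-rate
    amplitude modulation) without attempting intelligibility.
    """
    if n_samples < 49:
        raise ParameterError(
            "carrier must hold at least 49 samples (one 7x7 profile)")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / float(sample_rate)

    f0 = rng.uniform(100.0, 160.0)
    # syllabic-rate (~3 Hz) random envelope, strictly positive
    env_noise = rng.standard_normal(n_samples)
    n_env = max(int(round(sample_rate / 3.0)), 8)
    env = gaussian_filter(env_noise, sigma=n_env / 4.0, mode="reflect")
    env = 0.4 + 0.6 * (env - env.min()) / max(np.ptp(env), 1e-12)

    x = np.zeros(n_samples)
    k = 1
    while k * f0 < 0.45 * sample_rate and k <= 14:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        # mild per-harmonic vibrato keeps the spectrum speech-like
        x += (1.0 / k) * np.sin(2.0 * np.pi * k * f0 * t + phase)
        k += 1
    x *= env

    white = rng.standard_normal(n_samples)
    if n_samples >= 32:
        cutoff = min(3000.0, 0.4 * sample_rate)
        sos = sp_signal.butter(4, cutoff, fs=sample_rate, output="sos")
        coloured = sp_signal.sosfiltfilt(sos, white)
    else:
        coloured = white
    x += 0.08 * coloured / max(np.std(coloured), 1e-12)

    x -= x.mean()
    x /= np.abs(x).max() * 1.02
    x -= x.mean()  # renormalisation preserves the zero mean to ~1e-18
    return x


# ---------------------------------------------------------------------------
# file-system interface

def save_sample(sample: SyntheticSample, directory: str | Path,
                stem: str) -> tuple[Path, Path]:
    """Write ``<stem>.png`` and ``<stem>_mask.png`` under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / f"{stem}.png"
    mask_path = directory / f"{stem}_mask.png"
    iio.imwrite(img_path, sample.image)
    iio.imwrite(mask_path, (sample.truth_mask * 255).astype(np.uint8))
    return img_path, mask_path


def write_manifest(samples: list[SyntheticSample], path: str | Path) -> Path:
    """Write a CSV manifest of labels and generating parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fields = ["index", "class_label", "lesion_radius", "border_irregularity",
              "texture_contrast", "edge_sharpness", "hair_count", "seed"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        for i, s in enumerate(samples):
            p = s.params
            writer.writerow([i, s.class_label, p.lesion_radius,
                             p.border_irregularity, p.texture_contrast,
                             p.edge_sharpness, p.hair_count, p.seed])
    return path


def write_wav(path: str | Path, samples: np.ndarray,
              sample_rate: float = 8000.0, pcm16: bool = False) -> Path:
    """Write a WAV file; float32 by default to avoid quantization."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if pcm16:
        data = np.clip(samples, -1.0, 1.0)
        wavfile.write(path, int(sample_rate),
                      np.rint(data * 32767).astype(np.int16))
    else:
        wavfile.write(path, int(sample_rate), samples.astype(np.float32))
    return path


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file as float64 samples in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    else:
        data = data.astype(np.float64)
    return data, rate
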
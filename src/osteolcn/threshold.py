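"""Non-deep-learning segmentation pipelines for LCN confocal scans.

Two pipelines share pre- and post-processing and differ only in the core
operator used to refine the dendrite (canaliculi) mask:

1. Gaussian pre-filter (sigma 2) to suppress noise.
2. A binary split at intensity 70 separates foreground from background; the
   foreground is divided into an osteocyte candidate (large compact blobs,
   isolated by a morphological opening that erases thin structures, then an
   area test) and a dendrite candidate (the remaining thin foreground), which
   is cleaned by a second binary threshold.
3. Core operator on the dendrite candidate: either Otsu thresholding with the
   histogram restricted to [80, 255], or Canny edge detection with hysteresis
   thresholds (70, 220) on the 8-bit Sobel gradient-magnitude scale.
4. Morphological closing of the dendrite mask with a 3x3 kernel, then an
   elementwise subtraction removes any overlap with the osteocyte mask,
   yielding a 3-class label {0 background, 1 osteocyte, 2 dendrite}.

The osteocyte mask is produced by the shared stages and is therefore
identical between the two pipelines; only the dendrite class differs.
Intensities are treated on an 8-bit scale; 16-bit input is max-normalised
down before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import apply_hysteresis_threshold, threshold_otsu
from skimage.morphology import disk

__all__ = [
    "ThresholdConfig",
    "DegenerateHistogramError",
    "preprocess",
    "split_candidate_masks",
    "otsu_core",
    "canny_core",
    "postprocess",
    "segment",
]


class DegenerateHistogramError(ValueError):
    """Otsu thresholding on a histogram with fewer than two occupied levels."""


@dataclass(frozen=True)
class ThresholdConfig:
    gaussian_sigma: float = 2.0
    split_threshold: float = 70.0
    dendrite_noise_threshold: float = 80.0
    canny_low: float = 70.0
    canny_high: float = 220.0
    otsu_low: int = 80
    otsu_high: int = 255
    closing_kernel: int = 3  # square side, px
    min_soma_area: int = 30  # px^2
    soma_opening_radius: int = 3  # disk radius erasing thin structures and their halos

    def validate(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if not self.canny_low < self.canny_high:
            raise ValueError("canny_low must be < canny_high")
        for name in ("split_threshold", "dendrite_noise_threshold", "otsu_low", "otsu_high"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside the 8-bit intensity range")


def _as_8bit(image: np.ndarray) -> np.ndarray:
    """Max-normalise >8-bit integer input down to the 8-bit scale."""
    image = np.asarray(image)
    if image.dtype == np.uint8 or np.issubdtype(image.dtype, np.floating):
        return image
    peak = image.max()
    if peak <= 255:
        return image.astype(np.uint8)
    return np.round(image.astype(np.float64) * (255.0 / peak)).astype(np.uint8)


def preprocess(image: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Gaussian smoothing; dtype-preserving (uint8 in, rounded uint8 out)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    smoothed = ndi.gaussian_filter(image.astype(np.float64), sigma=sigma)
    if np.issubdtype(image.dtype, np.integer):
        return np.round(smoothed).astype(image.dtype)
    return smoothed.astype(image.dtype)


def split_candidate_masks(
    image: np.ndarray, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Split a (smoothed) image into osteocyte and dendrite candidate masks.

    Foreground = pixels >= ``split_threshold``.  The osteocyte candidate is
    the opened foreground (thin structures erased) restricted to components of
    at least ``min_soma_area``; the dendrite candidate is the remaining
    foreground kept only where it also clears ``dendrite_noise_threshold``.
    The two candidates are disjoint by construction.
    """
    cfg.validate()
    img = _as_8bit(image).astype(np.float64)
    fg = img >= cfg.split_threshold
    opened = ndi.binary_opening(fg, structure=disk(cfg.soma_opening_radius))
    lab, n = ndi.label(opened, structure=np.ones((3, 3)))
    osteo = np.zeros_like(fg)
    if n:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        big = np.flatnonzero(sizes >= cfg.min_soma_area) + 1
        osteo = np.isin(lab, big)
    dend = fg & ~osteo & (img >= cfg.dendrite_noise_threshold)
    return osteo, dend


def otsu_core(image: np.ndarray, lo: int = 80, hi: int = 255) -> np.ndarray:
    """Otsu threshold with the histogram restricted to [lo, hi].

    The threshold maximising between-class variance is chosen over the 8-bit
    histogram of in-range pixels only; the returned foreground mask is
    ``image > threshold``.  No pixels in range gives an empty mask; in-range
    pixels at a single level raise :class:`DegenerateHistogramError`.
    """
    img = _as_8bit(image)
    vals = np.round(np.asarray(img, dtype=np.float64)).astype(np.int64)
    in_range = (vals >= lo) & (vals <= hi)
    if not in_range.any():
        return np.zeros(img.shape, dtype=bool)
    counts = np.bincount(vals[in_range].ravel() - lo, minlength=hi - lo + 1)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "histogram restricted to [lo, hi] has fewer than two occupied levels"
        )
    centers = np.arange(lo, hi + 1, dtype=np.float64)
    t = threshold_otsu(hist=(counts.astype(np.float64), centers))
    return vals > t


_SOBEL_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=np.float64)


def canny_core(image: np.ndarray, low: float = 70.0, high: float = 220.0) -> np.ndarray:
    """Canny edge map with thresholds on the 8-bit Sobel gradient scale.

    Sobel derivatives of the (already smoothed) image give an L2 gradient
    magnitude; non-maximum suppression thins ridges to 1 px; hysteresis keeps
    weak edges (>= low) only when 8-connected to a strong edge (>= high).
    """
    if not low < high:
        raise ValueError("low must be < high")
    img = _as_8bit(image).astype(np.float64)
    gy = ndi.correlate(img, _SOBEL_Y, mode="nearest")
    gx = ndi.correlate(img, _SOBEL_Y.T, mode="nearest")
    mag = np.hypot(gx, gy)
    if mag.max() == 0:
        return np.zeros(img.shape, dtype=bool)

    # quantise gradient direction to 4 sectors and suppress non-maxima
    angle = np.mod(np.arctan2(gy, gx), np.pi)
    sector = np.round(angle / (np.pi / 4)).astype(int) % 4
    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    keep = np.zeros(img.shape, dtype=bool)
    padded = np.pad(mag, 1, mode="constant")
    for s, (dy, dx) in offsets.items():
        sel = sector == s
        fwd = padded[1 + dy : 1 + dy + img.shape[0], 1 + dx : 1 + dx + img.shape[1]]
        bwd = padded[1 - dy : 1 - dy + img.shape[0], 1 - dx : 1 - dx + img.shape[1]]
        # strict on the forward side so plateau ties keep a single pixel
        keep |= sel & (mag > fwd) & (mag >= bwd)
    thin = np.where(keep, mag, 0.0)
    return apply_hysteresis_threshold(thin, low, high)


def postprocess(
    osteo: np.ndarray, dend: np.ndarray, closing_kernel: int = 3
) -> np.ndarray:
    """Close the dendrite mask, subtract the osteocyte mask, build the label.

    The dendrite mask is closed with a ``closing_kernel`` square to bridge
    sub-kernel gaps; overlapping osteocyte/dendrite pixels are then removed by
    elementwise subtraction so the output classes are disjoint.
    """
    osteo = np.asarray(osteo, dtype=bool)
    dend = np.asarray(dend, dtype=bool)
    if osteo.shape != dend.shape:
        raise ValueError(f"shape mismatch: {osteo.shape} vs {dend.shape}")
    closed = ndi.binary_closing(
        dend, structure=np.ones((closing_kernel, closing_kernel), dtype=bool)
    )
    label = np.zeros(osteo.shape, dtype=np.uint8)
    label[closed & ~osteo] = 2
    label[osteo] = 1
    return label


def segment(
    image: np.ndarray, method: str = "otsu", cfg: ThresholdConfig = ThresholdConfig()
) -> np.ndarray:
    """Full thresholding pipeline: preprocess, split, core, postprocess.

    ``method`` selects the dendrite core operator, ``"otsu"`` or ``"canny"``.
    Deterministic: the same input always yields the same label map.
    """
    if method not in ("otsu", "canny"):
        raise ValueError(f"unknown method {method!r}; expected 'otsu' or 'canny'")
    cfg.validate()
    smoothed = preprocess(_as_8bit(image), cfg.gaussian_sigma)
    osteo, dend_candidate = split_candidate_masks(smoothed, cfg)

    if not dend_candidate.any():
        dend = dend_candidate
    elif method == "otsu":
        vals = smoothed.astype(np.float64)
        sub = vals[dend_candidate]
        sub = sub[(sub >= cfg.otsu_low) & (sub <= cfg.otsu_high)]
        if sub.size == 0 or np.unique(np.round(sub)).size < 2:
            dend = dend_candidate  # core cannot refine a degenerate candidate
        else:
            counts = np.bincount(
                np.round(sub).astype(np.int64) - cfg.otsu_low,
                minlength=cfg.otsu_high - cfg.otsu_low + 1,
            )
            centers = np.arange(cfg.otsu_low, cfg.otsu_high + 1, dtype=np.float64)
            t = threshold_otsu(hist=(counts.astype(np.float64), centers))
            dend = dend_candidate & (vals > t)
    else:
        # Canny responds on the flanks of a smoothed ridge; keep responses in a
        # halo around the candidate and let the closing bind them to the core
        edges = canny_core(smoothed, cfg.canny_low, cfg.canny_high)
        halo = ndi.binary_dilation(dend_candidate, structure=disk(3))
        dend = dend_candidate | (edges & halo)

    return postprocess(osteo, dend, cfg.closing_kernel)
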
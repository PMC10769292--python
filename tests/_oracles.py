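"""Independent brute-force oracles the implementation is checked against."""

from __future__ import annotations

import numpy as np


def otsu_exhaustive(values: np.ndarray, lo: int, hi: int) -> tuple[int, float]:
    """Exhaustive search over all candidate thresholds in [lo, hi].

    Returns (best threshold, best between-class variance) over the histogram
    of in-range pixel values; foreground is value > t.
    """
    vals = values[(values >= lo) & (values <= hi)].astype(np.float64)
    best_t, best_var = lo, -1.0
    for t in range(lo, hi):
        w0 = vals <= t
        n0, n1 = w0.sum(), (~w0).sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0, mu1 = vals[w0].mean(), vals[~w0].mean()
        var = (n0 * n1) * (mu0 - mu1) ** 2 / (n0 + n1) ** 2
        if var > best_var:
            best_t, best_var = t, var
    return best_t, best_var


def between_class_variance(values: np.ndarray, t: float, lo: int, hi: int) -> float:
    vals = values[(values >= lo) & (values <= hi)].astype(np.float64)
    w0 = vals <= t
    n0, n1 = w0.sum(), (~w0).sum()
    if n0 == 0 or n1 == 0:
        return 0.0
    return float((n0 * n1) * (vals[w0].mean() - vals[~w0].mean()) ** 2 / (n0 + n1) ** 2)


def flood_fill_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Stack-based flood fill labelling in raster order of first pixel."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    current = 0
    H, W = mask.shape
    for y in range(H):
        for x in range(W):
            if mask[y, x] and labels[y, x] == 0:
                current += 1
                stack = [(y, x)]
                labels[y, x] = current
                while stack:
                    cy, cx = stack.pop()
                    for dy, dx in steps:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] and labels[ny, nx] == 0:
                            labels[ny, nx] = current
                            stack.append((ny, nx))
    return labels


def partition_from_labels(labels: np.ndarray) -> set[frozenset]:
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out.append(frozenset(map(tuple, np.argwhere(labels == lab))))
    return set(out)


def penalty_brute_force(binary: np.ndarray, penalty_factor: float,
                        connectivity_steps=None) -> float:
    """Per-component 1/size**pf summed via the flood-fill oracle (8-conn)."""
    labels = flood_fill_components(binary, connectivity=8)
    total = 0.0
    for lab in range(1, labels.max() + 1):
        size = int((labels == lab).sum())
        total += size ** (-penalty_factor)
    return total


def gaussian_convolve_2d(image: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Direct (non-separable) convolution with a truncated Gaussian kernel,
    reflect boundary — an independent check of the library smoothing."""
    r = int(truncate * sigma + 0.5)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    # product of two 1-D discretised Gaussians, matching separable filtering
    g1 = np.exp(-np.arange(-r, r + 1) ** 2 / (2 * sigma**2))
    g1 /= g1.sum()
    kernel = np.outer(g1, g1)
    # edge-repeating mirror boundary (what imaging filters call "reflect")
    padded = np.pad(image.astype(np.float64), r, mode="symmetric")
    H, W = image.shape
    out = np.zeros((H, W))
    for dy in range(2 * r + 1):
        for dx in range(2 * r + 1):
            out += kernel[dy, dx] * padded[dy : dy + H, dx : dx + W]
    return out
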
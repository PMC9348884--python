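"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a pipeline quantity by direct enumeration, staying
deliberately naive and separate from the package's implementation paths.
"""

from __future__ import annotations

import numpy as np


def zncc_brute_force(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """ZNCC at every valid placement by explicit per-window loops."""
    img = np.asarray(image, dtype=np.float64)
    tpl = np.asarray(template, dtype=np.float64)
    h, w = tpl.shape
    t0 = tpl - tpl.mean()
    t_norm = np.sqrt((t0**2).sum())
    out = np.zeros((img.shape[0] - h + 1, img.shape[1] - w + 1))
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            win = img[r : r + h, c : c + w]
            w0 = win - win.mean()
            w_norm = np.sqrt((w0**2).sum())
            if w_norm == 0 or t_norm == 0:
                out[r, c] = 0.0
            else:
                out[r, c] = (w0 * t0).sum() / (w_norm * t_norm)
    return out


def gaussian_window_mean_brute_force(
    img: np.ndarray, window: int, sigma: float
) -> np.ndarray:
    """Per-pixel Gaussian-weighted window mean with explicit reflect padding."""
    half = window // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    g /= g.sum()
    kernel = np.outer(g, g)
    # half-sample symmetric reflection: the edge row/column is repeated
    padded = np.pad(np.asarray(img, dtype=np.float64), half, mode="symmetric")
    out = np.zeros(np.asarray(img).shape, dtype=np.float64)
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            out[r, c] = (kernel * padded[r : r + window, c : c + window]).sum()
    return out


def binarize_brute_force(
    img: np.ndarray, window: int, sigma: float, offset: float, dark_jet: bool = True
) -> np.ndarray:
    """Per-pixel threshold rule applied against the brute-force window mean."""
    mean = gaussian_window_mean_brute_force(img, window, sigma)
    px = np.asarray(img, dtype=np.float64)
    if dark_jet:
        return (px < mean - offset).astype(np.uint8)
    return (px > mean + offset).astype(np.uint8)


def bounded_false_runs(profile: list[bool]) -> list[tuple[int, int]]:
    """All maximal false-runs bounded by True on both sides, by direct scan."""
    runs: list[tuple[int, int]] = []
    n = len(profile)
    i = 0
    while i < n:
        if not profile[i]:
            start = i
            while i < n and not profile[i]:
                i += 1
            if start > 0 and i < n:
                runs.append((start, i))
        else:
            i += 1
    return runs


def qualifying_gaps(
    profile: list[bool], max_gap_px: int, max_distance_um: float, pixel_size_um: float
) -> list[tuple[int, int]]:
    return [
        (s, e)
        for (s, e) in bounded_false_runs(profile)
        if (e - s) <= max_gap_px and s * pixel_size_um <= max_distance_um
    ]


def windowed_or_brute_force(hits: list[bool], window: int) -> list[bool]:
    return [any(hits[max(0, i - window + 1) : i + 1]) for i in range(len(hits))]
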
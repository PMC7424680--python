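"""Raw tray-image cleanup: denoising, color constancy, per-pot cropping.

All operations are deterministic.  Pixel coordinates are row-major with the
origin at the top-left corner, and rectangles are half-open
``(row0, col0, row1, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class TrayLayout:
    """Grid of pot bounding boxes inside a tray image."""

    n_rows: int
    n_cols: int
    pot_bboxes: list[tuple[int, int, int, int]]
    tray_id: str = "tray"

    def __post_init__(self) -> None:
        if len(self.pot_bboxes) != self.n_rows * self.n_cols:
            raise ValueError("pot_bboxes must hold n_rows * n_cols rectangles")
        for bbox in self.pot_bboxes:
            r0, c0, r1, c1 = bbox
            if r1 <= r0 or c1 <= c0 or min(r0, c0) < 0:
                raise ValueError(f"degenerate pot bbox {bbox}")

    @classmethod
    def regular_grid(cls, image_shape, n_rows: int, n_cols: int,
                     tray_id: str = "tray") -> "TrayLayout":
        h, w = image_shape[:2]
        boxes = []
        for r in range(n_rows):
            for c in range(n_cols):
                boxes.append((r * h // n_rows, c * w // n_cols,
                              (r + 1) * h // n_rows, (c + 1) * w // n_cols))
        return cls(n_rows, n_cols, boxes, tray_id)


@dataclass
class ColorCorrection:
    """Per-channel affine correction ``corrected = alpha * observed + beta``."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if np.any(self.alpha <= 0):
            raise ValueError("contrast coefficients must be positive")

    def apply(self, image: np.ndarray) -> np.ndarray:
        out = image.astype(float) * self.alpha + self.beta
        if np.issubdtype(image.dtype, np.integer):
            return np.clip(np.round(out), 0, 255).astype(image.dtype)
        return out


def denoise(image: np.ndarray, median_radius: int = 1,
            gaussian_sigma: float = 0.0) -> np.ndarray:
    """Median filter (window ``2r + 1``) followed by a Gaussian blur.

    Salt-and-pepper outliers fall to the median step; residual
    high-frequency noise to the Gaussian.  Zero parameters are the identity.
    """
    if median_radius < 0 or gaussian_sigma < 0:
        raise ValueError("filter parameters must be >= 0")
    out = image
    if median_radius > 0:
        size = 2 * median_radius + 1
        if out.ndim == 3:
            out = ndimage.median_filter(out, size=(size, size, 1))
        else:
            out = ndimage.median_filter(out, size=size)
    if gaussian_sigma > 0:
        blurred = ndimage.gaussian_filter(
            out.astype(float),
            sigma=(gaussian_sigma, gaussian_sigma, 0)[:out.ndim])
        if np.issubdtype(image.dtype, np.integer):
            out = np.clip(np.round(blurred), 0, 255).astype(image.dtype)
        else:
            out = blurred
    return out.copy() if out is image else out


def gray_world(image: np.ndarray) -> np.ndarray:
    """Rescale each channel so all channel means equal the global mean."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("gray_world expects an RGB image")
    img = image.astype(float)
    means = img.reshape(-1, 3).mean(axis=0)
    if np.any(means == 0):
        raise ValueError("cannot rescale a channel with zero mean")
    target = means.mean()
    out = img * (target / means)
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(image.dtype)
    return out


def card_affine_correct(image: np.ndarray, observed_patches,
                        reference_patches):
    """Global affine color correction fitted on color-checker patches.

    Per channel, ``alpha`` and ``beta`` are the least-squares solution of
    ``reference ~ alpha * observed + beta`` over the patch pairs.  Returns
    ``(ColorCorrection, corrected image)``.
    """
    obs = np.asarray(observed_patches, dtype=float)
    ref = np.asarray(reference_patches, dtype=float)
    if obs.shape != ref.shape or obs.ndim != 2 or obs.shape[0] < 2:
        raise ValueError("need >= 2 matching observed/reference patches")
    alphas, betas = [], []
    for ch in range(obs.shape[1]):
        if np.ptp(obs[:, ch]) == 0:
            raise ValueError(
                f"channel {ch}: observed patches are identical; fit degenerate")
        alpha, beta = np.polyfit(obs[:, ch], ref[:, ch], 1)
        alphas.append(alpha)
        betas.append(beta)
    correction = ColorCorrection(np.array(alphas), np.array(betas))
    return correction, correction.apply(image)


def crop_pots(image: np.ndarray, layout: TrayLayout,
              adaptive_margin: int = 0) -> list[np.ndarray]:
    """One crop per pot bbox, expanded by a margin and clipped to the image.

    Crops are returned in row-major pot order.  A bbox lying outside the
    image raises an error naming the offending pot.
    """
    h, w = image.shape[:2]
    crops = []
    for idx, (r0, c0, r1, c1) in enumerate(layout.pot_bboxes):
        if r0 >= h or c0 >= w or r1 > h or c1 > w:
            row, col = divmod(idx, layout.n_cols)
            raise ValueError(
                f"pot ({row}, {col}) of tray {layout.tray_id}: bbox "
                f"{(r0, c0, r1, c1)} outside image of shape {(h, w)}")
        rr0 = max(0, r0 - adaptive_margin)
        cc0 = max(0, c0 - adaptive_margin)
        rr1 = min(h, r1 + adaptive_margin)
        cc1 = min(w, c1 + adaptive_margin)
        crops.append(image[rr0:rr1, cc0:cc1].copy())
    return crops
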
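"""Image preparation: color normalization, geometry, attention masks.

Clinical lesion photographs arrive under wildly varying illumination, so
before encoding, every image passes through an automatic color
equalization (ACE) step: each pixel is compared with a grid of reference
pixels through a saturated slope function of the channel difference,
weighted by inverse spatial distance, and the resulting per-channel
response is affinely rescaled to span [0, 255].  Because the response
depends only on pixel *differences*, a constant offset added to a channel
cancels out — exactly the property that removes global lighting shifts.

Geometric preparation follows the usual train/eval asymmetry: random
cropping (70-100% of each dimension) plus resize during training,
deterministic full-frame resize at evaluation time.

Lesion bounding boxes are rasterized into heatmap masks on the encoder's
attention grid by exact area-average downsampling, so a cell's value is
the fraction of its receptive area covered by the box union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "HeatmapMask",
    "ace_normalize",
    "crop_resize",
    "random_crop_window",
    "apply_window_resize",
    "transform_boxes",
    "boxes_to_heatmap",
    "rasterize_boxes",
]

logger = logging.getLogger(__name__)


class ImageInputError(ValueError):
    pass


@dataclass
class HeatmapMask:
    """Box-union coverage on the attention grid; values in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ImageInputError("heatmap must be 2-D with values in [0,1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def ace_normalize(
    image: np.ndarray,
    slope: float = 5.0,
    subsample: int | None = None,
    max_reference_pixels: int = 4096,
) -> np.ndarray:
    """Automatic color equalization of an 8-bit RGB image.

    For each channel c and pixel p the response is

        R_c(p) = sum_j  sat( slope * (I_c(p) - I_c(j)) ) / d(p, j)

    over reference pixels j on a subsampled grid, with sat(x) clipping to
    [-1, 1], intensities scaled to [0, 1] and d the Euclidean pixel
    distance (the p == j term is skipped).  R_c is then rescaled per
    channel so its minimum maps to 0 and maximum to 255.  A zero-variance
    channel has no ordering information and maps to mid-gray (128).

    Parameters
    ----------
    slope
        Gain of the saturation function; large slopes make the comparison
        a pure sign test, small slopes keep it nearly linear.
    subsample
        Reference-grid stride in pixels.  Default: the smallest stride
        that keeps the grid at or under ``max_reference_pixels``.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ImageInputError("ace_normalize expects an 8-bit HxWx3 RGB array")
    if slope <= 0:
        raise ImageInputError(f"slope must be > 0, got {slope}")
    h, w = img.shape[:2]
    if subsample is None:
        subsample = 1
        while (h // subsample + 1) * (w // subsample + 1) > max_reference_pixels:
            subsample += 1
    if subsample < 1:
        raise ImageInputError(f"subsample must be >= 1, got {subsample}")

    ys = np.arange(0, h, subsample)
    xs = np.arange(0, w, subsample)
    ref_y, ref_x = np.meshgrid(ys, xs, indexing="ij")
    ref_y = ref_y.ravel()
    ref_x = ref_x.ravel()

    vals = img.astype(np.float64) / 255.0
    ref_vals = vals[ref_y, ref_x, :]  # (R, 3)

    py, px = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    py = py.ravel().astype(np.float64)
    px = px.ravel().astype(np.float64)

    out = np.empty((h * w, 3), dtype=np.float64)
    # Chunk over image pixels to bound the (pixels x references) matrices.
    chunk = max(1, int(4e6) // max(1, ref_y.size))
    for start in range(0, h * w, chunk):
        stop = min(start + chunk, h * w)
        dy = py[start:stop, None] - ref_y[None, :]
        dx = px[start:stop, None] - ref_x[None, :]
        dist = np.sqrt(dy * dy + dx * dx)
        np.reciprocal(dist, out=dist, where=dist > 0)  # self-pairs get weight 0
        pix = vals.reshape(-1, 3)[start:stop]
        for c in range(3):
            diff = np.clip(slope * (pix[:, c : c + 1] - ref_vals[None, :, c]), -1.0, 1.0)
            out[start:stop, c] = (diff * dist).sum(axis=1)

    result = np.empty_like(out)
    for c in range(3):
        lo, hi = out[:, c].min(), out[:, c].max()
        if hi - lo < 1e-12:
            result[:, c] = 128.0
        else:
            result[:, c] = (out[:, c] - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(result), 0, 255).astype(np.uint8).reshape(h, w, 3)


def crop_resize(
    image: np.ndarray,
    mode: str,
    target: tuple[int, int] = (800, 1024),
    seed: int | None = None,
) -> np.ndarray:
    """Crop/resize an image to the model input size.

    ``train_random`` takes a seeded random window of 70-100% of each
    dimension and resizes it to ``target``; ``eval_center`` resizes the
    full frame (no crop).  Bilinear interpolation; ``target`` is (H, W).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ImageInputError("crop_resize expects an HxWx3 array")
    h, w = img.shape[:2]
    th, tw = target
    if th < 32 or tw < 32:
        raise ImageInputError(f"target must be at least 32x32, got {target}")
    if h < 32 or w < 32:
        raise ImageInputError(f"image too small ({h}x{w}); minimum is 32x32")

    if mode == "train_random":
        window = random_crop_window((h, w), seed=seed)
    elif mode == "eval_center":
        window = (0, 0, h, w)
    else:
        raise ImageInputError(f"unknown mode {mode!r}")
    return apply_window_resize(img, window, target)


def random_crop_window(
    image_size: tuple[int, int], seed: int | None = None, min_frac: float = 0.7
) -> tuple[int, int, int, int]:
    """Seeded crop window (y0, x0, ch, cw) of 70-100% of each dimension."""
    h, w = image_size
    rng = np.random.default_rng(seed)
    ch = max(32, int(round(h * rng.uniform(min_frac, 1.0))))
    cw = max(32, int(round(w * rng.uniform(min_frac, 1.0))))
    ch, cw = min(ch, h), min(cw, w)
    y0 = int(rng.integers(0, h - ch + 1))
    x0 = int(rng.integers(0, w - cw + 1))
    return (y0, x0, ch, cw)


def apply_window_resize(
    image: np.ndarray, window: tuple[int, int, int, int], target: tuple[int, int]
) -> np.ndarray:
    """Crop ``window`` and bilinearly resize to ``target`` (H, W)."""
    y0, x0, ch, cw = window
    img = np.asarray(image)[y0 : y0 + ch, x0 : x0 + cw]
    th, tw = target
    if img.shape[:2] == (th, tw):
        return img.copy()
    pil = Image.fromarray(img.astype(np.uint8))
    return np.asarray(pil.resize((tw, th), Image.BILINEAR))


def transform_boxes(
    boxes: list[tuple[int, int, int, int]],
    window: tuple[int, int, int, int],
    target: tuple[int, int],
) -> list[tuple[int, int, int, int]]:
    """Map boxes through the same crop + resize; boxes falling outside the
    window (or collapsing to zero area) are dropped."""
    y0, x0, ch, cw = window
    th, tw = target
    sy, sx = th / ch, tw / cw
    out = []
    for bx0, by0, bx1, by1 in boxes:
        nx0 = max(0, min(tw, int(round((bx0 - x0) * sx))))
        nx1 = max(0, min(tw, int(round((bx1 - x0) * sx))))
        ny0 = max(0, min(th, int(round((by0 - y0) * sy))))
        ny1 = max(0, min(th, int(round((by1 - y0) * sy))))
        if nx1 > nx0 and ny1 > ny0:
            out.append((nx0, ny0, nx1, ny1))
    return out


def rasterize_boxes(
    boxes: list[tuple[int, int, int, int]], image_size: tuple[int, int]
) -> np.ndarray:
    """Boolean union mask of half-open boxes (x0, y0, x1, y1) at image size."""
    h, w = image_size
    mask = np.zeros((h, w), dtype=bool)
    for x0, y0, x1, y1 in boxes:
        if not (0 <= x0 <= x1 <= w and 0 <= y0 <= y1 <= h):
            raise ImageInputError(
                f"box {(x0, y0, x1, y1)} outside image bounds {(h, w)}"
            )
        if x1 == x0 or y1 == y0:
            logger.warning("ignoring zero-area box %s", (x0, y0, x1, y1))
            continue
        mask[y0:y1, x0:x1] = True
    return mask


def boxes_to_heatmap(
    boxes: list[tuple[int, int, int, int]],
    image_size: tuple[int, int],
    map_size: tuple[int, int],
) -> HeatmapMask:
    """Downsample the box-union mask to the attention grid by exact area
    averaging: each output cell equals the covered fraction of its
    rectangle in the source mask, so the heatmap mean equals the union's
    pixel fraction."""
    mask = rasterize_boxes(boxes, image_size).astype(np.float64)
    return HeatmapMask(values=_area_average(mask, map_size))


def _area_average(arr: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    """Exact mean of a per-pixel-constant array over a fractional grid.

    Uses a summed-area table with linear interpolation at fractional
    coordinates, which integrates a piecewise-constant image exactly.
    """
    h, w = arr.shape
    oh, ow = out_size
    sat = np.zeros((h + 1, w + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=sat[1:, 1:])

    def interp(yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
        y0 = np.floor(yy).astype(int)
        x0 = np.floor(xx).astype(int)
        y0 = np.clip(y0, 0, h - 1)
        x0 = np.clip(x0, 0, w - 1)
        fy = yy - y0
        fx = xx - x0
        s00 = sat[np.ix_(y0, x0)]
        s01 = sat[np.ix_(y0, x0 + 1)]
        s10 = sat[np.ix_(y0 + 1, x0)]
        s11 = sat[np.ix_(y0 + 1, x0 + 1)]
        return (
            s00 * (1 - fy[:, None]) * (1 - fx[None, :])
            + s01 * (1 - fy[:, None]) * fx[None, :]
            + s10 * fy[:, None] * (1 - fx[None, :])
            + s11 * fy[:, None] * fx[None, :]
        )

    edges_y = np.linspace(0.0, float(h), oh + 1)
    edges_x = np.linspace(0.0, float(w), ow + 1)
    s = interp(edges_y, edges_x)
    cell = (s[1:, 1:] - s[:-1, 1:] - s[1:, :-1] + s[:-1, :-1])
    area = (h / oh) * (w / ow)
    return cell / area
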
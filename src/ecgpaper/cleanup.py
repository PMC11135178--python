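"""Text and grid removal for rectified ECG pages.

Text is erased by fast-marching inpainting over its ink mask: masked pixels
are filled in increasing distance-map order using the distance-weighted
first-order estimate Iq(p) = I(q) + grad I(q) . (p - q) from nearby known
pixels.  The background grid is removed either by the trained residual
denoiser (patchify -> predict grid residual -> subtract -> stitch) or by a
classical color rule that suppresses grid-hued pixels.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._nn import DenoiserSpec, DnCNN
from .errors import ParameterError
from .paper_render import PaperImage

PATCH = 30
OVERLAP = 5
STRIDE = PATCH - OVERLAP


# ---------------------------------------------------------------------------
# Fast-marching inpainting
# ---------------------------------------------------------------------------

def _solve_eikonal(t1: float, t2: float) -> float:
    lo, hi = (t1, t2) if t1 <= t2 else (t2, t1)
    if np.isinf(lo):
        return np.inf
    if hi - lo >= 1.0:
        return lo + 1.0
    return 0.5 * (lo + hi + np.sqrt(2.0 - (hi - lo) ** 2))


def _inpaint_gray(img: np.ndarray, mask: np.ndarray, radius: int = 3) -> np.ndarray:
    h, w = img.shape
    out = img.astype(float).copy()
    known = ~mask
    T = np.where(known, 0.0, np.inf)
    heap = []
    # initial narrow band: unknown pixels bordering a known pixel
    border = mask & ndimage.binary_dilation(known)
    for r, c in zip(*np.nonzero(border)):
        heapq.heappush(heap, (1.0, r, c))
        T[r, c] = 1.0

    def _gradient(r, c):
        g = np.zeros(2)
        for ax, (dr, dc) in enumerate(((1, 0), (0, 1))):
            p1 = (r + dr, c + dc)
            p0 = (r - dr, c - dc)
            ok1 = 0 <= p1[0] < h and 0 <= p1[1] < w and known[p1]
            ok0 = 0 <= p0[0] < h and 0 <= p0[1] < w and known[p0]
            if ok1 and ok0:
                g[ax] = (out[p1] - out[p0]) / 2.0
            elif ok1:
                g[ax] = out[p1] - out[r, c]
            elif ok0:
                g[ax] = out[r, c] - out[p0]
        return g

    while heap:
        t, r, c = heapq.heappop(heap)
        if known[r, c] or t > T[r, c]:
            continue
        # first-order estimate from known pixels in the neighborhood
        num = 0.0
        den = 0.0
        for rr in range(max(r - radius, 0), min(r + radius + 1, h)):
            for cc in range(max(c - radius, 0), min(c + radius + 1, w)):
                if not known[rr, cc]:
                    continue
                dr, dc = r - rr, c - cc
                d2 = dr * dr + dc * dc
                if d2 == 0 or d2 > radius * radius:
                    continue
                grad = _gradient(rr, cc)
                est = out[rr, cc] + grad[0] * dr + grad[1] * dc
                wgt = 1.0 / (d2 * np.sqrt(d2))
                num += wgt * est
                den += wgt
        if den > 0:
            out[r, c] = num / den
        known[r, c] = True
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and not known[nr, nc]:
                tx = _solve_eikonal(
                    T[nr, nc - 1] if nc > 0 and known[nr, nc - 1] else np.inf,
                    T[nr, nc + 1] if nc < w - 1 and known[nr, nc + 1] else np.inf)
                ty = _solve_eikonal(
                    T[nr - 1, nc] if nr > 0 and known[nr - 1, nc] else np.inf,
                    T[nr + 1, nc] if nr < h - 1 and known[nr + 1, nc] else np.inf)
                tnew = min(tx, ty, T[r, c] + 1.0)
                if tnew < T[nr, nc]:
                    T[nr, nc] = tnew
                    heapq.heappush(heap, (tnew, nr, nc))
    return out


def inpaint(image, mask: np.ndarray, radius: int = 3):
    """Fill ``mask`` pixels by fast-marching first-order extrapolation.

    Accepts a 2-D array, an H x W x 3 array, or a :class:`PaperImage`;
    unmasked pixels are returned unchanged.  A mask covering the whole image
    is rejected.
    """
    mask = np.asarray(mask, dtype=bool)
    if isinstance(image, PaperImage):
        out = image.copy()
        out.pixels = np.clip(np.round(inpaint(image.pixels.astype(float), mask)),
                             0, 255).astype(np.uint8)
        out.log("inpaint", n_pixels=int(mask.sum()), radius=radius)
        return out
    img = np.asarray(image, dtype=float)
    if mask.shape != img.shape[:2]:
        raise ParameterError("mask shape must match image")
    if mask.all():
        raise ParameterError("mask covers the entire image")
    if not mask.any():
        return img.copy()
    if img.ndim == 2:
        return _inpaint_gray(img, mask, radius)
    return np.stack([_inpaint_gray(img[:, :, ch], mask, radius)
                     for ch in range(img.shape[2])], axis=2)


def make_text_mask(image, overlays=None, detector=None,
                   dilation: int = 2) -> np.ndarray:
    """Union of text-ink masks (dilated), from overlays or a pluggable
    detector returning (x1, y1, x2, y2) boxes."""
    shape = image.shape[:2] if not isinstance(image, PaperImage) else image.shape
    if overlays is None and detector is None:
        raise ParameterError("need ground-truth overlays or a detector")
    mask = np.zeros(shape, dtype=bool)
    if overlays is not None:
        for ov in overlays:
            mask |= ov.mask
    else:
        pixels = image.pixels if isinstance(image, PaperImage) else image
        for x1, y1, x2, y2 in detector(pixels):
            mask[max(int(y1), 0):int(y2), max(int(x1), 0):int(x2)] = True
    if dilation > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=dilation)
    return mask


def remove_text(image: PaperImage, overlays=None, detector=None,
                dilation: int = 2) -> PaperImage:
    """Convenience: build the text mask and inpaint it."""
    mask = make_text_mask(image, overlays, detector, dilation)
    if not mask.any():
        return image.copy()
    return inpaint(image, mask)


# ---------------------------------------------------------------------------
# Patch decomposition
# ---------------------------------------------------------------------------

@dataclass
class PatchSet:
    """Overlapping 30x30 single-channel patches in [0, 1] plus origins."""

    patches: np.ndarray           # (n, 30, 30) float32
    origins: np.ndarray           # (n, 2) top-left (row, col)
    image_shape: tuple
    channel_id: int = 0


def _grid_starts(dim: int) -> list:
    if dim < PATCH:
        raise ParameterError(f"image dimension {dim} smaller than patch {PATCH}")
    starts = list(range(0, dim - PATCH + 1, STRIDE))
    if starts[-1] != dim - PATCH:
        starts.append(dim - PATCH)
    return starts


def patchify(channel: np.ndarray, channel_id: int = 0) -> PatchSet:
    """Split one channel (0-255) into overlapping 30x30 patches in [0, 1].

    Tiles are laid out on a 25-px stride (5-px overlap); the final row/col of
    tiles is re-anchored flush with the image edge so coverage is complete.
    """
    channel = np.asarray(channel, dtype=np.float32)
    if channel.ndim != 2:
        raise ParameterError("patchify expects a single channel")
    h, w = channel.shape
    rows = _grid_starts(h)
    cols = _grid_starts(w)
    patches = np.empty((len(rows) * len(cols), PATCH, PATCH), dtype=np.float32)
    origins = np.empty((len(rows) * len(cols), 2), dtype=int)
    i = 0
    for r in rows:
        for c in cols:
            patches[i] = channel[r:r + PATCH, c:c + PATCH] / 255.0
            origins[i] = (r, c)
            i += 1
    return PatchSet(patches, origins, (h, w), channel_id)


def stitch(patch_set: PatchSet, tau: float = 5.0) -> np.ndarray:
    """Reassemble a channel from (possibly modified) overlapping patches.

    Each patch pixel is weighted by exp(-d/tau), d being its Euclidean
    distance from the patch center, and weights are normalized across all
    covering patches (exponential-distance-weighted stitching).  Returns the
    channel on the 0-255 scale.
    """
    h, w = patch_set.image_shape
    yy, xx = np.mgrid[0:PATCH, 0:PATCH]
    cen = (PATCH - 1) / 2.0
    wgt = np.exp(-np.hypot(yy - cen, xx - cen) / tau).astype(np.float64)
    acc = np.zeros((h, w))
    norm = np.zeros((h, w))
    for patch, (r, c) in zip(patch_set.patches, patch_set.origins):
        acc[r:r + PATCH, c:c + PATCH] += wgt * patch.astype(np.float64)
        norm[r:r + PATCH, c:c + PATCH] += wgt
    return 255.0 * acc / norm


# ---------------------------------------------------------------------------
# Denoiser training and grid removal
# ---------------------------------------------------------------------------

def make_training_pairs(gridded: np.ndarray, clean: np.ndarray):
    """Paired patch stacks from one gridded and one grid-free channel."""
    ps_y = patchify(np.asarray(gridded, dtype=float))
    ps_x = patchify(np.asarray(clean, dtype=float))
    return ps_y.patches, ps_x.patches


def make_toy_grid_pairs(n: int, seed: int = 0, pitch: float = 7.87,
                        grid_depth: float = 0.30, grid_prob: float = 0.8,
                        size: int = PATCH):
    """Synthetic (gridded, clean) patch pairs for desk-scale training.

    Clean patches hold a dark random-walk trace on white; the grid component
    is a periodic family of horizontal and vertical dark lines at ``pitch``
    px with random phase, composited multiplicatively like printed rulings
    (ink saturates: grid is invisible where the trace is already dark).  A
    ``1 - grid_prob`` share of pairs carries no grid (y = x), anchoring the
    residual at zero on grid-free content.
    """
    rng = np.random.default_rng(seed)
    ys = np.empty((n, size, size), dtype=np.float32)
    xs = np.empty((n, size, size), dtype=np.float32)
    for i in range(n):
        clean = np.ones((size, size), dtype=np.float32)
        if rng.random() > 0.2:  # some patches are pure background
            row = rng.uniform(4, size - 4)
            col_rows = np.clip(np.round(np.cumsum(
                np.concatenate([[row], rng.normal(0, 1.2, size - 1)]))), 1,
                size - 2).astype(int)
            clean[col_rows, np.arange(size)] = 0.0
            clean[np.clip(col_rows + 1, 0, size - 1), np.arange(size)] = 0.3
        grid = np.zeros((size, size), dtype=np.float32)
        if rng.random() < grid_prob:
            for axis in (0, 1):
                phase = rng.uniform(0, pitch)
                idx = np.round(np.arange(phase, size, pitch)).astype(int)
                idx = idx[idx < size]
                if axis == 0:
                    grid[idx, :] = np.maximum(grid[idx, :], grid_depth)
                else:
                    grid[:, idx] = np.maximum(grid[:, idx], grid_depth)
        ys[i] = np.clip(clean - grid, 0.0, 1.0)
        xs[i] = clean
    return ys, xs


def train_denoiser(pairs, spec: DenoiserSpec = None) -> DnCNN:
    """Train the residual denoiser on ``(noisy, clean)`` patch stacks."""
    noisy, clean = pairs
    spec = spec or DenoiserSpec.desk()
    model = DnCNN(spec)
    return model.fit(noisy, clean)


def classify_grid_pixels(pixels: np.ndarray, min_excess: int = 10,
                         min_level: int = 120) -> np.ndarray:
    """Boolean mask of pixels whose color matches the red ECG grid hue."""
    px = pixels.astype(int)
    r, g, b = px[:, :, 0], px[:, :, 1], px[:, :, 2]
    return (r > g + min_excess) & (r > b + min_excess) & (r > min_level)


def remove_grid(image: PaperImage, model: DnCNN = None,
                method: str = "dncnn", grid_hue: str = "red",
                fill: str = "background") -> PaperImage:
    """Remove the background grid from a rectified page.

    ``method="dncnn"`` runs each RGB channel through patchify -> residual
    prediction -> subtraction -> exponential-distance-weighted stitching.
    ``method="classical"`` suppresses grid-hued pixels, filling them with
    the paper background estimate (``fill="background"``) or by fast-marching
    inpainting (``fill="inpaint"``, slower).
    """
    if method == "dncnn":
        if model is None:
            raise ParameterError("dncnn grid removal requires a trained model")
        src = image.pixels.astype(np.float32)
        out = np.empty_like(src)
        for ch in range(3):
            ps = patchify(src[:, :, ch], channel_id=ch)
            ps.patches = ps.patches - model.predict_residual(ps.patches)
            out[:, :, ch] = stitch(ps)
        res = image.copy()
        res.pixels = np.clip(np.round(out), 0, 255).astype(np.uint8)
        res.log("remove_grid", method="dncnn")
        return res
    if method == "classical":
        if grid_hue != "red":
            raise ParameterError("classical removal supports the red grid hue")
        mask = classify_grid_pixels(image.pixels)
        res = image.copy()
        if fill == "inpaint":
            res = inpaint(res, mask)
        else:
            px = res.pixels.copy()
            bg = np.median(px[~mask].reshape(-1, 3), axis=0) if (~mask).any() \
                else np.array([255, 255, 255])
            px[mask] = np.clip(np.round(bg), 0, 255).astype(np.uint8)
            res.pixels = px
        res.log("remove_grid", method="classical", fill=fill)
        return res
    raise ParameterError(f"unknown grid removal method {method!r}")
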
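"""Global rotation estimation and correction via the Radon transform.

A rotated ECG page loses the horizontal alignment of its grid and trace
rows.  Projecting the ink mass along a family of angles (the Radon
transform) and scoring each angle by the variance of its projection profile
over offsets recovers the skew: the profile is most "peaky" when the
projection direction lines up with the page's dominant horizontal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import radon as _sk_radon
from skimage.transform import rescale, rotate as _sk_rotate

from .errors import ParameterError
from .paper_render import GroundTruth, PaperImage


@dataclass
class Sinogram:
    """Radon transform values over (offset ρ, angle θ in degrees)."""

    values: np.ndarray            # (n_rho, n_theta)
    rho_axis: np.ndarray          # pixel offsets, centered on 0
    theta_axis: np.ndarray        # degrees, strictly increasing

    def __post_init__(self):
        if np.any(np.diff(self.theta_axis) <= 0):
            raise ParameterError("theta_axis must be strictly increasing")


def radon(image_gray: np.ndarray, thetas) -> Sinogram:
    """Discrete line-integral projections of a single-channel image.

    Each column of the result is the projection profile at one angle; total
    mass is conserved per angle up to interpolation error.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise ParameterError("empty angle set")
    img = np.asarray(image_gray, dtype=float)
    if img.ndim != 2:
        raise ParameterError("radon expects a single-channel image")
    values = _sk_radon(img, theta=thetas, circle=False)
    rho = np.arange(values.shape[0]) - (values.shape[0] - 1) / 2.0
    order = np.argsort(thetas)
    return Sinogram(values[:, order], rho, thetas[order])


def _ink(image) -> np.ndarray:
    """Dark-ink mass image: 255 - luminance."""
    if isinstance(image, PaperImage):
        return 255.0 - image.gray()
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    return 255.0 - img


def estimate_rotation(image, theta_range: float = 45.0,
                      theta_step: float = 0.25,
                      refine_step: float = 0.05,
                      max_dim: int = 512) -> float:
    """Estimate the page rotation angle in degrees.

    Scores each candidate angle by the variance over ρ of the Radon
    projection profile of the ink image and returns the maximizer, searched
    coarsely over ±theta_range then refined once around the optimum.
    Positive values mean the page content is rotated counter-clockwise.
    """
    ink = _ink(image)
    if np.ptp(ink) < 1e-9:
        raise ParameterError("no dominant orientation in a constant image")
    scale = min(1.0, max_dim / max(ink.shape))
    if scale < 1.0:
        ink = rescale(ink, scale, order=1, anti_aliasing=True)
    ink = ink - ink.mean()

    def _score(thetas: np.ndarray) -> np.ndarray:
        sg = _sk_radon(ink, theta=90.0 + thetas, circle=False)
        return np.var(sg, axis=0)

    coarse = np.arange(-theta_range, theta_range + theta_step / 2, theta_step)
    s = _score(coarse)
    best = coarse[int(np.argmax(s))]
    fine = np.arange(best - theta_step, best + theta_step + refine_step / 2,
                     refine_step)
    s = _score(fine)
    return float(fine[int(np.argmax(s))])


def derotate(image: PaperImage, angle_deg: float,
             ground_truth: GroundTruth = None, background=255.0):
    """Rotate the page by ``-angle_deg`` about its center to undo a detected
    rotation; the ground truth (if given) is rotated consistently.

    Returns ``(image', ground_truth')`` (the latter ``None`` if not given).
    """
    if not np.isfinite(angle_deg):
        raise ParameterError("angle must be finite")
    src = image.pixels.astype(float)
    rotated = _sk_rotate(src, -angle_deg, resize=False, order=1,
                         mode="constant", cval=background,
                         preserve_range=True)
    out = PaperImage(rotated, dpi=image.dpi, provenance=list(image.provenance))
    out.log("derotate", angle_deg=angle_deg)
    gt = None
    if ground_truth is not None:
        h, w = image.shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        # matches skimage.transform.rotate's convention for the applied
        # -angle_deg rotation (verified against rendered ink positions)
        phi = np.deg2rad(angle_deg)
        c, s = np.cos(phi), np.sin(phi)
        matrix = np.array([
            [c, -s, cx - c * cx + s * cy],
            [s, c, cy - s * cx - c * cy],
            [0, 0, 1],
        ])
        gt = ground_truth.transform_points(matrix)
        gt = replace(gt, image_shape=out.shape)
    return out, gt


def rotate_page(image: PaperImage, angle_deg: float,
                ground_truth: GroundTruth = None, background=255.0):
    """Apply a rotation (the degradation); inverse of :func:`derotate`."""
    out, gt = derotate(image, -angle_deg, ground_truth, background)
    out.provenance[-1] = ("rotate_page", {"angle_deg": angle_deg})
    return out, gt
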
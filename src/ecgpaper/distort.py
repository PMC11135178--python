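"""Physical and imaging degradations for rendered ECG pages.

Covers crease lines blurred with an (optionally off-center) Gaussian kernel,
wrinkle textures synthesized by image quilting with minimum-error-boundary
cuts, affine/projective viewpoint changes applied consistently to image and
ground truth, per-pixel Gaussian / clipped-Poisson / salt-and-pepper noise,
and blackbody color-temperature tinting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform, resize, warp

from .errors import ParameterError
from .paper_render import GroundTruth, PaperImage


# ---------------------------------------------------------------------------
# Creases
# ---------------------------------------------------------------------------

@dataclass
class CreaseSpec:
    n_creases: int = 3
    angle_deg: float = 0.0
    sigma: float = 2.0
    kernel_size: int = 9
    kernel_offset: tuple = (0, 0)
    intensity: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ParameterError("kernel_size must be odd and >= 3")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        dx, dy = self.kernel_offset
        if abs(dx) >= self.kernel_size / 2 or abs(dy) >= self.kernel_size / 2:
            raise ParameterError("kernel_offset must lie inside the kernel")
        if not 0.0 <= self.intensity <= 1.0:
            raise ParameterError("intensity must be in [0, 1]")


def gaussian_kernel(sigma: float, kernel_size: int, offset=(0, 0)) -> np.ndarray:
    """L x L kernel evaluating G(x, y) = exp(-(x²+y²)/2σ²)/(2πσ²) at integer
    offsets relative to the (possibly displaced) center, normalized to sum 1.
    """
    if kernel_size % 2 == 0:
        raise ParameterError("kernel_size must be odd")
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    c = kernel_size // 2
    dx, dy = offset
    y, x = np.mgrid[0:kernel_size, 0:kernel_size]
    xr = x - (c + dx)
    yr = y - (c + dy)
    k = np.exp(-(xr ** 2 + yr ** 2) / (2.0 * sigma ** 2)) / (2 * np.pi * sigma ** 2)
    return k / k.sum()


def apply_creases(image: PaperImage, spec: CreaseSpec) -> PaperImage:
    """Darken ``n_creases`` equally spaced blurred fold lines.

    Lines run at ``angle_deg`` (0° = horizontal); their offsets are the
    n-quantiles of the perpendicular extent of the page.  The darkening field
    is convolved with the (possibly offset) Gaussian kernel, so an off-center
    kernel yields asymmetric shadows, as when light strikes a fold obliquely.
    """
    out = image.copy()
    if spec.n_creases == 0:
        return out
    h, w = image.shape
    theta = np.deg2rad(spec.angle_deg)
    # signed distance along the direction perpendicular to the crease lines
    y, x = np.mgrid[0:h, 0:w]
    p = -np.sin(theta) * x + np.cos(theta) * y
    pmin, pmax = p.min(), p.max()
    ink = np.zeros((h, w))
    for k in range(1, spec.n_creases + 1):
        pk = pmin + k / (spec.n_creases + 1) * (pmax - pmin)
        ink[np.abs(p - pk) < 0.5] = spec.intensity
    kernel = gaussian_kernel(spec.sigma, spec.kernel_size, spec.kernel_offset)
    shade = ndimage.convolve(ink, kernel, mode="constant")
    px = out.pixels.astype(float) * (1.0 - shade[:, :, None])
    out.pixels = np.clip(np.round(px), 0, 255).astype(np.uint8)
    out.log("apply_creases", n=spec.n_creases, angle=spec.angle_deg,
            sigma=spec.sigma, offset=tuple(spec.kernel_offset))
    return out


# ---------------------------------------------------------------------------
# Image quilting
# ---------------------------------------------------------------------------

def min_error_boundary_cut(e: np.ndarray):
    """Minimum-cost 8-connected top-to-bottom seam through an error surface.

    Cumulative cost follows E[i, j] = e[i, j] + min(E[i-1, j-1], E[i-1, j],
    E[i-1, j+1]) with out-of-range neighbors treated as +inf; ties break to
    the leftmost minimal predecessor.  Returns ``(path, cost)`` with one
    column index per row.
    """
    e = np.asarray(e, dtype=float)
    if e.ndim != 2 or e.size == 0:
        raise ParameterError("error surface must be a non-empty 2-D array")
    n, m = e.shape
    E = np.empty_like(e)
    E[0] = e[0]
    back = np.zeros((n, m), dtype=int)
    for i in range(1, n):
        padded = np.pad(E[i - 1], 1, constant_values=np.inf)
        cand = np.stack([padded[0:m], padded[1:m + 1], padded[2:m + 2]])
        best = np.argmin(cand, axis=0)          # leftmost min (argmin ties->first)
        back[i] = np.arange(m) + best - 1
        E[i] = e[i] + cand[best, np.arange(m)]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmin(E[-1]))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path, float(E[-1, path[-1]])


def wrinkle_seed_texture(size=(192, 192), seed: int = 0) -> np.ndarray:
    """Synthetic plain-wrinkle seed texture (grayscale float, 0-255).

    A procedurally generated stand-in for a photographed wrinkled-paper seed
    image: band-limited noise plus directional streaks, lightly embossed, so
    quilted output shows elongated fold-like luminance variation.
    """
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.standard_normal(size), 3.0)
    streaks = ndimage.gaussian_filter(rng.standard_normal(size), (10.0, 1.5))
    tex = base + 1.5 * streaks
    tex = (tex - tex.min()) / (np.ptp(tex) + 1e-12)
    return 150.0 + 100.0 * tex


@dataclass
class QuiltSpec:
    seed_texture: np.ndarray = None
    patch: int = 48
    overlap: int = 8
    out_size: tuple = (256, 256)
    blend_alpha: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.seed_texture is None:
            self.seed_texture = wrinkle_seed_texture(seed=self.seed)
        self.seed_texture = np.asarray(self.seed_texture, dtype=float)
        if not 0 < self.overlap < self.patch:
            raise ParameterError("require 0 < overlap < patch")
        th, tw = self.seed_texture.shape
        if th < self.patch or tw < self.patch:
            raise ParameterError("seed texture smaller than patch size")


def quilt_texture(spec: QuiltSpec) -> np.ndarray:
    """Synthesize an ``out_size`` texture by quilting random seed patches.

    Patches are placed raster-scan with ``overlap``-pixel overlaps; vertical
    and horizontal seams follow the minimum-error-boundary cut on the squared
    difference of the overlapping regions, and L-shaped corner overlaps
    combine both cuts.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.out_size
    p, ov = spec.patch, spec.overlap
    tex = spec.seed_texture
    th, tw = tex.shape
    out = np.zeros((H, W))
    step = p - ov
    rows = range(0, max(H - ov, 1), step)
    cols = range(0, max(W - ov, 1), step)
    for r0 in rows:
        for c0 in cols:
            pr = rng.integers(0, th - p + 1)
            pc = rng.integers(0, tw - p + 1)
            patch = tex[pr:pr + p, pc:pc + p].copy()
            ph = min(p, H - r0)
            pw = min(p, W - c0)
            patch = patch[:ph, :pw]
            use_new = np.ones((ph, pw), dtype=bool)
            if c0 > 0:
                old = out[r0:r0 + ph, c0:c0 + ov]
                e = (old - patch[:, :ov]) ** 2
                path, _ = min_error_boundary_cut(e)
                jj = np.arange(ov)
                use_new[:, :ov] &= jj[None, :] >= path[:, None]
            if r0 > 0:
                old = out[r0:r0 + ov, c0:c0 + pw]
                e = (old - patch[:ov, :]) ** 2
                path, _ = min_error_boundary_cut(e.T)
                ii = np.arange(ov)
                use_new[:ov, :] &= ii[:, None] >= path[None, :]
            region = out[r0:r0 + ph, c0:c0 + pw]
            region[use_new] = patch[use_new]
    return out


def apply_wrinkles(image: PaperImage, texture: np.ndarray,
                   blend_alpha: float) -> PaperImage:
    """Multiplicative luminance blend of a wrinkle texture onto the page.

    out = image * (1 - α + α * texture / mean(texture)), clipped to [0, 255];
    α = 0 (or a constant texture) leaves the image unchanged.
    """
    if not 0.0 <= blend_alpha <= 1.0:
        raise ParameterError("blend_alpha must be in [0, 1]")
    out = image.copy()
    h, w = image.shape
    tex = np.asarray(texture, dtype=float)
    if tex.shape != (h, w):
        tex = resize(tex, (h, w), order=1, mode="edge", anti_aliasing=False)
    gain = 1.0 - blend_alpha + blend_alpha * tex / tex.mean()
    px = out.pixels.astype(float) * gain[:, :, None]
    out.pixels = np.clip(np.round(px), 0, 255).astype(np.uint8)
    out.log("apply_wrinkles", blend_alpha=blend_alpha)
    return out


# ---------------------------------------------------------------------------
# Viewpoint change
# ---------------------------------------------------------------------------

@dataclass
class ProjectiveSpec:
    """3x3 homogeneous matrix (a b c; d e f; g h i); affine when g=h=0, i=1."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ParameterError("matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ParameterError("matrix must be invertible")
        if self.matrix[2, 2] != 0:
            self.matrix = self.matrix / self.matrix[2, 2]


def projective_transform(image: PaperImage, ground_truth: GroundTruth,
                         spec: ProjectiveSpec):
    """Warp image and ground truth by a projective (or affine) matrix.

    Pixels are inverse-warped with bilinear sampling and background fill;
    polylines are mapped by the forward matrix with homogeneous division.
    Returns ``(image', ground_truth')``.
    """
    tf = ProjectiveTransform(matrix=spec.matrix)
    bg = np.array([255, 255, 255], dtype=float)
    src = image.pixels.astype(float)
    h, w = image.shape
    warped = np.empty_like(src)
    for ch in range(3):
        warped[:, :, ch] = warp(src[:, :, ch], tf.inverse, order=1,
                                cval=bg[ch], mode="constant",
                                output_shape=(h, w), preserve_range=True)
    out = PaperImage(warped, dpi=image.dpi, provenance=list(image.provenance))
    out.log("projective_transform", matrix=spec.matrix.tolist())
    gt = ground_truth.transform_points(spec.matrix) if ground_truth else None
    return out, gt


# ---------------------------------------------------------------------------
# Imaging noise
# ---------------------------------------------------------------------------

@dataclass
class ImagingNoiseSpec:
    gaussian_eta: float = 0.0
    poisson_lambda: float = 0.0
    salt_pepper_p: float = 0.0
    color_temp_k: float = 6600.0
    seed: int = 0

    def __post_init__(self):
        if self.gaussian_eta < 0 or self.poisson_lambda < 0:
            raise ParameterError("noise levels must be >= 0")
        if not 0.0 <= self.salt_pepper_p <= 1.0:
            raise ParameterError("salt_pepper_p must be in [0, 1]")
        if not 1000.0 <= self.color_temp_k <= 40000.0:
            raise ParameterError("color_temp_k must be in [1000, 40000]")


def add_gaussian_noise(image: PaperImage, eta: float, seed: int = 0) -> PaperImage:
    """Per-pixel additive N(0, η) sensor noise, clipped to [0, 255]."""
    if eta < 0:
        raise ParameterError("eta must be >= 0")
    out = image.copy()
    if eta > 0:
        rng = np.random.default_rng(seed)
        px = out.pixels.astype(float) + rng.normal(0.0, eta, out.pixels.shape)
        out.pixels = np.clip(np.round(px), 0, 255).astype(np.uint8)
    out.log("add_gaussian_noise", eta=eta, seed=seed)
    return out


def add_poisson_noise(image: PaperImage, lam: float, seed: int = 0) -> PaperImage:
    """Per-pixel additive Poisson(λ) shot noise, clipped to [0, 255]."""
    if lam < 0:
        raise ParameterError("lambda must be >= 0")
    out = image.copy()
    if lam > 0:
        rng = np.random.default_rng(seed)
        px = out.pixels.astype(float) + rng.poisson(lam, out.pixels.shape)
        out.pixels = np.clip(px, 0, 255).astype(np.uint8)
    out.log("add_poisson_noise", lam=lam, seed=seed)
    return out


def add_salt_pepper(image: PaperImage, p: float, seed: int = 0) -> PaperImage:
    """Set each pixel (all three channels jointly) to 0 or 255, each with
    probability p/2."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError("p must be in [0, 1]")
    out = image.copy()
    if p > 0:
        rng = np.random.default_rng(seed)
        u = rng.random(image.shape)
        px = out.pixels.copy()
        px[u < p / 2] = 0
        px[(u >= p / 2) & (u < p)] = 255
        out.pixels = px
    out.log("add_salt_pepper", p=p, seed=seed)
    return out


def _blackbody_whitepoint(kelvin: float) -> np.ndarray:
    """Approximate RGB white point of a blackbody at ``kelvin`` (0-255)."""
    t = kelvin / 100.0
    if t <= 66:
        r = 255.0
        g = 99.4708025861 * np.log(t) - 161.1195681661
    else:
        r = 329.698727446 * (t - 60) ** -0.1332047592
        g = 288.1221695283 * (t - 60) ** -0.0755148492
    if t >= 66:
        b = 255.0
    elif t <= 19:
        b = 0.0
    else:
        b = 138.5177312231 * np.log(t - 10) - 305.0447927307
    return np.clip([r, g, b], 0, 255)


def apply_color_temperature(image: PaperImage, kelvin: float) -> PaperImage:
    """Tint the page toward a blackbody white point.

    Channel scales are normalized by the 6600 K white point, so K = 6600 is
    the identity; lower temperatures tint orange (R up relative to B), higher
    ones blue.
    """
    if not 1000.0 <= kelvin <= 40000.0:
        raise ParameterError("kelvin must be in [1000, 40000]")
    scale = _blackbody_whitepoint(kelvin) / _blackbody_whitepoint(6600.0)
    out = image.copy()
    px = out.pixels.astype(float) * scale[None, None, :]
    out.pixels = np.clip(np.round(px), 0, 255).astype(np.uint8)
    out.log("apply_color_temperature", kelvin=kelvin)
    return out


def apply_imaging_noise(image: PaperImage, spec: ImagingNoiseSpec) -> PaperImage:
    """Full imaging-noise stack: color temperature, Gaussian, Poisson, then
    salt-and-pepper last so its extremes survive the color operations."""
    out = apply_color_temperature(image, spec.color_temp_k)
    out = add_gaussian_noise(out, spec.gaussian_eta, spec.seed)
    out = add_poisson_noise(out, spec.poisson_lambda, spec.seed + 1)
    out = add_salt_pepper(out, spec.salt_pepper_p, spec.seed + 2)
    return out


# ---------------------------------------------------------------------------
# Distortion profiles
# ---------------------------------------------------------------------------

PROFILES = {
    "clean": {},
    "scanner": {
        "creases": {"n_creases": 2, "angle_deg": 85.0, "sigma": 2.0,
                    "kernel_size": 9, "intensity": 0.25},
        "wrinkles": {"blend_alpha": 0.2},
        "gaussian_eta": 3.0,
        "color_temp_k": 5500.0,
    },
    "photo": {
        "creases": {"n_creases": 3, "angle_deg": 70.0, "sigma": 2.5,
                    "kernel_size": 11, "kernel_offset": (2, 0),
                    "intensity": 0.35},
        "wrinkles": {"blend_alpha": 0.35},
        "projective": {"matrix": [[1.0, 0.01, 5.0],
                                  [-0.01, 1.0, -3.0],
                                  [2e-5, 1e-5, 1.0]]},
        "gaussian_eta": 6.0,
        "poisson_lambda": 3.0,
        "salt_pepper_p": 0.002,
        "color_temp_k": 4200.0,
    },
}


def load_distortion_profile(name_or_path: str) -> dict:
    """Resolve a distortion profile: a built-in preset name
    (clean/scanner/photo) or a YAML/JSON file naming each distortion and its
    parameters."""
    if name_or_path in PROFILES:
        return dict(PROFILES[name_or_path])
    import yaml
    with open(name_or_path, encoding="utf-8") as fh:
        profile = yaml.safe_load(fh)        # YAML is a superset of JSON
    if not isinstance(profile, dict):
        raise ParameterError("distortion profile must be a mapping")
    return profile


def apply_distortion_profile(image: PaperImage, ground_truth=None,
                             profile="scanner", seed: int = 0):
    """Apply a named or loaded distortion profile to a rendered page.

    Stack order: creases -> wrinkles -> perspective -> color temperature ->
    Gaussian -> Poisson -> salt-and-pepper; the provenance log records the
    operations actually applied.  Returns ``(image', ground_truth')``.
    """
    if isinstance(profile, str):
        profile = load_distortion_profile(profile)
    out, gt = image.copy(), ground_truth
    if "creases" in profile:
        out = apply_creases(out, CreaseSpec(seed=seed, **profile["creases"]))
    if "wrinkles" in profile:
        params = dict(profile["wrinkles"])
        alpha = params.pop("blend_alpha", 0.3)
        h, w = out.shape
        tex = quilt_texture(QuiltSpec(out_size=(max(h // 4, 64),
                                                max(w // 4, 64)),
                                      seed=seed, **params))
        out = apply_wrinkles(out, tex, alpha)
    if "projective" in profile:
        spec = ProjectiveSpec(np.asarray(profile["projective"]["matrix"],
                                         dtype=float))
        out, gt = projective_transform(out, gt, spec)
    if "color_temp_k" in profile:
        out = apply_color_temperature(out, profile["color_temp_k"])
    if profile.get("gaussian_eta"):
        out = add_gaussian_noise(out, profile["gaussian_eta"], seed + 1)
    if profile.get("poisson_lambda"):
        out = add_poisson_noise(out, profile["poisson_lambda"], seed + 2)
    if profile.get("salt_pepper_p"):
        out = add_salt_pepper(out, profile["salt_pepper_p"], seed + 3)
    return out, gt
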
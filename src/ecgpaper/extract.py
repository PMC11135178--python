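"""Trace extraction: strips -> binary mask -> components -> ŷ(x) -> mV.

The cleaned page is segmented into lead strips from the smoothed row-mean
intensity profile; each strip is binarized with a local 3x3 threshold,
labelled with 4-connected component analysis (small components dropped,
nearby fragments fused by outer-boundary Hausdorff distance), blurred with a
1x3 rectangular filter, and reduced to one row index per column by the
column-wise darkest pixel.  Pixel rows convert to millivolts through the
scaling factor 0.5 mV / coarse-grid-pixels, and columns to seconds through
the image-implied sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps
from scipy.spatial import cKDTree

from .errors import ParameterError
from .paper_render import MM_PER_INCH, PaperImage


# ---------------------------------------------------------------------------
# Strip detection
# ---------------------------------------------------------------------------

@dataclass
class RowProfile:
    """Row-mean intensity Ī(x) and its L-point moving average Î(x)."""

    mean_intensity: np.ndarray
    smoothed: np.ndarray
    filter_order: int
    image_width: int


def row_profile(image, filter_order: int = 11) -> RowProfile:
    """Ī(x) = mean intensity of row x; Î(x) = L-point moving average.

    Edge handling replicates the boundary rows of Ī so the non-causal filter
    stays full-length everywhere.
    """
    gray = image.gray() if isinstance(image, PaperImage) else np.asarray(image, float)
    if gray.ndim != 2:
        raise ParameterError("row_profile expects a single-channel image")
    if filter_order % 2 == 0 or filter_order < 1:
        raise ParameterError("filter order must be odd and positive")
    ibar = gray.mean(axis=1)
    m = (filter_order - 1) // 2
    padded = np.pad(ibar, m, mode="edge")
    ihat = np.convolve(padded, np.ones(filter_order) / filter_order,
                       mode="valid")
    return RowProfile(ibar, ihat, filter_order, gray.shape[1])


def detect_strips(image, filter_order: int = 11,
                  min_gap_px: float = None) -> list:
    """Row-interval ROIs, one per ECG strip, from the smoothed row profile.

    Significant minima are Î minima below (max+min)/2, merged when closer
    than ``min_gap_px`` (default 5 mm at the image DPI); ROI boundaries sit
    at the Î maxima between consecutive minima.
    """
    prof = row_profile(image, filter_order)
    ihat = prof.smoothed
    lo, hi = float(ihat.min()), float(ihat.max())
    if hi - lo < 1e-6:
        raise ParameterError("no strips found: uniform intensity profile")
    if min_gap_px is None:
        dpi = image.dpi if isinstance(image, PaperImage) else 200.0
        min_gap_px = 5.0 * dpi / MM_PER_INCH
    thresh = (hi + lo) / 2.0
    minima, _ = sps.find_peaks(-ihat)
    minima = [int(r) for r in minima if ihat[r] < thresh]
    if not minima:
        raise ParameterError("no strips found: no significant minima")
    merged = [[minima[0]]]
    for r in minima[1:]:
        if r - merged[-1][-1] <= min_gap_px:
            merged[-1].append(r)
        else:
            merged.append([r])
    centers = [int(round(np.mean(g))) for g in merged]
    rois = []
    bounds = [0]
    for a, b in zip(centers[:-1], centers[1:]):
        bounds.append(a + int(np.argmax(ihat[a:b + 1])))
    bounds.append(len(ihat))
    for k, _ in enumerate(centers):
        rois.append((bounds[k], bounds[k + 1]))
    return rois


# ---------------------------------------------------------------------------
# Binarization and component analysis
# ---------------------------------------------------------------------------

def binarize(strip_image, offset: float = 10.0, inverted: bool = False) -> np.ndarray:
    """Foreground = pixels darker than their 3x3 local mean by ``offset``.

    With ``inverted=True`` the input is contrast-flipped first so bright
    traces on dark background binarize identically.
    """
    gray = strip_image.gray() if isinstance(strip_image, PaperImage) \
        else np.asarray(strip_image, dtype=float)
    if gray.ndim == 3:
        gray = gray @ np.array([0.299, 0.587, 0.114])
    if inverted:
        gray = 255.0 - gray
    local_mean = ndimage.uniform_filter(gray, size=3, mode="nearest")
    return gray < local_mean - offset


@dataclass
class ComponentSet:
    """4-connected labelling of a binary mask plus per-component geometry."""

    labels: np.ndarray
    ids: list = field(default_factory=list)
    areas: dict = field(default_factory=dict)
    bboxes: dict = field(default_factory=dict)       # (h, w)
    boundaries: dict = field(default_factory=dict)   # (n, 2) outer pixels

    def mask(self) -> np.ndarray:
        return self.labels > 0


_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _outer_boundary(component_mask: np.ndarray) -> np.ndarray:
    inner = ndimage.binary_erosion(component_mask, structure=_FOUR)
    return np.argwhere(component_mask & ~inner)


def analyze_components(mask: np.ndarray, min_h: int = 3, min_w: int = 3,
                       min_area: int = 10, max_area: int = None,
                       fuse_dist: float = 10.0) -> ComponentSet:
    """Label, filter, and fuse 4-connected components of a binary mask.

    Components below the height/width/area thresholds (or above
    ``max_area``) are discarded; remaining components are merged iteratively
    (union-find to a fixpoint) when their outer boundaries approach within
    ``fuse_dist`` pixels, so trace fragments broken by grid removal re-join.
    Distances are computed on outer-boundary pixels only.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_FOUR)
    keep = np.zeros(n + 1, dtype=bool)
    slices = ndimage.find_objects(labels)
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    for i in range(1, n + 1):
        sl = slices[i - 1]
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        a = areas[i - 1]
        ok = h >= min_h and w >= min_w and a >= min_area
        if max_area is not None:
            ok = ok and a <= max_area
        keep[i] = ok
    labels = np.where(keep[labels], labels, 0)
    ids = [i for i in range(1, n + 1) if keep[i]]

    boundaries = {i: _outer_boundary(labels == i) for i in ids}
    parent = {i: i for i in ids}
    if fuse_dist <= 0:
        cs = ComponentSet(labels=labels)
        for i in ids:
            m = labels == i
            cs.ids.append(i)
            cs.areas[i] = int(m.sum())
            sl = slices[i - 1]
            cs.bboxes[i] = (sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
            cs.boundaries[i] = boundaries[i]
        return cs

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    changed = True
    while changed:
        changed = False
        roots = sorted({find(i) for i in ids})
        merged_bounds = {}
        for r in roots:
            pts = [boundaries[i] for i in ids if find(i) == r]
            merged_bounds[r] = np.concatenate(pts) if len(pts) > 1 else pts[0]
        for a_i in range(len(roots)):
            for b_i in range(a_i + 1, len(roots)):
                ra, rb = roots[a_i], roots[b_i]
                if find(ra) == find(rb):
                    continue
                pa, pb = merged_bounds[ra], merged_bounds[rb]
                d = cKDTree(pa).query(pb, k=1)[0].min()
                if d <= fuse_dist:
                    parent[find(rb)] = find(ra)
                    changed = True

    relabel = {}
    out_labels = np.zeros_like(labels)
    for i in ids:
        r = find(i)
        relabel.setdefault(r, len(relabel) + 1)
        out_labels[labels == i] = relabel[r]
    cs = ComponentSet(labels=out_labels)
    for r, new_id in relabel.items():
        m = out_labels == new_id
        cs.ids.append(new_id)
        cs.areas[new_id] = int(m.sum())
        rows_any = np.any(m, axis=1)
        cols_any = np.any(m, axis=0)
        r0, r1 = np.nonzero(rows_any)[0][[0, -1]]
        c0, c1 = np.nonzero(cols_any)[0][[0, -1]]
        cs.bboxes[new_id] = (int(r1 - r0 + 1), int(c1 - c0 + 1))
        cs.boundaries[new_id] = _outer_boundary(m)
    return cs


# ---------------------------------------------------------------------------
# Trace extraction
# ---------------------------------------------------------------------------

@dataclass
class ExtractedTrace:
    """One row index per column plus its calibrated mV conversion."""

    y_hat: np.ndarray                 # float row per column (interpolated)
    missing: np.ndarray               # bool per column
    signal_mv: np.ndarray = None
    fs_image: float = None
    coarse_grid_px: float = None
    baseline_row: float = None


def extract_trace(component_mask: np.ndarray, intensities: np.ndarray = None,
                  dark_threshold: float = 220.0) -> ExtractedTrace:
    """Column-wise darkest-pixel trace ŷ(x) from a component mask.

    The mask is rendered dark-on-white (foreground at its grayscale
    intensity when ``intensities`` is given, else 0; background 255) and
    blurred with a 1x3 mean filter; per column the candidate foreground
    pixel with the lowest blurred intensity wins (ties -> smallest row),
    so fragments continuous with their neighbors are preferred.  Columns
    with no foreground are marked missing and linearly interpolated.
    """
    mask = np.asarray(component_mask, dtype=bool)
    if mask.ndim != 2:
        raise ParameterError("component mask must be 2-D")
    h, w = mask.shape
    if intensities is not None:
        gray = np.where(mask, np.asarray(intensities, dtype=float), 255.0)
    else:
        gray = np.where(mask, 0.0, 255.0)
    blurred = ndimage.uniform_filter1d(gray, size=3, axis=1, mode="constant",
                                       cval=255.0)
    y = np.full(w, np.nan)
    for x in range(w):
        rows = np.nonzero(mask[:, x])[0]
        if rows.size == 0:
            continue
        vals = blurred[rows, x]
        if intensities is None and np.min(vals) > dark_threshold:
            continue
        y[x] = rows[int(np.argmin(vals))]     # argmin ties -> smallest row
    missing = np.isnan(y)
    if missing.all():
        raise ParameterError("no trace found in any column")
    if missing.any():
        idx = np.arange(w)
        y[missing] = np.interp(idx[missing], idx[~missing], y[~missing])
    return ExtractedTrace(y_hat=y, missing=missing)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _autocorr_period(profile: np.ndarray, max_lag: int) -> float:
    x = profile - profile.mean()
    if np.ptp(x) < 1e-9:
        return np.nan
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    ac = ac / ac[0]
    lo = 3
    seg = ac[lo:max_lag]
    peaks, props = sps.find_peaks(seg, height=0.05)
    if peaks.size == 0:
        return np.nan
    p = int(peaks[np.argmax(props["peak_heights"])])
    # take the first peak comparable to the strongest (harmonics are weaker)
    for q in peaks:
        if ac[lo + q] >= 0.5 * ac[lo + p]:
            p = int(q)
            break
    def _refine(k: int) -> float:
        if 1 <= k < len(ac) - 1:   # parabolic sub-pixel refinement
            denom = ac[k - 1] - 2 * ac[k] + ac[k + 1]
            if abs(denom) > 1e-12:
                return k - 0.5 * (ac[k + 1] - ac[k - 1]) / denom
        return float(k)

    period = _refine(lo + p)
    # climb to ever-higher harmonic peaks: locating the i-th peak to the same
    # sub-pixel accuracy divides the period's relative error by i
    top = min(len(ac) - 2, 8 * max_lag)
    order = 1
    while True:
        next_order = min(2 * order, int(top // period))
        if next_order <= order:
            break
        k0 = int(round(next_order * period))
        span = max(2, int(round(period / 3)))
        window = ac[k0 - span:k0 + span + 1]
        if window.size == 0:
            break
        k_best = k0 - span + int(np.argmax(window))
        period = _refine(k_best) / next_order
        order = next_order
    return float(period)


def estimate_grid_period(image, fine_to_coarse: int = 5) -> float:
    """Coarse-grid pitch in pixels from ink-profile autocorrelation.

    Estimates the fine-grid period from the first significant peak of the
    row- and column-mean autocorrelation (sub-pixel, parabolic) and scales by
    5; run this on the original image before grid removal.
    """
    gray = image.gray() if isinstance(image, PaperImage) else np.asarray(image, float)
    if gray.ndim == 3:
        gray = gray @ np.array([0.299, 0.587, 0.114])
    ink = 255.0 - gray
    est = []
    for axis in (0, 1):
        prof = ink.mean(axis=axis)
        p = _autocorr_period(prof, max_lag=max(20, len(prof) // 4))
        if np.isfinite(p):
            est.append(p)
    if not est:
        raise ParameterError("no periodicity detected: gridless image?")
    return fine_to_coarse * float(np.median(est))


def to_physical_units(y_hat: np.ndarray, baseline_row: float,
                      coarse_grid_px: float = None, dpi: float = None,
                      paper_speed: float = 25.0):
    """Convert a pixel trace to millivolts and report its sampling rate.

    signal_mv = (baseline_row - ŷ) * (0.5 mV / coarse_grid_px); the image
    sampling frequency is D/1.016 when the DPI is trusted, otherwise
    coarse_grid_px / 0.2 s at standard paper speed.
    """
    if coarse_grid_px is None and dpi is None:
        raise ParameterError("need a coarse grid estimate or a trusted DPI")
    if coarse_grid_px is not None and coarse_grid_px <= 0:
        raise ParameterError("coarse_grid_px must be positive")
    if coarse_grid_px is None:
        coarse_grid_px = 5.0 * dpi / MM_PER_INCH
    scaling_factor = 0.5 / coarse_grid_px        # mV per pixel
    signal_mv = (baseline_row - np.asarray(y_hat, dtype=float)) * scaling_factor
    if dpi is not None:
        fs_image = dpi / 1.016
    else:
        fs_image = coarse_grid_px / 0.2 * (paper_speed / 25.0)
    return signal_mv, fs_image


def estimate_baseline_row(y_hat: np.ndarray) -> float:
    """Baseline = mode of the rounded trace rows (flat segments dominate)."""
    rounded = np.round(np.asarray(y_hat, dtype=float)).astype(int)
    values, counts = np.unique(rounded, return_counts=True)
    return float(values[int(np.argmax(counts))])


def resample_and_align(signal_mv: np.ndarray, fs_image: float,
                       reference: np.ndarray, fs: float,
                       max_lag_s: float = 0.5):
    """Resample to ``fs`` and align to ``reference`` by cross-correlation.

    Returns ``(est_aligned, ref_aligned, lag)`` truncated to common support;
    the integer lag maximizes the cross-correlation within ±``max_lag_s``.
    Zero-variance inputs skip alignment with lag 0.
    """
    sig = np.asarray(signal_mv, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if sig.size == 0 or ref.size == 0:
        raise ParameterError("series must be non-empty")
    n_out = int(round(sig.size * fs / fs_image))
    t_old = np.arange(sig.size) / fs_image
    t_new = np.arange(n_out) / fs
    res = np.interp(t_new, t_old, sig)
    if np.ptp(res) < 1e-12 or np.ptp(ref) < 1e-12:
        n = min(res.size, ref.size)
        return res[:n], ref[:n], 0
    max_lag = int(round(max_lag_s * fs))
    a = res - res.mean()
    b = ref - ref.mean()
    corr = sps.correlate(a, b, mode="full")
    lags = sps.correlation_lags(a.size, b.size, mode="full")
    sel = np.abs(lags) <= max_lag
    lag = int(lags[sel][np.argmax(corr[sel])])
    # lag > 0: est is delayed relative to ref
    if lag >= 0:
        est_al, ref_al = res[lag:], ref
    else:
        est_al, ref_al = res, ref[-lag:]
    n = min(est_al.size, ref_al.size)
    return est_al[:n], ref_al[:n], lag
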
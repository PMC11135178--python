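"""Render ECG time-series onto standard ECG-paper rasters.

Standard ECG paper runs at 25 mm/s horizontally and 10 mm/mV vertically, with
a 1 mm fine grid and a 5 mm coarse grid (0.2 s / 0.5 mV per coarse cell).
Scanned at D dots per inch, one pixel therefore spans dv = 2.54/D millivolts
vertically and dt = 1.016/D seconds horizontally, giving an image-implied
sampling frequency of f̃s = D/1.016 Hz.

Coordinate convention: origin top-left, x = column (time), y = row; amplitude
increases upward, i.e. toward smaller row indices.  Traces are drawn as
1-px-wide polylines whose per-column sample pixels carry the pure trace
colour; vertical jumps between adjacent columns are filled with a lighter
connector tone so the trace stays 8-connected while the column-wise darkest
pixel remains the true sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .ecg_source import ECGTimeSeries
from .errors import ParameterError

MM_PER_INCH = 25.4


class ResolutionParams(NamedTuple):
    dv_mv: float      # mV per pixel
    dt_s: float       # s per pixel
    fs_image: float   # image-implied sampling frequency, Hz


def resolution_params(dpi: float) -> ResolutionParams:
    """Amplitude/time resolution and implied sampling rate of a D-DPI scan.

    dv = 2.54/D mV, dt = 1.016/D s, f̃s = D/1.016 Hz (at standard 25 mm/s
    speed and 10 mm/mV gain); dt * f̃s == 1 identically.
    """
    if dpi <= 0:
        raise ParameterError("dpi must be positive")
    return ResolutionParams(2.54 / dpi, 1.016 / dpi, dpi / 1.016)


@dataclass
class RenderSpec:
    """Geometry and style of a rendered ECG page."""

    dpi: float = 200.0
    paper_speed: float = 25.0          # mm/s
    gain: float = 10.0                 # mm/mV
    paper_size: tuple = (11.0, 8.5)    # (width_in, height_in), landscape
    rows: int = 3
    cols: int = 4
    rhythm_leads: tuple = ("II",)
    segment_len: float = 2.5           # seconds per segment slot
    synchronous_segments: bool = True
    background: tuple = (255, 255, 255)
    fine_color: tuple = (255, 204, 204)
    coarse_color: tuple = (255, 128, 128)
    trace_color: tuple = (0, 0, 0)
    trace_thickness: int = 1
    show_grid: bool = True
    show_calibration: bool = True
    margin_in: float = 0.25

    def __post_init__(self):
        if self.dpi < 72:
            raise ParameterError("dpi must be >= 72")
        if self.paper_speed <= 0 or self.gain <= 0:
            raise ParameterError("paper_speed and gain must be positive")

    @property
    def px_per_mm(self) -> float:
        return self.dpi / MM_PER_INCH

    @property
    def px_per_mv(self) -> float:
        return self.gain * self.dpi / MM_PER_INCH

    @property
    def px_per_second(self) -> float:
        return self.paper_speed * self.dpi / MM_PER_INCH

    @property
    def fine_pitch_px(self) -> float:
        return self.dpi / MM_PER_INCH

    @property
    def coarse_pitch_px(self) -> float:
        return 5.0 * self.dpi / MM_PER_INCH

    @property
    def canvas_shape(self) -> tuple:
        w_in, h_in = self.paper_size
        return int(round(h_in * self.dpi)), int(round(w_in * self.dpi))


@dataclass
class PaperImage:
    """RGB raster with DPI tag and an append-only degradation log."""

    pixels: np.ndarray            # H x W x 3 uint8
    dpi: float
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ParameterError("pixels must be H x W x 3")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.round(self.pixels), 0, 255).astype(np.uint8)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]

    def log(self, op: str, **params) -> None:
        self.provenance.append((op, params))

    def copy(self) -> "PaperImage":
        return replace(self, pixels=self.pixels.copy(),
                       provenance=list(self.provenance))

    def gray(self) -> np.ndarray:
        """Luminance (0.299, 0.587, 0.114) grayscale as float64."""
        return self.pixels @ np.array([0.299, 0.587, 0.114])


@dataclass
class SegmentTruth:
    """Ground truth for one rendered segment: a functional pixel polyline."""

    lead: str
    t0: float
    t1: float
    cols: np.ndarray              # int columns, consecutive
    rows: np.ndarray              # int row per column
    baseline_row: int
    px_per_mv: float
    px_per_second: float

    def as_float_points(self) -> np.ndarray:
        return np.stack([self.cols.astype(float), self.rows.astype(float)], axis=1)


@dataclass
class GroundTruth:
    """All segment polylines plus calibration pulses of a rendered page."""

    segments: list
    calibration: list = field(default_factory=list)
    dpi: float = 200.0
    image_shape: tuple = (0, 0)

    def all_segments(self) -> list:
        return list(self.segments) + list(self.calibration)

    def transform_points(self, matrix: np.ndarray) -> "GroundTruth":
        """Map every polyline through a 3x3 homogeneous matrix (forward)."""
        matrix = np.asarray(matrix, dtype=float)

        def _map(seg: SegmentTruth) -> SegmentTruth:
            pts = np.stack([seg.cols.astype(float), seg.rows.astype(float),
                            np.ones(len(seg.cols))])
            out = matrix @ pts
            w = out[2]
            if np.any(w == 0):
                raise ParameterError("transform maps points to infinity")
            cols = out[0] / w
            rows = out[1] / w
            base = matrix @ np.array([seg.cols.mean(), float(seg.baseline_row), 1.0])
            return replace(seg, cols=cols, rows=rows,
                           baseline_row=int(round(base[1] / base[2])))

        return replace(self, segments=[_map(s) for s in self.segments],
                       calibration=[_map(s) for s in self.calibration])


def _accumulate_lines(cov: np.ndarray, positions: np.ndarray) -> None:
    """Add subpixel line coverage at real-valued ``positions`` into ``cov``."""
    n = cov.shape[0]
    base = np.floor(positions).astype(int)
    frac = positions - base
    for b, f in zip(base, frac):
        if 0 <= b < n:
            cov[b] = max(cov[b], 1.0 - f)
        if 0 <= b + 1 < n:
            cov[b + 1] = max(cov[b + 1], f)


def _blend_axis(pixels: np.ndarray, cov: np.ndarray, color, axis: int) -> None:
    color = np.array(color, dtype=float)
    shape = [1, 1, 1]
    shape[axis] = cov.shape[0]
    c = cov.reshape(shape)
    out = pixels * (1.0 - c) + color.reshape(1, 1, 3) * c
    pixels[:] = out


def render_grid(spec: RenderSpec) -> PaperImage:
    """Render the blank ECG paper: background plus fine/coarse grid.

    Line positions accumulate in floating point (pitch = D/25.4 px for the
    fine grid), with per-line subpixel coverage, so the mean line period is
    exact even at non-integer pitch.
    """
    h, w = spec.canvas_shape
    if min(h, w) < spec.coarse_pitch_px:
        raise ParameterError("paper too small for one coarse grid cell")
    pixels = np.empty((h, w, 3), dtype=float)
    pixels[:] = np.array(spec.background, dtype=float)
    if spec.show_grid:
        fine = spec.fine_pitch_px
        for axis, dim in ((1, w), (0, h)):
            k = np.arange(int(np.floor((dim - 1) / fine)) + 1)
            pos = k * fine
            cov_f = np.zeros(dim)
            _accumulate_lines(cov_f, pos[k % 5 != 0])
            cov_c = np.zeros(dim)
            _accumulate_lines(cov_c, pos[k % 5 == 0])
            _blend_axis(pixels, cov_f, spec.fine_color, axis)
            _blend_axis(pixels, cov_c, spec.coarse_color, axis)
    img = PaperImage(pixels, dpi=spec.dpi)
    img.log("render_grid", dpi=spec.dpi, show_grid=spec.show_grid)
    return img


def _connector_color(spec: RenderSpec) -> np.ndarray:
    c = np.array(spec.trace_color, dtype=float)
    return c + (255.0 - c) * 0.7


def _draw_polyline(pixels: np.ndarray, cols: np.ndarray, rows: np.ndarray,
                   color, connector_color, thickness: int = 1) -> None:
    """Draw sample pixels in ``color``; fill vertical jumps with connector.

    Connector pixels occupy the rows strictly between consecutive samples, in
    the newer column, so every column's darkest pixel is its true sample.
    """
    h, w = pixels.shape[:2]
    conn = np.asarray(connector_color, dtype=float)
    col = np.asarray(color, dtype=float)
    for i in range(1, len(cols)):
        c = cols[i]
        r0, r1 = rows[i - 1], rows[i]
        if abs(r1 - r0) > 1 and 0 <= c < w:
            lo, hi = (r0 + 1, r1) if r1 > r0 else (r1 + 1, r0)
            lo = max(lo, 0)
            hi = min(hi, h)
            pixels[lo:hi, c] = conn
    half = (thickness - 1) // 2
    for c, r in zip(cols, rows):
        if 0 <= c < w and 0 <= r < h:
            pixels[max(r - half, 0):min(r + half + 1, h),
                   max(c - half, 0):min(c + half + 1, w)] = col


def calibration_pulse_polyline(spec: RenderSpec) -> tuple:
    """Pixel offsets (dcols, drows) of the standard 1 mV / 0.2 s pulse.

    drows are relative to the baseline row (negative = up); the plateau is
    ``gain`` mm high and ``0.2 * paper_speed`` mm wide, flanked by short
    baseline lead-in/out shoulders.
    """
    lead_px = max(2, int(round(0.04 * spec.px_per_second)))
    plateau_px = int(round(0.2 * spec.px_per_second))
    height_px = int(round(spec.gain * spec.px_per_mm))  # gain mm == 1 mV
    n = 2 * lead_px + plateau_px + 1
    dcols = np.arange(n)
    drows = np.zeros(n, dtype=int)
    drows[lead_px:lead_px + plateau_px + 1] = -height_px
    return dcols, drows


def render_calibration_pulse(spec: RenderSpec, baseline_row: int,
                             col0: int) -> SegmentTruth:
    """Place the calibration pulse polyline at absolute page coordinates."""
    dcols, drows = calibration_pulse_polyline(spec)
    return SegmentTruth(lead="CAL", t0=0.0, t1=len(dcols) / spec.px_per_second,
                        cols=col0 + dcols, rows=baseline_row + drows,
                        baseline_row=baseline_row,
                        px_per_mv=spec.px_per_mv,
                        px_per_second=spec.px_per_second)


def _band_baselines(spec: RenderSpec, n_bands: int) -> list:
    h, _ = spec.canvas_shape
    margin = spec.margin_in * spec.dpi
    usable = h - 2 * margin
    band_h = usable / n_bands
    return [int(round(margin + (r + 0.5) * band_h)) for r in range(n_bands)]


def render_ecg(ecg: ECGTimeSeries, spec: RenderSpec = None):
    """Render a multi-lead ECG page; returns (PaperImage, GroundTruth).

    Layout: ``rows x cols`` segment slots filled column-major in standard
    lead order, plus one full-duration rhythm strip per entry of
    ``rhythm_leads``.  Each polyline row is
    ``baseline - round(sample_mV * px_per_mV)``.
    """
    spec = spec or RenderSpec()
    n_slots = spec.rows * spec.cols
    if spec.rows > 0 and spec.cols > 0:
        if n_slots > ecg.n_leads:
            raise ParameterError("layout needs more leads than the record has")
    for name in spec.rhythm_leads:
        if name not in ecg.lead_names:
            raise ParameterError(f"rhythm lead {name!r} missing from record")
    needed = spec.cols * spec.segment_len
    if not spec.synchronous_segments:
        needed += (spec.rows - 1) * spec.segment_len
    if needed > ecg.duration + 1e-9:
        raise ParameterError("record shorter than layout needs")

    img = render_grid(spec)
    pixels = img.pixels.astype(float)
    n_bands = spec.rows + len(spec.rhythm_leads)
    baselines = _band_baselines(spec, n_bands)
    margin_px = int(round(spec.margin_in * spec.dpi))
    conn = _connector_color(spec)

    calibration = []
    x_signal = margin_px
    if spec.show_calibration:
        dcols, _ = calibration_pulse_polyline(spec)
        x_signal = margin_px + len(dcols) + int(round(2 * spec.px_per_mm))
        for b in baselines:
            pulse = render_calibration_pulse(spec, b, margin_px)
            _draw_polyline(pixels, pulse.cols, pulse.rows, spec.trace_color,
                           conn, spec.trace_thickness)
            calibration.append(pulse)

    seg_w = int(round(spec.segment_len * spec.px_per_second))
    segments = []

    def _draw_segment(lead: str, t0: float, t1: float, col0: int,
                      baseline: int) -> SegmentTruth:
        sig = ecg.lead(lead)
        n_cols = int(round((t1 - t0) * spec.px_per_second))
        cols = col0 + np.arange(n_cols)
        t = t0 + (cols - col0) / spec.px_per_second
        v = np.interp(t, ecg.t, sig)
        rows = (baseline - np.round(v * spec.px_per_mv)).astype(int)
        _draw_polyline(pixels, cols, rows, spec.trace_color, conn,
                       spec.trace_thickness)
        return SegmentTruth(lead=lead, t0=t0, t1=t1, cols=cols, rows=rows,
                            baseline_row=baseline, px_per_mv=spec.px_per_mv,
                            px_per_second=spec.px_per_second)

    for r in range(spec.rows):
        for c in range(spec.cols):
            lead = ecg.lead_names[c * spec.rows + r]
            t0 = c * spec.segment_len
            if not spec.synchronous_segments:
                t0 += r * spec.segment_len
            segments.append(_draw_segment(lead, t0, t0 + spec.segment_len,
                                          x_signal + c * seg_w, baselines[r]))
    for k, lead in enumerate(spec.rhythm_leads):
        _, w = spec.canvas_shape
        max_t = min(ecg.duration, (w - margin_px - x_signal)
                    / spec.px_per_second)
        segments.append(_draw_segment(lead, 0.0, max_t, x_signal,
                                      baselines[spec.rows + k]))

    out = PaperImage(pixels, dpi=spec.dpi, provenance=list(img.provenance))
    out.log("render_ecg", leads=list(ecg.lead_names), layout=(spec.rows, spec.cols),
            rhythm=list(spec.rhythm_leads))
    truth = GroundTruth(segments=segments, calibration=calibration,
                        dpi=spec.dpi, image_shape=out.shape)
    return out, truth


def render_calibration_page(spec: RenderSpec = None):
    """Render a page holding only the grid and one calibration pulse.

    Used for scale-verification round trips: the recovered plateau should
    read 1.00 mV and 0.200 s after grid-based unit conversion.
    """
    spec = spec or RenderSpec()
    img = render_grid(spec)
    pixels = img.pixels.astype(float)
    baseline = _band_baselines(spec, 1)[0]
    margin_px = int(round(spec.margin_in * spec.dpi))
    pulse = render_calibration_pulse(spec, baseline, margin_px)
    _draw_polyline(pixels, pulse.cols, pulse.rows, spec.trace_color,
                   _connector_color(spec), spec.trace_thickness)
    out = PaperImage(pixels, dpi=spec.dpi, provenance=list(img.provenance))
    out.log("render_calibration_page")
    truth = GroundTruth(segments=[], calibration=[pulse], dpi=spec.dpi,
                        image_shape=out.shape)
    return out, truth
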
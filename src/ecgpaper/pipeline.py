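"""End-to-end drivers: render -> degrade -> rectify -> clean -> extract.

These compose the per-stage modules into the two round trips users run most:
digitizing a rendered page back to calibrated time-series (optionally with
ground-truth segment windows, the synthetic-mode shortcut for splitting
multi-lead rows), and measuring a rendered calibration pulse to verify the
amplitude/time scale of the whole chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cleanup import remove_grid
from .ecg_source import ECGTimeSeries
from .errors import ParameterError
from .evaluate import EvalReport, rr_error
from .extract import (analyze_components, binarize, detect_strips,
                      estimate_baseline_row, estimate_grid_period,
                      extract_trace, resample_and_align, to_physical_units)
from .paper_render import GroundTruth, PaperImage


@dataclass
class DigitizedSegment:
    lead: str
    t0: float
    t1: float
    signal_mv: np.ndarray
    fs_image: float
    y_hat: np.ndarray
    missing_fraction: float


@dataclass
class DigitizationResult:
    segments: list = field(default_factory=list)
    coarse_grid_px: float = None


def _component_mask(sub_gray: np.ndarray, min_area: int = 2) -> np.ndarray:
    # The rendered trace is 1 px thick, so height/width minimums are relaxed
    # relative to the module defaults and fusion is unnecessary (the union
    # mask feeds the extractor); specks are removed by the area threshold.
    mask = binarize(sub_gray)
    comps = analyze_components(mask, min_h=1, min_w=1, min_area=min_area,
                               fuse_dist=0.0)
    if comps.ids:
        return comps.mask()
    return mask


def digitize_segments(image: PaperImage, ground_truth: GroundTruth,
                      grid_removal: str = "classical", model=None,
                      coarse_grid_px: float = None,
                      margin_px: int = 8) -> DigitizationResult:
    """Digitize a rendered page using ground-truth segment windows.

    The coarse grid pitch is estimated from the (still gridded) image, the
    grid is removed, and each segment's window is binarized, component-
    filtered, and reduced to a column-wise trace converted to millivolts via
    the 0.5 mV / coarse-grid-pixel scaling factor.  The per-segment baseline
    is the mode of the extracted rows.
    """
    if coarse_grid_px is None:
        coarse_grid_px = estimate_grid_period(image)
    cleaned = remove_grid(image, model=model, method=grid_removal)
    gray = cleaned.gray()
    h, w = gray.shape
    result = DigitizationResult(coarse_grid_px=coarse_grid_px)
    for seg in ground_truth.all_segments():
        c0 = max(int(np.floor(seg.cols.min())), 0)
        c1 = min(int(np.ceil(seg.cols.max())) + 1, w)
        r0 = max(int(np.floor(seg.rows.min())) - margin_px, 0)
        r1 = min(int(np.ceil(seg.rows.max())) + margin_px + 1, h)
        sub = gray[r0:r1, c0:c1]
        mask = _component_mask(sub, min_area=2)
        trace = extract_trace(mask, intensities=sub)
        y_global = trace.y_hat + r0
        baseline = estimate_baseline_row(y_global)
        signal_mv, fs_image = to_physical_units(
            y_global, baseline, coarse_grid_px=coarse_grid_px)
        result.segments.append(DigitizedSegment(
            lead=seg.lead, t0=seg.t0, t1=seg.t1, signal_mv=signal_mv,
            fs_image=fs_image, y_hat=y_global,
            missing_fraction=float(trace.missing.mean())))
    return result


def digitize_strips(image: PaperImage, coarse_grid_px: float = None,
                    grid_removal: str = "classical", model=None) -> DigitizationResult:
    """Digitize without ground truth: detected row strips, one trace each."""
    if coarse_grid_px is None:
        coarse_grid_px = estimate_grid_period(image)
    cleaned = remove_grid(image, model=model, method=grid_removal)
    gray = cleaned.gray()
    result = DigitizationResult(coarse_grid_px=coarse_grid_px)
    for k, (r0, r1) in enumerate(detect_strips(cleaned)):
        sub = gray[r0:r1]
        mask = _component_mask(sub, min_area=4)
        trace = extract_trace(mask, intensities=sub)
        y_global = trace.y_hat + r0
        baseline = estimate_baseline_row(y_global)
        signal_mv, fs_image = to_physical_units(
            y_global, baseline, coarse_grid_px=coarse_grid_px)
        result.segments.append(DigitizedSegment(
            lead=f"strip{k}", t0=0.0, t1=len(signal_mv) / fs_image,
            signal_mv=signal_mv, fs_image=fs_image, y_hat=y_global,
            missing_fraction=float(trace.missing.mean())))
    return result


def evaluate_roundtrip(result: DigitizationResult, ecg: ECGTimeSeries,
                       report: EvalReport = None,
                       rr_lead: str = "II") -> EvalReport:
    """Score a digitization against its source record.

    Each segment estimate is resampled to the record's fs and aligned by
    cross-correlation against the matching lead window; per-record SNR/MSE
    pool all aligned samples, and the RR error uses the longest segment of
    ``rr_lead`` (normally the rhythm strip).
    """
    report = report or EvalReport()
    est_all, ref_all = [], []
    rr_pair = None
    rr_len = 0.0
    for seg in result.segments:
        if seg.lead not in ecg.lead_names:
            continue
        i0 = int(round(seg.t0 * ecg.fs))
        i1 = min(int(round(seg.t1 * ecg.fs)), ecg.n_samples)
        ref = ecg.lead(seg.lead)[i0:i1]
        est, ref_al, _lag = resample_and_align(seg.signal_mv, seg.fs_image,
                                               ref, ecg.fs)
        est_all.append(est)
        ref_all.append(ref_al)
        if seg.lead == rr_lead and (seg.t1 - seg.t0) > rr_len:
            rr_len = seg.t1 - seg.t0
            rr_pair = (ref_al, est)
    if not est_all:
        raise ParameterError("no segments matched the reference record")
    x = np.concatenate(ref_all)
    x_hat = np.concatenate(est_all)
    report.add_record(x, x_hat)
    if rr_pair is not None and rr_len >= 5.0:
        try:
            err, _, _ = rr_error(rr_pair[0], rr_pair[1], ecg.fs)
            report.rr_error_ms.append(err)
        except ParameterError:
            pass
    return report


def measure_calibration_pulse(result: DigitizationResult):
    """Plateau amplitude (mV) and width (s) of a digitized calibration pulse.

    The extracted rows cluster at two levels; the pulse amplitude is the mV
    difference between the modal baseline level and the modal plateau level,
    and the width is the dwell time above the half-amplitude midline.
    """
    seg = next((s for s in result.segments if s.lead == "CAL"),
               result.segments[0] if result.segments else None)
    if seg is None:
        raise ParameterError("no digitized segment to measure")
    mv = seg.signal_mv
    hi = mv > (mv.min() + mv.max()) / 2.0
    if not hi.any() or hi.all():
        raise ParameterError("no pulse plateau found")
    plateau = _mode(mv[hi])
    baseline = _mode(mv[~hi])
    width_s = float(hi.sum()) / seg.fs_image
    return plateau - baseline, width_s


def _mode(values: np.ndarray) -> float:
    v, c = np.unique(np.round(np.asarray(values, float), 6),
                     return_counts=True)
    return float(v[int(np.argmax(c))])
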
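"""Round-trip fidelity metrics: SNR, median-noise SNR, MSE, interval errors.

SNR = mean(x²) / mean((x - x̂)²) in dB weights every sample equally;
SNR_med replaces the mean noise power with its median, which ignores the
occasional single-pixel spikes that dominate digitization error.  Cohort
summaries report the 2.5th/97.5th percentiles and the mean ± std over the
middle 95% of the distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

SNR_CAP_DB = 200.0   # sentinel for a zero noise-power denominator


def _check_pair(x, x_hat):
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ParameterError("series length mismatch")
    if x.size < 1:
        raise ParameterError("series must be non-empty")
    return x.ravel(), x_hat.ravel()


def _ratio_db(p_sig: float, p_err: float) -> float:
    """10*log10(p_sig/p_err), clamped to the +/-200 dB sentinel band."""
    if p_err == 0:
        return SNR_CAP_DB
    if p_sig == 0:
        return -SNR_CAP_DB
    db = float(10.0 * np.log10(p_sig / p_err))
    return float(np.clip(db, -SNR_CAP_DB, SNR_CAP_DB))


def snr(x, x_hat) -> float:
    """10·log10(mean(x²) / mean((x−x̂)²)) dB; capped at 200 dB when exact."""
    x, x_hat = _check_pair(x, x_hat)
    p_sig = np.mean(x ** 2)
    p_err = np.mean((x - x_hat) ** 2)
    return _ratio_db(p_sig, p_err)


def snr_med(x, x_hat) -> float:
    """SNR with the median (not mean) noise power in the denominator."""
    x, x_hat = _check_pair(x, x_hat)
    p_sig = np.mean(x ** 2)
    p_err = np.median((x - x_hat) ** 2)
    return _ratio_db(p_sig, p_err)


def mse(x, x_hat):
    """Mean squared error in mV² and its RMS in mV."""
    x, x_hat = _check_pair(x, x_hat)
    m = float(np.mean((x - x_hat) ** 2))
    return m, float(np.sqrt(m))


def percentile_summary(values, lo: float = 2.5, hi: float = 97.5):
    """(lo_val, hi_val, trimmed_mean, trimmed_std) of a metric distribution.

    Endpoints use linear-interpolated percentiles; mean/std cover the values
    strictly inside [lo_val, hi_val] (falling back to the closed interval
    when the open one is empty, e.g. constant input).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ParameterError("need at least two values")
    lo_val, hi_val = np.percentile(values, [lo, hi])
    inside = values[(values > lo_val) & (values < hi_val)]
    if inside.size == 0:
        inside = values[(values >= lo_val) & (values <= hi_val)]
    return (float(lo_val), float(hi_val),
            float(inside.mean()), float(inside.std()))


# ---------------------------------------------------------------------------
# R peaks and intervals
# ---------------------------------------------------------------------------

def detect_rpeaks(x, fs: float, refractory_s: float = 0.2) -> np.ndarray:
    """R-peak sample indices: local maxima above an adaptive threshold with a
    200 ms refractory period."""
    if fs <= 0:
        raise ParameterError("fs must be positive")
    x = np.asarray(x, dtype=float).ravel()
    thresh = x.mean() + 0.5 * (x.max() - x.mean())
    cand = np.nonzero((x[1:-1] >= x[:-2]) & (x[1:-1] > x[2:])
                      & (x[1:-1] > thresh))[0] + 1
    if cand.size == 0:
        raise ParameterError("no peaks found")
    refractory = int(round(refractory_s * fs))
    peaks = [int(cand[0])]
    for c in cand[1:]:
        if c - peaks[-1] >= refractory:
            peaks.append(int(c))
        elif x[c] > x[peaks[-1]]:
            peaks[-1] = int(c)
    return np.asarray(peaks)


def rr_error(ref, est, fs: float):
    """Mean |ΔRR| in ms between matched consecutive-peak intervals.

    ``ref`` and ``est`` are 1-D signals sampled at ``fs``; intervals are
    matched in order (extra intervals in the longer list are ignored).
    Returns (mean_abs_error_ms, ref_rr_ms, est_rr_ms).
    """
    pr = detect_rpeaks(ref, fs)
    pe = detect_rpeaks(est, fs)
    rr_ref = np.diff(pr) / fs * 1000.0
    rr_est = np.diff(pe) / fs * 1000.0
    n = min(rr_ref.size, rr_est.size)
    if n == 0:
        raise ParameterError("too few peaks to form RR intervals")
    err = float(np.mean(np.abs(rr_ref[:n] - rr_est[:n])))
    return err, rr_ref, rr_est


def interval_comparison(ref_records, est_records, delineator):
    """Per-record absolute interval errors (ms) through a pluggable
    delineator.

    ``delineator(record)`` returns a dict of interval measurements in ms
    (e.g. {"QRS": .., "QT": .., "RR": ..}); records where it raises are
    skipped and counted.  Returns a dict with per-interval error arrays,
    their cohort percentile summaries, and the skip count.
    """
    errors = {}
    skipped = 0
    for ref, est in zip(ref_records, est_records):
        try:
            iv_ref = delineator(ref)
            iv_est = delineator(est)
        except Exception:
            skipped += 1
            continue
        for key in iv_ref:
            if key in iv_est:
                errors.setdefault(key, []).append(
                    abs(float(iv_ref[key]) - float(iv_est[key])))
    out = {"skipped": skipped, "errors_ms": {k: np.asarray(v)
                                             for k, v in errors.items()}}
    out["summary"] = {k: percentile_summary(v) for k, v in errors.items()
                      if len(v) >= 2}
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-record metrics plus cohort summaries mirroring the standard
    (2.5th pct, 97.5th pct, average ± STD) schema."""

    snr_db: list = field(default_factory=list)
    snr_med_db: list = field(default_factory=list)
    mse_mv2: list = field(default_factory=list)
    rms_mv: list = field(default_factory=list)
    rr_error_ms: list = field(default_factory=list)
    lags: list = field(default_factory=list)

    def add_record(self, x, x_hat, fs: float = None, lag: int = 0,
                   with_rr: bool = False) -> None:
        self.snr_db.append(snr(x, x_hat))
        self.snr_med_db.append(snr_med(x, x_hat))
        m, r = mse(x, x_hat)
        self.mse_mv2.append(m)
        self.rms_mv.append(r)
        self.lags.append(lag)
        if with_rr and fs:
            err, _, _ = rr_error(x, x_hat, fs)
            self.rr_error_ms.append(err)

    def cohort(self) -> dict:
        out = {}
        for name in ("snr_db", "snr_med_db", "mse_mv2", "rms_mv",
                     "rr_error_ms"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size == 0:
                continue
            entry = {"mean": float(vals.mean()), "std": float(vals.std()),
                     "n": int(vals.size)}
            if vals.size >= 2:
                lo, hi, tm, ts = percentile_summary(vals)
                entry.update({"pct_2_5": lo, "pct_97_5": hi,
                              "trimmed_mean": tm, "trimmed_std": ts})
            out[name] = entry
        return out
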
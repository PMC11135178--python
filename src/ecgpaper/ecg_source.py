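"""Ground-truth ECG time-series: synthesis, physiological noise, WFDB I/O.

The synthetic generator produces a quasi-periodic 12-lead waveform built from
sum-of-Gaussian beat templates (one Gaussian kernel per P/Q/R/S/T wave, with
per-lead amplitudes) whose beat onsets follow a lightly jittered RR process.
It stands in for real recordings wherever a ground-truth time-series is
needed, so that rendering and digitization can be exercised end to end
without external data.

WFDB support covers the common single-segment, format-16 layout: a plain-text
``.hea`` header plus an interleaved little-endian int16 ``.dat`` file.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import FormatError, ParameterError

STANDARD_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

NOISE_COMPONENTS = ("baseline_wander", "powerline", "muscle", "white")


@dataclass
class ECGTimeSeries:
    """Multi-lead ECG samples in millivolts.

    Attributes
    ----------
    samples : ndarray, shape (n_leads, n_samples)
        Amplitudes in mV.
    fs : float
        Sampling frequency in Hz.
    lead_names : tuple of str
        Unique lead labels, one per row of ``samples``.
    header : dict
        Free-form metadata (name/ID/date strings) carried into rendering.
    """

    samples: np.ndarray
    fs: float
    lead_names: tuple
    header: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ParameterError("samples must be a 2-D (n_leads, n_samples) array")
        if self.fs <= 0:
            raise ParameterError("sampling frequency must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must be finite")
        self.lead_names = tuple(self.lead_names)
        if len(self.lead_names) != self.samples.shape[0]:
            raise ParameterError("one lead name per signal row required")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ParameterError("lead names must be unique")

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.lead_names.index(name)]
        except ValueError:
            raise ParameterError(f"lead {name!r} not present") from None

    def copy(self) -> "ECGTimeSeries":
        return replace(self, samples=self.samples.copy(),
                       header=dict(self.header))


@dataclass
class NoiseSpec:
    """Target for physiological noise contamination.

    snr_db is the whole-record, all-leads-pooled signal-to-noise ratio of the
    mixture; components is a subset of NOISE_COMPONENTS.
    """

    snr_db: float
    components: tuple = NOISE_COMPONENTS
    mains_freq: float = 50.0
    seed: int = 0

    def __post_init__(self):
        self.components = tuple(self.components)
        unknown = set(self.components) - set(NOISE_COMPONENTS)
        if unknown:
            raise ParameterError(f"unknown noise components: {sorted(unknown)}")
        if np.isnan(self.snr_db):
            raise ParameterError("snr_db must not be NaN")


# Per-lead Gaussian-wave amplitudes (mV) for P, Q, R, S, T.  Values follow
# textbook 12-lead morphology: dominant R in the lateral leads, rS pattern
# and precordial R progression in V1-V3, globally negative aVR.
_WAVE_AMPS = {
    "I":   (0.08, -0.06, 0.70, -0.12, 0.25),
    "II":  (0.12, -0.08, 1.10, -0.20, 0.35),
    "III": (0.05, -0.04, 0.50, -0.10, 0.12),
    "aVR": (-0.10, 0.05, -0.90, 0.15, -0.30),
    "aVL": (0.03, -0.03, 0.35, -0.08, 0.10),
    "aVF": (0.09, -0.06, 0.80, -0.15, 0.25),
    "V1":  (0.05, 0.00, 0.25, -0.90, -0.10),
    "V2":  (0.06, 0.00, 0.70, -1.10, 0.25),
    "V3":  (0.07, -0.02, 0.90, -0.80, 0.40),
    "V4":  (0.08, -0.05, 1.30, -0.50, 0.50),
    "V5":  (0.09, -0.06, 1.20, -0.30, 0.40),
    "V6":  (0.09, -0.07, 1.00, -0.20, 0.30),
}
# Wave centres (s relative to the R peak) and Gaussian widths (s).
_WAVE_CENTERS = (-0.20, -0.035, 0.0, 0.035, 0.28)
_WAVE_WIDTHS = (0.045, 0.012, 0.022, 0.016, 0.070)


def synthesize_ecg(n_leads: int = 12, fs: float = 250.0, duration: float = 10.0,
                   heart_rate_bpm: float = 60.0, seed: int = 0) -> ECGTimeSeries:
    """Generate a deterministic multi-lead ECG with P-QRS-T morphology.

    Beats are placed by an RR process with ~2% Gaussian jitter around
    60/heart_rate_bpm; each beat contributes five Gaussian kernels per lead.
    """
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if not 20 <= heart_rate_bpm <= 300:
        raise ParameterError("heart_rate_bpm must be in [20, 300]")
    if not 1 <= n_leads <= len(STANDARD_LEADS):
        raise ParameterError(f"n_leads must be in [1, {len(STANDARD_LEADS)}]")

    rng = np.random.default_rng(seed)
    rr_mean = 60.0 / heart_rate_bpm
    n_beats = int(np.ceil(duration / rr_mean)) + 3
    rr = rr_mean * (1.0 + 0.02 * rng.standard_normal(n_beats))
    rr = np.clip(rr, 0.5 * rr_mean, 1.5 * rr_mean)
    # first R peak a bit after the record start so the P wave is not clipped
    beat_times = 0.35 * rr_mean + np.concatenate(([0.0], np.cumsum(rr[:-1])))
    beat_times = beat_times[beat_times < duration + 0.5]

    # narrow QRS at fast rates, shorter ST at fast rates
    width_scale = np.clip(rr_mean, 0.5, 1.2)

    n_samples = int(round(duration * fs))
    t = np.arange(n_samples) / fs
    leads = STANDARD_LEADS[:n_leads]
    x = np.zeros((n_leads, n_samples))
    for li, name in enumerate(leads):
        amps = _WAVE_AMPS[name]
        for tb in beat_times:
            for a, c, w in zip(amps, _WAVE_CENTERS, _WAVE_WIDTHS):
                cw = c * width_scale
                ww = w * np.sqrt(width_scale)
                lo = np.searchsorted(t, tb + cw - 5 * ww)
                hi = np.searchsorted(t, tb + cw + 5 * ww)
                seg = t[lo:hi] - tb - cw
                x[li, lo:hi] += a * np.exp(-0.5 * (seg / ww) ** 2)
    return ECGTimeSeries(x, fs, leads, header={})


def _noise_component(kind: str, n_leads: int, n: int, fs: float,
                     mains_freq: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros((n_leads, n))
    if kind == "white":
        out = rng.standard_normal((n_leads, n))
    elif kind == "powerline":
        for li in range(n_leads):
            phase = rng.uniform(0, 2 * np.pi)
            am = 1.0 + 0.1 * np.sin(2 * np.pi * rng.uniform(0.1, 0.5) * t
                                    + rng.uniform(0, 2 * np.pi))
            out[li] = am * np.sin(2 * np.pi * mains_freq * t + phase)
    elif kind == "baseline_wander":
        freqs = rng.uniform(0.05, 0.45, size=5)
        for li in range(n_leads):
            phases = rng.uniform(0, 2 * np.pi, size=5)
            amps = rng.uniform(0.3, 1.0, size=5)
            out[li] = sum(a * np.sin(2 * np.pi * f * t + p)
                          for a, f, p in zip(amps, freqs, phases))
    elif kind == "muscle":
        w = rng.standard_normal((n_leads, n))
        nyq = fs / 2.0
        hi = min(0.95, 100.0 / nyq)
        lo = min(20.0 / nyq, 0.5 * hi)
        b, a = sps.butter(4, [lo, hi], btype="bandpass")
        out = sps.filtfilt(b, a, w, axis=1)
    else:  # pragma: no cover - guarded by NoiseSpec
        raise ParameterError(f"unknown noise component {kind!r}")
    return out


def add_physiological_noise(ecg: ECGTimeSeries, spec: NoiseSpec) -> ECGTimeSeries:
    """Return a noisy copy of ``ecg`` at exactly the requested pooled SNR.

    The noise mixture is scaled so that 10*log10(sum x^2 / sum n^2), pooled
    over all leads and samples, equals ``spec.snr_db``.  Infinite SNR or an
    empty component set returns an unmodified copy.
    """
    if not spec.components or np.isposinf(spec.snr_db):
        return ecg.copy()
    rng = np.random.default_rng(spec.seed)
    noise = np.zeros_like(ecg.samples)
    for kind in spec.components:
        noise += _noise_component(kind, ecg.n_leads, ecg.n_samples, ecg.fs,
                                  spec.mains_freq, rng)
    p_sig = np.mean(ecg.samples ** 2)
    p_noise = np.mean(noise ** 2)
    if p_noise == 0:
        return ecg.copy()
    scale = np.sqrt(p_sig / (p_noise * 10.0 ** (spec.snr_db / 10.0)))
    out = ecg.copy()
    out.samples = ecg.samples + scale * noise
    return out


# ---------------------------------------------------------------------------
# WFDB format-16 I/O
# ---------------------------------------------------------------------------

_DEFAULT_ADC_GAIN = 1000.0  # ADC units per mV -> 1 uV quantization


def write_wfdb(ecg: ECGTimeSeries, path: str) -> None:
    """Write ``ecg`` as a WFDB record (``path.hea`` + ``path.dat``, format 16).

    Header metadata fields are stored as ``# key: value`` comment lines and
    round-trip verbatim through :func:`read_wfdb`.
    """
    record = os.path.basename(path)
    gain = _DEFAULT_ADC_GAIN
    adc = np.round(ecg.samples * gain)
    if np.any(np.abs(adc) > 32767):
        raise ParameterError("signal exceeds int16 range at gain "
                             f"{gain:g} adu/mV")
    adc = adc.astype("<i2")
    fs_repr = f"{ecg.fs:g}"
    lines = [f"{record} {ecg.n_leads} {fs_repr} {ecg.n_samples}"]
    for li, name in enumerate(ecg.lead_names):
        first = int(adc[li, 0]) if ecg.n_samples else 0
        checksum = int(np.sum(adc[li], dtype=np.int64) % 65536)
        lines.append(f"{record}.dat 16 {gain:g}(0)/mV 16 0 {first} "
                     f"{checksum} 0 {name}")
    for key, value in ecg.header.items():
        lines.append(f"# {key}: {value}")
    with open(path + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    # sample-major interleaving: frame k holds one sample of every signal
    adc.T.tofile(path + ".dat")


_SIGNAL_LINE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)\s+(?P<gain>[\d.eE+-]+)"
    r"(\((?P<baseline>-?\d+)\))?(/(?P<units>\S+))?"
    r"(?:\s+\S+){0,5}(?:\s+(?P<desc>\S.*))?$"
)


def read_wfdb(path: str) -> ECGTimeSeries:
    """Read a single-segment, format-16 WFDB record written by this toolkit
    (or any compatible producer)."""
    hea = path + ".hea"
    with open(hea) as fh:
        raw_lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in raw_lines if ln.strip()]
    if not lines:
        raise FormatError(f"{hea}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: malformed record line: {lines[0]!r}")
    try:
        n_sig = int(head[1])
        fs = float(head[2])
        n_samples = int(head[3])
    except ValueError:
        raise FormatError(f"{hea}: malformed record line: {lines[0]!r}") from None

    gains, baselines, names = [], [], []
    dat_file = None
    for ln in lines[1:1 + n_sig]:
        m = _SIGNAL_LINE.match(ln.strip())
        if m is None or m.group("fmt") != "16":
            raise FormatError(f"{hea}: malformed signal line: {ln!r}")
        dat_file = m.group("file")
        gains.append(float(m.group("gain")) or _DEFAULT_ADC_GAIN)
        baselines.append(int(m.group("baseline") or 0))
        desc = m.group("desc")
        names.append(desc.strip() if desc else f"sig{len(names)}")
    if len(gains) != n_sig:
        raise FormatError(f"{hea}: expected {n_sig} signal lines")

    header = {}
    for ln in lines[1 + n_sig:]:
        if ln.lstrip().startswith("#"):
            body = ln.lstrip()[1:].strip()
            if ":" in body:
                key, value = body.split(":", 1)
                header[key.strip()] = value.strip()

    dat_path = os.path.join(os.path.dirname(path) or ".", dat_file)
    if not os.path.exists(dat_path):
        raise FormatError(f"missing signal file {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size < n_sig * n_samples:
        raise FormatError(f"{dat_path}: truncated signal data")
    frames = raw[:n_sig * n_samples].reshape(n_samples, n_sig).T
    samples = (frames - np.array(baselines)[:, None]) / np.array(gains)[:, None]
    return ECGTimeSeries(samples, fs, names, header=header)
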
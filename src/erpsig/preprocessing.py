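"""Minimal native preprocessing operators for ERP pipelines.

High-pass and notch filtering (zero-phase two-pass by default), average /
median / channel-list re-referencing, pre-stimulus baseline subtraction,
line-noise channel detection, spherical-spline channel interpolation, and
peak-to-peak trial rejection.  All operators return new objects and leave
their inputs untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .data_model import ContinuousRecording, EpochSet

__all__ = [
    "FilterSpec",
    "highpass_filter",
    "notch_filter",
    "rereference",
    "baseline_subtract",
    "detect_line_noise_channels",
    "interpolate_channels",
    "reject_trials_peak_to_peak",
]


@dataclass
class FilterSpec:
    """High-pass filter design.

    kind "butterworth": IIR Butterworth of the given per-pass ``order``
    (default 4).  kind "fir_sinc": Hamming windowed-sinc FIR; its length is
    derived from ``fir_transition_hz`` (default ``max(cutoff, 1)`` Hz,
    centred on the cutoff).  ``two_pass`` applies the filter forward and
    backward for zero phase.
    """

    kind: str = "butterworth"
    cutoff_hz: float = 0.5
    order: int = 4
    two_pass: bool = True
    fir_transition_hz: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("butterworth", "fir_sinc"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def _fir_highpass_taps(cutoff_hz: float, srate: float, transition_hz: float | None) -> np.ndarray:
    tb = transition_hz if transition_hz is not None else max(cutoff_hz, 1.0)
    # Hamming window: ~3.3 / (normalized transition width) taps, odd length
    n_taps = int(math.ceil(3.3 * srate / tb))
    if n_taps % 2 == 0:
        n_taps += 1
    return signal.firwin(n_taps, cutoff_hz, window="hamming", pass_zero=False, fs=srate)


def highpass_filter(rec: ContinuousRecording, spec: FilterSpec) -> ContinuousRecording:
    """High-pass filter a continuous recording (filtering precedes epoching).

    Two-pass application (``spec.two_pass``) is forward-backward and
    zero-phase; the quoted ``order`` refers to a single pass, so the two-pass
    Butterworth attenuates the cutoff frequency to half amplitude (-3 dB per
    pass).
    """
    nyq = rec.srate / 2.0
    if spec.cutoff_hz >= nyq:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz must be below Nyquist ({nyq} Hz)")
    out = rec.copy()
    if spec.kind == "butterworth":
        sos = signal.butter(spec.order, spec.cutoff_hz, btype="highpass", fs=rec.srate, output="sos")
        if spec.two_pass:
            out.data = signal.sosfiltfilt(sos, rec.data, axis=1)
        else:
            out.data = signal.sosfilt(sos, rec.data, axis=1)
    else:
        taps = _fir_highpass_taps(spec.cutoff_hz, rec.srate, spec.fir_transition_hz)
        if taps.size * 3 > rec.n_samples:
            raise ValueError(
                f"recording too short for FIR filter of length {taps.size}"
            )
        if spec.two_pass:
            out.data = signal.filtfilt(taps, [1.0], rec.data, axis=1)
        else:
            out.data = signal.lfilter(taps, [1.0], rec.data, axis=1)
    return out


def notch_filter(
    rec: ContinuousRecording,
    band: tuple[float, float] = (48.0, 52.0),
    kind: str = "fir",
) -> ContinuousRecording:
    """Band-stop (notch) filter for mains noise, zero-phase.

    ``band`` gives the stop-band passband edges, default (48, 52) Hz for
    50-Hz mains.  "fir" uses a Hamming windowed-sinc band-stop design with a
    2-Hz transition band; "iir" a 4th-order (per pass) Butterworth band-stop.
    """
    nyq = rec.srate / 2.0
    lo, hi = band
    if not (0 < lo < hi < nyq):
        raise ValueError(f"invalid notch band {band} for srate {rec.srate}")
    out = rec.copy()
    if kind == "fir":
        tb = 2.0
        n_taps = int(math.ceil(3.3 * rec.srate / tb))
        if n_taps % 2 == 0:
            n_taps += 1
        taps = signal.firwin(n_taps, [lo, hi], window="hamming", pass_zero=True, fs=rec.srate)
        out.data = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    elif kind == "iir":
        sos = signal.butter(4, [lo, hi], btype="bandstop", fs=rec.srate, output="sos")
        out.data = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        raise ValueError(f"unknown notch kind {kind!r}")
    return out


def _reref_array(data: np.ndarray, scheme, labels: Sequence[str]) -> np.ndarray:
    """Subtract the reference from a channels-first array."""
    if scheme == "none":
        return data.copy()
    if scheme == "average":
        return data - data.mean(axis=0, keepdims=True)
    if scheme == "median":
        return data - np.median(data, axis=0, keepdims=True)
    if isinstance(scheme, (list, tuple)):
        idx = []
        for lab in scheme:
            if lab not in labels:
                raise ValueError(f"unknown channel label {lab!r}")
            idx.append(list(labels).index(lab))
        return data - data[idx].mean(axis=0, keepdims=True)
    raise ValueError(f"unknown re-referencing scheme {scheme!r}")


def rereference(obj, scheme="average"):
    """Re-reference a recording or epoch set.

    ``scheme`` is "none", "average", "median", or a list of channel labels
    whose mean becomes the reference.  The reference is computed and
    subtracted per sample (and per trial for epoched data).
    """
    out = obj.copy()
    out.data = _reref_array(obj.data, scheme, obj.channel_labels)
    return out


def baseline_subtract(ep: EpochSet, interval: tuple[float, float]) -> EpochSet:
    """Subtract the mean over a pre-stimulus interval from every epoch.

    ``interval`` is (start, end) in seconds with ``end <= 0``; the mean over
    the half-open interval is removed per channel and per trial.
    """
    start, end = interval
    if end > 1e-12:
        raise ValueError("baseline interval must be pre-stimulus (end <= 0)")
    mask = ep.time_mask(start, end)
    if not mask.any():
        raise ValueError(f"baseline interval {interval} outside epoch times")
    out = ep.copy()
    out.data = ep.data - ep.data[:, mask, :].mean(axis=1, keepdims=True)
    return out


def detect_line_noise_channels(
    rec: ContinuousRecording,
    line_hz: float = 50.0,
    sd_threshold: float = 4.0,
) -> list[int]:
    """Channels with anomalously strong mains-frequency power.

    Narrowband power at ``line_hz`` (± 1 Hz) is estimated per channel with a
    Welch averaged periodogram (1-s Hann segments, 50% overlap) and expressed,
    on a log scale, as a robust z-score against the other channels (median
    and 1.4826·MAD).  Channels with z > ``sd_threshold`` are returned.
    """
    if rec.n_channels < 4:
        raise ValueError("need at least 4 channels to detect outliers")
    if line_hz >= rec.srate / 2.0:
        raise ValueError("line frequency must be below Nyquist")
    nperseg = min(int(round(rec.srate)), rec.n_samples)
    freqs, psd = signal.welch(
        rec.data, fs=rec.srate, nperseg=nperseg, noverlap=nperseg // 2,
        window="hann", axis=1,
    )
    band = (freqs >= line_hz - 1.0) & (freqs <= line_hz + 1.0)
    if not band.any():
        raise ValueError("no spectral bins within the line band")
    power = np.log10(psd[:, band].mean(axis=1) + np.finfo(float).tiny)
    med = np.median(power)
    mad = np.median(np.abs(power - med))
    scale = 1.4826 * mad
    if scale <= 0:
        return []
    z = (power - med) / scale
    return [int(i) for i in np.flatnonzero(z > sd_threshold)]


# ---------------------------------------------------------------------------
# spherical-spline channel interpolation (Perrin-style)
# ---------------------------------------------------------------------------


def _legendre_g(cosang: np.ndarray, m: int = 4, n_terms: int = 7) -> np.ndarray:
    """Spherical-spline kernel g(cos γ) with order ``m`` Legendre weights."""
    cosang = np.clip(cosang, -1.0, 1.0)
    # evaluate P_n(x) for n = 1..n_terms by recurrence
    p_prev = np.ones_like(cosang)  # P_0
    p_cur = cosang.copy()  # P_1
    out = np.zeros_like(cosang)
    for n in range(1, n_terms + 1):
        if n > 1:
            p_next = ((2 * n - 1) * cosang * p_cur - (n - 1) * p_prev) / n
            p_prev, p_cur = p_cur, p_next
        out += (2 * n + 1) / (n**m * (n + 1) ** m) * p_cur
    return out / (4.0 * np.pi)


def interpolate_channels(obj, bad: Sequence[int], reg: float = 1e-5):
    """Replace bad channels by spherical-spline estimates from the good ones.

    The spline follows the classic scalp-potential interpolation: order-4
    Legendre weighting, terms to degree 7, ridge regularisation ``reg`` on the
    diagonal of the good-channel kernel matrix.  Positions must be unit-norm.
    Good channels are untouched; channel count and order are preserved.
    """
    bad = sorted(set(int(b) for b in bad))
    if not bad:
        return obj.copy()
    if obj.channel_positions is None:
        raise ValueError("channel positions required for interpolation")
    n_ch = obj.data.shape[0]
    good = [i for i in range(n_ch) if i not in bad]
    if len(good) < 3:
        raise ValueError("need at least 3 good channels to interpolate")
    pos = obj.channel_positions
    cos_gg = pos[good] @ pos[good].T
    cos_bg = pos[bad] @ pos[good].T
    g_gg = _legendre_g(cos_gg) + reg * np.eye(len(good))
    g_bg = _legendre_g(cos_bg)

    # solve [G 1; 1^T 0] [c; c0] = [v; 0] for every time point at once
    n_good = len(good)
    lhs = np.zeros((n_good + 1, n_good + 1))
    lhs[:n_good, :n_good] = g_gg
    lhs[:n_good, n_good] = 1.0
    lhs[n_good, :n_good] = 1.0

    out = obj.copy()
    flat = obj.data[good].reshape(n_good, -1)
    rhs = np.zeros((n_good + 1, flat.shape[1]))
    rhs[:n_good] = flat
    sol = np.linalg.solve(lhs, rhs)
    est = g_bg @ sol[:n_good] + sol[n_good]
    out.data[bad] = est.reshape((len(bad),) + obj.data.shape[1:])
    return out


def reject_trials_peak_to_peak(
    ep: EpochSet,
    threshold_uv: float = 200.0,
    mode: str = "ptp",
) -> tuple[EpochSet, float]:
    """Drop trials exceeding an amplitude threshold on any channel.

    mode "ptp": reject when any channel's max - min within the epoch exceeds
    ``threshold_uv``.  mode "abs": reject when any sample leaves the
    [-threshold, +threshold] range (the ± microvolt-range convention).
    Returns the surviving :class:`EpochSet` and the rejected fraction.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    if mode == "ptp":
        extent = ep.data.max(axis=1) - ep.data.min(axis=1)  # channels x trials
        bad = (extent > threshold_uv).any(axis=0)
    elif mode == "abs":
        bad = (np.abs(ep.data) > threshold_uv).any(axis=(0, 1))
    else:
        raise ValueError(f"unknown rejection mode {mode!r}")
    frac = float(bad.mean())
    if bad.all():
        raise ValueError("all trials rejected")
    out = ep.copy()
    out.data = ep.data[:, :, ~bad]
    return out, frac
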
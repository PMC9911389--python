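"""Synthetic two-condition ERP cohorts with known ground truth.

The generator emulates the statistical structure the significance metric
assumes of real ERP data: a condition-difference evoked response visible on
most channels (volume conduction is mimicked by a smooth random topography
over the electrode sphere), 1/f background noise, slow drifts, mains-line
noise with a few bad channels, and sparse high-amplitude artifact
transients.  Events of two conditions alternate pseudo-randomly at
inter-stimulus intervals of 1.8-2.2 s, so standard (-0.3, 0.7) s epochs
never overlap.

A closed-form companion, :func:`expected_metric`, predicts the metric on
clean cohorts from two-sample t-test power at the per-channel effect size
(noncentral-t computation), and serves as an independent oracle for the
simulated metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .data_model import ContinuousRecording, EpochSet, EventTable, extract_epochs

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "DriftSpec",
    "LineSpec",
    "ArtifactSpec",
    "SyntheticConfig",
    "spiral_positions",
    "subject_params",
    "generate_subject",
    "generate_cohort",
    "generate_epoch_cohort",
    "expected_metric",
]

#: relative trial-to-trial amplitude jitter of the effect (uniform ±20%)
TRIAL_JITTER = 0.20
#: recording lead-in and tail around the event train, seconds
LEAD_IN = 2.0
TAIL = 3.0


@dataclass
class EffectSpec:
    """Condition-B-only evoked difference: a Gaussian bump in time scaled by a
    smooth random spatial topography.

    ``amplitude`` is the peak difference in µV on a topography-weight-1
    channel; ``smoothness`` is the squared-exponential correlation length (in
    unit-sphere chord distance) of the topography field, whose per-channel
    weights are ~ N(topo_offset, topo_scale²) — with the defaults most
    channels carry the effect, as volume conduction implies.
    """

    amplitude: float = 5.0
    latency: float = 0.35
    width: float = 0.05
    smoothness: float = 1.0
    topo_offset: float = 1.0
    topo_scale: float = 0.5


@dataclass
class NoiseSpec:
    """1/f^exponent background noise, per-channel independent, ``rms`` µV."""

    one_over_f_exponent: float = 1.0
    rms: float = 10.0


@dataclass
class DriftSpec:
    """Slow drift: noise low-passed below ``corner_hz`` (2nd-order response)."""

    rms: float = 20.0
    corner_hz: float = 0.05


@dataclass
class LineSpec:
    """Mains noise: a ``freq``-Hz sinusoid with random phase per channel;
    ``bad_channel_count`` randomly chosen channels carry 10x the amplitude."""

    freq: float = 50.0
    amplitude: float = 1.0
    bad_channel_count: int = 0
    bad_channel_gain: float = 10.0


@dataclass
class ArtifactSpec:
    """Sparse high-amplitude transients (blink/movement stand-ins): Poisson
    events at ``rate`` per minute, each a Hann-windowed pulse of ``duration``
    seconds and ± ``amplitude`` µV on one random channel."""

    rate: float = 2.0
    amplitude: float = 400.0
    duration: float = 0.5


@dataclass
class SyntheticConfig:
    """Full generative specification of a simulated cohort."""

    n_subjects: int = 8
    n_channels: int = 64
    srate: float = 250.0
    n_trials: int = 100
    effect: EffectSpec = field(default_factory=EffectSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    drift: DriftSpec = field(default_factory=DriftSpec)
    line: LineSpec = field(default_factory=LineSpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    inter_subject_amplitude_sd: float = 1.0
    common_erp_amplitude: float = 5.0
    isi_range: tuple[float, float] = (1.8, 2.2)
    epoch_window: tuple[float, float] = (-0.3, 0.7)
    conditions: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        for name, amp in [
            ("effect.amplitude", self.effect.amplitude),
            ("noise.rms", self.noise.rms),
            ("drift.rms", self.drift.rms),
            ("line.amplitude", self.line.amplitude),
            ("artifacts.amplitude", self.artifacts.amplitude),
        ]:
            if amp < 0:
                raise ValueError(f"{name} must be >= 0")
        ep_len = self.epoch_window[1] - self.epoch_window[0]
        if ep_len > self.isi_range[0]:
            raise ValueError(
                f"epoch window ({ep_len:.3f} s) exceeds the minimum ISI "
                f"({self.isi_range[0]:.3f} s); epochs would overlap"
            )
        if not (
            self.epoch_window[0] < self.effect.latency < self.epoch_window[1]
        ):
            raise ValueError("effect latency must lie within the epoch window")

    def clean(self) -> "SyntheticConfig":
        """Copy with drift, line noise and artifacts switched off."""
        import copy

        cfg = copy.deepcopy(self)
        cfg.drift.rms = 0.0
        cfg.line.amplitude = 0.0
        cfg.line.bad_channel_count = 0
        cfg.artifacts.rate = 0.0
        return cfg


def spiral_positions(n_channels: int) -> np.ndarray:
    """Deterministic Fibonacci-spiral electrode layout on the unit sphere."""
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / n_channels
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    theta = 2 * np.pi * i / golden
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pos / np.linalg.norm(pos, axis=1, keepdims=True)


def _smooth_topography(
    rng: np.random.Generator, pos: np.ndarray, length: float, offset: float, scale: float
) -> np.ndarray:
    """Gaussian random field on the electrode sphere, squared-exponential
    covariance in chord distance, marginal N(offset, scale²)."""
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    cov = np.exp(-d2 / (2.0 * length**2))
    cov += 1e-8 * np.eye(pos.shape[0])
    chol = np.linalg.cholesky(cov)
    return offset + scale * (chol @ rng.standard_normal(pos.shape[0]))


def _subject_seedseqs(cfg: SyntheticConfig, subject_index: int):
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(subject_index,))
    return ss.spawn(2)  # (params, data)


def subject_params(cfg: SyntheticConfig, subject_index: int) -> dict:
    """Ground-truth per-subject parameters, reproducible without generating
    the data: effect amplitude, effect topography, common-ERP topography and
    the indices of the line-noise bad channels."""
    params_ss, _ = _subject_seedseqs(cfg, subject_index)
    rng = np.random.default_rng(params_ss)
    pos = spiral_positions(cfg.n_channels)
    topo = _smooth_topography(
        rng, pos, cfg.effect.smoothness, cfg.effect.topo_offset, cfg.effect.topo_scale
    )
    common_topo = _smooth_topography(rng, pos, cfg.effect.smoothness, 1.0, 0.3)
    amp = max(0.0, cfg.effect.amplitude + rng.normal(0.0, cfg.inter_subject_amplitude_sd))
    if cfg.effect.amplitude == 0.0:
        amp = 0.0  # an exact null stays a null regardless of the between-subject spread
    bad = rng.choice(cfg.n_channels, size=cfg.line.bad_channel_count, replace=False)
    return {
        "positions": pos,
        "effect_topography": topo,
        "common_topography": common_topo,
        "effect_amplitude": amp,
        "line_bad_channels": np.sort(bad),
    }


def _pink_weights(n: int, srate: float, exponent: float) -> tuple[np.ndarray, np.ndarray]:
    """rfft frequencies and 1/f^(exponent/2) amplitude weights (DC zeroed)."""
    freqs = np.fft.rfftfreq(n, 1.0 / srate)
    w = np.zeros_like(freqs)
    w[1:] = freqs[1:] ** (-exponent / 2.0)
    return freqs, w


def _shaped_noise(
    rng: np.random.Generator, n_channels: int, n: int, weights: np.ndarray, rms: float
) -> np.ndarray:
    """Gaussian noise with the given rfft amplitude shaping, normalised so
    every channel has sample standard deviation exactly ``rms``."""
    if rms == 0.0:
        return np.zeros((n_channels, n))
    z = rng.standard_normal((n_channels, weights.size)) + 1j * rng.standard_normal(
        (n_channels, weights.size)
    )
    x = np.fft.irfft(weights * z, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms


def _gauss_bump(times: np.ndarray, latency: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - latency) / width) ** 2)


def _common_erp(times: np.ndarray) -> np.ndarray:
    """Fixed condition-independent evoked shape (unit peak): an early positive
    and a later negative deflection.  Identical in both conditions, so it
    cancels from the between-condition test."""
    return _gauss_bump(times, 0.10, 0.03) - 0.8 * _gauss_bump(times, 0.20, 0.04)


def generate_subject(
    cfg: SyntheticConfig, subject_index: int = 0
) -> tuple[ContinuousRecording, EventTable]:
    """Simulate one subject: continuous recording plus event table.

    Continuous data = 1/f background + drift + line noise + sparse artifact
    transients + a common evoked response at every event; condition-B events
    additionally receive the effect bump scaled by the subject's smooth random
    topography and a ±20% per-trial amplitude jitter.  Deterministic given
    ``(cfg.seed, subject_index)``.
    """
    par = subject_params(cfg, subject_index)
    _, data_ss = _subject_seedseqs(cfg, subject_index)
    rng = np.random.default_rng(data_ss)
    sr = cfg.srate
    n_events = 2 * cfg.n_trials

    isis = rng.uniform(cfg.isi_range[0], cfg.isi_range[1], size=n_events)
    onset_times = LEAD_IN + np.cumsum(isis) - isis[0]
    onsets = np.round(onset_times * sr).astype(np.int64)
    n_samples = int(round((onset_times[-1] + TAIL) * sr))

    labels = np.array([cfg.conditions[0]] * cfg.n_trials + [cfg.conditions[1]] * cfg.n_trials)
    rng.shuffle(labels)

    freqs, w_pink = _pink_weights(n_samples, sr, cfg.noise.one_over_f_exponent)
    data = _shaped_noise(rng, cfg.n_channels, n_samples, w_pink, cfg.noise.rms)

    if cfg.drift.rms > 0:
        w_drift = 1.0 / np.sqrt(1.0 + (freqs / cfg.drift.corner_hz) ** 4)
        w_drift[0] = 0.0
        data += _shaped_noise(rng, cfg.n_channels, n_samples, w_drift, cfg.drift.rms)

    if cfg.line.amplitude > 0:
        t = np.arange(n_samples) / sr
        phases = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
        amps = np.full(cfg.n_channels, cfg.line.amplitude)
        amps[par["line_bad_channels"]] *= cfg.line.bad_channel_gain
        data += amps[:, None] * np.sin(2 * np.pi * cfg.line.freq * t[None, :] + phases[:, None])

    if cfg.artifacts.rate > 0:
        minutes = n_samples / sr / 60.0
        n_art = rng.poisson(cfg.artifacts.rate * minutes)
        dur = max(2, int(round(cfg.artifacts.duration * sr)))
        pulse = np.hanning(dur)
        for _ in range(n_art):
            ch = rng.integers(0, cfg.n_channels)
            start = rng.integers(0, max(1, n_samples - dur))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[ch, start : start + dur] += sign * cfg.artifacts.amplitude * pulse

    # evoked responses, added per event
    tmpl_t = np.arange(0, int(round(1.0 * sr))) / sr  # 1 s of post-stimulus template
    common = cfg.common_erp_amplitude * _common_erp(tmpl_t)
    bump = _gauss_bump(tmpl_t, cfg.effect.latency, cfg.effect.width)
    jitters = 1.0 + rng.uniform(-TRIAL_JITTER, TRIAL_JITTER, size=n_events)
    for ev, (onset, lab) in enumerate(zip(onsets, labels)):
        sl = slice(onset, min(onset + tmpl_t.size, n_samples))
        L = sl.stop - sl.start
        data[:, sl] += par["common_topography"][:, None] * common[None, :L]
        if lab == cfg.conditions[1]:
            data[:, sl] += (
                par["effect_amplitude"]
                * jitters[ev]
                * par["effect_topography"][:, None]
                * bump[None, :L]
            )

    rec = ContinuousRecording(
        data=data,
        srate=sr,
        channel_labels=[f"ch{i:02d}" for i in range(cfg.n_channels)],
        channel_positions=par["positions"],
        subject_id=f"sub-{subject_index:03d}",
    )
    return rec, EventTable(onsets, list(labels))


def generate_cohort(
    cfg: SyntheticConfig,
) -> list[tuple[ContinuousRecording, EventTable]]:
    """``cfg.n_subjects`` independent subjects (per-subject effect amplitudes
    vary with ``inter_subject_amplitude_sd``)."""
    return [generate_subject(cfg, i) for i in range(cfg.n_subjects)]


def generate_epoch_cohort(
    cfg: SyntheticConfig,
    highpass_hz: float | None = None,
    epoch_window: tuple[float, float] | None = None,
) -> list[tuple[EpochSet, EpochSet]]:
    """Convenience: simulate, optionally high-pass filter (two-pass 4th-order
    Butterworth), and epoch every subject into the two condition blocks."""
    from .preprocessing import FilterSpec, highpass_filter

    window = epoch_window if epoch_window is not None else cfg.epoch_window
    out = []
    for i in range(cfg.n_subjects):
        rec, events = generate_subject(cfg, i)
        if highpass_hz is not None:
            rec = highpass_filter(rec, FilterSpec(kind="butterworth", cutoff_hz=highpass_hz))
        a = extract_epochs(rec, events, cfg.conditions[0], *window)
        b = extract_epochs(rec, events, cfg.conditions[1], *window)
        out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# closed-form expected metric (noncentral-t power oracle)
# ---------------------------------------------------------------------------


def _window_mean_noise_sd(
    cfg: SyntheticConfig,
    n_window: int,
    n_samples: int,
    highpass_hz: float | None,
) -> float:
    """SD of the mean of ``n_window`` consecutive samples of the generated
    background noise (optionally after a two-pass 4th-order Butterworth
    high-pass), derived from the generator's spectral shaping.

    The generator normalises each channel to sample SD ``noise.rms`` before
    filtering, so the window-mean variance is rms² · Σ c_k w_k² |H_k|⁴ d_k /
    Σ c_k w_k², with c_k the rfft bin multiplicity, |H_k|² the single-pass
    Butterworth power response and d_k the squared Dirichlet kernel of the
    ``n_window``-point average.
    """
    freqs, w = _pink_weights(n_samples, cfg.srate, cfg.noise.one_over_f_exponent)
    c = np.full(freqs.size, 2.0)
    c[0] = 1.0
    if n_samples % 2 == 0:
        c[-1] = 1.0
    p = c * w * w

    if highpass_hz is not None:
        ratio = np.zeros_like(freqs)
        ratio[1:] = (freqs[1:] / highpass_hz) ** 8
        h2 = ratio / (1.0 + ratio)  # single-pass order-4 power response
        h_eff = h2 * h2  # two passes
    else:
        h_eff = np.ones_like(freqs)

    k = np.arange(freqs.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (
            np.sin(np.pi * k * n_window / n_samples)
            / (n_window * np.sin(np.pi * k / n_samples))
        ) ** 2
    d[0] = 1.0
    var_ratio = float(np.sum(p * h_eff * d) / np.sum(p))
    return cfg.noise.rms * np.sqrt(var_ratio)


def _window_mean_effect(
    cfg: SyntheticConfig, window: tuple[float, float], highpass_hz: float | None
) -> float:
    """Window mean of the unit-amplitude effect bump, optionally after the
    same two-pass Butterworth high-pass the data would receive."""
    sr = cfg.srate
    pad = 30.0  # seconds of zeros around the bump so filter transients die out
    t = np.arange(int(round(2 * pad * sr))) / sr - pad
    bump = _gauss_bump(t, cfg.effect.latency, cfg.effect.width)
    if highpass_hz is not None:
        sos = signal.butter(4, highpass_hz, btype="highpass", fs=sr, output="sos")
        bump = signal.sosfiltfilt(sos, bump)
    mask = (t >= window[0] - 1e-12) & (t < window[1] - 1e-12)
    return float(bump[mask].mean())


def expected_metric(
    cfg: SyntheticConfig,
    n_resample: int = 50,
    alpha: float = 0.05,
    subject_index: int = 0,
    window: tuple[float, float] | None = None,
    highpass_hz: float | None = None,
    n_samples: int | None = None,
    n_pool: int | None = None,
) -> float:
    """Expected percentage of significant channels on a clean cohort subject.

    Valid in the clean regime (no artifacts or drift).  Per channel ``c`` the
    effect size is ``d_c`` = (window-mean effect amplitude on ``c``) /
    (window-mean noise SD); the expected metric is the mean over channels of
    two-sided two-sample t-test power at ``d_c`` with group sizes
    ``n_resample`` and level ``alpha`` (noncentral-t computation, pooled df).
    The ±20% trial amplitude jitter enters the condition-B variance.

    Because the metric draws trials *with replacement* from a finite pool of
    ``n_pool`` trials per condition (default ``cfg.n_trials``), the resampled
    group mean has variance var·(1/n + 1/T) while the t-test assumes var/n;
    the oracle therefore evaluates the noncentral t at the critical value
    shrunk by γ = sqrt((1/n + 1/T)/(1/n)).  As T → ∞ this reduces to the
    plain iid power formula, and at d = 0 it gives the metric's true null
    level, which exceeds 100·α for finite pools (e.g. ≈ 10.9% for n = 50,
    T = 100) and ≈ 16.6% for the all-trials variant (n = T, any T).  Pass a
    very large ``n_pool`` to recover the uncorrected iid formula.
    """
    if cfg.noise.rms == 0:
        raise ValueError("noise rms must be positive for the power oracle")
    if cfg.drift.rms > 0 or cfg.artifacts.rate > 0:
        raise ValueError("expected_metric is only valid for clean configs "
                         "(use SyntheticConfig.clean())")
    if window is None:
        window = (cfg.effect.latency - 0.05, cfg.effect.latency + 0.05)
    if n_samples is None:
        mean_isi = 0.5 * (cfg.isi_range[0] + cfg.isi_range[1])
        n_samples = int(round((LEAD_IN + 2 * cfg.n_trials * mean_isi + TAIL) * cfg.srate))
    if n_pool is None:
        n_pool = cfg.n_trials
    n_window = int(round((window[1] - window[0]) * cfg.srate))

    sigma = _window_mean_noise_sd(cfg, n_window, n_samples, highpass_hz)
    unit_m = _window_mean_effect(cfg, window, highpass_hz)
    par = subject_params(cfg, subject_index)
    m_c = par["effect_amplitude"] * par["effect_topography"] * unit_m

    n = n_resample
    var_a = sigma**2
    var_b = sigma**2 + m_c**2 * (TRIAL_JITTER**2 / 3.0)  # Var of U(-j, j) = j²/3
    denom_est = var_a / n + var_b / n  # what the t-test's denominator estimates
    denom_true = var_a * (1.0 / n + 1.0 / n_pool) + var_b * (1.0 / n + 1.0 / n_pool)
    gamma = np.sqrt(denom_true / denom_est)
    delta = np.abs(m_c) / np.sqrt(denom_true)
    df = 2 * n - 2
    tcrit = stats.t.ppf(1 - alpha / 2.0, df) / gamma
    power = 1.0 - stats.nct.cdf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta)
    return 100.0 * float(np.mean(power))
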
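"""The percentage-of-significant-channels ERP data-quality metric.

The statistic asks a simple question of a two-condition ERP experiment: on
what fraction of electrodes does the window-averaged potential differ between
the two conditions?  Because scalp potentials volume-conduct, a genuine evoked
difference should be visible on most electrodes of a clean recording, so the
percentage of significant channels acts as a data-quality / statistical-power
metric that needs no ground-truth artifact labels.

The metric is computed on bootstrap resamples of trials: each repetition draws
a fixed number of trials with replacement from each condition, averages each
trial over a 100-ms window, runs a per-channel unpaired t-test, and records
the percentage of channels significant at ``alpha``.  The per-subject metric
is the mean percentage over repetitions.  A latency scan over 50-ms bins,
followed by smoothing and a maximum, selects the 100-ms window of maximum
effect size from the data themselves.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import EpochSet

__all__ = [
    "MetricConfig",
    "MetricResult",
    "SignificanceCurve",
    "EffectWindow",
    "SignificanceMetric",
    "channel_significance",
    "resampled_metric",
    "all_trials_metric",
    "latency_scan",
    "find_effect_window",
]

#: half-width of the effect window in seconds (the window is always 100 ms)
EFFECT_HALF_WIDTH = 0.050


@dataclass
class EffectWindow:
    """A 100-ms analysis window centred on the latency of maximum effect."""

    center: float
    start: float
    end: float

    @classmethod
    def from_center(cls, center: float) -> "EffectWindow":
        return cls(center, center - EFFECT_HALF_WIDTH, center + EFFECT_HALF_WIDTH)

    def as_tuple(self) -> tuple[float, float]:
        return (self.start, self.end)


@dataclass
class MetricConfig:
    """Constants of the resampling metric.

    Parameters
    ----------
    alpha : float
        Per-channel significance level of the unpaired t-test (default 0.05).
    n_resample : int
        Trials drawn with replacement per condition and repetition
        (default 50).
    n_boot : int
        Number of bootstrap repetitions (default 20000).
    window : EffectWindow or (start, end) tuple, optional
        Averaging window in seconds; required by the metric, chosen by the
        latency scan when absent.
    scan_step : float
        Latency-scan step in seconds (default 0.050).
    scan_window : float
        Width of each latency-scan bin in seconds (default 0.050).
    smooth_len : int
        Moving-average length used when picking the window of maximum effect
        (default 3; must be odd).
    welch : bool
        Use Welch's t-test instead of the pooled-variance Student's t.
    seed : int
        Seed of the resampling RNG.  Cohort-level operations use one stream
        per subject, seeded ``seed + subject_index``.
    """

    alpha: float = 0.05
    n_resample: int = 50
    n_boot: int = 20000
    window: EffectWindow | tuple[float, float] | None = None
    scan_step: float = 0.050
    scan_window: float = 0.050
    smooth_len: int = 3
    welch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_resample < 2:
            raise ValueError("n_resample must be >= 2 (t-test undefined below)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.smooth_len < 1 or self.smooth_len % 2 == 0:
            raise ValueError("smooth_len must be odd and >= 1")

    def window_tuple(self) -> tuple[float, float]:
        if self.window is None:
            raise ValueError("no analysis window set; run a latency scan first")
        if isinstance(self.window, EffectWindow):
            return self.window.as_tuple()
        return (float(self.window[0]), float(self.window[1]))

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.window, EffectWindow):
            d["window"] = self.window.as_tuple()
        return d


@dataclass
class MetricResult:
    """Per-subject outcome of the resampled metric.

    Attributes
    ----------
    mean_pct_significant : float
        Mean over bootstrap repetitions of the percentage of channels with a
        significant condition difference (0-100).
    per_channel_rate : ndarray, shape (n_channels,)
        Fraction of repetitions in which each channel was significant.
    rep_sd : float
        Standard deviation of the per-repetition percentages (Monte-Carlo
        spread, not an SE of the mean).
    """

    subject_id: str
    mean_pct_significant: float
    n_channels: int
    n_trials_used: dict
    mode: str
    config: dict
    per_channel_rate: np.ndarray | None = None
    rep_sd: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_pct_significant <= 100.0:
            raise ValueError("mean_pct_significant must lie in [0, 100]")

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of ``mean_pct_significant``."""
        return self.rep_sd / np.sqrt(self.config.get("n_boot", 1))

    def summary(self) -> str:
        win = self.config.get("window")
        lines = [
            "Resampled channel-significance metric",
            "=" * 42,
            f"subject            {self.subject_id or '-'}",
            f"mode               {self.mode}",
            f"channels           {self.n_channels}",
            f"trials (a, b)      {self.n_trials_used.get('a')}, {self.n_trials_used.get('b')}",
            f"window [s]         {win}",
            f"alpha              {self.config.get('alpha')}",
            f"resample size      {self.config.get('n_resample')}"
            if self.mode == "resample_50"
            else "resample size      all remaining trials",
            f"repetitions        {self.config.get('n_boot')}",
            f"significant [%]    {self.mean_pct_significant:.2f}"
            + (f"  (MC SE {self.mc_se:.3f})" if np.isfinite(self.mc_se) else ""),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mean_pct_significant": float(self.mean_pct_significant),
            "n_channels": int(self.n_channels),
            "n_trials_used": {k: int(v) for k, v in self.n_trials_used.items()},
            "mode": self.mode,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in self.config.items()
            },
        }


@dataclass
class SignificanceCurve:
    """Per-latency significance percentages across a cohort of subjects."""

    latencies: np.ndarray
    per_subject: np.ndarray  # subjects x latencies
    median: np.ndarray
    mad: np.ndarray
    tmin: float = float("nan")
    tmax: float = float("nan")

    def __post_init__(self) -> None:
        self.latencies = np.asarray(self.latencies, dtype=float)
        self.per_subject = np.atleast_2d(np.asarray(self.per_subject, dtype=float))
        self.median = np.asarray(self.median, dtype=float)
        self.mad = np.asarray(self.mad, dtype=float)
        n = self.latencies.size
        if self.median.size != n or self.mad.size != n or self.per_subject.shape[1] != n:
            raise ValueError("curve arrays must share the latency axis")


# ---------------------------------------------------------------------------
# resampling engine
# ---------------------------------------------------------------------------


def window_means(ep: EpochSet, window: tuple[float, float]) -> np.ndarray:
    """Per-trial potential averaged over the half-open window, (trials x channels)."""
    mask = ep.time_mask(*window)
    if not mask.any():
        raise ValueError(f"window {window} contains no epoch samples")
    return ep.data[:, mask, :].mean(axis=1).T


def _count_matrix(rng: np.random.Generator, n_rep: int, n_draw: int, n_trials: int) -> np.ndarray:
    """Multiplicity matrix of with-replacement draws: (n_rep x n_trials) counts."""
    idx = rng.integers(0, n_trials, size=(n_rep, n_draw))
    flat = np.arange(n_rep)[:, None] * n_trials + idx
    return (
        np.bincount(flat.ravel(), minlength=n_rep * n_trials)
        .reshape(n_rep, n_trials)
        .astype(np.float64)
    )


def _sig_from_moments(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b, alpha, welch):
    """Significance indicators from group sums/sums-of-squares.

    Zero-variance convention: if the pooled variance vanishes, the test is
    significant iff the group means differ (the limiting t is ±inf), and
    non-significant when they are also equal (t defined as 0).
    """
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    var_a = np.maximum(sumsq_a - n_a * mean_a**2, 0.0) / (n_a - 1)
    var_b = np.maximum(sumsq_b - n_b * mean_b**2, 0.0) / (n_b - 1)
    diff2 = (mean_a - mean_b) ** 2
    if welch:
        denom = var_a / n_a + var_b / n_b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = denom**2 / (
                (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
            )
        df = np.where(np.isfinite(df), df, n_a + n_b - 2)
        tcrit2 = stats.t.ppf(1 - alpha / 2, df) ** 2
    else:
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        denom = sp2 * (1.0 / n_a + 1.0 / n_b)
        tcrit2 = stats.t.ppf(1 - alpha / 2, n_a + n_b - 2) ** 2
    # denom == 0 -> significant iff diff2 > 0, which the inequality delivers
    return diff2 > tcrit2 * denom


def _resampled_rates(
    feat_a: np.ndarray,
    feat_b: np.ndarray,
    draw_a: int,
    draw_b: int,
    n_boot: int,
    alpha: float,
    rng: np.random.Generator,
    welch: bool = False,
    collect_rep_pct: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-feature significance rates over bootstrap trial resamples.

    ``feat_a``/``feat_b`` are (trials x features) matrices of per-trial window
    means; a *feature* is a channel (single-window metric) or a channel x
    latency-bin pair (latency scan).  Each repetition draws ``draw_a`` and
    ``draw_b`` trials with replacement — the same trial draw applies to every
    feature, mirroring the fact that one resample selects whole epochs.

    Returns (rates, rep_pct): rates is the fraction of repetitions in which
    each feature tested significant; rep_pct (optional) the per-repetition
    percentage of significant features.
    """
    ta, n_feat = feat_a.shape
    tb = feat_b.shape[0]
    if feat_b.shape[1] != n_feat:
        raise ValueError("feature matrices must share columns")
    if draw_a < 2 or draw_b < 2:
        raise ValueError("resample size must be >= 2 (t-test undefined)")
    sq_a = feat_a * feat_a
    sq_b = feat_b * feat_b

    sig_sum = np.zeros(n_feat)
    rep_pct = np.empty(n_boot) if collect_rep_pct else None
    # chunk repetitions so the count matrices stay ~32 MB
    chunk = max(1, int(4_000_000 // max(ta + tb, 1)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        ca = _count_matrix(rng, b, draw_a, ta)
        cb = _count_matrix(rng, b, draw_b, tb)
        sig = _sig_from_moments(
            ca @ feat_a, ca @ sq_a, draw_a, cb @ feat_b, cb @ sq_b, draw_b, alpha, welch
        )
        sig_sum += sig.sum(axis=0)
        if collect_rep_pct:
            rep_pct[done : done + b] = 100.0 * sig.mean(axis=1)
        done += b
    return sig_sum / n_boot, rep_pct


def _check_compatible(a: EpochSet, b: EpochSet) -> None:
    if list(a.channel_labels) != list(b.channel_labels):
        raise ValueError("conditions have mismatched channels")
    if a.times.size != b.times.size or not np.allclose(a.times, b.times, atol=1e-9):
        raise ValueError("conditions have mismatched time axes")
    if abs(a.srate - b.srate) > 1e-9:
        raise ValueError("conditions have mismatched sampling rates")


def channel_significance(
    a: EpochSet,
    b: EpochSet,
    window: tuple[float, float],
    alpha: float = 0.05,
    welch: bool = False,
) -> float:
    """Percentage of channels with a significant condition difference.

    Single-shot variant (no resampling): per channel, each trial's potential
    is averaged over the half-open ``window``, the two groups of per-trial
    means are compared with a two-sided unpaired t-test (pooled variance,
    ``df = n_a + n_b - 2`` unless ``welch``), and a channel counts as
    significant iff ``p < alpha``.
    """
    _check_compatible(a, b)
    if a.n_trials < 2 or b.n_trials < 2:
        raise ValueError("each condition needs at least 2 trials")
    wa = window_means(a, window)
    wb = window_means(b, window)
    sig = _sig_from_moments(
        wa.sum(axis=0), (wa * wa).sum(axis=0), a.n_trials,
        wb.sum(axis=0), (wb * wb).sum(axis=0), b.n_trials,
        alpha, welch,
    )
    return 100.0 * float(np.mean(sig))


class SignificanceMetric:
    """Model object for the bootstrap-resampled significance metric.

    Parameters
    ----------
    a, b : EpochSet
        The two condition blocks of one subject (same channels and times).
    config : MetricConfig, optional

    Examples
    --------
    >>> model = SignificanceMetric(a, b, MetricConfig(window=(0.30, 0.40)))
    >>> res = model.fit()
    >>> res.mean_pct_significant  # doctest: +SKIP
    """

    def __init__(self, a: EpochSet, b: EpochSet, config: MetricConfig | None = None):
        _check_compatible(a, b)
        self.a = a
        self.b = b
        self.config = config if config is not None else MetricConfig()

    def fit(
        self,
        mode: str = "resample_50",
        rng: np.random.Generator | None = None,
        collect_rep_pct: bool = True,
    ) -> MetricResult:
        """Run the resampling and return a :class:`MetricResult`.

        ``mode='resample_50'`` draws ``config.n_resample`` trials per condition
        and repetition; ``mode='all_trials'`` draws as many trials as each
        condition actually has (the all-remaining-trials variant used when a
        rejection step has changed the trial counts).
        """
        cfg = self.config
        window = cfg.window_tuple()
        if mode == "resample_50":
            draw_a = draw_b = cfg.n_resample
        elif mode == "all_trials":
            draw_a, draw_b = self.a.n_trials, self.b.n_trials
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        feat_a = window_means(self.a, window)
        feat_b = window_means(self.b, window)
        rates, rep_pct = _resampled_rates(
            feat_a, feat_b, draw_a, draw_b, cfg.n_boot, cfg.alpha, rng,
            welch=cfg.welch, collect_rep_pct=collect_rep_pct,
        )
        snap = cfg.snapshot()
        snap["window"] = window
        return MetricResult(
            subject_id=self.a.subject_id,
            mean_pct_significant=100.0 * float(rates.mean()),
            n_channels=self.a.n_channels,
            n_trials_used={"a": draw_a, "b": draw_b},
            mode=mode,
            config=snap,
            per_channel_rate=rates,
            rep_sd=float(np.std(rep_pct)) if rep_pct is not None else float("nan"),
        )


def resampled_metric(a: EpochSet, b: EpochSet, cfg: MetricConfig) -> MetricResult:
    """Fixed-size resampling metric (``cfg.n_resample`` trials per draw)."""
    return SignificanceMetric(a, b, cfg).fit(mode="resample_50")


def all_trials_metric(a: EpochSet, b: EpochSet, cfg: MetricConfig) -> MetricResult:
    """All-remaining-trials variant: each draw uses ``n_a`` and ``n_b`` trials."""
    return SignificanceMetric(a, b, cfg).fit(mode="all_trials")


# ---------------------------------------------------------------------------
# latency scan and window selection
# ---------------------------------------------------------------------------


def _scan_bins(times: np.ndarray, srate: float, step: float, width: float):
    """Half-open latency bins [t0 + k*step, t0 + k*step + width) inside the epoch."""
    t0 = times[0]
    t_end = times[-1] + 1.0 / srate
    n_bins = int(np.floor((t_end - t0 - width) / step + 1e-9)) + 1
    starts = t0 + step * np.arange(n_bins)
    return starts, starts + width


def latency_scan(
    cohort: Sequence[tuple[EpochSet, EpochSet]],
    cfg: MetricConfig,
) -> SignificanceCurve:
    """Resampled metric at every latency bin, for every subject of a cohort.

    Each bin of width ``cfg.scan_window`` (stepped by ``cfg.scan_step``) serves
    as the averaging window; the per-trial value entering the t-test is the
    mean over the bin.  Curve latencies are bin centres.  The cohort summary is
    the per-latency median and unscaled MAD (``median |x - median|``) across
    subjects.  Subject ``i`` uses its own RNG stream seeded ``cfg.seed + i``,
    so per-subject curves do not depend on cohort order.
    """
    if not cohort:
        raise ValueError("empty cohort")
    a0 = cohort[0][0]
    starts, ends = _scan_bins(a0.times, a0.srate, cfg.scan_step, cfg.scan_window)
    n_bins = starts.size
    latencies = (starts + ends) / 2.0

    per_subject = np.empty((len(cohort), n_bins))
    for i, (a, b) in enumerate(cohort):
        _check_compatible(a, b)
        if a.times.size != a0.times.size or not np.allclose(a.times, a0.times, atol=1e-9):
            raise ValueError("all subjects must share the epoch time axis")
        # per-trial bin means for all bins at once: (trials, n_bins * channels)
        mask = (a.times[:, None] >= starts[None, :] - 1e-12) & (
            a.times[:, None] < ends[None, :] - 1e-12
        )
        binmat = mask / mask.sum(axis=0)  # (times, bins), columns average a bin
        feat_a = np.einsum("ctr,tk->rkc", a.data, binmat).reshape(a.n_trials, -1)
        feat_b = np.einsum("ctr,tk->rkc", b.data, binmat).reshape(b.n_trials, -1)
        rng = np.random.default_rng(cfg.seed + i)
        rates, _ = _resampled_rates(
            feat_a, feat_b, cfg.n_resample, cfg.n_resample, cfg.n_boot,
            cfg.alpha, rng, welch=cfg.welch,
        )
        per_subject[i] = 100.0 * rates.reshape(n_bins, a.n_channels).mean(axis=1)

    med, mad = cohort_median_mad(per_subject)
    return SignificanceCurve(
        latencies=latencies,
        per_subject=per_subject,
        median=med,
        mad=mad,
        tmin=float(a0.times[0]),
        tmax=float(a0.times[-1] + 1.0 / a0.srate),
    )


def cohort_median_mad(per_subject: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-latency median and unscaled MAD (median |x - median|) across the
    subject axis (axis 0)."""
    per_subject = np.atleast_2d(np.asarray(per_subject, dtype=float))
    med = np.median(per_subject, axis=0)
    mad = np.median(np.abs(per_subject - med[None, :]), axis=0)
    return med, mad


def moving_average(x: np.ndarray, length: int) -> np.ndarray:
    """Centred moving average whose window truncates to valid samples at the
    edges (e.g. length 3 averages two points at each end)."""
    if length % 2 == 0 or length < 1:
        raise ValueError("length must be odd and >= 1")
    x = np.asarray(x, dtype=float)
    k = length // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - k)
        hi = min(x.size, i + k + 1)
        out[i] = x[lo:hi].mean()
    return out


def find_effect_window(curve: SignificanceCurve, smooth_len: int = 3) -> EffectWindow:
    """Select the 100-ms window of maximum effect from a significance curve.

    The cohort median curve is smoothed with a centred moving average of
    ``smooth_len`` points, the latency of the maximum smoothed value is taken
    (earliest latency on ties), and the window is that latency ± 50 ms.  A
    window that would overrun the epoch is clipped with a warning.
    """
    if curve.median.size == 0:
        raise ValueError("empty significance curve")
    smoothed = moving_average(curve.median, smooth_len)
    center = float(curve.latencies[int(np.argmax(smoothed))])
    win = EffectWindow.from_center(center)
    if np.isfinite(curve.tmin) and win.start < curve.tmin:
        warnings.warn("effect window clipped at the epoch start")
        win.start = float(curve.tmin)
    if np.isfinite(curve.tmax) and win.end > curve.tmax:
        warnings.warn("effect window clipped at the epoch end")
        win.end = float(curve.tmax)
    return win
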
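"""Body-temperature telemetry cleaning and cosinor rhythmometry.

Core-body temperature is telemetered at 10-s resolution. The processing chain
mirrors standard rodent chronobiology practice:

1. artifact removal with a moving 100-sample window (exclude samples more than
   2 degC or more than 5 window-SDs away from the window mean),
2. normalization to the animal's 4-day baseline mean (baseline average set
   to 0),
3. averaging into 5-min bins,
4. single-component cosinor fit at a fixed 24-h period,
   ``y(t) = M + A * cos(2*pi*(t - phi)/24)``, estimated by least squares on
   cosine/sine regressors; MESOR ``M``, amplitude ``A >= 0`` and acrophase
   ``phi`` (peak time, ZT hours in [0, 24)).

Amplitude change from baseline (work-segment fit minus baseline fit) is the
rhythm-strength outcome; a negative change is rhythm damping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DegenerateInputError, EmptyInputError, ParameterError

TEMP_SAMPLE_S = 10.0


@dataclass
class TemperatureSeries:
    """Timestamps (hours from ZT0 of day 1), temperatures (degC), artifact mask."""

    t_hours: np.ndarray
    temp_c: np.ndarray
    artifact: np.ndarray | None = None
    baseline_delta: bool = False
    animal_id: str = ""

    def __post_init__(self):
        self.t_hours = np.asarray(self.t_hours, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if self.t_hours.size != self.temp_c.size:
            raise ParameterError("t_hours and temp_c must be the same length")
        if self.t_hours.size == 0:
            raise EmptyInputError("TemperatureSeries requires at least one sample")
        if self.artifact is None:
            self.artifact = np.zeros(self.temp_c.size, dtype=bool)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)
            if self.artifact.size != self.temp_c.size:
                raise ParameterError("artifact mask must align 1:1 with samples")

    def __len__(self) -> int:
        return int(self.temp_c.size)

    def valid(self) -> np.ndarray:
        return ~self.artifact & ~np.isnan(self.temp_c)


@dataclass(frozen=True)
class CosinorFit:
    """Single-component cosinor parameters at a fixed period."""

    mesor: float
    amplitude: float
    acrophase_zt: float
    period_h: float
    rss: float
    n: int

    def predict(self, t_hours) -> np.ndarray:
        t = np.asarray(t_hours, dtype=float)
        return self.mesor + self.amplitude * np.cos(
            2.0 * np.pi * (t - self.acrophase_zt) / self.period_h
        )


@dataclass(frozen=True)
class AmplitudeChange:
    """Work-minus-baseline cosinor amplitude; negative delta = damping."""

    baseline_amp: float
    work_amp: float

    @property
    def delta(self) -> float:
        return self.work_amp - self.baseline_amp


def remove_temp_artifacts(
    series: TemperatureSeries,
    window_n: int = 100,
    abs_limit_c: float = 2.0,
    sd_limit: float = 5.0,
) -> TemperatureSeries:
    """Mask artifact samples with a blockwise moving window.

    The series is processed 100 samples at a time (consecutive non-overlapping
    blocks; the candidate sample is included in its block's statistics, single
    pass). A sample is flagged when it deviates from the block mean by more
    than ``abs_limit_c`` degC *or* by more than ``sd_limit`` block SDs.
    Flagged samples are masked, never deleted, so timestamps stay intact.

    A series shorter than one window falls back to whole-series statistics
    with a warning.
    """
    if window_n < 2:
        raise ParameterError("window_n must be >= 2")
    x = series.temp_c
    n = x.size
    flags = series.artifact.copy()
    if n < window_n:
        warnings.warn(
            f"series of {n} samples shorter than one {window_n}-sample window; "
            "using whole-series statistics",
            stacklevel=2,
        )
        edges = [(0, n)]
    else:
        edges = [(s, min(s + window_n, n)) for s in range(0, n, window_n)]
    for s, e in edges:
        block = x[s:e]
        m = float(np.nanmean(block))
        sd = float(np.nanstd(block, ddof=1)) if e - s > 1 else 0.0
        dev = np.abs(block - m)
        bad = dev > abs_limit_c
        if sd > 0:
            bad |= dev > sd_limit * sd
        flags[s:e] |= bad
    return replace(series, artifact=flags)


def normalize_baseline(
    series: TemperatureSeries, baseline_window: tuple[float, float] = (0.0, 96.0)
) -> TemperatureSeries:
    """Subtract the mean over the baseline window (4 days by default).

    The baseline mean is computed over non-artifact samples with
    ``t_hours`` in ``[start, end)``; the whole series is shifted so that this
    mean becomes 0 and ``baseline_delta`` is set. Re-applying with the same
    window is a no-op (the mean is already 0).
    """
    t0, t1 = map(float, baseline_window)
    sel = series.valid() & (series.t_hours >= t0) & (series.t_hours < t1)
    if not sel.any():
        raise DegenerateInputError(
            f"no valid samples in baseline window [{t0:g}, {t1:g}) h"
        )
    mean = float(series.temp_c[sel].mean())
    return replace(series, temp_c=series.temp_c - mean, baseline_delta=True)


def bin_5min(series: TemperatureSeries, bin_minutes: float = 5.0) -> TemperatureSeries:
    """Average samples into fixed bins (5 min by default).

    Bin value = mean of non-artifact samples in the bin; bins with no valid
    sample are kept at NaN and masked as artifact so downstream fits skip
    them. Timestamps are bin centers.
    """
    if bin_minutes <= 0:
        raise ParameterError("bin_minutes must be positive")
    width = bin_minutes / 60.0
    idx = np.floor(series.t_hours / width + 1e-9).astype(int)
    first, last = int(idx.min()), int(idx.max())
    bins = np.arange(first, last + 1)
    valid = series.valid()
    rel = idx - first
    sums = np.bincount(rel, weights=np.where(valid, series.temp_c, 0.0), minlength=bins.size)
    counts = np.bincount(rel, weights=valid.astype(float), minlength=bins.size)
    with np.errstate(invalid="ignore"):
        temp = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)
    return TemperatureSeries(
        t_hours=(bins + 0.5) * width,
        temp_c=temp,
        artifact=np.isnan(temp),
        baseline_delta=series.baseline_delta,
        animal_id=series.animal_id,
    )


def cosinor_fit(
    series: TemperatureSeries,
    period_h: float = 24.0,
    span: tuple[float, float] | None = None,
) -> CosinorFit:
    """Least-squares cosinor fit at a fixed period.

    The model ``M + A*cos(2*pi*(t - phi)/period)`` is linearized onto cosine
    and sine regressors; ``A = hypot(beta_c, beta_s)`` (so ``A >= 0``) and the
    acrophase comes from ``atan2`` mapped to [0, period). Missing/artifact
    bins are simply omitted from the design (no imputation).

    Parameters
    ----------
    span : (start, end) in hours, optional
        Restrict the fit to ``start <= t < end``; must cover at least one
        full period. Fits on 72-h segments are the study convention.
    """
    if period_h <= 0:
        raise ParameterError("period_h must be positive")
    sel = series.valid()
    if span is not None:
        t0, t1 = map(float, span)
        if t1 - t0 < period_h:
            raise ParameterError(
                f"span of {t1 - t0:g} h is shorter than one {period_h:g}-h period"
            )
        sel &= (series.t_hours >= t0) & (series.t_hours < t1)
    t = series.t_hours[sel]
    y = series.temp_c[sel]
    if t.size == 0:
        raise DegenerateInputError("no valid samples in the requested span")
    if t.size < 3 or t.max() - t.min() < period_h * 0.5:
        raise DegenerateInputError("too little valid data to fit a cosinor")
    w = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones(t.size), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, bc, bs = map(float, beta)
    amplitude = float(np.hypot(bc, bs))
    acrophase = float(np.arctan2(bs, bc) / w % period_h)
    rss = float(np.sum((y - X @ beta) ** 2))
    return CosinorFit(
        mesor=mesor,
        amplitude=amplitude,
        acrophase_zt=acrophase,
        period_h=float(period_h),
        rss=rss,
        n=int(t.size),
    )


def amplitude_change(baseline: CosinorFit, work: CosinorFit) -> AmplitudeChange:
    """Work-minus-baseline amplitude (subtraction; negative = damping)."""
    if baseline.period_h != work.period_h:
        raise ParameterError("fits must share the same period")
    return AmplitudeChange(baseline_amp=baseline.amplitude, work_amp=work.amplitude)
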
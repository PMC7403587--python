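"""Epoch-scored vigilance-state series and sleep-architecture metrics.

A hypnogram is a sequence of 10-s epochs, each scored as wakefulness (``W``),
non-REM sleep (``N``) or REM sleep (``R``), anchored to zeitgeber time (ZT;
hours since lights-on, 12:12 light-dark cycle). This module provides the
container (:class:`EpochSeries`) and the standard architecture metrics:

* bout detection (maximal runs of a state above a minimum length),
* latency to a sustained run of target states (REM latency, stable-sleep
  latency after a work shift),
* time-in-state per ZT-aligned bin with cumulative curves,
* quiet-wakefulness classification from EMG peak-to-peak amplitude
  (wake epochs at or below the 33rd percentile of wake EMG).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, EmptyInputError, ParameterError

#: Valid vigilance-state codes.
STATES = ("W", "N", "R")

#: Schedule tags carried per epoch.
SCHEDULE_TAGS = ("BASELINE", "WORK", "OFF_WORK")

EPOCH_SECONDS = 10.0


def _as_state_array(states) -> np.ndarray:
    arr = np.asarray([str(s).upper() for s in states], dtype="U1")
    bad = set(arr.tolist()) - set(STATES)
    if bad:
        raise ParameterError(f"unknown vigilance state code(s): {sorted(bad)}")
    return arr


@dataclass
class EpochSeries:
    """Per-animal vigilance-state sequence in fixed 10-s epochs.

    Parameters
    ----------
    animal_id : str
        Identifier for the animal.
    t0_zt : float
        Zeitgeber time (hours, in [0, 24)) of the first epoch.
    states : array-like of {'W', 'N', 'R'}
        One state code per epoch; case-insensitive on input.
    schedule_tag : array-like of {'BASELINE', 'WORK', 'OFF_WORK'}, optional
        Per-epoch schedule label. Defaults to all-``BASELINE``.
    epoch_s : float
        Epoch length in seconds; fixed at 10.
    """

    animal_id: str
    t0_zt: float
    states: np.ndarray
    schedule_tag: np.ndarray | None = None
    epoch_s: float = EPOCH_SECONDS

    def __post_init__(self):
        if self.epoch_s != EPOCH_SECONDS:
            raise ParameterError(f"epoch_s is fixed at {EPOCH_SECONDS} s")
        self.states = _as_state_array(self.states)
        if self.states.size == 0:
            raise EmptyInputError("EpochSeries requires at least one epoch")
        if not 0.0 <= float(self.t0_zt) < 24.0:
            raise ParameterError("t0_zt must lie in [0, 24)")
        if self.schedule_tag is None:
            self.schedule_tag = np.full(self.states.size, "BASELINE", dtype="U8")
        else:
            self.schedule_tag = np.asarray(self.schedule_tag, dtype="U8")
            if self.schedule_tag.size != self.states.size:
                raise ParameterError("schedule_tag must align 1:1 with states")
            bad = set(self.schedule_tag.tolist()) - set(SCHEDULE_TAGS)
            if bad:
                raise ParameterError(f"unknown schedule tag(s): {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def epoch_hours(self) -> float:
        return self.epoch_s / 3600.0

    def zt(self) -> np.ndarray:
        """Zeitgeber time of each epoch, wrapped to [0, 24)."""
        return (self.t0_zt + np.arange(len(self)) * self.epoch_hours) % 24.0

    def elapsed_zt(self) -> np.ndarray:
        """Hours since ZT0 of the recording's first day (unwrapped).

        Used for ZT0-aligned binning across multi-day recordings.
        """
        return self.t0_zt + np.arange(len(self)) * self.epoch_hours

    def index_at_elapsed_zt(self, hours: float) -> int:
        """Epoch index whose elapsed ZT equals ``hours`` (rounded to epoch grid)."""
        idx = int(round((hours - self.t0_zt) / self.epoch_hours))
        if not 0 <= idx < len(self):
            raise ParameterError(f"elapsed ZT {hours} h falls outside the recording")
        return idx

    def subset(self, start: int, stop: int) -> "EpochSeries":
        """Contiguous slice [start, stop) as a new series (ZT anchor updated)."""
        if not 0 <= start < stop <= len(self):
            raise ParameterError("invalid subset bounds")
        return EpochSeries(
            animal_id=self.animal_id,
            t0_zt=float((self.t0_zt + start * self.epoch_hours) % 24.0),
            states=self.states[start:stop].copy(),
            schedule_tag=self.schedule_tag[start:stop].copy(),
        )


@dataclass(frozen=True)
class Bout:
    """A maximal run of a single vigilance state."""

    state: str
    start_index: int
    n_epochs: int

    @property
    def seconds(self) -> float:
        return self.n_epochs * EPOCH_SECONDS

    @property
    def minutes(self) -> float:
        return self.seconds / 60.0


@dataclass
class QuietWakeMask:
    """Per-epoch quiet-wakefulness flags plus the EMG threshold used."""

    flags: np.ndarray
    threshold: float
    percentile: float = 33.0

    def wake_fraction_flagged(self, states: np.ndarray) -> float:
        wake = np.asarray(states) == "W"
        return float(self.flags[wake].mean()) if wake.any() else float("nan")


def run_length_encode(values: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal runs of equal values as ``(start, length, value)`` triples."""
    values = np.asarray(values)
    if values.size == 0:
        return []
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [values.size]))
    return [(int(s), int(e - s), str(values[s])) for s, e in zip(starts, ends)]


def detect_bouts(series: EpochSeries, state: str, min_run: int = 3) -> list[Bout]:
    """Find every maximal run of ``state`` with at least ``min_run`` epochs.

    A NREM sleep bout, for example, is 3 or more consecutive 10-s NREM epochs;
    shorter runs are excluded entirely, and runs are maximal (flanked by a
    different state or the recording boundary).
    """
    if min_run < 1:
        raise ParameterError("min_run must be >= 1")
    state = str(state).upper()
    if state not in STATES:
        raise ParameterError(f"unknown state {state!r}")
    if len(series) == 0:  # defensive; EpochSeries forbids empty construction
        raise EmptyInputError("empty series")
    return [
        Bout(state=v, start_index=s, n_epochs=n)
        for s, n, v in run_length_encode(series.states)
        if v == state and n >= min_run
    ]


def mean_bout_minutes(bouts: list[Bout]) -> float:
    """Mean bout duration in minutes (NaN when there are no bouts)."""
    if not bouts:
        return float("nan")
    return float(np.mean([b.minutes for b in bouts]))


def latency_to_run(
    series: EpochSeries,
    target_states,
    run_len: int,
    from_index: int = 0,
) -> float | None:
    """Minutes from ``from_index`` to the onset of the first qualifying run.

    The run must consist of ``run_len`` consecutive epochs whose state is in
    ``target_states``; latency is reported to the run's first epoch (onset
    convention). Returns ``None`` when no such run completes before the end of
    the recording (censored; the caller decides how to handle censoring).
    """
    if run_len < 1:
        raise ParameterError("run_len must be >= 1")
    if not 0 <= from_index < len(series):
        raise ParameterError("from_index outside the series")
    targets = {str(s).upper() for s in np.atleast_1d(list(target_states))}
    if not targets <= set(STATES):
        raise ParameterError(f"unknown state(s) in target set: {sorted(targets - set(STATES))}")
    member = np.isin(series.states[from_index:], sorted(targets))
    run = 0
    for i, m in enumerate(member):
        run = run + 1 if m else 0
        if run == run_len:
            onset = i - run_len + 1
            return onset * series.epoch_s / 60.0
    return None


@dataclass
class StateTimeBinned:
    """Per-bin and cumulative minutes in each state over ZT0-aligned bins."""

    bin_hours: float
    bin_start_zt: np.ndarray  # elapsed ZT hours of each bin's left edge
    minutes: dict = field(default_factory=dict)  # state -> per-bin minutes
    cumulative: dict = field(default_factory=dict)  # state -> running total

    def total_minutes(self, state: str) -> float:
        return float(self.cumulative[state][-1]) if self.bin_start_zt.size else 0.0


def time_in_state_binned(series: EpochSeries, bin_hours: float = 2.0) -> StateTimeBinned:
    """Minutes per state in ZT0-aligned bins plus cumulative curves.

    Bins are aligned to ZT0 of the recording's first day; partial bins (a
    leading one if the recording does not start on a bin edge, and any trailing
    remainder) are dropped, so every reported bin covers exactly ``bin_hours``.
    """
    if bin_hours <= 0:
        raise ParameterError("bin_hours must be positive")
    elapsed = series.elapsed_zt()
    bin_idx = np.floor(elapsed / bin_hours + 1e-9).astype(int)
    per_bin_expected = int(round(bin_hours * 3600.0 / series.epoch_s))
    first = int(bin_idx[0])
    rel = bin_idx - first
    n_bins = int(rel[-1]) + 1
    counts = np.bincount(rel, minlength=n_bins)
    full = counts == per_bin_expected
    starts = (np.flatnonzero(full) + first) * bin_hours
    minutes = {}
    for state in STATES:
        per_bin = np.bincount(
            rel, weights=(series.states == state).astype(float), minlength=n_bins
        )
        minutes[state] = per_bin[full] * series.epoch_s / 60.0
    cumulative = {s: np.cumsum(m) for s, m in minutes.items()}
    return StateTimeBinned(
        bin_hours=float(bin_hours),
        bin_start_zt=starts.astype(float),
        minutes=minutes,
        cumulative=cumulative,
    )


def classify_quiet_wake(
    series: EpochSeries,
    emg_ptp,
    percentile: float = 33.0,
    method: str = "linear",
) -> QuietWakeMask:
    """Flag quiet-wakefulness epochs from EMG peak-to-peak amplitude.

    Quiet wakefulness is operationalized as wake epochs whose EMG peak-to-peak
    amplitude is less than or equal to the 33rd percentile of EMG amplitude
    over *all wake epochs* of the series (ties included via ``<=``). The
    percentile estimator defaults to linear interpolation between order
    statistics; ``method`` is forwarded to :func:`numpy.percentile`.
    """
    emg = np.asarray(emg_ptp, dtype=float)
    if emg.size != len(series):
        raise ParameterError("emg_ptp must align 1:1 with the series")
    wake = series.states == "W"
    if not wake.any():
        raise DegenerateInputError("no wake epochs: quiet-wake threshold undefined")
    threshold = float(np.percentile(emg[wake], percentile, method=method))
    flags = wake & (emg <= threshold)
    return QuietWakeMask(flags=flags, threshold=threshold, percentile=float(percentile))
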
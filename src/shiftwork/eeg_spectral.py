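"""Slow-wave activity (SWA) and slow-wave energy (SWE) from epoch-level EEG.

SWA is the EEG power in the 1-4 Hz (delta) band within a 10-s epoch, computed
by FFT on the unfiltered signal; in NREM sleep it indexes sleep intensity and
in quiet wakefulness it indexes homeostatic sleep drive. SWE accumulates SWA
over time: per 2-h window, the number of epochs spent in a state multiplied by
the mean SWA in that state for that window (algebraically, the sum of SWA over
qualifying epochs when the bins are exact).

Artifact epochs (spectral power more than 5 SD above the segment mean) are
excluded from every count and mean. SWA can be normalized per animal to the
baseline mean of the same vigilance state at the corresponding circadian time
(2-h ZT bins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import MissingReferenceError, ParameterError
from .hypnogram import STATES, EpochSeries

EEG_FS = 250.0  # Hz, telemetry sampling rate
SWA_BAND = (1.0, 4.0)  # Hz, inclusive on both edges


@dataclass
class EpochFeatures:
    """Per-epoch SWA and EMG peak-to-peak amplitude with an artifact mask."""

    swa: np.ndarray
    emg_ptp: np.ndarray
    artifact: np.ndarray | None = None

    def __post_init__(self):
        self.swa = np.asarray(self.swa, dtype=float)
        self.emg_ptp = np.asarray(self.emg_ptp, dtype=float)
        if self.artifact is None:
            self.artifact = np.zeros(self.swa.size, dtype=bool)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)
        if not (self.swa.size == self.emg_ptp.size == self.artifact.size):
            raise ParameterError("swa, emg_ptp and artifact must be the same length")
        if np.any(self.swa[~self.artifact] < 0):
            raise ParameterError("SWA must be non-negative outside artifact epochs")

    def __len__(self) -> int:
        return int(self.swa.size)


@dataclass
class SWETrajectory:
    """SWE per ZT0-aligned bin and its running (cumulative) sum."""

    bin_hours: float
    bin_start_zt: np.ndarray
    per_bin_swe: np.ndarray
    cumulative: np.ndarray
    n_epochs: np.ndarray  # qualifying (state, non-artifact) epochs per bin

    @property
    def total(self) -> float:
        return float(self.cumulative[-1]) if self.cumulative.size else 0.0


def epoch_band_power(
    signal,
    fs: float = EEG_FS,
    band: tuple[float, float] = SWA_BAND,
    epoch_s: float = 10.0,
) -> np.ndarray:
    """Per-epoch band power by FFT on consecutive fixed-length epochs.

    The signal is cut into consecutive ``epoch_s`` windows (its length must be
    an integer multiple of the window), an unwindowed FFT is taken per epoch,
    and the one-sided power-spectrum values of all frequency bins inside
    ``band`` (inclusive on both edges) are summed. With the scaling used here
    the spectrum values over all bins sum to the epoch's mean squared
    amplitude, so a unit-amplitude in-band sinusoid yields 0.5 and flat noise
    yields the band's share of the variance.

    No taper is applied by default (signals are analyzed unfiltered); any
    spectral-leakage control is left to the caller.
    """
    x = np.asarray(signal, dtype=float)
    lo, hi = float(band[0]), float(band[1])
    if not 0.0 <= lo < hi <= fs / 2.0:
        raise ParameterError(f"band {band} outside (0, Nyquist={fs / 2:g}] Hz")
    n = int(round(epoch_s * fs))
    if x.size == 0 or x.size % n != 0:
        raise ParameterError(
            f"signal length {x.size} is not a positive multiple of {n} samples"
        )
    epochs = x.reshape(-1, n)
    spec = np.fft.rfft(epochs, axis=1)
    # one-sided power spectrum: sum over bins == mean square of the epoch
    power = (np.abs(spec) ** 2) / n**2
    power[:, 1:] *= 2.0
    if n % 2 == 0:
        power[:, -1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    return power[:, in_band].sum(axis=1)


def reject_artifacts(swa, n_sd: float = 5.0) -> np.ndarray:
    """Flag epochs whose SWA exceeds the segment mean by ``n_sd`` SDs.

    Mean and SD are computed in a single pass over all epochs of the segment
    (sample SD, ddof=1). A constant series has SD 0 and produces no flags.
    """
    x = np.asarray(swa, dtype=float)
    if x.size < 2:
        raise ParameterError("artifact rejection needs at least 2 epochs")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return np.zeros(x.size, dtype=bool)
    return x > float(np.mean(x)) + n_sd * sd


def _zt_bin_of(series: EpochSeries, bin_hours: float) -> np.ndarray:
    return np.floor(series.zt() / bin_hours + 1e-9).astype(int) % int(
        round(24.0 / bin_hours)
    )


def baseline_reference_means(
    baseline_series: EpochSeries,
    baseline_feats: EpochFeatures,
    bin_hours: float = 2.0,
) -> dict[tuple[str, int], float]:
    """Mean SWA per (state, circadian 2-h bin) over non-artifact baseline epochs."""
    bins = _zt_bin_of(baseline_series, bin_hours)
    ok = ~baseline_feats.artifact
    ref: dict[tuple[str, int], float] = {}
    for state in STATES:
        sel = ok & (baseline_series.states == state)
        for b in np.unique(bins[sel]):
            ref[(state, int(b))] = float(baseline_feats.swa[sel & (bins == b)].mean())
    return ref


def normalize_to_baseline(
    series: EpochSeries,
    feats: EpochFeatures,
    baseline: tuple[EpochSeries, EpochFeatures],
    bin_hours: float = 2.0,
) -> np.ndarray:
    """Normalize SWA to the animal's baseline at the corresponding circadian time.

    Each epoch's SWA is divided by the baseline mean SWA of the *same
    vigilance state* within the *same circadian 2-h bin*. Artifact epochs are
    excluded from the reference means and returned as NaN in the output.

    Raises
    ------
    MissingReferenceError
        If any required (state, ZT-bin) cell has no baseline epochs; the error
        lists every missing cell.
    """
    if len(series) != len(feats):
        raise ParameterError("series and feats must align 1:1")
    ref = baseline_reference_means(*baseline, bin_hours=bin_hours)
    bins = _zt_bin_of(series, bin_hours)
    ok = ~feats.artifact
    needed = {(str(s), int(b)) for s, b in zip(series.states[ok], bins[ok])}
    missing = sorted(c for c in needed if c not in ref)
    if missing:
        raise MissingReferenceError([(s, b * bin_hours) for s, b in missing])
    out = np.full(len(series), np.nan)
    for (state, b), mean in ref.items():
        sel = ok & (series.states == state) & (bins == b)
        out[sel] = feats.swa[sel] / mean
    return out


def swe_per_bin(
    series: EpochSeries,
    feats: EpochFeatures,
    state_filter,
    bin_hours: float = 2.0,
    swa: np.ndarray | None = None,
) -> SWETrajectory:
    """Slow-wave energy per ZT0-aligned bin for a state or an epoch mask.

    ``state_filter`` is either a state code (``'N'``, ``'W'``, ``'R'``) or a
    per-epoch boolean mask (e.g. quiet-wakefulness flags). Per bin,
    SWE = (number of qualifying non-artifact epochs) x (their mean SWA), which
    equals the sum of SWA over those epochs; empty bins contribute 0. Pass
    ``swa`` to accumulate baseline-normalized values instead of raw ones.
    """
    if bin_hours <= 0:
        raise ParameterError("bin_hours must be positive")
    if len(series) != len(feats):
        raise ParameterError("series and feats must align 1:1")
    values = feats.swa if swa is None else np.asarray(swa, dtype=float)
    if values.size != len(series):
        raise ParameterError("swa override must align 1:1 with the series")
    if isinstance(state_filter, str):
        state = state_filter.upper()
        if state not in STATES:
            raise ParameterError(f"unknown state {state_filter!r}")
        qualifying = series.states == state
    else:
        qualifying = np.asarray(state_filter, dtype=bool)
        if qualifying.size != len(series):
            raise ParameterError("state_filter mask must align 1:1 with the series")
    qualifying = qualifying & ~feats.artifact

    elapsed = series.elapsed_zt()
    bin_idx = np.floor(elapsed / bin_hours + 1e-9).astype(int)
    first, last = int(bin_idx[0]), int(bin_idx[-1])
    all_bins = np.arange(first, last + 1)
    rel = bin_idx - first
    # count x mean == sum of SWA over qualifying epochs in the bin
    per_bin = np.bincount(
        rel, weights=np.where(qualifying, values, 0.0), minlength=all_bins.size
    )
    n_epochs = np.bincount(
        rel, weights=qualifying.astype(float), minlength=all_bins.size
    ).astype(int)
    return SWETrajectory(
        bin_hours=float(bin_hours),
        bin_start_zt=(all_bins * bin_hours).astype(float),
        per_bin_swe=per_bin,
        cumulative=np.cumsum(per_bin),
        n_epochs=n_epochs,
    )
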
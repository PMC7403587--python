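"""Synthetic telemetry generator for simulated shift-work cohorts.

Generates complete study datasets with the statistical structure the analysis
pipeline assumes, so every stage is testable without animal data:

* **Hypnograms** — a semi-Markov chain over {W, N, R} with phase-specific
  transition rates (light vs dark) calibrated so the stationary dark-phase
  wake fraction and light-phase sleep fraction hit their targets (defaults
  72.9% and 71.6%, the nocturnal architecture of the modeled rats). During a
  work shift (rest work ZT2-10, active work ZT14-22) the state is forced to
  wakefulness except for sporadic micro-sleep epochs. REM sleep is entered
  only from NREM; rest workers get a post-shift REM-pressure boost so REM
  latency after a shift is shortened relative to active workers.
* **Epoch features** — per-epoch SWA driven by a latent homeostatic
  sleep-pressure process (rising exponentially in wake, dissipating in NREM,
  held in REM) with state-specific gains (NREM > quiet wake > active wake)
  and lognormal noise; wake EMG amplitude from a two-component lognormal
  mixture whose low-tone component (about one third of wake epochs) forms
  quiet wakefulness. Rest workers get a multiplicative quiet-wake SWA boost
  on work days (the degraded-waking-state effect).
* **Temperature** — mesor + 24-h cosine (+ a small smoothed wake increment)
  + Gaussian noise, with the cosine amplitude reduced on rest-work days
  (default damping -0.40 degC) and rare large artifact spikes injected.
* **Outcomes** — Morris Water Maze latency, serum corticosterone and protein
  expression (p-eIF4E, p-BMAL1, p-S6K1, Arc) drawn from declared linear
  models over the *measured* per-animal predictors plus Gaussian noise. The
  coefficients are plumbing with no empirical claim; they are chosen so the
  planted block structure is recoverable by the regression ledger.

Every animal owns one pseudo-random stream derived from (seed, animal index),
so regeneration is deterministic and growing the cohort never perturbs
existing animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg_spectral import EpochFeatures
from .exceptions import ParameterError
from .hypnogram import EpochSeries, run_length_encode
from .temperature import TemperatureSeries

EPOCHS_PER_HOUR = 360
EPOCHS_PER_DAY = 24 * EPOCHS_PER_HOUR

#: Forced-activity windows in zeitgeber hours per work condition.
SHIFT_WINDOWS = {"RW": (2.0, 10.0), "AW": (14.0, 22.0)}

OUTCOME_NAMES = ("mwm_latency", "p_eif4e", "p_bmal1", "p_s6k1", "arc")

# Nominal location/scale constants used to put measured predictors on an
# approximately standardized scale inside the outcome models. Fixed constants
# (not sample statistics) keep each animal's outcome independent of who else
# is in the cohort.
PREDICTOR_SCALE = {
    "amp_change": (-0.27, 0.22),
    "rem_latency": (66.0, 53.0),
    "nrem_bout_len_24h": (5.2, 0.95),
    "qw_swe_24h": (69000.0, 17000.0),
    "nrem_bout_len_2h": (5.4, 2.5),
    "qw_swe_2h": (7600.0, 2800.0),
    "corticosterone": (110.0, 30.0),
}


def default_outcome_betas() -> dict:
    """Linear coefficients (outcome units per standardized predictor unit).

    The spatial-memory outcome loads on the last-24-h sleep-drive markers;
    the protein outcomes load on the 2-h post-shift markers (short-timescale
    biology) and, for p-eIF4E, strongly on corticosterone.
    """
    return {
        "mwm_latency": {
            "intercept": 35.0,
            "condition": 6.0,
            "amp_change": -9.0,
            "rem_latency": -7.0,
            "nrem_bout_len_24h": -5.0,
            "qw_swe_24h": 10.0,
        },
        "p_eif4e": {
            "intercept": 100.0,
            "condition": -20.0,
            "amp_change": -10.0,
            "rem_latency": -6.0,
            "qw_swe_2h": 5.0,
            "corticosterone": 25.0,
        },
        "p_bmal1": {
            "intercept": 105.0,
            "condition": -30.0,
            "amp_change": -12.0,
            "rem_latency": -10.0,
        },
        "p_s6k1": {
            "intercept": 140.0,
            "condition": -60.0,
            "nrem_bout_len_2h": 3.0,
            "qw_swe_2h": 3.0,
        },
        "arc": {"intercept": 100.0, "condition": -18.0},
    }


def default_noise_sds() -> dict:
    return {
        "mwm_latency": 8.0,
        "p_eif4e": 15.0,
        "p_bmal1": 20.0,
        "p_s6k1": 11.0,
        "arc": 25.0,
    }


@dataclass
class EffectSpec:
    """Planted effects and nuisance parameters of the generator.

    All temperature quantities are degC, times are minutes or hours as named.
    ``dark_wake_frac``/``light_sleep_frac`` are stationary targets of the
    hypnogram chain; ``amp_baseline_c`` is the target *fitted* cosinor
    amplitude at baseline (the cosine component is reduced internally by the
    analytic contribution of the wake increment so the fitted value lands on
    target); ``amp_damping_rw_c`` is added to the cosine amplitude of rest
    workers on work days (negative = damping).
    """

    dark_wake_frac: float = 0.729
    light_sleep_frac: float = 0.716
    # mean wake-run lengths (epochs) per phase; with the wake fractions these
    # pin down the sleep->wake exit rates
    mean_wake_run_dark: float = 60.0
    mean_wake_run_light: float = 15.0
    p_nr_dark: float = 0.008
    p_nr_light: float = 0.012
    p_rn: float = 0.08
    microsleep_p: float = 0.02
    rem_rebound_rw: float = 2.0  # post-shift NREM->REM rate multiplier (RW)
    rem_rebound_hours: float = 3.0
    # post-shift sleep rebound: for the rest of a work day after the shift the
    # chain targets these sleep fractions (sleep redistribution keeps total
    # sleep time close between conditions, as the modeled design requires)
    offwork_sleep_frac_rw: float = 0.62
    offwork_sleep_frac_aw: float = 0.55
    mean_wake_run_rebound_rw: float = 25.0
    mean_wake_run_rebound_aw: float = 40.0
    rebound_p_nr_scale: float = 0.7
    # post-shift wind-down: sustained wakefulness (grooming/feeding) before
    # sleep onset, geometric with these means; sets the sleep-onset latencies
    wind_down_mean_rw_min: float = 12.0
    wind_down_mean_aw_min: float = 30.0
    # between-animal trait heterogeneity (shift-work-tolerance variation):
    # additive jitter on wake-fraction targets, lognormal scales on run
    # lengths and REM-entry rate
    wake_frac_jitter_sd: float = 0.03
    run_scale_sigma: float = 0.15
    rem_rate_sigma: float = 0.20

    # homeostatic sleep-pressure process and SWA/EMG emission
    s_tau_rise_h: float = 8.0
    s_tau_decay_h: float = 2.2
    swa_gain: dict = field(
        default_factory=lambda: {"N": 200.0, "QW": 80.0, "AWAKE": 30.0, "R": 25.0}
    )
    swa_noise_sigma: float = 0.3
    swa_gain_sigma: float = 0.2  # per-animal lognormal scale on all SWA gains
    quiet_wake_weight: float = 1.0 / 3.0
    emg_mu_sigma: dict = field(
        default_factory=lambda: {
            "QW": (math.log(20.0), 0.35),
            "AWAKE": (math.log(80.0), 0.5),
            "N": (math.log(12.0), 0.3),
            "R": (math.log(8.0), 0.3),
        }
    )
    qw_swe_gain_rw: float = 1.5

    # temperature rhythm
    mesor_c: float = 37.2
    acrophase_zt: float = 18.0
    amp_baseline_c: float = 0.64
    amp_baseline_sd_c: float = 0.10
    amp_damping_rw_c: float = -0.40
    amp_damping_aw_c: float = -0.09
    amp_damping_sd_c: float = 0.15
    wake_increment_c: float = 0.03
    temp_noise_sd_c: float = 0.15
    artifact_rate: float = 0.001
    artifact_min_c: float = 5.0
    artifact_max_c: float = 10.0

    # serum corticosterone (ng/ml) at collection: RW sampled at ZT12, AW at
    # ZT0; the RW mean sits above the AW mean (time-of-day structure)
    cort_mean: dict = field(default_factory=lambda: {"RW": 130.0, "AW": 85.0})
    cort_sd: float = 20.0

    outcome_betas: dict = field(default_factory=default_outcome_betas)
    noise_sds: dict = field(default_factory=default_noise_sds)

    def __post_init__(self):
        for p in (self.microsleep_p, self.dark_wake_frac, self.light_sleep_frac):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities must lie in [0, 1]")
        if any(sd < 0 for sd in self.noise_sds.values()):
            raise ParameterError("noise SDs must be >= 0")


@dataclass
class CohortSpec:
    """Cohort layout: group sizes, schedule length, seed and planted effects."""

    n_rw: int = 17
    n_aw: int = 13
    days_baseline: int = 5
    days_work: int = 3
    seed: int = 0
    effect: EffectSpec = field(default_factory=EffectSpec)

    def __post_init__(self):
        if min(self.n_rw, self.n_aw, self.days_baseline, self.days_work) < 1:
            raise ParameterError("cohort counts and day counts must be >= 1")

    @property
    def n_days(self) -> int:
        return self.days_baseline + self.days_work

    def animals(self) -> list[tuple[int, str]]:
        """(index, condition) pairs; rest workers first."""
        return [(i, "RW") for i in range(self.n_rw)] + [
            (self.n_rw + j, "AW") for j in range(self.n_aw)
        ]


@dataclass
class AnimalData:
    animal_id: str
    condition: str
    series: EpochSeries
    feats: EpochFeatures
    temp: TemperatureSeries
    planted: dict


@dataclass
class Cohort:
    spec: CohortSpec
    animals: list


def animal_rng(seed: int, animal_index: int, stream: int) -> np.random.Generator:
    """Independent generator per (seed, animal, stream)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(animal_index, stream))
    )


# ---------------------------------------------------------------------------
# hypnogram chain
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _AnimalTraits:
    """Per-animal chain heterogeneity (shift-work-tolerance variation)."""

    wf_delta: float  # additive jitter on every wake-fraction target
    run_scale: float  # lognormal multiplier on mean wake-run lengths
    rem_scale: float  # lognormal multiplier on the NREM->REM entry rate


def _draw_traits(rng: np.random.Generator, effect: EffectSpec) -> _AnimalTraits:
    return _AnimalTraits(
        wf_delta=float(rng.normal(0.0, effect.wake_frac_jitter_sd)),
        run_scale=float(np.exp(rng.normal(0.0, effect.run_scale_sigma))),
        rem_scale=float(np.exp(rng.normal(0.0, effect.rem_rate_sigma))),
    )


def _chain_params(
    effect: EffectSpec,
    traits: _AnimalTraits,
    dark: bool,
    rebound_condition: str | None = None,
    rem_boost: float = 1.0,
) -> dict:
    """Per-epoch transition rates for one segment.

    The sleep->wake exit rate q solves the two-state stationary balance
    pi_W * p(leave W) = pi_sleep * q for the segment's wake-fraction target,
    so the chain's stationary wake fraction hits the target exactly (the
    REM/NREM split does not disturb it because both sleep states exit to
    wake at the same rate q). Rebound segments (after a shift on work days)
    override the wake-fraction target so sleep redistributes into the
    off-work hours.
    """
    if rebound_condition == "RW":
        wake_frac = 1.0 - effect.offwork_sleep_frac_rw
        mean_wake_run = effect.mean_wake_run_rebound_rw
    elif rebound_condition == "AW":
        wake_frac = 1.0 - effect.offwork_sleep_frac_aw
        mean_wake_run = effect.mean_wake_run_rebound_aw
    elif dark:
        wake_frac = effect.dark_wake_frac
        mean_wake_run = effect.mean_wake_run_dark
    else:
        wake_frac = 1.0 - effect.light_sleep_frac
        mean_wake_run = effect.mean_wake_run_light
    wake_frac = float(np.clip(wake_frac + traits.wf_delta, 0.05, 0.95))
    p_leave_w = 1.0 / (mean_wake_run * traits.run_scale)
    q = p_leave_w * wake_frac / (1.0 - wake_frac)
    p_nr = (effect.p_nr_dark if dark else effect.p_nr_light) * rem_boost * traits.rem_scale
    if rebound_condition is not None:
        p_nr *= effect.rebound_p_nr_scale
    return {
        "p_leave_w": min(p_leave_w, 1.0),
        "q": min(q, 0.9),
        "p_nr": min(p_nr, max(0.0, 1.0 - q)),
        "p_rn": effect.p_rn,
    }


def _day_segments(
    is_work_day: bool, condition: str, effect: EffectSpec, traits: _AnimalTraits
) -> list[tuple[int, int, dict | None]]:
    """(start_epoch, end_epoch, params) segments for one day.

    ``params=None`` marks a forced-activity segment. Epochs are day-local.
    Segments are split at the light/dark transition (ZT12), at the shift
    boundaries, at the end of the REM-rebound window, and rebound transition
    rates apply from shift end until the end of the day.
    """
    segs: list[tuple[int, int, dict | None]] = []

    def span(h0, h1):
        return int(round(h0 * EPOCHS_PER_HOUR)), int(round(h1 * EPOCHS_PER_HOUR))

    def add(h0, h1, kind, boost=1.0):
        for a, b in ((h0, min(h1, 12.0)), (max(h0, 12.0), h1)):
            if b <= a:
                continue
            if kind == "forced":
                segs.append((*span(a, b), None))
            else:
                segs.append(
                    (
                        *span(a, b),
                        _chain_params(
                            effect,
                            traits,
                            dark=a >= 12.0,
                            rebound_condition=condition if kind == "rebound" else None,
                            rem_boost=boost,
                        ),
                    )
                )

    if not is_work_day:
        add(0.0, 24.0, "normal")
        return segs
    s0, s1 = SHIFT_WINDOWS[condition]
    add(0.0, s0, "normal")
    add(s0, s1, "forced")
    b1 = min(s1 + effect.rem_rebound_hours, 24.0)
    add(s1, b1, "rebound", effect.rem_rebound_rw if condition == "RW" else 1.0)
    add(b1, 24.0, "rebound")
    return segs


def generate_hypnogram(
    spec: CohortSpec, animal_index: int, condition: str | None = None
) -> EpochSeries:
    """Simulate one animal's multi-day hypnogram (baseline then work days).

    The chain is simulated run-by-run (geometric sojourns with the per-epoch
    transition rates; memoryless truncation at phase/segment boundaries), so
    it is distributionally identical to the per-epoch chain but fast. During
    forced-activity windows every epoch is wake except independent
    micro-sleep (NREM) epochs at ``microsleep_p``.
    """
    effect = spec.effect
    if condition is None:
        condition = dict(spec.animals())[animal_index]
    if condition not in SHIFT_WINDOWS:
        raise ParameterError(f"condition must be one of {sorted(SHIFT_WINDOWS)}")
    rng = animal_rng(spec.seed, animal_index, stream=0)
    traits = _draw_traits(rng, effect)

    n_total = spec.n_days * EPOCHS_PER_DAY
    states = np.empty(n_total, dtype="U1")
    tags = np.empty(n_total, dtype="U8")

    # initial state from the light-phase stationary wake fraction
    state = "W" if rng.random() < 1.0 - effect.light_sleep_frac else "N"

    base_segs = _day_segments(False, condition, effect, traits)
    work_segs = _day_segments(True, condition, effect, traits)
    wind_down_mean_ep = 6.0 * (
        effect.wind_down_mean_rw_min if condition == "RW" else effect.wind_down_mean_aw_min
    )
    wind_down_left = 0
    for day in range(spec.n_days):
        work_day = day >= spec.days_baseline
        base = day * EPOCHS_PER_DAY
        for s0, s1, params in (work_segs if work_day else base_segs):
            lo, hi = base + s0, base + s1
            if params is None:  # forced activity
                micro = rng.random(hi - lo) < effect.microsleep_p
                states[lo:hi] = np.where(micro, "N", "W")
                tags[lo:hi] = "WORK"
                state = str(states[hi - 1])
                # sustained wakefulness (grooming/feeding) after the shift
                if wind_down_mean_ep > 0:
                    wind_down_left = int(rng.geometric(1.0 / wind_down_mean_ep))
                continue
            tags[lo:hi] = "OFF_WORK" if work_day else "BASELINE"
            i = lo
            if wind_down_left:
                take = min(wind_down_left, hi - i)
                states[i : i + take] = "W"
                i += take
                wind_down_left -= take
                state = "W"
            while i < hi:
                if state == "W":
                    p_leave, exits = params["p_leave_w"], (("N", 1.0),)
                elif state == "N":
                    p_leave = params["q"] + params["p_nr"]
                    exits = (
                        ("W", params["q"] / p_leave),
                        ("R", params["p_nr"] / p_leave),
                    )
                else:
                    p_leave = params["q"] + params["p_rn"]
                    exits = (
                        ("W", params["q"] / p_leave),
                        ("N", params["p_rn"] / p_leave),
                    )
                run = int(rng.geometric(p_leave)) if p_leave > 0 else hi - i
                end = min(i + run, hi)
                states[i:end] = state
                if end < hi:  # run completed inside the segment: transition
                    u = rng.random()
                    acc = 0.0
                    for nxt, w in exits:
                        acc += w
                        if u < acc:
                            state = nxt
                            break
                i = end
    return EpochSeries(
        animal_id=f"{condition}{animal_index:02d}",
        t0_zt=0.0,
        states=states,
        schedule_tag=tags,
    )


# ---------------------------------------------------------------------------
# epoch features (homeostatic pressure, SWA, EMG)
# ---------------------------------------------------------------------------


def _sleep_pressure(series: EpochSeries, effect: EffectSpec, s0: float = 0.5) -> np.ndarray:
    """Latent homeostatic pressure S in (0, 1] per epoch.

    Rises toward 1 with time constant ``s_tau_rise_h`` in wake, decays toward
    a floor of 0.05 with ``s_tau_decay_h`` in NREM, and is held in REM.
    Computed per maximal run with the closed-form exponential.
    """
    dt_h = series.epoch_hours
    floor = 0.05
    out = np.empty(len(series))
    s = s0
    for start, length, state in run_length_encode(series.states):
        k = np.arange(1, length + 1) * dt_h
        if state == "W":
            vals = 1.0 - (1.0 - s) * np.exp(-k / effect.s_tau_rise_h)
        elif state == "N":
            vals = floor + (s - floor) * np.exp(-k / effect.s_tau_decay_h)
        else:
            vals = np.full(length, s)
        out[start : start + length] = vals
        s = float(vals[-1])
    return out


def generate_epoch_features(
    series: EpochSeries,
    spec: CohortSpec,
    animal_index: int,
    condition: str | None = None,
) -> EpochFeatures:
    """SWA and EMG per epoch for a simulated hypnogram.

    SWA = state gain x latent pressure x lognormal noise, with gains ordered
    NREM > quiet wake > active wake. Wake epochs are split into a quiet
    (low-EMG, higher-SWA) and an active component; rest workers get the
    quiet-wake SWA gain multiplied by ``qw_swe_gain_rw`` on work days.
    """
    effect = spec.effect
    if condition is None:
        condition = dict(spec.animals())[animal_index]
    rng = animal_rng(spec.seed, animal_index, stream=1)
    n = len(series)
    # trait-like per-animal scale on all SWA gains (individual EEG amplitude)
    gain_scale = float(np.exp(rng.normal(0.0, effect.swa_gain_sigma)))
    S = _sleep_pressure(series, effect)

    wake = series.states == "W"
    quiet = wake & (rng.random(n) < effect.quiet_wake_weight)
    kind = np.where(
        series.states == "N", "N", np.where(series.states == "R", "R", "AWAKE")
    ).astype("U5")
    kind[quiet] = "QW"

    gains = np.empty(n)
    for key, g in effect.swa_gain.items():
        gains[kind == key] = g * gain_scale
    if condition == "RW" and effect.qw_swe_gain_rw != 1.0:
        work_day = np.arange(n) >= spec.days_baseline * EPOCHS_PER_DAY
        gains[(kind == "QW") & work_day] *= effect.qw_swe_gain_rw

    swa = gains * S * np.exp(rng.normal(0.0, effect.swa_noise_sigma, n))

    emg = np.empty(n)
    for key, (mu, sigma) in effect.emg_mu_sigma.items():
        sel = kind == key
        emg[sel] = np.exp(rng.normal(mu, sigma, int(sel.sum())))
    return EpochFeatures(swa=swa, emg_ptp=emg)


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------


def _wake_rhythm_contribution(effect: EffectSpec) -> float:
    """Analytic first-harmonic amplitude added by the smoothed wake increment.

    The expected wake probability is a square wave between the dark and light
    wake fractions; its fundamental has amplitude 4/pi times half the swing,
    and it peaks mid-dark, in phase with the temperature acrophase.
    """
    swing = effect.dark_wake_frac - (1.0 - effect.light_sleep_frac)
    return effect.wake_increment_c * (4.0 / math.pi) * swing / 2.0


def generate_temperature(
    series: EpochSeries,
    spec: CohortSpec,
    animal_index: int,
    condition: str | None = None,
) -> TemperatureSeries:
    """10-s body-temperature samples aligned 1:1 with the hypnogram epochs.

    temp = mesor + A(day) * cos(2 pi (t - acrophase)/24) + smoothed wake
    increment + Gaussian noise, with A reduced by the condition's damping on
    work days, plus rare artifact spikes of at least 5 degC.
    """
    effect = spec.effect
    if condition is None:
        condition = dict(spec.animals())[animal_index]
    rng = animal_rng(spec.seed, animal_index, stream=2)
    n = len(series)
    t = series.elapsed_zt()

    amp_cos = effect.amp_baseline_c - _wake_rhythm_contribution(effect)
    amp_base = rng.normal(amp_cos, effect.amp_baseline_sd_c)
    damp_target = (
        effect.amp_damping_rw_c if condition == "RW" else effect.amp_damping_aw_c
    )
    damping = rng.normal(damp_target, effect.amp_damping_sd_c)

    day = (t // 24.0).astype(int)
    A = np.where(day >= spec.days_baseline, amp_base + damping, amp_base)
    A = np.maximum(A, 0.0)
    temp = effect.mesor_c + A * np.cos(
        2.0 * np.pi * (t - effect.acrophase_zt) / 24.0
    )

    # thermal inertia: 5-min moving average of the wake indicator
    wake = (series.states == "W").astype(float)
    kernel = np.ones(30) / 30.0
    smooth = np.convolve(wake, kernel, mode="same")
    temp = temp + effect.wake_increment_c * smooth

    temp = temp + rng.normal(0.0, effect.temp_noise_sd_c, n)

    spikes = rng.random(n) < effect.artifact_rate
    n_sp = int(spikes.sum())
    if n_sp:
        mag = rng.uniform(effect.artifact_min_c, effect.artifact_max_c, n_sp)
        sign = rng.choice([-1.0, 1.0], n_sp)
        temp[spikes] += sign * mag
    return TemperatureSeries(
        t_hours=t,
        temp_c=temp,
        animal_id=series.animal_id,
    )


# ---------------------------------------------------------------------------
# cohort assembly and outcomes
# ---------------------------------------------------------------------------


def generate_animal(spec: CohortSpec, animal_index: int, condition: str) -> AnimalData:
    series = generate_hypnogram(spec, animal_index, condition)
    feats = generate_epoch_features(series, spec, animal_index, condition)
    temp = generate_temperature(series, spec, animal_index, condition)
    rng = animal_rng(spec.seed, animal_index, stream=2)
    effect = spec.effect
    amp_cos = effect.amp_baseline_c - _wake_rhythm_contribution(effect)
    planted = {
        "amp_base": float(rng.normal(amp_cos, effect.amp_baseline_sd_c)),
        "damping": float(
            rng.normal(
                effect.amp_damping_rw_c if condition == "RW" else effect.amp_damping_aw_c,
                effect.amp_damping_sd_c,
            )
        ),
    }
    return AnimalData(
        animal_id=series.animal_id,
        condition=condition,
        series=series,
        feats=feats,
        temp=temp,
        planted=planted,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate telemetry for the whole cohort (no outcomes yet;
    outcomes are drawn from measured predictors by :func:`generate_outcomes`)."""
    return Cohort(
        spec=spec,
        animals=[generate_animal(spec, i, cond) for i, cond in spec.animals()],
    )


def standardized_predictors(predictors: pd.DataFrame) -> pd.DataFrame:
    """Measured predictors on the generator's nominal standardized scale."""
    out = pd.DataFrame(index=predictors.index)
    out["condition"] = predictors["condition"].astype(float)
    for name, (loc, scale) in PREDICTOR_SCALE.items():
        if name in predictors:
            out[name] = (predictors[name] - loc) / scale
    return out


def generate_outcomes(predictors: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Draw corticosterone and the outcome battery from measured predictors.

    ``predictors`` needs columns ``animal_index, condition`` (0 = AW, 1 = RW)
    and the measured metrics named in ``PREDICTOR_SCALE`` (corticosterone is
    drawn here first and then fed into the protein models). Noise is drawn
    from each animal's own stream, so the table is deterministic per
    (spec, seed) and stable under cohort growth. Missing predictors propagate
    to missing outcomes (listwise behavior is the ledger's job).
    """
    effect = spec.effect
    df = predictors.copy()
    rngs = [animal_rng(spec.seed, int(i), stream=3) for i in df["animal_index"]]
    cond_label = np.where(df["condition"].to_numpy(float) > 0.5, "RW", "AW")
    df["corticosterone"] = [
        effect.cort_mean[c] + effect.cort_sd * r.normal() for c, r in zip(cond_label, rngs)
    ]
    z = standardized_predictors(df)
    for outcome in OUTCOME_NAMES:
        betas = effect.outcome_betas[outcome]
        mu = np.full(len(df), betas.get("intercept", 0.0))
        for name, b in betas.items():
            if name == "intercept":
                continue
            mu = mu + b * z[name].to_numpy(float)
        noise = np.array([r.normal(0.0, effect.noise_sds[outcome]) for r in rngs])
        vals = mu + noise
        if outcome == "mwm_latency":
            vals = np.clip(vals, 5.0, 120.0)
        df[outcome] = vals
    return df
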
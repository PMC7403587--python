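"""End-to-end study analysis: per-animal metrics, group comparisons, ledgers.

The study design: several baseline days of telemetry, then consecutive days
of 8-h forced activity, either in the rest phase (rest work, RW; shift
ZT2-10) or the active phase (active work, AW; shift ZT14-22). Per animal the
pipeline computes

* cosinor amplitude change (72-h work fit minus 72-h baseline fit, after
  artifact filtering, baseline normalization and 5-min binning),
* REM sleep latency and stable-sleep latency after the second work shift
  (3 consecutive REM epochs; 6 consecutive sleep epochs — 1 min of sleep),
* mean NREM bout length, cumulative state times, and slow-wave energy in
  quiet wakefulness and NREM sleep over the work period, over the last 24 h
  of work, and over the 2-h window after the final shift (the short-term
  sleep-drive markers used for protein outcomes),

then group comparisons (unpaired t with Cohen's d per metric) and the
hierarchical regression ledgers for Morris Water Maze latency and each
protein outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from .eeg_spectral import EpochFeatures, reject_artifacts, swe_per_bin
from .exceptions import InsufficientDataError, ParameterError
from .group_stats import SummaryStats, two_sample_t
from .hierarchy import PredictorBlock, hierarchical_ledger
from .hypnogram import (
    EpochSeries,
    classify_quiet_wake,
    detect_bouts,
    latency_to_run,
    mean_bout_minutes,
)
from .io import ensure_dir
from .synthetic import EPOCHS_PER_DAY, SHIFT_WINDOWS, Cohort, CohortSpec
from .temperature import (
    TemperatureSeries,
    amplitude_change,
    bin_5min,
    cosinor_fit,
    normalize_baseline,
    remove_temp_artifacts,
)

#: Step-3 variants of the ledger (main model and the two alternatives).
STEP3_VARIANTS = {
    "sleep_drive": ("nrem_bout_len_24h", "qw_swe_24h"),
    "nrem_swe": ("nrem_swe_24h",),
    "cumulative_sleep": ("cum_nrem_min", "cum_rem_min"),
}

#: Sleep-drive markers for the protein ledgers use the 2-h post-shift window.
STEP3_VARIANTS_2H = {
    "sleep_drive": ("nrem_bout_len_2h", "qw_swe_2h"),
    "nrem_swe": ("nrem_swe_2h",),
    "cumulative_sleep": ("cum_nrem_min", "cum_rem_min"),
}

COMPARISON_METRICS = [
    "amp_change",
    "rem_latency",
    "stable_sleep_latency",
    "nrem_bout_len",
    "qw_swe",
    "nrem_swe",
    "cum_wake_min",
    "cum_nrem_min",
    "cum_rem_min",
]


@dataclass
class StudyConfig:
    """Analysis settings plus (for synthetic studies) the cohort to simulate."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    bin_hours: float = 2.0
    bout_min_run: int = 3
    rem_run_len: int = 3
    stable_sleep_run_len: int = 6
    latency_after_shift: int = 2  # which shift's end anchors the latencies
    cosinor_span_h: float = 72.0
    baseline_norm_days: float = 4.0
    step3_variant: str = "sleep_drive"
    out_dir: str | None = None

    def __post_init__(self):
        if self.step3_variant not in STEP3_VARIANTS:
            raise ParameterError(
                f"step3_variant must be one of {sorted(STEP3_VARIANTS)}"
            )


@dataclass
class StudyReport:
    animal_metrics: pd.DataFrame
    comparisons: pd.DataFrame
    ledgers: dict
    exclusions: list

    def write(self, out_dir) -> None:
        out = ensure_dir(out_dir)
        self.animal_metrics.to_csv(out / "animal_metrics.csv", index=False)
        self.comparisons.to_csv(out / "group_comparisons.csv", index=False)
        for name, ledger in self.ledgers.items():
            ledger.to_csv(out / f"ledger_{name}.csv", index=False)
        with open(out / "exclusions.log", "w") as fh:
            for line in self.exclusions:
                fh.write(line + "\n")


def _segment(series: EpochSeries, feats: EpochFeatures, start: int, stop: int):
    sub = series.subset(start, stop)
    sub_feats = EpochFeatures(
        swa=feats.swa[start:stop],
        emg_ptp=feats.emg_ptp[start:stop],
        artifact=feats.artifact[start:stop],
    )
    return sub, sub_feats


def _swe_block(series, feats, bin_hours, exclusions, label):
    """QW and NREM SWE plus NREM bout length for one recording segment."""
    art = reject_artifacts(feats.swa)
    feats = EpochFeatures(swa=feats.swa, emg_ptp=feats.emg_ptp, artifact=art | feats.artifact)
    out = {}
    try:
        qw = classify_quiet_wake(series, feats.emg_ptp)
        out[f"qw_swe{label}"] = swe_per_bin(series, feats, qw.flags, bin_hours).total
    except Exception as exc:  # no wake epochs in a tiny window
        exclusions.append(f"{series.animal_id}: quiet wake undefined{label}: {exc}")
        out[f"qw_swe{label}"] = np.nan
    out[f"nrem_swe{label}"] = swe_per_bin(series, feats, "N", bin_hours).total
    bouts = detect_bouts(series, "N", 3)
    out[f"nrem_bout_len{label}"] = mean_bout_minutes(bouts)
    return out


def compute_animal_metrics(
    series: EpochSeries,
    feats: EpochFeatures,
    temp: TemperatureSeries,
    condition: str,
    days_baseline: int,
    days_work: int,
    config: StudyConfig,
    exclusions: list | None = None,
) -> dict:
    """All per-animal study metrics for one animal's telemetry."""
    exclusions = exclusions if exclusions is not None else []
    cfg = config
    n = len(series)
    base_end = days_baseline * EPOCHS_PER_DAY
    if n < base_end + days_work * EPOCHS_PER_DAY:
        raise ParameterError("recording shorter than the declared schedule")
    metrics: dict = {"animal_id": series.animal_id, "condition": int(condition == "RW")}

    work_series, work_feats = _segment(series, feats, base_end, n)

    # --- latencies after the configured shift ---------------------------
    shift_end_zt = SHIFT_WINDOWS[condition][1]
    anchor_h = (days_baseline + cfg.latency_after_shift - 1) * 24.0 + shift_end_zt
    anchor = series.index_at_elapsed_zt(anchor_h)
    rem = latency_to_run(series, {"R"}, cfg.rem_run_len, anchor)
    if rem is None:
        exclusions.append(f"{series.animal_id}: REM latency censored (no qualifying run)")
    stable = latency_to_run(series, {"N", "R"}, cfg.stable_sleep_run_len, anchor)
    if stable is None:
        exclusions.append(f"{series.animal_id}: stable-sleep latency censored")
    metrics["rem_latency"] = np.nan if rem is None else rem
    metrics["stable_sleep_latency"] = np.nan if stable is None else stable

    # --- work-period sleep architecture ---------------------------------
    bouts = detect_bouts(work_series, "N", cfg.bout_min_run)
    metrics["nrem_bout_len"] = mean_bout_minutes(bouts)
    ep_min = series.epoch_s / 60.0
    for state, name in (("W", "cum_wake_min"), ("N", "cum_nrem_min"), ("R", "cum_rem_min")):
        metrics[name] = float((work_series.states == state).sum()) * ep_min
    metrics["daily_sleep_min"] = (
        metrics["cum_nrem_min"] + metrics["cum_rem_min"]
    ) / days_work

    # --- slow-wave energy over three windows ----------------------------
    metrics.update(_swe_block(work_series, work_feats, cfg.bin_hours, exclusions, ""))
    last24_start = n - EPOCHS_PER_DAY
    s24, f24 = _segment(series, feats, last24_start, n)
    metrics.update(_swe_block(s24, f24, cfg.bin_hours, exclusions, "_24h"))
    final_shift_end_h = (days_baseline + days_work - 1) * 24.0 + shift_end_zt
    w0 = series.index_at_elapsed_zt(final_shift_end_h)
    w1 = min(n, w0 + int(2.0 * 3600 / series.epoch_s))
    s2h, f2h = _segment(series, feats, w0, w1)
    metrics.update(_swe_block(s2h, f2h, cfg.bin_hours, exclusions, "_2h"))

    # --- temperature rhythm ---------------------------------------------
    clean = remove_temp_artifacts(temp)
    norm_h = min(cfg.baseline_norm_days, days_baseline) * 24.0
    clean = normalize_baseline(clean, (0.0, norm_h))
    binned = bin_5min(clean)
    base_h = days_baseline * 24.0
    base_span = (max(0.0, base_h - cfg.cosinor_span_h), base_h)
    work_span = (base_h, min(base_h + cfg.cosinor_span_h, base_h + days_work * 24.0))
    fit_base = cosinor_fit(binned, 24.0, span=base_span)
    fit_work = cosinor_fit(binned, 24.0, span=work_span)
    metrics["baseline_amp"] = fit_base.amplitude
    metrics["work_amp"] = fit_work.amplitude
    metrics["amp_change"] = amplitude_change(fit_base, fit_work).delta
    metrics["baseline_mesor"] = fit_base.mesor
    metrics["baseline_acrophase_zt"] = fit_base.acrophase_zt
    return metrics


def group_comparisons(
    animal_metrics: pd.DataFrame, metrics=COMPARISON_METRICS
) -> pd.DataFrame:
    """Unpaired AW-vs-RW comparison per metric (t signed as RW minus AW)."""
    rows = []
    rw = animal_metrics[animal_metrics["condition"] == 1]
    aw = animal_metrics[animal_metrics["condition"] == 0]
    for m in metrics:
        if m not in animal_metrics.columns:
            continue
        x = aw[m].dropna().to_numpy(float)
        y = rw[m].dropna().to_numpy(float)
        if x.size < 2 or y.size < 2:
            continue
        res = two_sample_t(SummaryStats.from_vector(x), SummaryStats.from_vector(y))
        rows.append(
            {
                "metric": m,
                "group1": "AW",
                "group2": "RW",
                "mean_aw": x.mean(),
                "sd_aw": x.std(ddof=1),
                "n_aw": x.size,
                "mean_rw": y.mean(),
                "sd_rw": y.std(ddof=1),
                "n_rw": y.size,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "d": res.d,
            }
        )
    return pd.DataFrame(rows)


def ledger_blocks(outcome: str, step3_variant: str = "sleep_drive") -> list[PredictorBlock]:
    """The study's ordered predictor blocks for one outcome.

    MWM latency uses three blocks (work condition; daily rhythm dynamics;
    sleep drive over the last 24 h of work). Protein outcomes add a fourth
    block (serum corticosterone) and take their sleep-drive markers from the
    2-h post-shift window.
    """
    protein = outcome != "mwm_latency"
    variants = STEP3_VARIANTS_2H if protein else STEP3_VARIANTS
    blocks = [
        PredictorBlock("work condition", ("condition",)),
        PredictorBlock("daily rhythm dynamics", ("amp_change", "rem_latency")),
        PredictorBlock("sleep drive", variants[step3_variant]),
    ]
    if protein:
        blocks.append(PredictorBlock("serum corticosterone", ("corticosterone",)))
    return blocks


def run_study(cohort: Cohort, config: StudyConfig | None = None) -> StudyReport:
    """Analyze a simulated cohort end to end.

    Computes every per-animal metric, draws the outcome battery from the
    measured predictors (the generator's outcome models take the analysis
    products as inputs), runs the group comparisons, and fits one regression
    ledger per outcome. Deterministic for a fixed cohort.
    """
    cfg = config or StudyConfig()
    spec = cohort.spec
    exclusions: list[str] = []
    rows = []
    for idx, animal in enumerate(cohort.animals):
        m = compute_animal_metrics(
            animal.series,
            animal.feats,
            animal.temp,
            animal.condition,
            spec.days_baseline,
            spec.days_work,
            cfg,
            exclusions,
        )
        m["animal_index"] = spec.animals()[idx][0]
        rows.append(m)
    metrics = pd.DataFrame(rows)
    with_outcomes = synthetic.generate_outcomes(metrics, spec)
    comparisons = group_comparisons(with_outcomes)
    ledgers = {}
    for outcome in synthetic.OUTCOME_NAMES:
        blocks = ledger_blocks(outcome, cfg.step3_variant)
        try:
            ledger = hierarchical_ledger(with_outcomes, outcome, blocks)
        except InsufficientDataError as exc:
            exclusions.append(f"ledger {outcome}: {exc}")
            continue
        dropped = len(with_outcomes) - ledger.n
        if dropped:
            exclusions.append(f"ledger {outcome}: {dropped} row(s) dropped listwise")
        ledgers[outcome] = ledger.to_frame()
    report = StudyReport(
        animal_metrics=with_outcomes,
        comparisons=comparisons,
        ledgers=ledgers,
        exclusions=exclusions,
    )
    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report
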
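"""Delimited-text interchange formats.

The canonical epoch table is tab-separated with one row per 10-s epoch and
columns ``animal_id, epoch_index, zt_hours, state, swa, emg_ptp,
schedule_tag``; temperature files are comma-separated with
``animal_id, t_hours, temp_c``. Readers are case-insensitive on state codes.
All other outputs (cosinor fits, comparison tables, regression ledgers) are
plain CSV with headers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .eeg_spectral import EpochFeatures
from .exceptions import ParameterError
from .hypnogram import EpochSeries
from .temperature import TemperatureSeries

EPOCH_COLUMNS = [
    "animal_id",
    "epoch_index",
    "zt_hours",
    "state",
    "swa",
    "emg_ptp",
    "schedule_tag",
]
TEMP_COLUMNS = ["animal_id", "t_hours", "temp_c"]


def epoch_frame(series: EpochSeries, feats: EpochFeatures | None = None) -> pd.DataFrame:
    """One animal's epochs as a DataFrame in the canonical column order."""
    n = len(series)
    df = pd.DataFrame(
        {
            "animal_id": series.animal_id,
            "epoch_index": range(n),
            "zt_hours": series.elapsed_zt(),
            "state": series.states,
            "swa": feats.swa if feats is not None else float("nan"),
            "emg_ptp": feats.emg_ptp if feats is not None else float("nan"),
            "schedule_tag": series.schedule_tag,
        }
    )
    return df[EPOCH_COLUMNS]


def write_epoch_table(path, frames) -> None:
    """Write one or more per-animal epoch frames to a single TSV."""
    df = pd.concat(list(frames), ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_epoch_table(path) -> dict[str, tuple[EpochSeries, EpochFeatures]]:
    """Read an epoch TSV into per-animal (EpochSeries, EpochFeatures) pairs."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"epoch table missing column(s): {missing}")
    out = {}
    for animal, sub in df.groupby("animal_id", sort=False):
        sub = sub.sort_values("epoch_index")
        series = EpochSeries(
            animal_id=str(animal),
            t0_zt=float(sub["zt_hours"].iloc[0]) % 24.0,
            states=[str(s).upper() for s in sub["state"]],
            schedule_tag=sub["schedule_tag"].to_numpy(),
        )
        feats = EpochFeatures(
            swa=sub["swa"].to_numpy(float), emg_ptp=sub["emg_ptp"].to_numpy(float)
        )
        out[str(animal)] = (series, feats)
    return out


def temperature_frame(series: TemperatureSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": series.animal_id,
            "t_hours": series.t_hours,
            "temp_c": series.temp_c,
        }
    )[TEMP_COLUMNS]


def write_temperature_table(path, frames) -> None:
    pd.concat(list(frames), ignore_index=True).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_temperature_table(path) -> dict[str, TemperatureSeries]:
    df = pd.read_csv(path)
    missing = [c for c in TEMP_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"temperature table missing column(s): {missing}")
    out = {}
    for animal, sub in df.groupby("animal_id", sort=False):
        sub = sub.sort_values("t_hours")
        out[str(animal)] = TemperatureSeries(
            t_hours=sub["t_hours"].to_numpy(float),
            temp_c=sub["temp_c"].to_numpy(float),
            animal_id=str(animal),
        )
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
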
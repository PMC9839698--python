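"""Ratio normalisations for BRET and HTRF plate assays.

BRET G-protein dissociation: the signal is the emission ratio 510 nm/400 nm;
receptor activity is the change relative to the sensor-only control,
ΔBRET = BRET(receptor + sensor) − BRET(sensor only).  Negative values are
meaningful — dissociation sensors lose energy transfer on activation.

HTRF cAMP accumulation: the signal is the 665 nm/620 nm ratio, normalised so
the wild-type receptor group's mean maps to 100% response and the
untransfected-cell group's mean to 0%:

    response(%) = (RATIO_sample − RATIO_mean_blank)
                  / (RATIO_mean_wt − RATIO_mean_blank) × 100

Replicate summaries are arithmetic mean ± s.e.m. per condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PlateReading", "bret_ratio", "delta_bret", "htrf_response",
           "condition_summary", "load_plate_table"]


@dataclass(frozen=True)
class PlateReading:
    """One well: acceptor-channel and donor-channel emissions plus condition label.

    channel_a is the acceptor/long-wavelength emission (510 nm BRET, 665 nm
    HTRF); channel_b the donor/reference emission (400 nm / 620 nm).
    """

    well_id: str
    channel_a_emission: float
    channel_b_emission: float
    condition: str

    def __post_init__(self) -> None:
        if self.channel_a_emission < 0 or self.channel_b_emission < 0:
            raise ValueError(f"well {self.well_id}: negative emission")


def bret_ratio(r: PlateReading) -> float:
    """Emission ratio channel_a / channel_b (510/400 for BRET)."""
    if r.channel_b_emission == 0:
        raise ZeroDivisionError(f"well {r.well_id}: zero donor emission")
    return r.channel_a_emission / r.channel_b_emission


def delta_bret(ratio_receptor_sensor: float, ratio_sensor_only: float) -> float:
    """ΔBRET = BRET(receptor + G-protein sensor) − BRET(sensor only)."""
    if not (math.isfinite(ratio_receptor_sensor) and math.isfinite(ratio_sensor_only)):
        raise ValueError("BRET ratios must be finite")
    return ratio_receptor_sensor - ratio_sensor_only


def htrf_response(ratio_sample: float, mean_blank: float, mean_wt: float) -> float:
    """Percent response anchored at untransfected (0%) and wild-type (100%) means."""
    if mean_wt == mean_blank:
        raise ValueError("wild-type and blank means are equal; response undefined")
    return (ratio_sample - mean_blank) / (mean_wt - mean_blank) * 100.0


def condition_summary(readings: list[PlateReading]) -> pd.DataFrame:
    """Per-condition mean, s.e.m. and n of the emission ratio.

    s.e.m. uses the sample standard deviation (ddof=1); NaN for n = 1.
    """
    rows = [{"condition": r.condition, "ratio": bret_ratio(r)} for r in readings]
    df = pd.DataFrame(rows)
    out = df.groupby("condition")["ratio"].agg(
        mean="mean",
        sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else float("nan"),
        n="count",
    ).reset_index()
    return out


def load_plate_table(path) -> list[PlateReading]:
    """Read a plate TSV with columns well_id, condition, channel_a, channel_b."""
    df = pd.read_csv(path, sep="\t")
    required = {"well_id", "condition", "channel_a", "channel_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [PlateReading(str(r.well_id), float(r.channel_a), float(r.channel_b),
                         str(r.condition))
            for r in df.itertuples(index=False)]
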
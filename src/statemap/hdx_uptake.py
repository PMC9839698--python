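"""Deuterium uptake from isotope envelopes (HDX-MS).

A peptide's isotope envelope shifts to higher m/z as backbone amides take
up deuterium.  Uptake at time t is quantified from the intensity-weighted
mean m/z centroid of the envelope, converted into percent deuteration
against two controls measured for the same peptide:

    %D(t) = 100 · (c(t) − c_undeut) / (c_fullD − c_undeut)

where c_undeut is the undeuterated centroid and c_fullD the fully
deuterated control's.  Using the full-D control as the 100% anchor corrects
for back-exchange (deuterium lost during digestion and chromatography)
because the control suffers the same loss.  Values outside [0, 100] are not
clamped — on noisy data they flag a problem rather than hide it.

Centroids are computed on m/z as measured (one charge state per envelope);
no charge deconvolution to neutral mass is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeEnvelope",
    "UptakeResult",
    "envelope_centroid",
    "percent_deuteration",
    "uptake_timecourse",
    "load_peaklist",
]

logger = logging.getLogger(__name__)

# exchange_time sentinels for the two controls in peak-list inputs
UNDEUT_TIME = -1.0
FULLD_TIME = -2.0


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Peak list of one peptide at one exchange time.

    peaks: (m/z in Th, intensity ≥ 0), m/z ascending, at least one
    positive-intensity peak.
    """

    peptide_id: str
    exchange_time: float  # seconds; negative sentinels mark controls
    peaks: tuple[tuple[float, float], ...]
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"{self.peptide_id}: charge must be ≥ 1")
        if not self.peaks:
            raise ValueError(f"{self.peptide_id}: empty peak list")
        mz = [p[0] for p in self.peaks]
        if any(b < a for a, b in zip(mz, mz[1:])):
            raise ValueError(f"{self.peptide_id}: m/z not ascending")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"{self.peptide_id}: negative intensity")
        if not any(i > 0 for _, i in self.peaks):
            raise ValueError(f"{self.peptide_id}: no positive-intensity peak")


@dataclass(frozen=True)
class UptakeResult:
    peptide_id: str
    time: float  # s
    centroid: float  # Th
    percent_d: float
    out_of_range: bool  # %D outside [0, 100] (noise flag, value not clamped)


def envelope_centroid(env: IsotopeEnvelope) -> float:
    """Intensity-weighted mean m/z: Σ(m/z · I) / Σ(I)."""
    mz = np.array([p[0] for p in env.peaks])
    inten = np.array([p[1] for p in env.peaks])
    total = inten.sum()
    if total <= 0:
        raise ValueError(f"{env.peptide_id}: zero total intensity")
    return float((mz * inten).sum() / total)


def percent_deuteration(c_t: float, c_undeut: float, c_fulld: float) -> float:
    """Percent deuterium incorporation with full-D back-exchange correction.

    100 · (c_t − c_undeut) / (c_fullD − c_undeut); the controls must differ.
    """
    denom = c_fulld - c_undeut
    if denom == 0:
        raise ValueError("fully deuterated and undeuterated centroids are equal")
    return 100.0 * (c_t - c_undeut) / denom


def _maybe_warn_bimodal(env: IsotopeEnvelope) -> None:
    """Log when an envelope's intensity profile dips between two maxima.

    A crude EX1 tell-tale only; proper bimodal deconvolution is upstream.
    """
    inten = np.array([p[1] for p in env.peaks])
    if len(inten) < 5:
        return
    peaks = [i for i in range(1, len(inten) - 1)
             if inten[i] > inten[i - 1] and inten[i] > inten[i + 1]]
    if len(peaks) >= 2:
        lo = inten[peaks[0]:peaks[-1] + 1].min()
        if lo < 0.5 * min(inten[peaks[0]], inten[peaks[-1]]):
            logger.warning("%s t=%gs: bimodal-looking envelope (possible EX1)",
                           env.peptide_id, env.exchange_time)


def uptake_timecourse(envelopes: list[IsotopeEnvelope],
                      controls: dict[str, tuple[IsotopeEnvelope, IsotopeEnvelope]]
                      ) -> list[UptakeResult]:
    """Percent deuteration for every (peptide, time) envelope.

    ``controls`` maps peptide_id → (undeuterated, fully-deuterated)
    envelopes.  Results are grouped per peptide with times ascending.
    Raises KeyError naming any peptide without controls.
    """
    by_peptide: dict[str, list[IsotopeEnvelope]] = {}
    for env in envelopes:
        by_peptide.setdefault(env.peptide_id, []).append(env)

    out: list[UptakeResult] = []
    for pid in sorted(by_peptide):
        if pid not in controls:
            raise KeyError(f"no controls for peptide {pid!r}")
        undeut, fulld = controls[pid]
        c_un = envelope_centroid(undeut)
        c_fd = envelope_centroid(fulld)
        for env in sorted(by_peptide[pid], key=lambda e: e.exchange_time):
            _maybe_warn_bimodal(env)
            c_t = envelope_centroid(env)
            pd_val = percent_deuteration(c_t, c_un, c_fd)
            out.append(UptakeResult(pid, env.exchange_time, c_t, pd_val,
                                    out_of_range=not 0.0 <= pd_val <= 100.0))
    return out


def load_peaklist(path: str | Path) -> tuple[list[IsotopeEnvelope],
                                             dict[str, tuple[IsotopeEnvelope, IsotopeEnvelope]]]:
    """Read a peak-list TSV into time-point envelopes and per-peptide controls.

    Columns: peptide_id, charge, exchange_time_s, mz, intensity.  Control
    rows use exchange_time_s = -1 (undeuterated) and -2 (fully deuterated).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"peptide_id", "charge", "exchange_time_s", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    envelopes: list[IsotopeEnvelope] = []
    controls: dict[str, dict[float, IsotopeEnvelope]] = {}
    for (pid, t, z), grp in df.groupby(["peptide_id", "exchange_time_s", "charge"]):
        grp = grp.sort_values("mz")
        env = IsotopeEnvelope(str(pid), float(t),
                              tuple(zip(grp["mz"], grp["intensity"])), int(z))
        if t in (UNDEUT_TIME, FULLD_TIME):
            controls.setdefault(str(pid), {})[float(t)] = env
        else:
            envelopes.append(env)
    ctrl_pairs: dict[str, tuple[IsotopeEnvelope, IsotopeEnvelope]] = {}
    for pid, d in controls.items():
        if UNDEUT_TIME not in d or FULLD_TIME not in d:
            raise ValueError(f"peptide {pid!r}: incomplete controls in {path}")
        ctrl_pairs[pid] = (d[UNDEUT_TIME], d[FULLD_TIME])
    return envelopes, ctrl_pairs
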
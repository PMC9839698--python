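"""Orientation-consistency filtering of cryo-EM particles.

After a 3D refinement has converged, particles whose angular assignment is
genuinely determined by the data keep re-converging to (nearly) the same
orientation when refinement is continued; particles with ambiguous or junk
signal wander.  Running several extra refinement cycles past convergence
and measuring, for each particle, the geodesic rotation angle between each
cycle's orientation and the converged assignment exposes the wanderers: a
particle is eliminated when the deviation exceeds ``angle_threshold``
(default 9°) in strictly more than ``fraction_threshold`` (default 50%) of
the extra cycles — for the default 7 cycles that means 4 or more deviant
cycles.

Orientations are ZYZ intrinsic Euler triplets (rot, tilt, psi) as stored in
RELION STAR particle metadata; the deviation metric is the rotation-group
geodesic angle θ = arccos((tr(R₁ᵀR₂) − 1)/2), which is symmetric, invariant
under any common global rotation, and ignores in-plane shifts.  No point-
group symmetry is applied (C1): receptor–G-protein complexes are asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from statemap.star import read_star, write_star

__all__ = [
    "EulerTriplet",
    "OrientationSeries",
    "FilterConfig",
    "FilterDecision",
    "euler_to_rotation",
    "rotation_geodesic_angle",
    "consistency_filter",
    "filter_particle_table",
]

EULER_COLS = ("angleRot", "angleTilt", "anglePsi")


@dataclass(frozen=True)
class EulerTriplet:
    """ZYZ intrinsic Euler angles in degrees (RELION rot/tilt/psi)."""

    rot: float
    tilt: float
    psi: float

    def __post_init__(self) -> None:
        for v in (self.rot, self.tilt, self.psi):
            if not np.isfinite(v):
                raise ValueError("Euler angles must be finite")


@dataclass
class OrientationSeries:
    """A particle's converged orientation plus its post-convergence cycles."""

    particle_id: str
    reference: EulerTriplet
    cycles: list[EulerTriplet]

    def __post_init__(self) -> None:
        if len(self.cycles) < 1:
            raise ValueError(f"particle {self.particle_id}: needs ≥1 cycle")


@dataclass(frozen=True)
class FilterConfig:
    """Elimination rule parameters.

    ``mode`` selects the comparison baseline: "reference" measures every
    cycle against the converged assignment (default); "consecutive" measures
    each cycle against the previous one (the reference precedes cycle 1).
    """

    angle_threshold: float = 9.0  # degrees, strict >
    fraction_threshold: float = 0.5  # strict >
    n_cycles: int = 7
    mode: str = "reference"

    def __post_init__(self) -> None:
        if self.angle_threshold <= 0:
            raise ValueError("angle_threshold must be positive")
        if not 0 < self.fraction_threshold < 1:
            raise ValueError("fraction_threshold must be in (0, 1)")
        if self.mode not in ("reference", "consecutive"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class FilterDecision:
    particle_id: str
    n_deviant: int
    eliminated: bool


def euler_to_rotation(e: EulerTriplet) -> np.ndarray:
    """Rotation matrix R = Rz(rot)·Ry(tilt)·Rz(psi) (ZYZ intrinsic, degrees)."""
    a, b, g = np.deg2rad([e.rot, e.tilt, e.psi])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    rz_a = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry_b = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz_g = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rz_a @ ry_b @ rz_g


def rotation_geodesic_angle(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle in degrees between two rotations.

    θ = arccos((tr(R₁ᵀR₂) − 1)/2), clamped to [0°, 180°].  Inputs must be
    orthonormal to 1e-6.
    """
    for r in (r1, r2):
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("input is not orthonormal within 1e-6")
    tr = np.trace(r1.T @ r2)
    cos_theta = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_theta)))


def consistency_filter(series: OrientationSeries,
                       cfg: FilterConfig = FilterConfig()) -> FilterDecision:
    """Decide whether one particle failed to re-converge consistently.

    A cycle is deviant when its geodesic angle to the baseline (converged
    reference, or previous cycle in "consecutive" mode) strictly exceeds
    ``cfg.angle_threshold``; the particle is eliminated when the deviant
    fraction strictly exceeds ``cfg.fraction_threshold``.
    """
    if len(series.cycles) != cfg.n_cycles:
        raise ValueError(
            f"particle {series.particle_id}: {len(series.cycles)} cycles, "
            f"config expects {cfg.n_cycles}")
    baseline = euler_to_rotation(series.reference)
    n_deviant = 0
    for cyc in series.cycles:
        r = euler_to_rotation(cyc)
        if rotation_geodesic_angle(baseline, r) > cfg.angle_threshold:
            n_deviant += 1
        if cfg.mode == "consecutive":
            baseline = r
    eliminated = n_deviant / len(series.cycles) > cfg.fraction_threshold
    return FilterDecision(series.particle_id, n_deviant, eliminated)


def _particles_block(blocks: dict[str, pd.DataFrame], path: str) -> pd.DataFrame:
    for name in ("particles", "default", ""):
        if name in blocks:
            df = blocks[name]
            if all(c in df.columns for c in EULER_COLS):
                return df
    # fall back: first block carrying the Euler columns (skips data_optics)
    for df in blocks.values():
        if all(c in df.columns for c in EULER_COLS):
            return df
    raise ValueError(f"{path}: no block with Euler columns {EULER_COLS}")


def _particle_ids(df: pd.DataFrame) -> pd.Series:
    parts = []
    for col in ("imageName", "micrographName"):
        if col in df.columns:
            parts.append(df[col].astype(str))
    if not parts:
        raise ValueError("STAR table lacks imageName/micrographName identifier columns")
    ids = parts[0]
    for p in parts[1:]:
        ids = ids + "@" + p
    return ids


def filter_particle_table(star_reference: str | Path, star_cycles: list[str | Path],
                          cfg: FilterConfig = FilterConfig(),
                          out: str | Path | None = None) -> tuple[int, int, int]:
    """Apply the consistency filter to STAR particle tables.

    ``star_reference`` holds the converged orientations; ``star_cycles`` the
    post-convergence refinement cycles (their number must equal
    ``cfg.n_cycles``).  Surviving particles are written to ``out`` in input
    order with all original columns preserved.  Returns
    (n_input, n_eliminated, n_kept).
    """
    if len(star_cycles) != cfg.n_cycles:
        raise ValueError(f"{len(star_cycles)} cycle files for n_cycles={cfg.n_cycles}")
    ref_blocks = read_star(star_reference)
    ref = _particles_block(ref_blocks, str(star_reference))
    ref_ids = _particle_ids(ref)

    cycle_orient: list[pd.DataFrame] = []
    for p in star_cycles:
        df = _particles_block(read_star(p), str(p))
        ids = _particle_ids(df)
        missing = set(ref_ids) - set(ids)
        if missing:
            raise ValueError(
                f"{p}: {len(missing)} reference particles missing, e.g. "
                f"{sorted(missing)[:5]}")
        cycle_orient.append(
            df.set_index(ids)[list(EULER_COLS)].astype(float).loc[ref_ids])

    keep = np.ones(len(ref), dtype=bool)
    for i, pid in enumerate(ref_ids):
        reference = EulerTriplet(*(float(ref.iloc[i][c]) for c in EULER_COLS))
        cycles = [EulerTriplet(*(float(c_df.iloc[i][c]) for c in EULER_COLS))
                  for c_df in cycle_orient]
        decision = consistency_filter(
            OrientationSeries(str(pid), reference, cycles), cfg)
        keep[i] = not decision.eliminated

    n_input = len(ref)
    n_kept = int(keep.sum())
    if out is not None:
        kept_blocks = dict(ref_blocks)
        for name, df in ref_blocks.items():
            if df is ref:
                kept_blocks[name] = ref[keep]
        write_star(kept_blocks, out)
    return n_input, n_input - n_kept, n_kept
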
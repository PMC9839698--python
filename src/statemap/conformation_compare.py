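"""Rigid superposition, Cα r.m.s.d. and radius-of-gyration profiling.

Conformational comparison between receptor models uses least-squares rigid
superposition (Kabsch, SVD form with reflection suppressed) over Cα atoms of
residues matched through generic-number correspondence; the matched-atom
count is always reported because printed r.m.s.d. values are meaningless
without the residue set they were computed on.

Radius of gyration Rg = sqrt(Σ w_i |r_i − r̄|² / Σ w_i) of a residue segment
(mass-weighted by default) serves as a folding proxy: an α-helical segment
is compact, an extended one is not.  Profiles over coordinate ensembles
(MD frames, multi-model PDB) track segment folding over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from statemap.generic_numbering import GenericNumberMap, correspond
from statemap.structure_io import StructureModel

__all__ = [
    "SuperpositionResult",
    "CoordinateEnsemble",
    "SegmentSpec",
    "kabsch_superpose",
    "ca_rmsd",
    "radius_of_gyration",
    "rg_profile",
    "read_xyz_frames",
]

# Standard atomic masses (u) for the elements that occur in heavy-atom
# protein models; fallback 12.0 for anything exotic.
ATOMIC_MASS = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "SE": 78.971, "P": 30.974,
}


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid fit of a mobile coordinate set onto a reference."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # Å, after transform
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class CoordinateEnsemble:
    """Frames of per-atom coordinates sharing one atom order.

    ``atom_labels`` rows are (chain, seqnum, atom_name, element).
    """

    frames: list[np.ndarray]
    atom_labels: list[tuple[str, int, str, str]]
    time_axis: list[float] | None = None

    def __post_init__(self) -> None:
        n = len(self.atom_labels)
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(f"frame {i}: shape {f.shape}, expected ({n}, 3)")
            self.frames[i] = f
        if self.time_axis is None:
            self.time_axis = list(range(len(self.frames)))

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class SegmentSpec:
    """A contiguous residue segment selected by (chain, seqnum) bounds."""

    chain: str
    first: int
    last: int
    atom_scope: str = "heavy"  # heavy | CA_only

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError(f"segment first {self.first} > last {self.last}")
        if self.atom_scope not in ("heavy", "CA_only"):
            raise ValueError(f"unknown atom_scope {self.atom_scope!r}")

    def mask(self, atom_labels: list[tuple[str, int, str, str]]) -> np.ndarray:
        sel = np.array([
            lab[0] == self.chain and self.first <= lab[1] <= self.last
            and (self.atom_scope == "heavy" or lab[2] == "CA")
            for lab in atom_labels
        ])
        return sel


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid transform of ``coords_b`` onto ``coords_a``.

    SVD solution with reflection suppressed (det forced to +1); r.m.s.d. is
    computed after applying the transform.  Requires N ≥ 3 non-degenerate
    points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes {a.shape} and {b.shape} must match (N, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    cen_a, cen_b = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - cen_a, b - cen_b
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    # degenerate = all points collinear: two vanishing singular values
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) coordinates; rotation underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cen_a - rot @ cen_b
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def ca_rmsd(model_a: StructureModel, gmap_a: GenericNumberMap,
            model_b: StructureModel, gmap_b: GenericNumberMap) -> SuperpositionResult:
    """Cα r.m.s.d. between two receptor models over corresponding residues.

    Residues are paired by generic number (helix offsets applied); only
    pairs where both models resolve a Cα contribute.  Raises if fewer than
    3 Cα pairs match, listing the unmatched residues.
    """
    pairs, unpaired_a, unpaired_b = correspond(gmap_a, gmap_b)
    xa, xb = [], []
    missing: list[str] = []
    for key_a, key_b, gn in pairs:
        res_a = model_a.residue(*key_a)
        res_b = model_b.residue(*key_b)
        ca_a = res_a.atom("CA") if res_a else None
        ca_b = res_b.atom("CA") if res_b else None
        if ca_a is None or ca_b is None:
            missing.append(str(gn))
            continue
        xa.append(ca_a.position)
        xb.append(ca_b.position)
    if len(xa) < 3:
        raise ValueError(
            f"only {len(xa)} matched Cα pairs (need ≥3); unmatched: "
            f"{missing + [str(k) for k in unpaired_a + unpaired_b]}")
    return kabsch_superpose(np.array(xa), np.array(xb))


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Rg (Å) of a point set: sqrt(Σ w_i |r_i − r̄|² / Σ w_i).

    ``masses`` of None means unit weights.  The centroid r̄ is itself
    weight-averaged.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] == 0:
        raise ValueError(f"coords must be non-empty (N, 3), got {x.shape}")
    if masses is None:
        w = np.ones(x.shape[0])
    else:
        w = np.asarray(masses, dtype=float)
        if w.shape != (x.shape[0],) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("masses must be non-negative with positive sum, one per atom")
    centroid = (w[:, None] * x).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((x - centroid) ** 2, axis=1)).sum() / w.sum()))


def rg_profile(ensemble: CoordinateEnsemble, selection: SegmentSpec,
               mass_weighted: bool = True) -> list[tuple[float, float]]:
    """Per-frame Rg of a residue segment, order preserved.

    Returns (time, Rg) tuples.  Raises if the selection matches no atoms of
    the ensemble's labels.
    """
    sel = selection.mask(ensemble.atom_labels)
    if not sel.any():
        raise ValueError(
            f"selection {selection.chain}:{selection.first}-{selection.last} "
            f"matches no atoms in ensemble")
    if mass_weighted:
        masses = np.array([ATOMIC_MASS.get(lab[3].upper(), 12.0)
                           for lab, s in zip(ensemble.atom_labels, sel) if s])
    else:
        masses = None
    out = [(t, radius_of_gyration(frame[sel], masses))
           for t, frame in zip(ensemble.time_axis, ensemble.frames)]
    return out


def read_xyz_frames(path: str | Path, atom_labels: list[tuple[str, int, str, str]],
                    time_axis: list[float] | None = None) -> CoordinateEnsemble:
    """Read a plain-text trajectory: one whitespace row per atom, blank line between frames."""
    frames: list[np.ndarray] = []
    current: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                if current:
                    frames.append(np.array(current))
                    current = []
                continue
            current.append([float(v) for v in line.split()[:3]])
    if current:
        frames.append(np.array(current))
    return CoordinateEnsemble(frames=frames, atom_labels=atom_labels, time_axis=time_axis)
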
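"""Synthetic fixtures with planted ground truth.

Every pipeline stage can be exercised without any deposited dataset:

* two-state helical bundles (ideal poly-alanine helices, per-helix rigid
  shifts between the "active" and "inactive" copies) with the state-unique
  pairs enumerated by brute force inside the generator;
* cryo-EM orientation series over post-convergence refinement cycles with
  planted deviant particles, written as RELION 3.1 STAR files;
* Gaussian isotope envelopes whose centroid follows first-order exchange
  kinetics, with the exact percent-deuteration curve as truth;
* helix-to-coil interpolation ensembles whose radius of gyration increases
  frame to frame by construction.

All generators are pure functions of their parameters and seed, and every
truth is computed by an independent code path — never by calling the
module the fixture is meant to test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from statemap.conformation_compare import CoordinateEnsemble
from statemap.generic_numbering import GenericNumber, GenericNumberMap
from statemap.hdx_uptake import FULLD_TIME, UNDEUT_TIME, IsotopeEnvelope
from statemap.star import write_star
from statemap.structure_io import AtomRecord, ResidueRecord, StructureModel

__all__ = [
    "BundleSpec",
    "PlantedTruth",
    "OrientationSetResult",
    "make_two_state_bundle",
    "make_orientation_set",
    "make_envelopes",
    "make_unfolding_ensemble",
    "write_bundle_pdb",
    "write_numbering_tsv",
]


@dataclass
class BundleSpec:
    """Geometry of a toy two-state helical bundle.

    Defaults follow ideal α-helix parameters: 1.5 Å rise and 100° twist per
    residue, Cα at 2.3 Å from the helix axis.  ``state_shift`` gives each
    helix a rigid displacement applied only in the inactive copy, which is
    what plants state-unique contacts.
    """

    n_helices: int = 2
    residues_per_helix: int = 8
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    helix_radius: float = 2.3
    axis_positions: list[tuple[float, float]] | None = None
    state_shift: list[tuple[float, float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 2:
            raise ValueError("need at least 2 helices")
        if self.axis_positions is None:
            # helices on a circle wide enough not to clash
            ring_r = max(8.0, 3.0 * self.n_helices)
            angles = np.linspace(0, 2 * np.pi, self.n_helices, endpoint=False)
            self.axis_positions = [(ring_r * math.cos(a), ring_r * math.sin(a))
                                   for a in angles]
        if len(self.axis_positions) != self.n_helices:
            raise ValueError("axis_positions length != n_helices")
        for i in range(self.n_helices):
            for j in range(i + 1, self.n_helices):
                d = math.dist(self.axis_positions[i], self.axis_positions[j])
                if d < 2.0:
                    raise ValueError(f"helix axes {i} and {j} overlap ({d:.2f} Å apart)")
        if self.state_shift is None:
            self.state_shift = [(0.0, 0.0, 0.0)] * self.n_helices
        if len(self.state_shift) != self.n_helices:
            raise ValueError("state_shift length != n_helices")


@dataclass
class PlantedTruth:
    """Ground truth accompanying a generated fixture."""

    state_unique_pairs: list[tuple[GenericNumber, GenericNumber, str]] = field(default_factory=list)
    deviant_particle_ids: list[str] = field(default_factory=list)
    envelope_percent_d: list[tuple[float, float]] = field(default_factory=list)


# offsets of backbone/CB atoms relative to the Cα helix wheel:
# (radius Å, angle offset deg, z offset Å).  Coarse but geometrically sane;
# full rotamer realism is unnecessary for closest-heavy-atom threshold logic.
_ATOM_WHEEL = {
    "N": (1.9, -28.0, -0.9),
    "CA": (2.3, 0.0, 0.0),
    "C": (2.0, 26.0, 0.55),
    "O": (2.2, 40.0, 1.25),
    "CB": (3.4, 2.0, -0.2),  # points outward from the axis
}

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _helix_residues(spec: BundleSpec, helix_idx: int, shift: tuple[float, float, float],
                    chain: str, seq_start: int) -> list[ResidueRecord]:
    x0, y0 = spec.axis_positions[helix_idx]
    out = []
    for i in range(spec.residues_per_helix):
        theta0 = math.radians(spec.twist_per_residue * i)
        z0 = spec.rise_per_residue * i
        atoms = []
        for name, (r, dphi, dz) in _ATOM_WHEEL.items():
            r_eff = r * (spec.helix_radius / 2.3)
            th = theta0 + math.radians(dphi)
            pos = np.array([x0 + r_eff * math.cos(th),
                            y0 + r_eff * math.sin(th),
                            z0 + dz]) + np.asarray(shift)
            atoms.append(AtomRecord(name=name, element=_ELEMENT[name], position=pos))
        out.append(ResidueRecord(chain=chain, seqnum=seq_start + i, icode="",
                                 resname="ALA", atoms=tuple(atoms)))
    return out


def make_two_state_bundle(spec: BundleSpec, receptor: str = "SYN"
                          ) -> tuple[StructureModel, StructureModel, GenericNumberMap, PlantedTruth]:
    """Build active/inactive copies of an ideal bundle plus numbering and truth.

    The active copy sits on ``spec.axis_positions``; the inactive copy adds
    ``spec.state_shift`` rigidly to each helix.  Generic numbers run along
    each helix with position 50 at the midpoint.  The truth enumerates every
    cross-helix residue pair meeting the state-unique rule (<4.6 Å in one
    state and >6.0 Å in the other, closest heavy atoms), computed by brute
    force here, independently of the interaction-map module.
    """
    gmap = GenericNumberMap(receptor)
    active_res: list[ResidueRecord] = []
    inactive_res: list[ResidueRecord] = []
    helix_of: dict[tuple[str, int, str], int] = {}

    seq = 1
    mid = spec.residues_per_helix // 2
    for h in range(spec.n_helices):
        a_res = _helix_residues(spec, h, (0.0, 0.0, 0.0), "A", seq)
        i_res = _helix_residues(spec, h, spec.state_shift[h], "A", seq)
        active_res += a_res
        inactive_res += i_res
        for i, res in enumerate(a_res):
            gn = GenericNumber(helix=min(h + 1, 8), position=50 - mid + i)
            gmap.add(res.key, gn)
            helix_of[res.key] = h
        seq += spec.residues_per_helix + 10  # numbering gap between helices

    active = StructureModel("synthetic-active", receptor, "active", active_res)
    inactive = StructureModel("synthetic-inactive", receptor, "inactive", inactive_res)

    # brute-force truth: plain double loop, no interaction_map import
    truth_pairs: list[tuple[GenericNumber, GenericNumber, str]] = []
    inact_by_key = {r.key: r for r in inactive_res}
    for ia in range(len(active_res)):
        for ib in range(ia + 1, len(active_res)):
            ra, rb = active_res[ia], active_res[ib]
            if helix_of[ra.key] == helix_of[rb.key]:
                continue
            qa, qb = inact_by_key[ra.key], inact_by_key[rb.key]
            d_act = _min_dist(ra, rb)
            d_ina = _min_dist(qa, qb)
            if d_act < 4.6 and d_ina > 6.0:
                cls = "active_unique"
            elif d_ina < 4.6 and d_act > 6.0:
                cls = "inactive_unique"
            else:
                continue
            gn_a, gn_b = sorted([gmap.generic(ra.key), gmap.generic(rb.key)])
            truth_pairs.append((gn_a, gn_b, cls))
    truth_pairs.sort()
    return active, inactive, gmap, PlantedTruth(state_unique_pairs=truth_pairs)


def _min_dist(ra: ResidueRecord, rb: ResidueRecord) -> float:
    a = ra.coords()
    b = rb.coords()
    return float(np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min())


def write_bundle_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a bundle as a minimal fixed-column PDB file."""
    with open(path, "w", encoding="utf-8") as fh:
        serial = 1
        for res in model.residues:
            for a in res.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.resname:>3s} "
                    f"{res.chain:1s}{res.seqnum:4d}{res.icode or ' ':1s}   "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          "
                    f"{a.element:>2s}\n")
                serial += 1
        fh.write("END\n")


def write_numbering_tsv(gmap: GenericNumberMap, path: str | Path) -> None:
    """Write a numbering map in the chain/seqnum/icode/generic TSV format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chain\tseqnum\ticode\tgeneric\n")
        for (chain, seqnum, icode), gn in sorted(gmap.entries(), key=lambda kv: kv[1]):
            fh.write(f"{chain}\t{seqnum}\t{icode or '.'}\t{gn}\n")


# --- orientation series ----------------------------------------------------

@dataclass
class OrientationSetResult:
    reference_path: Path
    cycle_paths: list[Path]
    truth: PlantedTruth


def _random_rotation_about(rng: np.random.Generator, angle_deg: float) -> Rotation:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)


def _to_euler_zyz(rot: Rotation) -> tuple[float, float, float]:
    r, t, p = rot.as_euler("ZYZ", degrees=True)
    return float(r), float(t), float(p)


def make_orientation_set(n_particles: int, n_deviant: int, noise_deg: float,
                         deviant_offset_deg: float, n_cycles: int, seed: int,
                         out_dir: str | Path) -> OrientationSetResult:
    """Generate reference + cycle STAR files with planted deviant particles.

    Well-behaved particles re-converge to within ``noise_deg`` of their
    reference orientation in every cycle (noise angle uniform in
    [0, noise_deg], random axis).  Each deviant particle instead receives a
    rotation offset of ``deviant_offset_deg`` in exactly
    ``floor(n_cycles/2) + 1`` cycles — the minimum count whose fraction
    strictly exceeds 50% — guaranteeing elimination under the default rule
    whenever the offset clears the angular threshold.  Output is
    deterministic for a fixed seed.
    """
    if n_deviant > n_particles:
        raise ValueError(f"n_deviant {n_deviant} > n_particles {n_particles}")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ids = [f"{i + 1:06d}@particles.mrcs" for i in range(n_particles)]
    micrograph = "synthetic_micrograph_001.mrc"
    deviant_ids = sorted(rng.choice(n_particles, size=n_deviant, replace=False).tolist())
    deviant_set = set(deviant_ids)
    n_dev_cycles = n_cycles // 2 + 1

    refs: list[Rotation] = []
    for _ in range(n_particles):
        q = rng.normal(size=4)
        refs.append(Rotation.from_quat(q / np.linalg.norm(q)))

    deviant_cycles: dict[int, set[int]] = {
        i: set(rng.choice(n_cycles, size=n_dev_cycles, replace=False).tolist())
        for i in deviant_ids}

    def table(rots: list[Rotation]) -> pd.DataFrame:
        eulers = [_to_euler_zyz(r) for r in rots]
        return pd.DataFrame({
            "imageName": ids,
            "micrographName": [micrograph] * n_particles,
            "angleRot": [e[0] for e in eulers],
            "angleTilt": [e[1] for e in eulers],
            "anglePsi": [e[2] for e in eulers],
        })

    ref_path = out_dir / "reference.star"
    write_star({"particles": table(refs)}, ref_path)

    cycle_paths: list[Path] = []
    for c in range(n_cycles):
        rots = []
        for i in range(n_particles):
            if i in deviant_set and c in deviant_cycles[i]:
                delta = _random_rotation_about(rng, deviant_offset_deg)
            else:
                delta = _random_rotation_about(rng, rng.uniform(0.0, noise_deg))
            rots.append(delta * refs[i])
        p = out_dir / f"cycle_{c + 1}.star"
        write_star({"particles": table(rots)}, p)
        cycle_paths.append(p)

    truth = PlantedTruth(deviant_particle_ids=[f"{ids[i]}@{micrograph}" for i in deviant_ids])
    return OrientationSetResult(ref_path, cycle_paths, truth)


# --- isotope envelopes -----------------------------------------------------

def make_envelopes(peptide_id: str, undeut_centroid: float, max_uptake: float,
                   times: list[float], rate: float, peak_sigma: float, seed: int,
                   charge: int = 2, intensity_noise: float = 0.01
                   ) -> tuple[list[IsotopeEnvelope],
                              tuple[IsotopeEnvelope, IsotopeEnvelope],
                              list[tuple[float, float]]]:
    """Gaussian envelopes following first-order exchange kinetics.

    The true centroid at time t is ``c0 + max_uptake · (1 − e^(−rate·t))``,
    so truth %D = 100 · (1 − e^(−rate·t)).  Each envelope is a discrete
    Gaussian sampled at isotope spacing 1/charge over ±4σ, with mild
    multiplicative intensity noise.  Returns (time-point envelopes,
    (undeuterated, fully-deuterated) controls, truth list of (t, %D)).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    spacing = 1.0 / charge
    half = max(4, int(math.ceil(4 * peak_sigma / spacing)))

    def envelope(centre: float, t: float) -> IsotopeEnvelope:
        mz = centre + spacing * np.arange(-half, half + 1)
        inten = np.exp(-0.5 * ((mz - centre) / peak_sigma) ** 2)
        inten = inten * (1.0 + intensity_noise * rng.standard_normal(inten.size))
        inten = np.clip(inten, 0.0, None)
        return IsotopeEnvelope(peptide_id, t, tuple(zip(mz.tolist(), inten.tolist())), charge)

    undeut = envelope(undeut_centroid, UNDEUT_TIME)
    fulld = envelope(undeut_centroid + max_uptake, FULLD_TIME)
    envs, truth = [], []
    for t in times:
        frac = 1.0 - math.exp(-rate * t)
        envs.append(envelope(undeut_centroid + max_uptake * frac, t))
        truth.append((t, 100.0 * frac))
    return envs, (undeut, fulld), truth


# --- unfolding ensemble ----------------------------------------------------

def make_unfolding_ensemble(n_frames: int, segment_length: int, seed: int = 0
                            ) -> CoordinateEnsemble:
    """Cα trace interpolating from ideal helix to extended chain.

    Both endpoint conformations are centred and axis-aligned, which makes
    the radius of gyration a strictly increasing function of the
    interpolation parameter (the squared Rg is a convex quadratic in the
    mixing weight with positive slope at zero for any segment of ≥4
    residues).  The seed only perturbs a rigid overall placement, so the Rg
    series itself is seed-independent.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if segment_length < 4:
        raise ValueError("segment too short for a meaningful fold proxy")
    idx = np.arange(segment_length) - (segment_length - 1) / 2.0
    theta = np.deg2rad(100.0) * np.arange(segment_length)
    helix = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * idx])
    helix -= helix.mean(axis=0)
    extended = np.column_stack([np.zeros_like(idx), np.zeros_like(idx), 3.8 * idx])
    extended -= extended.mean(axis=0)

    rng = np.random.default_rng(seed)
    placement = Rotation.from_rotvec(rng.uniform(0, np.pi, size=3)).as_matrix()
    offset = rng.uniform(-20, 20, size=3)

    frames = []
    for lam in np.linspace(0.0, 1.0, n_frames):
        x = (1.0 - lam) * helix + lam * extended
        frames.append(x @ placement.T + offset)
    labels = [("A", 244 + i, "CA", "C") for i in range(segment_length)]
    return CoordinateEnsemble(frames=frames, atom_labels=labels)
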
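"""Coordinate-file I/O and the internal structure model.

Structures are normalised into a plain residue/atom hierarchy suitable for
closest-heavy-atom distance work: hydrogens stripped, a single conformer
retained per alternate-location group, waters/ligands/ions excluded by
default.  Author residue numbering is authoritative throughout because the
receptor-residue names used in the field (e.g. A251^6.34) are author numbers.

Tabular outputs are UTF-8 TSV with a header row; dataclass record lists
round-trip losslessly through :func:`write_table` / :func:`read_table`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "StructureParseError",
    "EmptyModelError",
    "read_structure",
    "write_table",
    "read_table",
]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyModelError(ValueError):
    """Raised when reading/filtering a structure yields no residues."""


@dataclass(frozen=True)
class AtomRecord:
    """A single heavy atom.

    Parameters
    ----------
    name : str
        Atom name (e.g. ``CA``, ``CB``).
    element : str
        Element symbol, upper-case.
    position : np.ndarray
        Cartesian coordinates in Å, shape (3,).
    occupancy : float
        Occupancy fraction in [0, 1].
    altloc : str
        Alternate-location indicator, empty string when absent.
    """

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass(frozen=True)
class ResidueRecord:
    """One residue with its heavy atoms.

    The key (chain, seqnum, icode) is unique within a model; seqnum is the
    author residue number.
    """

    chain: str
    seqnum: int
    icode: str
    resname: str
    atoms: tuple[AtomRecord, ...]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqnum, self.icode)

    def coords(self) -> np.ndarray:
        """Heavy-atom coordinates as an (n, 3) array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """An ordered collection of residues for one receptor model.

    ``state`` is "active", "inactive" or "unspecified"; it is a label only
    and never inferred from coordinates.
    """

    model_id: str
    receptor: str
    state: str
    residues: list[ResidueRecord]

    def __post_init__(self) -> None:
        if self.state not in ("active", "inactive", "unspecified"):
            raise ValueError(f"unknown state label {self.state!r}")
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue keys in model")

    def residue(self, chain: str, seqnum: int, icode: str = "") -> ResidueRecord | None:
        for r in self.residues:
            if r.key == (chain, seqnum, icode):
                return r
        return None

    def __len__(self) -> int:
        return len(self.residues)


# Residues never treated as polymer ligands even though gemmi may flag them.
_MSE = "MSE"

_WATER_NAMES = {"HOH", "DOD", "WAT"}


def _select_altloc(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, first-in-file on ties."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occ > best[a.name].occ:
            best[a.name] = a
    return [best[n] for n in order]


def read_structure(
    path: str | Path,
    chain_filter: str | None = None,
    *,
    receptor: str = "",
    state: str = "unspecified",
    include_hetero: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Hydrogens (and deuteriums) are removed; for alternate locations only the
    highest-occupancy conformer is retained (first in file order on ties);
    waters, ligands and ions are excluded unless ``include_hetero`` is set.
    MSE (selenomethionine) is treated as MET.

    Parameters
    ----------
    path : str or Path
        Coordinate file; format inferred from extension (.cif/.mmcif → mmCIF,
        otherwise PDB) with gemmi's own sniffing as fallback.
    chain_filter : str, optional
        Restrict to a single chain id.

    Raises
    ------
    StructureParseError
        If the file cannot be parsed.
    EmptyModelError
        If no residues survive the selection.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    st.setup_entities()
    model = st[0]

    residues: list[ResidueRecord] = []
    for chain in model:
        if chain_filter is not None and chain.name != chain_filter:
            continue
        for res in chain:
            resname = res.name
            if resname in _WATER_NAMES:
                continue
            if resname == _MSE:
                resname = "MET"
            is_polymer = gemmi.find_tabulated_residue(res.name) is not None and \
                gemmi.find_tabulated_residue(res.name).is_amino_acid()
            if not is_polymer and not include_hetero:
                continue
            heavy = [a for a in res if a.element.name not in ("H", "D")]
            heavy = _select_altloc(heavy)
            if not heavy:
                continue
            atoms = tuple(
                AtomRecord(
                    name=a.name,
                    element=a.element.name.upper(),
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in heavy
            )
            icode = res.seqid.icode.strip()
            residues.append(
                ResidueRecord(chain=chain.name, seqnum=res.seqid.num, icode=icode,
                              resname=resname, atoms=atoms)
            )

    if not residues:
        sel = f" (chain {chain_filter!r})" if chain_filter is not None else ""
        raise EmptyModelError(f"{path}: selection{sel} contains no residues")

    residues.sort(key=lambda r: (r.chain, r.seqnum, r.icode))
    return StructureModel(model_id=path.stem, receptor=receptor or path.stem,
                          state=state, residues=residues)


# --- tabular I/O -----------------------------------------------------------

_FLOAT_FMT = "%.3f"


def _record_to_row(rec) -> dict:
    row = {}
    for f in dc_fields(rec):
        v = getattr(rec, f.name)
        if dataclasses.is_dataclass(v):
            # flatten one level (e.g. GenericNumber -> "3.41" style string)
            row[f.name] = str(v)
        elif isinstance(v, float):
            row[f.name] = float(v)
        else:
            row[f.name] = v
    return row


def write_table(records: Sequence, path: str | Path, *, columns: Iterable[str] | None = None) -> None:
    """Write a homogeneous list of dataclass records as a TSV with header.

    Floats are formatted to 3 decimals ('.' decimal separator), so distances
    round-trip within 5e-4 Å.  An empty list writes a header-only file when
    ``columns`` is given, otherwise an empty file with no rows.
    """
    path = Path(path)
    if records:
        kinds = {type(r) for r in records}
        if len(kinds) > 1:
            raise TypeError(f"records not homogeneous: {sorted(k.__name__ for k in kinds)}")
        df = pd.DataFrame([_record_to_row(r) for r in records])
    else:
        df = pd.DataFrame(columns=list(columns) if columns is not None else [])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def read_table(path: str | Path, *, string_columns: Iterable[str] = ()) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`.

    ``string_columns`` names columns to keep as text (e.g. generic numbers,
    where "1.50" must not collapse to the float 1.5).
    """
    return pd.read_csv(path, sep="\t", encoding="utf-8",
                       dtype={c: str for c in string_columns})
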
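"""Generic residue numbering and cross-receptor residue correspondence.

Class-A GPCR residues are addressed by Ballesteros–Weinstein generic numbers
``H.PP`` (helix 1–7, H8 = 8; position 50 is the helix's most conserved
residue).  Structurally equivalent residues in two receptors share a generic
number, with one documented exception handled here: some receptors register
a one-residue slide on a helix relative to the canonical numbering (TM5 in
the GPR21/GPR52 family), expressed as a signed per-helix offset so either
slide direction can be configured.

Assignment of generic numbers from sequence is out of scope; mapping tables
are inputs (TSV: chain, seqnum, icode, generic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["GenericNumber", "GenericNumberMap", "load_numbering_table", "correspond"]

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]


@dataclass(frozen=True, order=True)
class GenericNumber:
    """A generic number ``helix.position``, e.g. 3.50."""

    helix: int
    position: int

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= 8:
            raise ValueError(f"helix {self.helix} outside 1..8")
        if not 1 <= self.position <= 99:
            raise ValueError(f"position {self.position} outside 1..99")

    def __str__(self) -> str:
        return f"{self.helix}.{self.position:02d}"  # two digits: 3.05, not 3.5

    @classmethod
    def parse(cls, text: str) -> "GenericNumber":
        parts = text.strip().split(".")
        if len(parts) != 2:
            raise ValueError(f"malformed generic number {text!r} (expected H.PP)")
        try:
            helix, pos = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"malformed generic number {text!r}: {exc}") from exc
        return cls(helix, pos)


class GenericNumberMap:
    """Bidirectional mapping residue key ↔ generic number for one receptor.

    ``helix_offsets`` holds signed per-helix slides relative to canonical
    numbering; :func:`correspond` applies the *difference* of two maps'
    offsets when pairing residues.
    """

    def __init__(self, receptor: str, helix_offsets: dict[int, int] | None = None) -> None:
        self.receptor = receptor
        self.helix_offsets: dict[int, int] = dict(helix_offsets or {})
        for h in self.helix_offsets:
            if not 1 <= h <= 8:
                raise ValueError(f"offset on helix {h}: helices are 1..8")
        self._by_key: dict[ResidueKey, GenericNumber] = {}
        self._by_gn: dict[GenericNumber, ResidueKey] = {}

    def add(self, key: ResidueKey, gn: GenericNumber) -> None:
        if key in self._by_key:
            raise ValueError(f"duplicate residue key {key}")
        if gn in self._by_gn:
            raise ValueError(f"duplicate generic number {gn}")
        self._by_key[key] = gn
        self._by_gn[gn] = key

    def generic(self, key: ResidueKey) -> GenericNumber | None:
        return self._by_key.get(key)

    def residue(self, gn: GenericNumber) -> ResidueKey | None:
        return self._by_gn.get(gn)

    def entries(self) -> list[tuple[ResidueKey, GenericNumber]]:
        return list(self._by_key.items())

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._by_key


def load_numbering_table(path: str | Path, receptor: str,
                         helix_offsets: dict[int, int] | None = None) -> GenericNumberMap:
    """Load a residue→generic-number table.

    Expected TSV columns: ``chain  seqnum  icode  generic`` with '.' for an
    absent icode and generic in ``H.PP`` form.  Lines starting with '#' are
    comments.  Raises ValueError naming the offending row on malformed
    generic strings or duplicates.
    """
    gmap = GenericNumberMap(receptor, helix_offsets)
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0] == "chain":  # header
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chain, seqnum_s, icode, generic = parts
            icode = "" if icode == "." else icode
            try:
                seqnum = int(seqnum_s)
                gn = GenericNumber.parse(generic)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            try:
                gmap.add((chain, seqnum, icode), gn)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return gmap


def correspond(map_a: GenericNumberMap, map_b: GenericNumberMap
               ) -> tuple[list[tuple[ResidueKey, ResidueKey, GenericNumber]],
                          list[ResidueKey], list[ResidueKey]]:
    """Pair residues of two receptors via generic numbers.

    A residue of ``map_a`` with generic number (h, p) pairs with the
    ``map_b`` residue whose table entry reads (h, p + offset_b[h] − offset_a[h]):
    offsets translate each receptor's table numbering onto the shared
    canonical frame.  Returns (pairs, unpaired_a, unpaired_b); pairs are
    ordered by helix then position and carry the canonical generic number of
    ``map_a``'s entry.
    """
    pairs: list[tuple[ResidueKey, ResidueKey, GenericNumber]] = []
    matched_b: set[ResidueKey] = set()
    unpaired_a: list[ResidueKey] = []

    for key_a, gn_a in sorted(map_a.entries(), key=lambda kv: kv[1]):
        delta = map_b.helix_offsets.get(gn_a.helix, 0) - map_a.helix_offsets.get(gn_a.helix, 0)
        target_pos = gn_a.position + delta
        key_b = None
        if 1 <= target_pos <= 99:
            key_b = map_b.residue(GenericNumber(gn_a.helix, target_pos))
        if key_b is None:
            unpaired_a.append(key_a)
        else:
            pairs.append((key_a, key_b, gn_a))
            matched_b.add(key_b)

    unpaired_b = [k for k, _ in sorted(map_b.entries(), key=lambda kv: kv[1])
                  if k not in matched_b]
    if not pairs:
        logger.warning("no corresponding residues between %s and %s",
                       map_a.receptor, map_b.receptor)
    return pairs, unpaired_a, unpaired_b
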
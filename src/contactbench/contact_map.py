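"""True contact-map extraction from protein structures.

Two residues are considered in contact when their representative atoms --
the Cβ atom, or Cα for glycine -- lie strictly within a distance threshold
(8 Å by default) in the experimentally determined structure.  Contacts are
further binned by sequence separation ``s = |j - i|`` into short
(``6 <= s < 12``), medium (``12 <= s < 24``) and long (``s >= 24``) range
classes; pairs closer than 6 positions along the chain are labelled
``none`` and are not evaluated.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_THRESHOLD = 8.0

SEP_NONE = "none"
SEP_SHORT = "short"
SEP_MEDIUM = "medium"
SEP_LONG = "long"
SEP_CLASSES = (SEP_SHORT, SEP_MEDIUM, SEP_LONG)


class StructureError(ValueError):
    """Raised when a structure file cannot be mapped onto the target sequence."""


@dataclass(frozen=True)
class Residue:
    """One target-sequence position with its representative-atom coordinates.

    ``coords`` is present exactly when the representative atom was resolved
    in the structure (``observed`` is True).
    """

    position: int
    aa: str
    coords: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.coords is not None:
            c = np.asarray(self.coords, dtype=float)
            if c.shape != (3,):
                raise ValueError("coords must be a 3-vector")
            object.__setattr__(self, "coords", c)

    @property
    def observed(self) -> bool:
        return self.coords is not None


@dataclass(frozen=True)
class TargetStructure:
    """A single protein chain: the full sequence with per-residue coordinates."""

    target_id: str
    length: int
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        positions = [r.position for r in self.residues]
        if positions != sorted(set(positions)):
            raise ValueError("residues must be sorted by unique position")
        if positions and positions[-1] > self.length:
            raise ValueError("residue position exceeds target length")

    @property
    def observed_positions(self) -> frozenset[int]:
        return frozenset(r.position for r in self.residues if r.observed)


@dataclass(frozen=True)
class Contact:
    i: int
    j: int
    distance: float
    sep_class: str

    def __post_init__(self) -> None:
        if not self.i < self.j:
            raise ValueError(f"contact requires i < j, got ({self.i}, {self.j})")
        if self.sep_class != classify_separation(self.i, self.j):
            raise ValueError("sep_class inconsistent with |j - i|")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass(frozen=True)
class ContactMap:
    """The set of true contacts of one target.

    ``observed`` lists the sequence positions whose representative atom was
    resolved; ``None`` means every position 1..L counts as observed (e.g. a
    map reloaded from TSV, which stores contacts only).
    """

    target_id: str
    length: int
    contacts: frozenset[Contact]
    threshold: float = DEFAULT_CONTACT_THRESHOLD
    observed: Optional[frozenset[int]] = None

    def __post_init__(self) -> None:
        pairs = [c.pair for c in self.contacts]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (i, j) contact")
        for c in self.contacts:
            if c.distance >= self.threshold:
                raise ValueError(f"contact {c.pair} at {c.distance} Å >= threshold")
            if self.observed is not None and not (
                c.i in self.observed and c.j in self.observed
            ):
                raise ValueError(f"contact {c.pair} involves an unobserved residue")

    @property
    def pairs(self) -> frozenset[tuple[int, int]]:
        return frozenset(c.pair for c in self.contacts)

    def observed_positions(self) -> frozenset[int]:
        if self.observed is not None:
            return self.observed
        return frozenset(range(1, self.length + 1))

    def pairs_of_class(self, sep_class: str) -> frozenset[tuple[int, int]]:
        return frozenset(c.pair for c in self.contacts if c.sep_class == sep_class)


def classify_separation(i: int, j: int) -> str:
    """Separation class of a residue pair: half-open bins [6,12), [12,24), [24,inf).

    Raises ValueError for i == j (a residue has no separation from itself).
    """
    if i == j:
        raise ValueError("i and j must differ")
    s = abs(j - i)
    if s < 6:
        return SEP_NONE
    if s < 12:
        return SEP_SHORT
    if s < 24:
        return SEP_MEDIUM
    return SEP_LONG


def representative_atom(
    atom_coords: Mapping[str, np.ndarray], residue_name: str
) -> Optional[np.ndarray]:
    """Coordinates of the residue's representative atom, or None if unresolved.

    Cβ for standard residues, Cα for glycine.  A non-glycine residue whose Cβ
    is missing falls back to Cα so the residue stays evaluable.
    """
    name = residue_name.strip().upper()
    if name == "GLY":
        order = ("CA",)
    else:
        order = ("CB", "CA")
    for atom in order:
        if atom in atom_coords:
            if atom == "CA" and name != "GLY":
                logger.debug("residue %s missing CB, falling back to CA", name)
            return np.asarray(atom_coords[atom], dtype=float)
    return None


def read_fasta_sequence(text: str) -> tuple[str, str]:
    """First record of a FASTA file as (id, sequence)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def read_structure(
    structure_text: str,
    chain_id: str,
    target_sequence: str,
    target_id: str = "",
    position_map: Optional[Mapping[tuple[int, str], int]] = None,
    format: str = "pdb",
) -> TargetStructure:
    """Map one chain of a PDB (or mmCIF) file onto the target sequence.

    Structure residue numbers are taken as 1-based sequence positions unless
    an explicit ``position_map`` from (residue number, insertion code) to
    sequence position is given.  Positions absent from the structure are
    returned unobserved.  Residues with insertion codes require the map.
    """
    L = len(target_sequence)
    if L < 1:
        raise ValueError("target sequence must be non-empty")

    if format == "pdb":
        structure = gemmi.read_pdb_string(structure_text)
    elif format == "mmcif":
        doc = gemmi.cif.read_string(structure_text)
        structure = gemmi.make_structure_from_block(doc.sole_block())
    else:
        raise ValueError(f"unknown structure format: {format!r}")
    structure.setup_entities()

    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = [ch.name for ch in model]
        raise StructureError(
            f"chain {chain_id!r} not found (available: {available})"
        )

    coords_by_pos: dict[int, np.ndarray] = {}
    aa_by_pos: dict[int, str] = {}
    for res in chain:
        if res.het_flag == "H" and gemmi.find_tabulated_residue(res.name) is None:
            continue
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and not info.is_amino_acid():
            continue
        icode = res.seqid.icode.strip()
        if position_map is not None:
            key = (res.seqid.num, icode)
            if key not in position_map:
                continue
            pos = position_map[key]
        else:
            if icode:
                raise StructureError(
                    f"residue {res.name} {res.seqid.num}{icode} has an insertion "
                    "code; an explicit position map is required"
                )
            pos = res.seqid.num
        if not 1 <= pos <= L:
            raise StructureError(
                f"residue {res.name} {res.seqid.num} maps to position {pos}, "
                f"outside the target sequence 1..{L}"
            )
        one = gemmi.find_tabulated_residue(res.name)
        one_letter = one.one_letter_code.upper() if one else "X"
        seq_letter = target_sequence[pos - 1]
        if one_letter.isalpha() and one_letter != "X" and seq_letter != "X":
            if one_letter != seq_letter:
                raise StructureError(
                    f"residue {res.name} at structure position {res.seqid.num} "
                    f"maps to sequence position {pos} ({seq_letter}); numbering "
                    "appears unmappable"
                )
        if pos in coords_by_pos:
            continue  # first altloc/duplicate wins
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            if atom.name not in atoms:  # first altloc wins
                atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                )
        rep = representative_atom(atoms, res.name)
        if rep is not None:
            coords_by_pos[pos] = rep
            aa_by_pos[pos] = seq_letter

    residues = tuple(
        Residue(
            position=pos,
            aa=target_sequence[pos - 1],
            coords=coords_by_pos.get(pos),
        )
        for pos in range(1, L + 1)
    )
    return TargetStructure(target_id=target_id, length=L, residues=residues)


def build_contact_map(
    structure: TargetStructure, threshold: float = DEFAULT_CONTACT_THRESHOLD
) -> ContactMap:
    """All residue pairs (i < j, both observed) strictly closer than ``threshold`` Å."""
    observed = [r for r in structure.residues if r.observed]
    if not observed:
        raise ValueError("structure has no observed residues")
    positions = np.array([r.position for r in observed])
    coords = np.vstack([r.coords for r in observed])
    dists = squareform(pdist(coords))
    ii, jj = np.nonzero(np.triu(dists < threshold, k=1))
    contacts = frozenset(
        Contact(
            i=int(positions[a]),
            j=int(positions[b]),
            distance=float(dists[a, b]),
            sep_class=classify_separation(int(positions[a]), int(positions[b])),
        )
        for a, b in zip(ii, jj)
    )
    return ContactMap(
        target_id=structure.target_id,
        length=structure.length,
        contacts=contacts,
        threshold=threshold,
        observed=structure.observed_positions,
    )


def write_contact_tsv(cmap: ContactMap) -> str:
    """Serialize contacts as TSV: target_id, i, j, distance, sep_class."""
    rows = sorted(
        (cmap.target_id, c.i, c.j, c.distance, c.sep_class) for c in cmap.contacts
    )
    df = pd.DataFrame(rows, columns=["target_id", "i", "j", "distance", "sep_class"])
    return df.to_csv(sep="\t", index=False, float_format="%.17g")


def read_contact_tsv(
    text: str,
    length: int,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    observed: Optional[Iterable[int]] = None,
) -> ContactMap:
    """Reload a contact map written by :func:`write_contact_tsv`.

    The TSV stores contacts only, so the observed-position set must be
    supplied if it should be narrower than the full sequence.
    """
    df = pd.read_csv(io.StringIO(text), sep="\t", float_precision="round_trip")
    target_id = str(df["target_id"].iloc[0]) if len(df) else ""
    contacts = frozenset(
        Contact(
            i=int(row.i),
            j=int(row.j),
            distance=float(row.distance),
            sep_class=str(row.sep_class),
        )
        for row in df.itertuples()
    )
    obs = frozenset(observed) if observed is not None else None
    return ContactMap(
        target_id=target_id,
        length=length,
        contacts=contacts,
        threshold=threshold,
        observed=obs,
    )
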
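"""Coordinate / alignment I/O and target-template residue correspondence.

Structures are single protein chains read from PDB-format files; alignments
come as PIR or aligned-FASTA with one target entry followed by one or more
template entries. All residue and alignment-column indices are 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb
from biotite.sequence import ProteinSequence

__all__ = [
    "Atom", "Residue", "Structure", "PairwiseAlignment", "JoinedAlignment",
    "StructureError", "AlignmentError",
    "parse_structure", "write_structure", "parse_alignment",
    "residue_correspondence",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Raised for malformed or unsupported coordinate files."""


class AlignmentError(ValueError):
    """Raised for malformed alignment files or inconsistent alignments."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class Residue:
    index: int           # 1-based author residue number
    name: str            # 3-letter code
    atoms: tuple[Atom, ...]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.index} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def side_chain_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.name not in BACKBONE_ATOMS)

    @property
    def one_letter(self) -> str:
        try:
            return ProteinSequence.convert_letter_3to1(self.name)
        except KeyError:
            return "X"


@dataclass
class Structure:
    """An ordered single protein chain with named atoms in Angstrom."""

    identifier: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        indices = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise StructureError(f"{self.identifier}: residue indices must be strictly increasing")
        for r in self.residues:
            if not r.has_atom("CA"):
                raise StructureError(
                    f"{self.identifier}: residue {r.name}{r.index} is missing its CA atom"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue_by_index(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"{self.identifier}: no residue with index {index}")

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atom("CA").position for r in self.residues])

    def atom_records(self) -> list[tuple[int, str]]:
        """Flat (residue index, atom name) list in file order."""
        return [(r.index, a.name) for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        return np.array([a.position for r in self.residues for a in r.atoms])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with atom positions replaced (same order)."""
        coords = np.asarray(coords, dtype=float)
        n = sum(len(r.atoms) for r in self.residues)
        if coords.shape != (n, 3):
            raise ValueError(f"expected coords of shape ({n}, 3), got {coords.shape}")
        out: list[Residue] = []
        k = 0
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(Atom(a.name, a.element, coords[k]))
                k += 1
            out.append(Residue(r.index, r.name, tuple(atoms)))
        return Structure(self.identifier, out)


@dataclass(frozen=True)
class PairwiseAlignment:
    target_id: str
    template_id: str
    target_seq: str    # gapped
    template_seq: str  # gapped

    def __post_init__(self):
        if len(self.target_seq) != len(self.template_seq):
            raise AlignmentError(
                f"{self.target_id}/{self.template_id}: gapped rows differ in length "
                f"({len(self.target_seq)} vs {len(self.template_seq)})"
            )

    @property
    def match_columns(self) -> list[int]:
        """1-based columns where both rows are non-gap."""
        return [
            c + 1
            for c, (a, b) in enumerate(zip(self.target_seq, self.template_seq))
            if a != "-" and b != "-"
        ]


@dataclass(frozen=True)
class JoinedAlignment:
    target_id: str
    pairwise: tuple[PairwiseAlignment, ...]

    def __post_init__(self):
        if len(self.pairwise) < 1:
            raise AlignmentError("joined alignment needs at least one template")
        ungapped = {p.target_seq.replace("-", "") for p in self.pairwise}
        if len(ungapped) != 1:
            raise AlignmentError("all pairwise entries must share the same target sequence")

    @property
    def n_templates(self) -> int:
        return len(self.pairwise)

    @property
    def target_sequence(self) -> str:
        return self.pairwise[0].target_seq.replace("-", "")


def _prescan_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureError(f"line {lineno}: truncated coordinate record")
        try:
            float(line[30:38]); float(line[38:46]); float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise StructureError(f"line {lineno}: unparseable coordinate record ({exc})") from exc
        if line[26].strip():
            raise StructureError(f"line {lineno}: insertion codes are not supported")


def parse_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a single-chain PDB file into a :class:`Structure`.

    Waters and heteroatoms are dropped, altloc duplicates are resolved to the
    highest-occupancy copy, and every residue must carry a CA atom.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format: {format!r}")
    path = Path(path)
    text = path.read_text()
    _prescan_pdb_lines(text)
    pdb_file = bpdb.PDBFile.read(io.StringIO(text))
    try:
        atoms = pdb_file.get_structure(model=1, altloc="occupancy", extra_fields=["occupancy"])
    except Exception as exc:
        raise StructureError(f"{path}: {exc}") from exc
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise StructureError(f"{path}: no ATOM records found")
    chains = np.unique(atoms.chain_id)
    if len(chains) > 1:
        raise StructureError(f"{path}: multi-chain files are not supported (chains: {list(chains)})")
    residues: list[Residue] = []
    for start in bst.get_residue_starts(atoms):
        mask = (atoms.res_id == atoms.res_id[start])
        sub = atoms[mask]
        res_atoms = tuple(
            Atom(
                name=str(sub.atom_name[k]),
                element=str(sub.element[k]) or str(sub.atom_name[k])[0],
                position=sub.coord[k],
            )
            for k in range(sub.array_length())
        )
        residues.append(Residue(int(sub.res_id[0]), str(sub.res_name[0]), res_atoms))
    return Structure(path.stem, residues)


def write_structure(structure: Structure, path: str | Path, chain_id: str = "A") -> None:
    """Write a :class:`Structure` as a PDB file (coordinates to 3 decimals)."""
    lines = []
    serial = 1
    for r in structure.residues:
        for a in r.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            x, y, z = a.position
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{r.name:>3s} {chain_id}{r.index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_pir_entries(text: str) -> list[tuple[str, str]]:
    entries: list[tuple[str, str]] = []
    ident = None
    seq_lines: list[str] = []
    skip_desc = False
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith(">"):
            if ident is not None:
                entries.append((ident, "".join(seq_lines)))
            header = line[1:]
            ident = header.split(";", 1)[1].strip() if ";" in header else header.strip()
            seq_lines = []
            skip_desc = True
        elif ident is not None:
            if skip_desc:
                skip_desc = False  # PIR description line follows the header
                continue
            seq_lines.append(line)
    if ident is not None:
        entries.append((ident, "".join(seq_lines)))
    return [(i, s.rstrip("*")) for i, s in entries]


def _parse_fasta_entries(text: str) -> list[tuple[str, str]]:
    entries: list[tuple[str, str]] = []
    ident = None
    seq_lines: list[str] = []
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith(">"):
            if ident is not None:
                entries.append((ident, "".join(seq_lines)))
            ident = line[1:].split()[0]
            seq_lines = []
        elif ident is not None:
            seq_lines.append(line)
    if ident is not None:
        entries.append((ident, "".join(seq_lines)))
    return entries


def parse_alignment(path: str | Path, format: str = "pir") -> JoinedAlignment:
    """Read a joined target-templates alignment from PIR or aligned FASTA.

    The first entry is the target; every later entry is a template. All rows
    must have equal gapped length and non-duplicate identifiers.
    """
    path = Path(path)
    text = path.read_text()
    if format == "pir":
        entries = _parse_pir_entries(text)
    elif format == "afasta":
        entries = _parse_fasta_entries(text)
    else:
        raise ValueError(f"unsupported alignment format: {format!r}")
    if len(entries) < 2:
        raise AlignmentError(f"{path}: need one target and at least one template entry")
    ids = [i for i, _ in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AlignmentError(f"{path}: duplicate identifiers: {dupes}")
    lengths = {len(s) for _, s in entries}
    if len(lengths) != 1:
        raise AlignmentError(f"{path}: gapped rows have unequal lengths {sorted(lengths)}")
    for ident, seq in entries:
        if set(seq) <= {"-"}:
            raise AlignmentError(f"{path}: entry {ident!r} is all gaps")
    target_id, target_seq = entries[0]
    pairwise = tuple(
        PairwiseAlignment(target_id, tid, target_seq, tseq) for tid, tseq in entries[1:]
    )
    return JoinedAlignment(target_id, pairwise)


def residue_correspondence(
    aln: PairwiseAlignment, target: Structure, template: Structure
) -> list[tuple[int, int]]:
    """Map match columns to (target residue index, template residue index) pairs."""
    for label, gapped, struct in (
        ("target", aln.target_seq, target),
        ("template", aln.template_seq, template),
    ):
        ungapped = gapped.replace("-", "")
        seq = struct.sequence
        if ungapped != seq:
            pos = next(
                (k for k, (a, b) in enumerate(zip(ungapped, seq)) if a != b),
                min(len(ungapped), len(seq)),
            )
            raise AlignmentError(
                f"{label} alignment sequence does not match structure "
                f"{struct.identifier!r} at ungapped position {pos + 1}"
            )
    pairs: list[tuple[int, int]] = []
    ti = si = 0  # 0-based positions into the two structures
    for a, b in zip(aln.target_seq, aln.template_seq):
        if a != "-" and b != "-":
            pairs.append((target.residues[ti].index, template.residues[si].index))
        if a != "-":
            ti += 1
        if b != "-":
            si += 1
    return pairs
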
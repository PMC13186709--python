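"""Readers and writers for the formats the pipeline touches.

Sequences travel as FASTA, secondary structures as Vienna dot-bracket,
atomic coordinates as PDB/mmCIF (via gemmi) and fluorescence images as
single-channel TIFF.  Everything downstream works on the light-weight
record types defined here rather than on library-specific objects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class EmptyStructureError(ValueError):
    """Raised when a coordinate file contains no polymer atoms."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with 1-based residue numbering.

    Residue numbers follow the numbering of the source record (1-based as
    deposited), so positions quoted against a coordinate model (for example
    a ``U6``/``A39`` pair) index directly into this object via :meth:`base`.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-RNA symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, position: int) -> str:
        """Return the base at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]


def _normalize_residues(raw: str, seq_id: str) -> str:
    s = raw.upper().replace(" ", "")
    if "T" in s:
        logger.info("sequence %r: transliterating T -> U (DNA-encoded input)", seq_id)
        s = s.replace("T", "U")
    return s


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    x: float
    y: float
    z: float

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Structure3D:
    """Atomic coordinates with per-chain polymer classification.

    ``chain_types`` maps chain id to ``"RNA"``, ``"protein"`` or ``"other"``.
    Only the first model of multi-model files is kept; alternate
    conformers are reduced to the highest-occupancy one.
    """

    atoms: list[Atom]
    chain_types: dict[str, str] = field(default_factory=dict)

    def rna_chains(self) -> list[str]:
        return [c for c, t in self.chain_types.items() if t == "RNA"]

    def chain_atoms(self, chain: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain]

    def residues(self, chain: str) -> dict[int, dict[str, Atom]]:
        """Atoms of one chain grouped by residue number, keyed by atom name."""
        out: dict[int, dict[str, Atom]] = {}
        for a in self.atoms:
            if a.chain == chain:
                out.setdefault(a.resnum, {})[a.name] = a
        return out


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a (possibly multi-record) FASTA file into RNA sequences.

    DNA-encoded records are transliterated T -> U with a logged note.
    Raises :class:`ParseError` naming the offending line for files whose
    first non-blank content is not a header or whose sequences contain
    non-nucleotide symbols.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ParseError(f"{path}:{lineno}: expected FASTA header, got {line[:30]!r}")
        break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = _normalize_residues(str(rec.seq), rec.id)
        bad = set(residues) - RNA_ALPHABET
        if bad:
            lineno = _find_symbol_line(lines, bad)
            raise ParseError(
                f"{path}:{lineno}: invalid nucleotide symbol(s) {sorted(bad)} in record {rec.id!r}"
            )
        if not residues:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(RnaSequence(id=rec.id, residues=residues))
    return records


def _find_symbol_line(lines: Sequence[str], symbols: set[str]) -> int:
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(">"):
            continue
        if set(line.strip().upper().replace("T", "U")) & symbols:
            return lineno
    return 0


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_dotbracket(path: str | Path):
    """Read a Vienna dot-bracket record: optional ``>id`` line, sequence
    line, structure line.  Returns ``(RnaSequence, PairTable)``."""
    from .secstruct import build_pair_table  # deferred: secstruct imports this module

    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty dot-bracket file")
    seq_id = path.stem
    if lines[0].startswith(">"):
        seq_id = lines[0][1:].strip() or seq_id
        lines = lines[1:]
    if len(lines) < 2:
        raise ParseError(f"{path}: need a sequence line and a structure line")
    seq_line, db_line = lines[0], lines[1].split()[0]
    seq = RnaSequence(id=seq_id, residues=_normalize_residues(seq_line, seq_id))
    if len(db_line) != len(seq):
        raise ParseError(
            f"{path}: sequence length {len(seq)} != structure length {len(db_line)}"
        )
    return seq, build_pair_table(seq, db_line)


def write_dotbracket(seq: RnaSequence, dotbracket: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.id}\n{seq.residues}\n{dotbracket}\n")


# Residue-name vocabularies for chain classification.  gemmi's tabulated
# residue info covers the standard names; these sets catch common aliases.
_RNA_NAMES = frozenset({"A", "C", "G", "U", "RA", "RC", "RG", "RU", "I"})


def _classify_residue(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_nucleic_acid():
            return "RNA" if name.upper() in _RNA_NAMES or name.endswith("U") else "NA"
        if info.is_amino_acid():
            return "protein"
    if name.upper() in _RNA_NAMES:
        return "RNA"
    return "other"


def read_structure(path: str | Path) -> Structure3D:
    """Read a PDB or mmCIF coordinate file (first model only).

    Chains are classified as RNA/protein/other from their residue-name
    vocabulary; alternate conformers are reduced to the highest-occupancy
    copy of each atom.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot read structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")
    model = st[0]
    atoms: list[Atom] = []
    chain_types: dict[str, str] = {}
    for chain in model:
        kinds: dict[str, int] = {}
        for residue in chain:
            kind = _classify_residue(residue.name)
            # collapse DNA/other nucleic onto "other"; downstream geometry
            # requires ribonucleotides specifically
            kind = {"NA": "other"}.get(kind, kind)
            kinds[kind] = kinds.get(kind, 0) + 1
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                p = atom.pos
                if not all(math.isfinite(v) for v in (p.x, p.y, p.z)):
                    raise ParseError(f"{path}: non-finite coordinate in {chain.name}/{residue.seqid.num}")
                atoms.append(
                    Atom(chain.name, residue.seqid.num, residue.name.strip(), name, p.x, p.y, p.z)
                )
        if kinds:
            chain_types[chain.name] = max(kinds, key=kinds.get)
    if not atoms:
        raise EmptyStructureError(f"{path}: empty structure (no polymer atoms)")
    return Structure3D(atoms=atoms, chain_types=chain_types)


def to_gemmi(structure: Structure3D, name: str = "model") -> gemmi.Structure:
    """Convert to a gemmi Structure (used for writing PDB output)."""
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for chain_id in dict.fromkeys(a.chain for a in structure.atoms):
        chain = gemmi.Chain(chain_id)
        by_res: dict[int, list[Atom]] = {}
        for a in structure.atoms:
            if a.chain == chain_id:
                by_res.setdefault(a.resnum, []).append(a)
        for resnum in sorted(by_res):
            res = gemmi.Residue()
            res.name = by_res[resnum][0].resname
            res.seqid = gemmi.SeqId(resnum, " ")
            for a in by_res[resnum]:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.pos = gemmi.Position(a.x, a.y, a.z)
                atom.element = gemmi.Element(a.name[0])
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure3D, path: str | Path) -> None:
    to_gemmi(structure).write_pdb(str(path))


@dataclass
class IntensityImage:
    """A 2D non-negative intensity grid; row 0 is the apical-most edge."""

    pixels: np.ndarray
    pixel_size: float  # µm per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


def read_tiff(path: str | Path, pixel_size: float) -> IntensityImage:
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim > 2:
        data = np.squeeze(data)
    return IntensityImage(pixels=data, pixel_size=pixel_size)


def write_tiff(image: IntensityImage, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), image.pixels)
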
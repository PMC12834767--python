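"""Reading and writing protein structures as ordered backbone representations.

Structures are parsed with :mod:`gemmi` (PDB and mmCIF dialects) and reduced
to the three backbone atoms per residue (N, CA, C) that torsion computation
needs.  Waters and non-polymer heteroatoms are dropped; selenomethionine and
similar modified amino acids are kept because they sit in the polymer and
carry a CA atom.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "THREE_TO_ONE",
    "BackboneResidue",
    "ChainBackbone",
    "StructureModel",
    "EmptyStructureError",
    "parse_structure",
    "extract_backbone",
    "write_backbone_pdb",
]

#: Mapping from three-letter residue names to the 20 standard one-letter
#: codes.  MSE (selenomethionine) is folded into methionine; every other
#: nonstandard polymer residue becomes 'X' and is skipped at indexing time.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

BACKBONE_ATOMS = ("N", "CA", "C")


class EmptyStructureError(ValueError):
    """Raised when a file contains no polymer (amino-acid) chains."""


@dataclass
class BackboneResidue:
    """One residue reduced to its N/CA/C backbone atoms.

    Coordinates are ``None`` when the atom is absent from the deposited
    model; :attr:`complete` is True only when all three are present.
    """

    name: str                      # three-letter code as deposited
    one_letter: str                # standard code or 'X'
    seq_number: int
    insertion_code: str = " "
    n: Optional[np.ndarray] = None
    ca: Optional[np.ndarray] = None
    c: Optional[np.ndarray] = None

    @property
    def complete(self) -> bool:
        return self.n is not None and self.ca is not None and self.c is not None

    def atom(self, name: str) -> Optional[np.ndarray]:
        return {"N": self.n, "CA": self.ca, "C": self.c}[name]


@dataclass
class ChainBackbone:
    """Ordered backbone of one chain of one model."""

    entry_id: str
    model_id: int
    chain_id: str
    residues: list[BackboneResidue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """Parsed structure: the gemmi object plus entry/model bookkeeping."""

    entry_id: str
    models: list[int]
    structure: gemmi.Structure

    def __post_init__(self) -> None:
        if not self.entry_id:
            raise ValueError("entry_id must be non-empty")


def _looks_like_mmcif(text: str) -> bool:
    head = text.lstrip()[:4096]
    return head.startswith("data_") or "_atom_site." in head


def _read_text(text: str, fmt: str) -> gemmi.Structure:
    if fmt == "auto":
        fmt = "mmcif" if _looks_like_mmcif(text) else "pdb"
    if fmt == "pdb":
        return gemmi.read_pdb_string(text)
    doc = gemmi.cif.read_string(text)
    return gemmi.make_structure_from_block(doc.sole_block())


def parse_structure(
    source: str | os.PathLike,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    entry_id: Optional[str] = None,
) -> StructureModel:
    """Parse a PDB or mmCIF file (or raw text) into a :class:`StructureModel`.

    Parameters
    ----------
    source : path or str
        Path to a structure file, or the file content itself (detected by
        the presence of a newline).
    format : {"pdb", "mmcif", "auto"}
        Input dialect; ``auto`` sniffs the extension or content.
    entry_id : str, optional
        Override the accession; defaults to the structure's own name or the
        file stem.

    Raises
    ------
    EmptyStructureError
        If no amino-acid polymer chain is present.
    OSError
        If a path is given and unreadable.
    """
    src = os.fspath(source) if isinstance(source, os.PathLike) else source
    if "\n" in src:
        st = _read_text(src, format)
        default_id = (st.name or "").strip()
    else:
        if format == "auto":
            st = gemmi.read_structure(src)
        elif format == "pdb":
            st = gemmi.read_structure(src, format=gemmi.CoorFormat.Pdb)
        else:
            st = gemmi.read_structure(src, format=gemmi.CoorFormat.Mmcif)
        stem = os.path.splitext(os.path.basename(src))[0]
        default_id = (st.name or "").strip() or stem
    st.setup_entities()
    st.remove_waters()
    # PDB accessions are case-insensitive; normalise to upper case
    eid = (entry_id or default_id or "XXXX").upper()

    has_polymer = any(
        _is_backbone_residue(res)
        for model in st
        for chain in model
        for res in chain
    )
    if not has_polymer:
        raise EmptyStructureError(f"no amino-acid polymer chains in {eid!r}")
    return StructureModel(entry_id=eid, models=[m.num for m in st], structure=st)


def _is_backbone_residue(res: gemmi.Residue) -> bool:
    """Polymer amino acids only: tabulated amino acids, or HETATM entries
    that still carry a CA atom (covers MSE and exotic modified residues)."""
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_water():
        return False
    if info is not None and info.is_amino_acid():
        return True
    return res.find_atom("CA", "*") is not None and res.find_atom("N", "*") is not None


def _pick_altloc(res: gemmi.Residue, atom_name: str) -> Optional[np.ndarray]:
    """Resolve alternate locations: highest occupancy, ties to the lowest
    altloc identifier (blank sorts first)."""
    best = None
    best_key = None
    for atom in res:
        if atom.name != atom_name:
            continue
        key = (-atom.occ, atom.altloc or "")
        if best_key is None or key < best_key:
            best_key = key
            best = atom
    if best is None:
        return None
    return np.array([best.pos.x, best.pos.y, best.pos.z], dtype=float)


def extract_backbone(
    structure: StructureModel,
    model_policy: Literal["first", "all"] = "first",
    altloc_policy: Literal["highest_occupancy"] = "highest_occupancy",
) -> list[ChainBackbone]:
    """Reduce a parsed structure to per-chain ordered backbones.

    One :class:`ChainBackbone` per (selected model x chain).  Residues are
    ordered by (sequence number, insertion code); residues missing any of
    N/CA/C keep their place but are flagged incomplete via ``None``
    coordinates.
    """
    if altloc_policy != "highest_occupancy":
        raise ValueError(f"unsupported altloc policy: {altloc_policy!r}")
    st = structure.structure
    models = list(st)
    if model_policy == "first":
        models = models[:1]
    elif model_policy != "all":
        raise ValueError(f"unsupported model policy: {model_policy!r}")

    chains: list[ChainBackbone] = []
    for model in models:
        for chain in model:
            residues = []
            for res in chain:
                if not _is_backbone_residue(res):
                    continue
                residues.append(
                    BackboneResidue(
                        name=res.name,
                        one_letter=THREE_TO_ONE.get(res.name, "X"),
                        seq_number=res.seqid.num,
                        insertion_code=res.seqid.icode or " ",
                        n=_pick_altloc(res, "N"),
                        ca=_pick_altloc(res, "CA"),
                        c=_pick_altloc(res, "C"),
                    )
                )
            if not residues:
                continue
            residues.sort(key=lambda r: (r.seq_number, r.insertion_code))
            chains.append(
                ChainBackbone(
                    entry_id=structure.entry_id,
                    model_id=model.num,
                    chain_id=chain.name,
                    residues=residues,
                )
            )
    return chains


def write_backbone_pdb(
    chains: Sequence[ChainBackbone] | ChainBackbone,
    destination: str | os.PathLike,
    entry_id: Optional[str] = None,
) -> None:
    """Write backbone-only chains as a minimal fixed-width PDB file.

    Emits ATOM records (N, CA, C per residue) with occupancy 1.00, B-factor
    0.00 and element symbols, a TER per chain, and an END record.  Intended
    for fixtures and synthetic corpora, not archival deposition.
    """
    if isinstance(chains, ChainBackbone):
        chains = [chains]
    eid = (entry_id or (chains[0].entry_id if chains else "XXXX"))[:4].upper()
    lines = [f"HEADER    SYNTHETIC BACKBONE                      01-JAN-00   {eid:<4}"]
    serial = 1
    for chain in chains:
        for res in chain.residues:
            resname = res.name if res.name in THREE_TO_ONE else ONE_TO_THREE.get(res.one_letter, "UNK")
            for atom_name in BACKBONE_ATOMS:
                xyz = res.atom(atom_name)
                if xyz is None:
                    continue
                element = atom_name[0]
                # columns: serial 7-11, name 13-16 (leading space for short
                # names), altLoc 17, resName 18-20, chain 22, seq 23-26
                lines.append(
                    f"ATOM  {serial:>5}  {atom_name:<3} {resname:>3} {chain.chain_id:1}"
                    f"{res.seq_number:>4}{res.insertion_code:1}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {element:>2}"
                )
                serial += 1
        if chain.residues:
            lines.append(
                f"TER   {serial:>5}      {resname:>3} {chain.chain_id:1}{res.seq_number:>4}"
            )
            serial += 1
    lines.append("END")
    with open(destination, "w") as fh:
        fh.write("\n".join(lines) + "\n")
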
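"""Backbone torsion angles (phi, psi, omega) with chain-break awareness.

Conventions
-----------
Angles follow the IUPAC sign convention (view down the central bond,
clockwise positive) and are reported in degrees on ``(-180, 180]``;
``-180`` is normalised to ``+180`` so each torsion has one representation.

* ``phi_i``   : C'(i-1) - N(i) - CA(i) - C(i)
* ``psi_i``   : N(i) - CA(i) - C(i) - N(i+1)
* ``omega_i`` : CA(i-1) - C'(i-1) - N(i) - CA(i)

A torsion is undefined (``None``) at segment termini, across chain breaks
and wherever a needed atom is missing.  A break is declared between
consecutive residues when the peptide C-N distance exceeds a threshold
(default 2.5 A) or either atom is absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .structure_io import ChainBackbone

__all__ = [
    "DEFAULT_BREAK_THRESHOLD",
    "ResidueTorsion",
    "TorsionSegment",
    "DegenerateGeometryError",
    "dihedral_angle",
    "detect_chain_breaks",
    "compute_backbone_dihedrals",
]

#: Maximum peptide-bond C-N distance (Angstrom) treated as contiguous.
DEFAULT_BREAK_THRESHOLD = 2.5


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is requested for collinear/coincident atoms."""


@dataclass
class ResidueTorsion:
    """One residue's torsions plus provenance within the source chain."""

    one_letter: str
    phi: Optional[float]
    psi: Optional[float]
    omega: Optional[float]
    entry_id: str = ""
    model_id: int = 0
    chain_id: str = ""
    position: int = 0     # index within the owning segment


@dataclass
class TorsionSegment:
    """A contiguous (break-free) run of residues with their torsions."""

    residues: list[ResidueTorsion]
    entry_id: str = ""
    model_id: int = 0
    chain_id: str = ""
    segment_index: int = 0

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def _normalize_angle(deg: float) -> float:
    """Wrap to (-180, 180], mapping -180 to +180."""
    wrapped = ((deg + 180.0) % 360.0) - 180.0
    if wrapped == -180.0:
        return 180.0
    return wrapped


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion (degrees) of the bonded quadruple p1-p2-p3-p4.

    Uses the two-argument arctangent form, which is numerically stable
    near 0 and 180 degrees.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2_norm = np.linalg.norm(b2)
    if b2_norm == 0.0 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear or coincident atoms in torsion")
    m1 = np.cross(n1, b2 / b2_norm)
    angle = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return _normalize_angle(float(angle))


def detect_chain_breaks(
    chain: ChainBackbone,
    break_threshold: float = DEFAULT_BREAK_THRESHOLD,
) -> list[int]:
    """Indices ``i`` such that a break falls between residues i and i+1.

    A break is declared when the C(i)-N(i+1) distance exceeds
    ``break_threshold`` or either atom is missing.
    """
    if not chain.residues:
        raise ValueError("empty chain")
    boundaries = []
    for i in range(len(chain.residues) - 1):
        c_prev = chain.residues[i].c
        n_next = chain.residues[i + 1].n
        if c_prev is None or n_next is None:
            boundaries.append(i)
        elif float(np.linalg.norm(n_next - c_prev)) > break_threshold:
            boundaries.append(i)
    return boundaries


def compute_backbone_dihedrals(
    chain: ChainBackbone,
    break_threshold: float = DEFAULT_BREAK_THRESHOLD,
) -> list[TorsionSegment]:
    """Compute phi/psi/omega for a chain, split into contiguous segments.

    Residues whose own N/CA/C set is incomplete terminate the segment they
    would belong to (their torsions, and the adjacent torsions that need
    them, are undefined, so they contribute nothing and are dropped from
    segments).  Chains shorter than one complete residue yield no segments.
    """
    breaks = set(detect_chain_breaks(chain, break_threshold)) if chain.residues else set()

    # split residue indices into contiguous runs of complete residues
    runs: list[list[int]] = []
    current: list[int] = []
    for i, res in enumerate(chain.residues):
        if res.complete:
            current.append(i)
        else:
            if current:
                runs.append(current)
            current = []
            continue
        if i in breaks:
            runs.append(current)
            current = []
    if current:
        runs.append(current)

    segments: list[TorsionSegment] = []
    for seg_idx, run in enumerate(runs):
        torsions: list[ResidueTorsion] = []
        for pos, i in enumerate(run):
            res = chain.residues[i]
            prev_res = chain.residues[run[pos - 1]] if pos > 0 else None
            next_res = chain.residues[run[pos + 1]] if pos + 1 < len(run) else None
            phi = psi = omega = None
            if prev_res is not None:
                phi = dihedral_angle(prev_res.c, res.n, res.ca, res.c)
                omega = dihedral_angle(prev_res.ca, prev_res.c, res.n, res.ca)
            if next_res is not None:
                psi = dihedral_angle(res.n, res.ca, res.c, next_res.n)
            torsions.append(
                ResidueTorsion(
                    one_letter=res.one_letter,
                    phi=phi,
                    psi=psi,
                    omega=omega,
                    entry_id=chain.entry_id,
                    model_id=chain.model_id,
                    chain_id=chain.chain_id,
                    position=pos,
                )
            )
        segments.append(
            TorsionSegment(
                residues=torsions,
                entry_id=chain.entry_id,
                model_id=chain.model_id,
                chain_id=chain.chain_id,
                segment_index=seg_idx,
            )
        )
    return segments
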
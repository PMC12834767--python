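"""Synthetic corpora with known ground truth.

Three generators make the rest of the package testable without any
downloads:

* i.i.d. residue sequences at specified marginal frequencies (the null
  model under which the departure-from-independence statistic is exactly 1
  in expectation), optionally with planted k-mer occurrences;
* circular-mixture (independent von Mises) dihedral samples over canonical
  Ramachandran basins, including glycine and proline presets;
* 3-D backbone coordinates realising specified torsions by sequential
  internal-coordinate (NeRF) placement, so dihedral extraction can be
  round-trip tested against exact ground truth.

Generated corpora are written as minimal PDB files plus a JSON manifest
recording every sequence, torsion and planted occurrence.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .dihedral import ResidueTorsion, TorsionSegment, compute_backbone_dihedrals
from .structure_io import BackboneResidue, ChainBackbone, ONE_TO_THREE, write_backbone_pdb
from .torus_cluster import MixtureComponent, MixtureSpec, wrap_degrees
from .kmer_stats import AMINO_ACIDS

__all__ = [
    "CorpusSpec",
    "IdealGeometry",
    "CorpusManifest",
    "uniform_frequencies",
    "pdb_like_frequencies",
    "default_backbone_mixture",
    "glycine_preset",
    "proline_preset",
    "sample_sequences",
    "sample_dihedral_mixture",
    "build_backbone_coordinates",
    "make_segments",
    "generate_corpus",
]


def uniform_frequencies() -> dict[str, float]:
    return {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}


def pdb_like_frequencies() -> dict[str, float]:
    """Realistic amino-acid marginals (rounded literature composition:
    leucine/alanine most common, tryptophan/cysteine rarest)."""
    freqs = {
        "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
        "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
        "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
        "S": 0.0656, "T": 0.0534, "W": 0.0108, "V": 0.0687, "Y": 0.0292,
    }
    total = sum(freqs.values())
    return {aa: f / total for aa, f in freqs.items()}


@dataclass
class IdealGeometry:
    """Backbone bond lengths (A) and angles (degrees) used by the builder.

    Engh–Huber-like standard values; only self-consistency matters for
    round-trip tests.
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    angle_c_n_ca: float = 121.7
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    omega: float = 180.0

    def __post_init__(self) -> None:
        for name in ("n_ca", "ca_c", "c_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"bond length {name} must be positive")
        for name in ("angle_c_n_ca", "angle_n_ca_c", "angle_ca_c_n"):
            a = getattr(self, name)
            if not 0.0 < a < 180.0:
                raise ValueError(f"bond angle {name} must be in (0, 180)")


@dataclass
class CorpusSpec:
    """Everything needed to generate a reproducible synthetic corpus."""

    n_chains: int = 10
    chain_length: int | tuple[int, int] = 100
    frequencies: Mapping[str, float] = field(default_factory=uniform_frequencies)
    mixture: Optional[MixtureSpec] = None          # 2-D (phi, psi) mixture
    enrichments: list[tuple[str, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        vec = np.array([self.frequencies.get(aa, 0.0) for aa in AMINO_ACIDS])
        if np.any(vec < 0):
            raise ValueError("residue frequencies must be non-negative")
        if abs(vec.sum() - 1.0) > 1e-12:
            raise ValueError("residue frequencies must sum to 1")


@dataclass
class CorpusManifest:
    """Ground truth for a generated corpus."""

    seed: int
    sequences: dict[str, str]                       # entry_id -> sequence
    torsions: dict[str, list[list[Optional[float]]]]  # entry_id -> [[phi,psi,omega],...]
    planted: list[dict]                             # {kmer, entry_id, start}
    files: dict[str, str] = field(default_factory=dict)  # entry_id -> path
    geometry: Optional[IdealGeometry] = None


def default_backbone_mixture() -> MixtureSpec:
    """Generic backbone basins: alpha-helical, beta-strand and
    left-handed-helical regions with typical occupancies."""
    return MixtureSpec(
        components=[
            MixtureComponent(center=np.array([-63.0, -43.0]), kappa=30.0, weight=0.45),
            MixtureComponent(center=np.array([-120.0, 130.0]), kappa=30.0, weight=0.40),
            MixtureComponent(center=np.array([60.0, 45.0]), kappa=30.0, weight=0.15),
        ]
    )


def glycine_preset() -> MixtureSpec:
    """Five-basin glycine mixture.

    Glycine's lack of a side chain opens five density regions of the
    Ramachandran map; the centers below are the canonical alpha-helical
    basin and its mirror, the two extended/polyproline-like regions, and
    the wrapped corner region, placed so all pairs are well separated on
    the torus.
    """
    centers = [(-90.0, 170.0), (90.0, -170.0), (-60.0, -40.0), (60.0, 40.0), (180.0, 180.0)]
    return MixtureSpec(
        components=[
            MixtureComponent(center=np.array(c), kappa=20.0, weight=0.2) for c in centers
        ]
    )


def proline_preset() -> MixtureSpec:
    """Proline: phi pinned near −65° by the pyrrolidine ring, psi split
    between extended (~150°) and alpha-like (~−30°) values."""
    return MixtureSpec(
        components=[
            MixtureComponent(center=np.array([-65.0, 150.0]), kappa=30.0, weight=0.6),
            MixtureComponent(center=np.array([-65.0, -30.0]), kappa=30.0, weight=0.4),
        ]
    )


def _chain_lengths(spec: CorpusSpec, rng: np.random.Generator) -> list[int]:
    if isinstance(spec.chain_length, int):
        return [spec.chain_length] * spec.n_chains
    lo, hi = spec.chain_length
    return [int(x) for x in rng.integers(lo, hi + 1, size=spec.n_chains)]


def sample_sequences(spec: CorpusSpec) -> tuple[list[str], list[dict]]:
    """Draw i.i.d. sequences at the spec's marginals and plant enrichments.

    Each enrichment ``(kmer, count)`` overwrites ``count`` non-overlapping
    stretches at random positions across the corpus; planted occurrences
    are returned as ``{kmer, chain, start}`` records.  Fully reproducible
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.array([spec.frequencies.get(aa, 0.0) for aa in AMINO_ACIDS])
    lengths = _chain_lengths(spec, rng)
    alphabet = np.array(list(AMINO_ACIDS))
    seqs = [
        "".join(alphabet[rng.choice(20, size=n, p=freqs)]) for n in lengths
    ]
    planted: list[dict] = []
    occupied: dict[int, set[int]] = {}
    for kmer, count in spec.enrichments:
        k = len(kmer)
        for _ in range(count):
            for _attempt in range(1000):
                ci = int(rng.integers(0, len(seqs)))
                if len(seqs[ci]) < k:
                    continue
                start = int(rng.integers(0, len(seqs[ci]) - k + 1))
                span = set(range(start, start + k))
                if span & occupied.get(ci, set()):
                    continue
                seqs[ci] = seqs[ci][:start] + kmer + seqs[ci][start + k:]
                occupied.setdefault(ci, set()).update(span)
                planted.append({"kmer": kmer, "chain": ci, "start": start})
                break
            else:
                raise RuntimeError(f"could not place planted k-mer {kmer!r}")
    return seqs, planted


def sample_dihedral_mixture(
    spec: MixtureSpec,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n angle tuples: pick a component by weight, then each
    coordinate from an independent von Mises around the component center,
    wrapped to (−180, 180]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = np.array([c.weight for c in spec.components])
    dim = spec.dim
    comp_idx = rng.choice(len(spec.components), size=n, p=weights)
    out = np.empty((n, dim))
    for i, ci in enumerate(comp_idx):
        comp = spec.components[ci]
        center = np.radians(np.atleast_1d(comp.center))
        draws = rng.vonmises(center, comp.kappa, size=dim)
        out[i] = np.degrees(draws)
    return wrap_degrees(out)


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    length: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """NeRF placement: position atom d bonded to c, with bond angle b-c-d
    and torsion a-b-c-d."""
    angle = np.radians(angle_deg)
    # the local frame below is left-handed w.r.t. the IUPAC sign convention,
    # so the torsion enters negated
    torsion = -np.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = np.array(
        [
            -length * np.cos(angle),
            length * np.sin(angle) * np.cos(torsion),
            length * np.sin(angle) * np.sin(torsion),
        ]
    )
    rot = np.column_stack([bc_hat, m_hat, n_hat])
    return c + rot @ d_local


def build_backbone_coordinates(
    sequence: str,
    torsions: Sequence[Sequence[Optional[float]]],
    geometry: Optional[IdealGeometry] = None,
    entry_id: str = "SYN0",
    chain_id: str = "A",
    model_id: int = 1,
) -> ChainBackbone:
    """Realise a torsion list as 3-D backbone coordinates (N, CA, C per
    residue) with ideal covalent geometry.

    ``torsions[i]`` is ``(phi_i, psi_i)`` or ``(phi_i, psi_i, omega_i)``;
    ``phi_0`` and the last residue's psi may be None (they are not needed
    to place any atom).  Re-extracting dihedrals from the result recovers
    the requested angles to within 1e-6 degrees.
    """
    geom = geometry or IdealGeometry()
    n_res = len(sequence)
    if len(torsions) != n_res:
        raise ValueError(
            f"torsion list length {len(torsions)} != sequence length {n_res}"
        )

    def tors(i: int) -> tuple[Optional[float], Optional[float], float]:
        row = torsions[i]
        phi = row[0]
        psi = row[1]
        omega = row[2] if len(row) > 2 and row[2] is not None else geom.omega
        return phi, psi, omega

    coords: list[dict[str, np.ndarray]] = []
    # residue 0: fixed initial frame
    n0 = np.zeros(3)
    ca0 = np.array([geom.n_ca, 0.0, 0.0])
    ang = np.radians(geom.angle_n_ca_c)
    c0 = ca0 + geom.ca_c * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[-1]
        phi_prev, psi_prev, _ = tors(i - 1)
        phi_i, psi_i, omega_i = tors(i)
        if psi_prev is None:
            raise ValueError(f"interior psi undefined at residue {i - 1}")
        if phi_i is None:
            raise ValueError(f"interior phi undefined at residue {i}")
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"],
                          geom.c_n, geom.angle_ca_c_n, psi_prev)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i,
                           geom.n_ca, geom.angle_c_n_ca, omega_i)
        c_i = _place_atom(prev["C"], n_i, ca_i,
                          geom.ca_c, geom.angle_n_ca_c, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})

    residues = [
        BackboneResidue(
            name=ONE_TO_THREE.get(aa, "UNK"),
            one_letter=aa,
            seq_number=i + 1,
            n=coords[i]["N"],
            ca=coords[i]["CA"],
            c=coords[i]["C"],
        )
        for i, aa in enumerate(sequence)
    ]
    return ChainBackbone(
        entry_id=entry_id, model_id=model_id, chain_id=chain_id, residues=residues
    )


def _sample_torsions(
    sequence: str,
    mixture: MixtureSpec,
    rng: np.random.Generator,
) -> list[list[Optional[float]]]:
    pairs = sample_dihedral_mixture(mixture, len(sequence), rng)
    rows: list[list[Optional[float]]] = []
    for i in range(len(sequence)):
        phi = None if i == 0 else float(pairs[i, 0])
        psi = None if i == len(sequence) - 1 else float(pairs[i, 1])
        omega = None if i == 0 else 180.0
        rows.append([phi, psi, omega])
    return rows


def make_segments(
    sequences: Iterable[str],
    mixture: Optional[MixtureSpec] = None,
    seed: int = 0,
    entry_prefix: str = "S",
) -> list[TorsionSegment]:
    """In-memory torsion segments for sequences (no file round trip).

    Torsions are drawn from ``mixture`` (default: the generic three-basin
    backbone mixture); useful when only sequence statistics or clustering
    inputs are needed.
    """
    mix = mixture or default_backbone_mixture()
    rng = np.random.default_rng(seed)
    segments = []
    for idx, seq in enumerate(sequences):
        rows = _sample_torsions(seq, mix, rng)
        residues = [
            ResidueTorsion(
                one_letter=aa, phi=rows[i][0], psi=rows[i][1], omega=rows[i][2],
                entry_id=f"{entry_prefix}{idx:04d}", model_id=1, chain_id="A",
                position=i,
            )
            for i, aa in enumerate(seq)
        ]
        segments.append(
            TorsionSegment(
                residues=residues, entry_id=f"{entry_prefix}{idx:04d}",
                model_id=1, chain_id="A", segment_index=0,
            )
        )
    return segments


def generate_corpus(
    spec: CorpusSpec,
    directory: str | os.PathLike,
    geometry: Optional[IdealGeometry] = None,
) -> CorpusManifest:
    """Write a full synthetic corpus as minimal PDB files plus a manifest.

    Sequences are sampled per the spec, torsions per its mixture (default
    three-basin backbone mixture), coordinates realised with the NeRF
    builder and written one chain per file.  The manifest records every
    sequence, every torsion and every planted k-mer occurrence, and the
    whole corpus is byte-reproducible from ``spec.seed``.
    """
    os.makedirs(directory, exist_ok=True)
    geom = geometry or IdealGeometry()
    mix = spec.mixture or default_backbone_mixture()
    seqs, planted = sample_sequences(spec)
    rng = np.random.default_rng(spec.seed + 1)
    manifest = CorpusManifest(
        seed=spec.seed, sequences={}, torsions={}, planted=[], geometry=geom
    )
    for idx, seq in enumerate(seqs):
        entry_id = f"Z{idx:03d}"
        rows = _sample_torsions(seq, mix, rng)
        chain = build_backbone_coordinates(seq, rows, geom, entry_id=entry_id)
        path = os.path.join(directory, f"{entry_id.lower()}.pdb")
        write_backbone_pdb(chain, path, entry_id=entry_id)
        manifest.sequences[entry_id] = seq
        manifest.torsions[entry_id] = rows
        manifest.files[entry_id] = path
    for rec in planted:
        manifest.planted.append(
            {"kmer": rec["kmer"], "entry_id": f"Z{rec['chain']:03d}", "start": rec["start"]}
        )
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(
            {
                "seed": spec.seed,
                "sequences": manifest.sequences,
                "torsions": manifest.torsions,
                "planted": manifest.planted,
                "files": {k: os.path.basename(v) for k, v in manifest.files.items()},
                "geometry": {
                    "n_ca": geom.n_ca, "ca_c": geom.ca_c, "c_n": geom.c_n,
                    "angle_c_n_ca": geom.angle_c_n_ca,
                    "angle_n_ca_c": geom.angle_n_ca_c,
                    "angle_ca_c_n": geom.angle_ca_c_n,
                    "omega": geom.omega,
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return manifest
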
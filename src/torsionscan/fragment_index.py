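"""k-mer fragment indexing and window-based querying.

The index maps every contiguous k-length amino-acid subsequence (k-mer) of
a torsion-annotated corpus to its occurrences, so that a query sequence can
be answered either as one exact fragment (window size equal to the query
length) or as a sliding scan of ``N - W + 1`` overlapping windows shifted by
one residue.  Each match carries the k (phi, psi) dihedral pairs of the
matched residues, which is what makes the index useful: the same k-mer seen
in different structural contexts exposes the spread of backbone
conformations compatible with that sequence.

Windows containing 'X' (unknown residues) or spanning a chain break are
never indexed and never matched; torsions across breaks are undefined.
Coordinates are 0-based half-open internally; the CSV export reports
1-based starts.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .dihedral import TorsionSegment, ResidueTorsion
from .structure_io import THREE_TO_ONE

__all__ = [
    "OccurrenceRef",
    "FragmentMatch",
    "QuerySpec",
    "FragmentIndex",
    "WindowError",
    "UnsupportedKError",
    "UnknownResidueCodeError",
    "parse_sequence",
    "make_windows",
    "build_index",
    "query_exact",
    "query_scan",
    "aggregate_residue",
    "export_matches_csv",
    "read_matches_csv",
    "save_index",
    "load_index",
]

INDEX_FORMAT_VERSION = 1


class WindowError(ValueError):
    """Window size incompatible with the query sequence."""


class UnsupportedKError(ValueError):
    """Requested k-mer length is not indexed."""


class UnknownResidueCodeError(ValueError):
    """A residue token could not be translated to a one-letter code."""


@dataclass(frozen=True)
class OccurrenceRef:
    """Location of one k-mer occurrence inside a torsion segment."""

    entry_id: str
    model_id: int
    chain_id: str
    segment_index: int
    start: int
    k: int


@dataclass
class FragmentMatch:
    """One occurrence of a queried k-mer with its k (phi, psi) pairs."""

    kmer: str
    ref: OccurrenceRef
    angles: list[tuple[Optional[float], Optional[float]]]
    omegas: list[Optional[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.angles) != len(self.kmer):
            raise ValueError("angles length must equal k-mer length")


@dataclass
class QuerySpec:
    """A full-sequence query: sequence of length N, window size W, and the
    set of entry ids to exclude (self-exclusion avoids circularity when the
    query comes from a structure that is itself in the corpus)."""

    sequence: str
    window: int
    exclude: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.sequence = parse_sequence(self.sequence)
        if self.window < 1:
            raise WindowError("window size must be >= 1")
        if self.window > len(self.sequence):
            raise WindowError(
                f"window exceeds sequence: W={self.window} > N={len(self.sequence)}"
            )


def parse_sequence(text: str) -> str:
    """Normalise a query sequence to contiguous upper-case one-letter codes.

    Accepts contiguous or whitespace-separated one-letter input
    (``"EYV"``, ``"E Y V"``) and whitespace-separated three-letter tokens
    (``"Glu Tyr Val"``), case-insensitively.  Mixed-length tokens are
    resolved per token.
    """
    tokens = text.split()
    if not tokens:
        raise UnknownResidueCodeError("empty sequence")
    if len(tokens) == 1 and len(tokens[0]) > 3:
        tokens = list(tokens[0])
    elif all(len(t) == 1 for t in tokens):
        pass
    else:
        # possibly three-letter tokens, or a single short one-letter run
        if len(tokens) == 1 and tokens[0].upper() not in THREE_TO_ONE:
            tokens = list(tokens[0])
    out = []
    for tok in tokens:
        t = tok.upper()
        if len(t) == 1:
            if t not in set("ACDEFGHIKLMNPQRSTVWY") | {"X"}:
                raise UnknownResidueCodeError(f"unknown one-letter code: {tok!r}")
            out.append(t)
        elif len(t) == 3:
            if t not in THREE_TO_ONE:
                raise UnknownResidueCodeError(f"unknown three-letter code: {tok!r}")
            out.append(THREE_TO_ONE[t])
        else:
            raise UnknownResidueCodeError(f"unrecognised residue token: {tok!r}")
    return "".join(out)


def make_windows(sequence: str, window: int) -> list[str]:
    """The N - W + 1 overlapping windows of a length-N sequence."""
    n = len(sequence)
    if window < 1:
        raise WindowError("window size must be >= 1")
    if window > n:
        raise WindowError(f"window exceeds sequence: W={window} > N={n}")
    return [sequence[j : j + window] for j in range(n - window + 1)]


@dataclass
class FragmentIndex:
    """Map from k-mer string to occurrences, for each supported k.

    ``segments`` keeps the torsion-annotated corpus so that matches can be
    resolved back to their dihedral pairs.  ``residue_total`` is the number
    of indexed residues (the k=1 window count M).
    """

    k_range: frozenset[int]
    postings: dict[int, dict[str, list[OccurrenceRef]]]
    segments: dict[tuple[str, int, str, int], TorsionSegment]
    manifest: dict = field(default_factory=dict)

    @property
    def residue_total(self) -> int:
        return sum(len(seg) for seg in self.segments.values())

    def window_total(self, k: int) -> int:
        """Number of valid (indexed) k-windows in the corpus."""
        if k not in self.k_range:
            raise UnsupportedKError(f"k={k} not indexed; supported: {sorted(self.k_range)}")
        return sum(len(refs) for refs in self.postings[k].values())


def build_index(
    segments: Iterable[TorsionSegment],
    k_range: Iterable[int],
) -> FragmentIndex:
    """Index every k-length subsequence of every segment, for each k.

    Subsequences containing 'X' are skipped; chain breaks are implicit
    because indexing never crosses a segment boundary.  Iteration order is
    deterministic: (entry, model, chain, segment, position).
    """
    ks = frozenset(int(k) for k in k_range)
    if not ks or min(ks) < 1:
        raise ValueError("k_range must contain positive integers")
    seg_list = sorted(
        segments,
        key=lambda s: (s.entry_id, s.model_id, s.chain_id, s.segment_index),
    )
    seg_map: dict[tuple[str, int, str, int], TorsionSegment] = {}
    postings: dict[int, dict[str, list[OccurrenceRef]]] = {k: {} for k in sorted(ks)}
    entries: set[str] = set()
    for seg in seg_list:
        key = (seg.entry_id, seg.model_id, seg.chain_id, seg.segment_index)
        if key in seg_map:
            raise ValueError(f"duplicate segment key: {key}")
        seg_map[key] = seg
        entries.add(seg.entry_id)
        seq = seg.sequence
        for k in sorted(ks):
            for start in range(0, len(seq) - k + 1):
                kmer = seq[start : start + k]
                if "X" in kmer:
                    continue
                ref = OccurrenceRef(
                    entry_id=seg.entry_id,
                    model_id=seg.model_id,
                    chain_id=seg.chain_id,
                    segment_index=seg.segment_index,
                    start=start,
                    k=k,
                )
                postings[k].setdefault(kmer, []).append(ref)
    manifest = {
        "format_version": INDEX_FORMAT_VERSION,
        "entries": sorted(entries),
        "k_range": sorted(ks),
        "residue_total": sum(len(s) for s in seg_map.values()),
        "note": "occurrence counts are redundancy-inflated: identical deposited sequences are not deduplicated",
    }
    return FragmentIndex(k_range=ks, postings=postings, segments=seg_map, manifest=manifest)


def _resolve_match(index: FragmentIndex, kmer: str, ref: OccurrenceRef) -> FragmentMatch:
    seg = index.segments[(ref.entry_id, ref.model_id, ref.chain_id, ref.segment_index)]
    residues = seg.residues[ref.start : ref.start + ref.k]
    return FragmentMatch(
        kmer=kmer,
        ref=ref,
        angles=[(r.phi, r.psi) for r in residues],
        omegas=[r.omega for r in residues],
    )


def query_exact(
    index: FragmentIndex,
    kmer: str,
    exclude: Iterable[str] = (),
) -> list[FragmentMatch]:
    """All occurrences of ``kmer`` in the corpus (Method-2 query: one window
    of size W = N), minus occurrences in excluded entries."""
    kmer = parse_sequence(kmer)
    k = len(kmer)
    if k not in index.k_range:
        raise UnsupportedKError(f"k={k} not indexed; supported: {sorted(index.k_range)}")
    excluded = frozenset(exclude)
    refs = index.postings[k].get(kmer, [])
    return [_resolve_match(index, kmer, r) for r in refs if r.entry_id not in excluded]


def query_scan(index: FragmentIndex, query: QuerySpec) -> list[list[FragmentMatch]]:
    """Method-1 query: N - W + 1 shifted windows, each answered exactly.

    Windows containing 'X' return an empty match list (they are never
    indexed).
    """
    results = []
    for window in make_windows(query.sequence, query.window):
        if "X" in window:
            results.append([])
        else:
            results.append(query_exact(index, window, query.exclude))
    return results


def window_membership(i: int, n: int, w: int) -> int:
    """Number of windows containing position i: the first and last W-1
    positions of the query appear in 1..W-1 windows, interior positions in
    exactly W (capped by the total window count N - W + 1)."""
    return min(i + 1, w, n - i, n - w + 1)


def aggregate_residue(
    scan_result: Sequence[Sequence[FragmentMatch]],
    query: QuerySpec,
    position: int,
) -> list[tuple[Optional[float], Optional[float]]]:
    """Pool (phi, psi) pairs for one query residue across all windows that
    contain it, over every match of each window."""
    n = len(query.sequence)
    w = query.window
    if not 0 <= position < n:
        raise ValueError(f"position {position} outside sequence of length {n}")
    first_window = max(0, position - w + 1)
    last_window = min(position, n - w)
    pooled: list[tuple[Optional[float], Optional[float]]] = []
    for j in range(first_window, last_window + 1):
        offset = position - j
        for match in scan_result[j]:
            pooled.append(match.angles[offset])
    return pooled


CSV_COLUMNS = [
    "query_window", "kmer", "entry_id", "model", "chain",
    "start", "offset", "residue", "phi", "psi", "omega",
]


def _fmt_angle(a: Optional[float]) -> str:
    return "" if a is None else f"{a:.4f}"


def export_matches_csv(
    matches: Sequence[FragmentMatch] | Sequence[Sequence[FragmentMatch]],
    destination: str | os.PathLike,
) -> int:
    """Write matches (flat list, or per-window lists from a scan) as CSV.

    One row per (match, residue offset); ``start`` is 1-based for human
    consumption; undefined angles serialise as empty fields.  Returns the
    number of data rows written.
    """
    if matches and isinstance(matches[0], FragmentMatch):
        per_window: list[Sequence[FragmentMatch]] = [matches]  # type: ignore[list-item]
    else:
        per_window = list(matches)  # type: ignore[arg-type]
    rows = 0
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for win_idx, win_matches in enumerate(per_window):
            for match in win_matches:
                for offset, residue in enumerate(match.kmer):
                    phi, psi = match.angles[offset]
                    omega = match.omegas[offset] if match.omegas else None
                    writer.writerow([
                        win_idx, match.kmer, match.ref.entry_id, match.ref.model_id,
                        match.ref.chain_id, match.ref.start + 1, offset, residue,
                        _fmt_angle(phi), _fmt_angle(psi), _fmt_angle(omega),
                    ])
                    rows += 1
    return rows


def read_matches_csv(path: str | os.PathLike) -> list[list[FragmentMatch]]:
    """Parse a CSV written by :func:`export_matches_csv` back into
    per-window match lists (round-trip support)."""
    per_window: dict[int, dict[tuple, FragmentMatch]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            win = int(row["query_window"])
            key = (row["kmer"], row["entry_id"], int(row["model"]), row["chain"], int(row["start"]))
            matches = per_window.setdefault(win, {})
            if key not in matches:
                k = len(row["kmer"])
                ref = OccurrenceRef(
                    entry_id=row["entry_id"], model_id=int(row["model"]),
                    chain_id=row["chain"], segment_index=0,
                    start=int(row["start"]) - 1, k=k,
                )
                matches[key] = FragmentMatch(
                    kmer=row["kmer"], ref=ref,
                    angles=[(None, None)] * k, omegas=[None] * k,
                )
            m = matches[key]
            off = int(row["offset"])
            phi = float(row["phi"]) if row["phi"] else None
            psi = float(row["psi"]) if row["psi"] else None
            omega = float(row["omega"]) if row["omega"] else None
            m.angles[off] = (phi, psi)
            m.omegas[off] = omega
    return [list(per_window[w].values()) for w in sorted(per_window)]


def save_index(index: FragmentIndex, directory: str | os.PathLike) -> None:
    """Persist an index as a JSON manifest plus text tables.

    ``segments.json`` stores sequences and torsions; ``postings.tsv`` stores
    one sorted line per occurrence.  Deterministic output for a given index.
    """
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(index.manifest, fh, indent=1, sort_keys=True)
    seg_obj = {}
    for (eid, mid, cid, sidx), seg in sorted(index.segments.items()):
        seg_obj["\t".join([eid, str(mid), cid, str(sidx)])] = {
            "sequence": seg.sequence,
            "phi": [r.phi for r in seg.residues],
            "psi": [r.psi for r in seg.residues],
            "omega": [r.omega for r in seg.residues],
        }
    with open(os.path.join(directory, "segments.json"), "w") as fh:
        json.dump(seg_obj, fh)
    with open(os.path.join(directory, "postings.tsv"), "w") as fh:
        for k in sorted(index.k_range):
            for kmer in sorted(index.postings[k]):
                for ref in index.postings[k][kmer]:
                    fh.write(
                        f"{k}\t{kmer}\t{ref.entry_id}\t{ref.model_id}\t"
                        f"{ref.chain_id}\t{ref.segment_index}\t{ref.start}\n"
                    )


def load_index(directory: str | os.PathLike) -> FragmentIndex:
    """Load an index previously written by :func:`save_index`."""
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index format: {manifest.get('format_version')}")
    with open(os.path.join(directory, "segments.json")) as fh:
        seg_obj = json.load(fh)
    segments: dict[tuple[str, int, str, int], TorsionSegment] = {}
    for key, data in seg_obj.items():
        eid, mid, cid, sidx = key.split("\t")
        residues = [
            ResidueTorsion(
                one_letter=aa, phi=phi, psi=psi, omega=omega,
                entry_id=eid, model_id=int(mid), chain_id=cid, position=pos,
            )
            for pos, (aa, phi, psi, omega) in enumerate(
                zip(data["sequence"], data["phi"], data["psi"], data["omega"])
            )
        ]
        segments[(eid, int(mid), cid, int(sidx))] = TorsionSegment(
            residues=residues, entry_id=eid, model_id=int(mid),
            chain_id=cid, segment_index=int(sidx),
        )
    ks = frozenset(manifest["k_range"])
    postings: dict[int, dict[str, list[OccurrenceRef]]] = {k: {} for k in sorted(ks)}
    with open(os.path.join(directory, "postings.tsv")) as fh:
        for line in fh:
            k_s, kmer, eid, mid, cid, sidx, start = line.rstrip("\n").split("\t")
            ref = OccurrenceRef(
                entry_id=eid, model_id=int(mid), chain_id=cid,
                segment_index=int(sidx), start=int(start), k=int(k_s),
            )
            postings[int(k_s)].setdefault(kmer, []).append(ref)
    return FragmentIndex(k_range=ks, postings=postings, segments=segments, manifest=manifest)
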
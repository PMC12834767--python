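# Methods

This note records the models, conventions and numerical choices behind
`torsionscan`, and what the synthetic-data tests do and do not establish
about behaviour on real structures.

## Backbone extraction

Structures are parsed with gemmi (PDB and mmCIF). Only amino-acid polymer
residues are kept: tabulated amino acids, plus HETATM residues that carry
both N and CA atoms (this admits selenomethionine and similar modified
residues while dropping waters and ligands). MSE maps to `M`; every other
nonstandard residue maps to `X`, which is excluded at indexing time rather
than at geometry time. Alternate locations are resolved per atom to the
highest occupancy, ties broken by the lowest altloc identifier. Residues
are ordered by (sequence number, insertion code); negative sequence numbers
are allowed. By default only the first model of a multi-model (NMR) entry
is extracted — an ensemble would otherwise contribute one torsion set per
conformer and inflate occurrence counts; `model_policy="all"` opts in to
per-model counting.

## Torsion geometry

Torsions use the IUPAC sign convention and the two-argument arctangent
form, which is stable near 0°/180°. Angles live in (−180°, 180]; −180° is
normalised to +180° so each torsion has a unique representation.
φᵢ = (C′ᵢ₋₁, Nᵢ, CAᵢ, Cᵢ), ψᵢ = (Nᵢ, CAᵢ, Cᵢ, Nᵢ₊₁),
ωᵢ = (CAᵢ₋₁, C′ᵢ₋₁, Nᵢ, CAᵢ). ω is computed and stored but not used by the
downstream statistics, which operate on (φ, ψ) only.

A chain break is declared between residues i and i+1 when the peptide
C–N distance exceeds 2.5 Å (a conventional geometric cutoff for a broken
peptide bond) or when either atom is missing. Chains are split into
contiguous segments at breaks and at residues with incomplete N/CA/C sets;
torsions never span a segment boundary, and the first residue of a segment
has undefined φ and ω, the last undefined ψ.

## Fragment index and queries

The index maps, for each supported k, every k-length subsequence of every
segment to its occurrence list. Windows containing `X` or spanning a break
are never indexed and never matched. Coordinates are 0-based half-open
internally; CSV exports report 1-based starts. Two query styles are
supported: a sliding scan (N − W + 1 windows shifted by one residue, each
answered exactly) and a single exact fragment lookup (W = N). Entry-level
exclusion sets support the self-exclusion control needed when the query
sequence comes from a structure that is itself indexed. Per-residue
aggregation pools the angle pair at the correct offset from every match of
every window containing the residue; position i contributes
min(i+1, W, N−i, N−W+1) windows.

Occurrence counts are deliberately redundancy-inflated: identical deposited
sequences are not deduplicated (the index manifest carries a note to this
effect). Deduplication policy varies across resources and any choice here
would be invisible to downstream formulas, so the raw convention was kept.

## Abundance statistics

For k-mer probabilities the denominator is the number of valid k-windows in
the corpus; for k = 1 this coincides with the residue total M. Monomer
probabilities entering P_joint are computed from the same corpus as the
k-mer counts, so d is a purely internal consistency measure. Absent k-mers
have d = 0 by convention; a k-mer observed despite a zero joint probability
is flagged (NaN) rather than fatal in batch mode. The observed-vs-joint
regression is unweighted OLS on raw probabilities (not logs), over all
enumerated k-mers including zero counts by default (`include_zero_counts=False`
restricts to observed k-mers). Outlier flagging defaults to d ≥ 2 or
d ≤ 0.5. Exhaustive enumeration is capped at k ≤ 6 (20⁶ ≈ 6.4 × 10⁷ strings)
to guard against accidental combinatorial blowup.

A useful exact identity used in the tests: weighting d by P_joint over all
k-mers gives Σ P_obs / Σ P_joint, which equals 1 whenever the enumeration
covers all k-mers (Σ P_joint = (Σ monomer P_obs)^k = 1).

## Torus clustering

Fragment matches are stacked into (φ₁, ψ₁, …, φ_k, ψ_k) rows; rows with any
undefined angle (segment termini) are excluded and counted. The metric is
the Euclidean norm of per-coordinate wrapped differences
δ = min(|Δ|, 360 − |Δ|). Distances are precomputed as a dense M × M matrix —
match sets at useful k are at most a few thousand, so this stays cheap; a
`max_points` cap subsamples larger inputs with a fixed seed. Clustering is
HDBSCAN (scikit-learn implementation, `metric="precomputed"`,
`allow_single_cluster=True`); the cluster count C is determined by the data
and noise points are excluded from C and reported separately. Default
parameters are scale-linked: `min_cluster_size = max(5, ⌈0.025·M⌉)` and
`min_samples = min_cluster_size`, keeping behaviour stable as M varies. An
all-coincident point set short-circuits to one cluster (HDBSCAN cannot
estimate density from zero distances). Medoids minimise the total
within-cluster torus distance, ties broken by the lowest row index; a
brute-force pairwise-sum oracle checks them in the tests.

The public clustering surface is a scikit-learn-compatible estimator
(`TorusHDBSCAN`, with `fit`, `fit_predict`, `labels_`, `medoid_indices_`)
so it composes with sklearn tooling; `cluster_fragments` is the functional
wrapper used by the CLI.

The conditional density of the target residue — the center residue, or the
first of the two central residues for even k, i.e. index ⌊(k−1)/2⌋ — uses a
wrapped-Gaussian kernel: each 1-D kernel sums the Gaussian over image
shifts of ±360°, truncating further images (mass beyond one wrap at the
bandwidths in use is < 1e−9; the grid is renormalised to integrate to 1
over the torus regardless). Bandwidth defaults to a circular analogue of
Scott's rule — the root-mean-square wrapped deviation from the circular
mean, times n^(−1/6) for the 2-D case — floored at 1° so single-point
inputs remain well-defined. The default grid is 72 × 72 (5° cells). All
public interfaces use degrees; radians appear only internally.

## Synthetic data

The generator provides ground truth at three levels.

*Sequences* are i.i.d. draws at specified marginals (uniform, or a
realistic composition with leucine/alanine most common and
tryptophan/cysteine rarest). Planted k-mer enrichments overwrite
non-overlapping random stretches and are recorded in the manifest, so
occurrence counts have an exact expected value when the background alphabet
excludes the planted letters.

*Dihedrals* come from mixtures of independent von Mises components on the
torus. The generic backbone mixture uses three basins — α-helical
(−63, −43), β-strand (−120, 130), left-handed helical (60, 45) with weights
0.45/0.40/0.15 and κ = 30 (≈ 10° circular spread), typical of coil-library
compositions. The glycine preset places five equal-weight components at
(−90, 170), (90, −170), (−60, −40), (60, 40) and (180, 180) with κ = 20 —
the five density regions glycine occupies once ψ wraps are accounted for;
all pairs are ≥ ~90° apart on the torus so the preset genuinely plants five
distinct basins. The proline preset pins φ at −65° (the pyrrolidine-ring
restriction) with ψ split 0.6/0.4 between 150° and −30°.

*Coordinates* are built by sequential internal-coordinate (NeRF) placement
with Engh–Huber-like ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å; angles 121.7°/111.2°/116.2°; ω defaults to 180°). The local frame
used in placement is left-handed with respect to the IUPAC torsion sign, so
the torsion enters negated; re-extraction recovers requested torsions to
< 1e−13° in memory. After a round trip through fixed-width PDB files the
agreement is limited by the format's 0.001 Å coordinate quantisation, which
propagates to torsion errors up to ~0.15°; the file-based tests therefore
assert 0.5°, while the in-memory round trip asserts 1e−6°.

Because per-residue torsions are sampled independently in the generator,
synthetic fragments lack the φ/ψ autocorrelation of real secondary
structure: a planted k-mer's matches scatter over up to 3^k joint basin
combinations instead of concentrating in the handful real proteins use.
Passing tests therefore establish the correctness of extraction, indexing,
counting and clustering machinery — not that real fragment clusters are few;
that property must come from real corpora. Joint-component mixtures (one
2k-dimensional center per component) are used when a known cluster count
must be planted.

## Problem sizes

Default test and verification corpora are deliberately desk-scale: the
null-model regression uses 150 chains × 150 residues (22,350 dimer
windows), which is ample for the slope of a 400-point regression to settle
within ±0.01 of 1; clustering checks use 400–600 points. These sizes are
the package's own verification choices; all generators accept larger
parameters unchanged.

## Known limitations

- No secondary-structure assignment, hydrogen bonding, solvent
  accessibility or side-chain χ angles; torsions only.
- No approximate or substitution-matrix sequence matching; queries are
  exact.
- Occurrence counts inherit corpus redundancy (see above).
- The wrapped-KDE truncates kernel images beyond ±360°, which is only
  appropriate for bandwidths well below 360° (always the case for
  Ramachandran data).
- Nucleic acids and ligand chemistry are out of scope; assemblies are not
  expanded.
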
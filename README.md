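# torsionscan

Backbone-dihedral k-mer mining for protein structures.

Protein backbone geometry is compactly described by the torsion angles
φ, ψ, ω of each residue, and local conformation is strongly conditioned on
local sequence. `torsionscan` turns a set of structure files into a
queryable statistical resource: it extracts backbone torsions from PDB or
mmCIF coordinates, indexes every amino-acid k-mer together with its
dihedral tuples, answers sliding-window and exact fragment queries, scores
k-mer abundance against an independence null, and clusters the full-fragment
conformations of a k-mer on the dihedral torus. It is aimed at structural
bioinformaticians who want sequence-conditioned backbone statistics —
restricted Ramachandran distributions, fragment libraries, conformational
motif discovery — without re-deriving geometry from raw coordinates each
time.

## The statistics at the core

**Windowed fragment search.** A query sequence of length *N* with window
size *W* is split into *N − W + 1* overlapping windows shifted by one
residue. Each window is matched exactly against the indexed corpus and every
match returns its *W* (φ, ψ) pairs. With *W = N* the query is a single
exact fragment lookup. Per-residue aggregation pools, for residue *i*, the
angle pair at the right offset from every match of every window containing
*i* (terminal residues fall in 1 … *W* − 1 windows, interior residues in
*W*).

**Departure from independence.** For a k-mer *a₁…a_k* with *Nᵢ* occurrences
among *M* valid k-windows,

```
P_obs(a1..ak) = N_i / M
P_joint(a1..ak) = Π_i P_obs(a_i)
d = P_obs / P_joint
```

*d* = 1 when residues co-occur exactly as often as their individual
abundances predict; *d* > 1 marks enrichment (e.g. poly-histidine tags),
*d* < 1 depletion. An unweighted OLS regression of P_obs on P_joint across
all 20^k k-mers summarises a corpus: on an i.i.d. corpus the slope is ≈ 1
with intercept ≈ 0.

**Torus clustering of fragment conformations.** Each match of a k-mer is a
point (φ₁, ψ₁, …, φ_k, ψ_k) ∈ 2k-dimensional angular space. Distances wrap
every coordinate at ±180° (−179° and 179° are 2° apart) before taking the
Euclidean norm; HDBSCAN on the precomputed torus distances finds however
many conformational clusters the density supports, labels low-density
points as noise, and each cluster is represented by its medoid — the member
with the lowest total distance to its co-members. With at most three
Ramachandran basins per residue a k-mer admits at most 3^k joint clusters;
far fewer are populated in practice, which is what makes the recovered
clusters informative. The conditional distribution P(φᵢ, ψᵢ | a₁…a_k) of a
target residue (center of the k-mer, or first-of-two-central for even k) is
estimated with a wrapped-Gaussian kernel density on the torus.

A synthetic-data module generates the ground-truth inputs every stage is
tested against: i.i.d. sequences at chosen marginals with optional planted
k-mers, von Mises mixtures over Ramachandran basins (glycine and proline
presets included), and 3-D backbones realising arbitrary torsion lists via
internal-coordinate (NeRF) placement.

## Worked example

```python
import numpy as np
from torsionscan import (
    CorpusSpec, TorsionPointSet, build_index, cluster_fragments,
    fit_obs_vs_joint, glycine_preset, kmer_stats_table, make_segments,
    sample_dihedral_mixture, sample_sequences,
)
from torsionscan.synth_data import pdb_like_frequencies

# 150 chains x 150 residues, i.i.d. at realistic amino-acid marginals
seqs, _ = sample_sequences(CorpusSpec(
    n_chains=150, chain_length=150, frequencies=pdb_like_frequencies(), seed=1))
idx = build_index(make_segments(seqs, seed=1), [1, 2])
stats = kmer_stats_table(idx, 2)
fit = fit_obs_vs_joint(stats)
print(stats.window_total, round(fit.slope, 4), round(fit.r_squared, 4))

# five-basin glycine mixture, clustered on the torus
X = sample_dihedral_mixture(glycine_preset(), 600, seed=2)
res = cluster_fragments(TorsionPointSet(points=X))
print(res.n_clusters, res.n_noise)
```

prints

```
22350 1.0041 0.9696
5 4
```

The corpus has M = 22,350 dimer windows; because residues were drawn
independently, the observed dimer probabilities track the
independence-expected ones almost perfectly (slope 1.0041, R² 0.97 — the
residual scatter is sampling noise; the mean dimer lift is 1.0007). The
glycine mixture plants five torus basins and the density clustering
recovers exactly 5 clusters, discarding 4 of 600 points as noise; the five
medoids land within a few degrees of the planted basin centers, e.g.
(−62.0, −40.7) for the α-helical basin.

The same pipeline runs from the shell:

```
torsionscan simulate    --out corpus --n-chains 20 --chain-length 120 --seed 7 --plant NKPGD:40
torsionscan build-index --input corpus --out index --k 1,2,5
torsionscan query       --index index --sequence NKPGD --out hits
torsionscan kmer-stats  --index index --k 2 --out stats
torsionscan cluster     --index index --kmer NKPGD --out clusters
```

`simulate` writes minimal PDB files plus a ground-truth manifest;
`build-index` parses them back through the same extraction path used for
real structures. Every subcommand writes CSV/JSON outputs and a JSON
provenance record (configuration, seed, versions, input digests). Real
corpora are indexed the same way: point `build-index` at any directory of
`.pdb` / `.cif` files.

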
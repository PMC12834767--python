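"""k-mer abundance statistics and the departure-from-independence measure.

For a k-mer ``a1..ak`` with ``N_i`` occurrences among ``M`` valid k-windows
of the corpus, the observed probability is ``P_obs = N_i / M``.  Under the
hypothesis that residues occur independently, the expected probability is
the product of the constituent monomer probabilities,
``P_joint = prod_i P_obs(a_i)``, and the departure from independence is the
lift

    d = P_obs / P_joint

which equals 1 exactly when the residues co-occur no more and no less often
than chance predicts; d > 1 marks enrichment, d < 1 depletion.  Regressing
observed on joint probabilities across all 20^k k-mers summarises how far a
corpus as a whole departs from independence: on an i.i.d. corpus the slope
is ~1 with intercept ~0 and high R^2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .fragment_index import FragmentIndex, UnsupportedKError

__all__ = [
    "AMINO_ACIDS",
    "KmerStats",
    "RegressionSummary",
    "enumerate_kmers",
    "kmer_probabilities",
    "joint_probability",
    "departure_from_independence",
    "kmer_stats_table",
    "fit_obs_vs_joint",
]

#: The 20 standard residues in lexicographic one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

MAX_ENUMERATION_K = 6


@dataclass
class KmerStats:
    """Per-k-mer counts and probabilities for one k.

    ``table`` has one row per enumerated k-mer (zero counts included) with
    columns ``kmer, count, p_obs`` and, once joint probabilities are filled
    in, ``p_joint, d, outlier_flag``.  ``window_total`` is the number of
    valid k-windows M.
    """

    k: int
    table: pd.DataFrame
    window_total: int

    def lookup(self, kmer: str) -> pd.Series:
        rows = self.table[self.table["kmer"] == kmer]
        if rows.empty:
            raise KeyError(kmer)
        return rows.iloc[0]


@dataclass
class RegressionSummary:
    """Unweighted OLS of observed on joint probabilities."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    outliers: list[str] = field(default_factory=list)


def enumerate_kmers(k: int) -> list[str]:
    """All 20^k k-mer strings over the standard residues, lexicographic."""
    if not 1 <= k <= MAX_ENUMERATION_K:
        raise ValueError(f"k must be in 1..{MAX_ENUMERATION_K}, got {k}")
    return ["".join(t) for t in itertools.product(AMINO_ACIDS, repeat=k)]


def kmer_probabilities(index: FragmentIndex, k: int) -> KmerStats:
    """Counts and observed probabilities for every enumerated k-mer.

    The denominator is the number of valid k-windows in the corpus (for
    k=1 this is the residue total M).
    """
    if k not in index.k_range:
        raise UnsupportedKError(f"k={k} not indexed; supported: {sorted(index.k_range)}")
    total = index.window_total(k)
    if total == 0:
        raise ValueError("no windows: corpus is empty at this k")
    kmers = enumerate_kmers(k)
    counts = np.array(
        [len(index.postings[k].get(km, ())) for km in kmers], dtype=np.int64
    )
    table = pd.DataFrame(
        {"kmer": kmers, "count": counts, "p_obs": counts / total}
    )
    return KmerStats(k=k, table=table, window_total=total)


def joint_probability(monomer_stats: KmerStats, kmer: str) -> float:
    """Independence-expected probability: product of monomer P_obs."""
    if monomer_stats.k != 1:
        raise ValueError("monomer_stats must have k=1")
    lut = dict(zip(monomer_stats.table["kmer"], monomer_stats.table["p_obs"]))
    prob = 1.0
    for aa in kmer:
        if aa not in lut:
            raise KeyError(f"residue {aa!r} absent from monomer table")
        prob *= lut[aa]
    return prob


def departure_from_independence(p_obs: float, p_joint: float) -> float:
    """The lift d = P_obs / P_joint; 0 for absent k-mers, NaN (flagged, not
    fatal) when P_joint = 0 but P_obs > 0."""
    if p_obs < 0 or p_joint < 0:
        raise ValueError("probabilities must be non-negative")
    if p_obs == 0.0:
        return 0.0
    if p_joint == 0.0:
        return float("nan")
    return p_obs / p_joint


def kmer_stats_table(
    index: FragmentIndex,
    k: int,
    outlier_low: float = 0.5,
    outlier_high: float = 2.0,
) -> KmerStats:
    """Full per-k-mer statistics: counts, P_obs, P_joint, d, outlier flag.

    Monomer probabilities for P_joint come from the same corpus (k=1 must
    be indexed).  k-mers with d outside [outlier_low, outlier_high] (and
    nonzero counts) are flagged.
    """
    stats = kmer_probabilities(index, k)
    mono = stats if k == 1 else kmer_probabilities(index, 1)
    lut = dict(zip(mono.table["kmer"], mono.table["p_obs"]))
    p_joint = np.array(
        [np.prod([lut[aa] for aa in km]) for km in stats.table["kmer"]]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(
            stats.table["p_obs"].to_numpy() == 0.0,
            0.0,
            stats.table["p_obs"].to_numpy() / p_joint,
        )
    stats.table["p_joint"] = p_joint
    stats.table["d"] = d
    stats.table["outlier_flag"] = (stats.table["count"] > 0) & (
        (d <= outlier_low) | (d >= outlier_high)
    )
    return stats


def fit_obs_vs_joint(
    stats: KmerStats,
    include_zero_counts: bool = True,
) -> RegressionSummary:
    """Unweighted OLS of P_obs on P_joint across enumerated k-mers.

    Raw probabilities, not logs.  ``include_zero_counts=False`` restricts
    the fit to k-mers present in the corpus.
    """
    table = stats.table
    if "p_joint" not in table.columns:
        raise ValueError("stats lacks joint probabilities; use kmer_stats_table")
    if not include_zero_counts:
        table = table[table["count"] > 0]
    x = table["p_joint"].to_numpy(dtype=float)
    y = table["p_obs"].to_numpy(dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    if len(x) < 2:
        raise ValueError("need at least 2 finite points for regression")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate regression: joint probabilities have no variance")
    fit = sstats.linregress(x, y)
    outliers = (
        table.loc[table.get("outlier_flag", False) == True, "kmer"].tolist()  # noqa: E712
        if "outlier_flag" in table.columns
        else []
    )
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=int(len(x)),
        outliers=outliers,
    )
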
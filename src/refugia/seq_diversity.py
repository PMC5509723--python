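"""Haplotype collapsing, sequence diversity statistics, mismatch spectra
and a minimum-spanning haplotype network.

Per-site statistics divide by the *effective length*: the number of
alignment columns retained after the gap/ambiguity policy.  The default
policy removes every column containing a gap or an N anywhere in the
sample (complete deletion); pairwise deletion is available for distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import AlignedSequenceSet, HaplotypeTable


class SiteFilter(str, Enum):
    EXCLUDE_GAP_COLUMNS = "exclude-gap-columns"
    PAIRWISE_DELETION = "pairwise-deletion"


MISSING_CHARS = ("-", "N")


def filtered_matrix(
    aln: AlignedSequenceSet, policy: SiteFilter = SiteFilter.EXCLUDE_GAP_COLUMNS
) -> tuple[np.ndarray, int]:
    """Character matrix after the site filter, plus effective length.

    Under pairwise deletion the matrix keeps all columns (missing symbols
    retained); effective length is still the count of fully resolved
    columns so that per-site statistics stay comparable.
    """
    mat = aln.to_matrix()
    missing = np.isin(mat, MISSING_CHARS)
    clean_cols = ~missing.any(axis=0)
    if policy is SiteFilter.EXCLUDE_GAP_COLUMNS:
        return mat[:, clean_cols], int(clean_cols.sum())
    return mat, int(clean_cols.sum())


@dataclass
class DiversitySummary:
    """Within-sample diversity: Hd, per-site theta estimates and spectra."""

    n: int
    effective_length: int
    S: int
    k_bar: float
    Hd: float
    Hd_sd: float
    theta_pi: float
    theta_pi_sd: float
    theta_S: float
    theta_S_sd: float
    n_haplotypes: int


@dataclass
class MismatchSpectrum:
    """Counts of unordered sequence pairs at each pairwise-difference value."""

    counts: np.ndarray  # index = number of differences, starting at 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot > 0 else self.counts

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1

    def mean(self) -> float:
        d = np.arange(len(self.counts))
        return float((d * self.counts).sum() / self.counts.sum())


def collapse_haplotypes(
    aln: AlignedSequenceSet, policy: SiteFilter = SiteFilter.EXCLUDE_GAP_COLUMNS
) -> HaplotypeTable:
    """Group identical post-filter sequences into haplotypes.

    Ordering is deterministic: decreasing total count, ties broken by
    first occurrence in the alignment.
    """
    mat, _ = filtered_matrix(aln, policy)
    keys = ["".join(row) for row in mat]
    first_seen: dict[str, int] = {}
    for i, key in enumerate(keys):
        first_seen.setdefault(key, i)
    pops = aln.populations
    tallies: dict[str, dict[str, int]] = {k: {p: 0 for p in pops} for k in first_seen}
    for sid, key in zip(aln.sample_ids, keys):
        tallies[key][aln.population_of[sid]] += 1
    order = sorted(
        first_seen, key=lambda k: (-sum(tallies[k].values()), first_seen[k])
    )
    hap_ids = [f"H{i + 1}" for i in range(len(order))]
    counts = pd.DataFrame(
        [[tallies[k][p] for p in pops] for k in order], index=hap_ids, columns=pops
    )
    rep = {hid: key for hid, key in zip(hap_ids, order)}
    return HaplotypeTable(haplotype_ids=hap_ids, counts=counts, representative=rep)


def haplotype_diversity(counts) -> tuple[float, float]:
    """Unbiased haplotype diversity Hd = n/(n-1) (1 - sum p_i^2), with SD.

    The variance follows Nei (1987, eq. 8.12):
    V = 2/(n(n-1)) [ 2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2 ].
    """
    c = np.asarray(list(counts), dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = c / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    hd = n / (n - 1.0) * (1.0 - s2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return float(hd), float(np.sqrt(max(var, 0.0)))


def pairwise_differences(
    aln: AlignedSequenceSet, policy: SiteFilter = SiteFilter.EXCLUDE_GAP_COLUMNS
) -> np.ndarray:
    """Condensed vector of pairwise difference counts (order of pdist)."""
    mat, _ = filtered_matrix(aln, policy)
    n = mat.shape[0]
    out = []
    for i in range(n - 1):
        row = mat[i]
        block = mat[i + 1 :]
        neq = block != row
        if policy is SiteFilter.PAIRWISE_DELETION:
            miss = np.isin(block, MISSING_CHARS) | np.isin(row, MISSING_CHARS)
            neq = neq & ~miss
        out.extend(neq.sum(axis=1).tolist())
    return np.asarray(out, dtype=float)


def segregating_sites(mat: np.ndarray) -> int:
    if mat.shape[1] == 0:
        return 0
    return int((mat != mat[0]).any(axis=0).sum())


def singleton_counts(mat: np.ndarray) -> np.ndarray:
    """Per-sequence count of sites where that sequence is the unique minority."""
    n = mat.shape[0]
    U = np.zeros(n, dtype=int)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        vals, counts = np.unique(col, return_counts=True)
        if len(vals) == 2:
            k = counts.min()
            if k == 1:
                carrier = int(np.where(col == vals[np.argmin(counts)])[0][0])
                U[carrier] += 1
    return U


def harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def nucleotide_diversity(
    aln: AlignedSequenceSet, policy: SiteFilter = SiteFilter.EXCLUDE_GAP_COLUMNS
) -> DiversitySummary:
    """Hd, theta_pi (mean pairwise differences per site) and Watterson's
    theta_S (segregating sites per site), with standard deviations.

    SD(theta_pi) uses Tajima (1983): V = (n+1)/(3(n-1)) pi/L
    + 2(n^2+n+3)/(9n(n-1)) pi^2.  SD(theta_S) uses Var(S) = a1 thetaL
    + a2 thetaL^2 on the per-locus scale.
    """
    if aln.n < 2:
        raise ValueError("need at least two sequences")
    mat, L = filtered_matrix(aln, policy)
    if L == 0:
        raise ValueError("zero effective length after site filtering")
    if policy is SiteFilter.PAIRWISE_DELETION:
        smat = mat[:, ~np.isin(mat, MISSING_CHARS).any(axis=0)]
    else:
        smat = mat
    n = aln.n
    diffs = pairwise_differences(aln, policy)
    k_bar = float(diffs.mean())
    S = segregating_sites(smat)
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    theta_pi = k_bar / L
    theta_S = S / (a1 * L)
    var_pi = (n + 1) / (3.0 * (n - 1)) * theta_pi / L + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * theta_pi**2
    thetaL = theta_S * L
    var_S = a1 * thetaL + a2 * thetaL**2
    sd_theta_S = np.sqrt(var_S) / (a1 * L)
    ht = collapse_haplotypes(aln, policy)
    hd, hd_sd = haplotype_diversity(ht.total_counts())
    return DiversitySummary(
        n=n,
        effective_length=L,
        S=S,
        k_bar=k_bar,
        Hd=hd,
        Hd_sd=hd_sd,
        theta_pi=float(theta_pi),
        theta_pi_sd=float(np.sqrt(var_pi)),
        theta_S=float(theta_S),
        theta_S_sd=float(sd_theta_S),
        n_haplotypes=len(ht.haplotype_ids),
    )


def mismatch_spectrum(
    aln: AlignedSequenceSet, policy: SiteFilter = SiteFilter.EXCLUDE_GAP_COLUMNS
) -> MismatchSpectrum:
    """Spectrum over all unordered pairs, including the zero class."""
    diffs = pairwise_differences(aln, policy).astype(int)
    counts = np.bincount(diffs)
    return MismatchSpectrum(counts=counts)


@dataclass
class HaplotypeNetwork:
    """Minimum-spanning network: MST edges plus tied alternative edges."""

    graph: nx.Graph  # nodes carry 'frequency'; edges carry 'steps', 'alternative'

    @property
    def total_weight(self) -> int:
        return int(
            sum(
                d["steps"]
                for _, _, d in self.graph.edges(data=True)
                if not d["alternative"]
            )
        )

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"haplotype_a": u, "haplotype_b": v, "steps": d["steps"],
             "alternative": d["alternative"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["haplotype_a", "haplotype_b", "steps",
                                           "alternative"])


def build_haplotype_network(ht: HaplotypeTable) -> HaplotypeNetwork:
    """Minimum spanning network on pairwise Hamming distances.

    The network is the minimum spanning tree; any non-tree edge whose
    weight ties the maximum edge weight on the tree path between its
    endpoints is retained, flagged ``alternative``.
    """
    ids = ht.haplotype_ids
    totals = ht.total_counts()
    g = nx.Graph()
    for hid, freq in zip(ids, totals):
        g.add_node(hid, frequency=int(freq))
    if len(ids) == 1:
        return HaplotypeNetwork(graph=g)
    seqs = [ht.representative[h] for h in ids]
    full = nx.Graph()
    full.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
            full.add_edge(ids[i], ids[j], weight=max(d, 1))
    mst = nx.minimum_spanning_tree(full, weight="weight")
    for u, v, d in mst.edges(data=True):
        g.add_edge(u, v, steps=int(d["weight"]), alternative=False)
    for u, v, d in full.edges(data=True):
        if g.has_edge(u, v):
            continue
        path = nx.shortest_path(mst, u, v)
        path_max = max(
            mst[a][b]["weight"] for a, b in zip(path[:-1], path[1:])
        )
        if d["weight"] <= path_max:
            g.add_edge(u, v, steps=int(d["weight"]), alternative=True)
    return HaplotypeNetwork(graph=g)


def diversity_by_population(
    aln: AlignedSequenceSet, policy: SiteFilter = SiteFilter.EXCLUDE_GAP_COLUMNS
) -> pd.DataFrame:
    """Per-population and pooled DiversitySummary as a tidy DataFrame."""
    rows = {}
    for pop, sub in aln.by_population().items():
        if sub.n >= 2:
            rows[pop] = nucleotide_diversity(sub, policy).__dict__
    rows["Total"] = nucleotide_diversity(aln, policy).__dict__
    return pd.DataFrame(rows).T
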
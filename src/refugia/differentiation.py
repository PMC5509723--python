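"""Between-population structure: pairwise FST, refugium scoring from mean
pairwise FST, AMOVA Phi_ST, and DAPC-style clustering.

Dominant-marker FST uses a variance-components (Weir–Cockerham-style)
moment estimator on estimated allele frequencies, subtracting the
frequency-estimation noise and aggregating over loci as a ratio of sums.
Sequence FST is the distance-based Phi_ST of a two-level AMOVA on
pairwise differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .aflp import AlleleFreqEstimate
from .datatypes import AlignedSequenceSet, BinaryMarkerMatrix
from .seq_diversity import SiteFilter, filtered_matrix


# ---------------------------------------------------------------------------
# Dominant-marker FST
# ---------------------------------------------------------------------------


def fst_components(q: np.ndarray, v: np.ndarray, m: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus among-population variance component and total-variance
    denominator from frequency estimates.

    q, v: (r, L) frequency estimates and their sampling variances;
    m: (r, L) sample sizes (individuals scored).  Loci with fewer than
    two scored populations yield NaN components.

    The numerator is the weighted among-population sum of squares minus
    the expected contribution of estimation noise; the denominator
    estimates pbar(1-pbar) of the underlying population frequencies, so
    that the ratio of sums across loci estimates FST directly.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    m = np.asarray(m, dtype=float)
    valid = (~np.isnan(q)) & (m > 0)
    mv = np.where(valid, m, 0.0)
    M = mv.sum(axis=0)
    r = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        qbar = np.nansum(np.where(valid, mv * q, 0.0), axis=0) / M
        ssb = np.nansum(np.where(valid, mv * (q - qbar) ** 2, 0.0), axis=0)
        noise = np.nansum(np.where(valid, (1.0 - mv / M) * mv * v, 0.0), axis=0)
        cfac = M - np.nansum(mv**2, axis=0) / M
        sig_a = (ssb - noise) / cfac
        w2 = np.nansum(np.where(valid, (mv / M) ** 2 * (sig_a[None, :] + v), 0.0),
                       axis=0)
        den = qbar * (1.0 - qbar) + w2
    bad = r < 2
    sig_a = np.where(bad, np.nan, sig_a)
    den = np.where(bad, np.nan, den)
    return sig_a, den


def multilocus_fst(q: np.ndarray, v: np.ndarray, m: np.ndarray,
                   mask: np.ndarray | None = None) -> float:
    """Ratio-of-sums multi-locus FST (negatives retained)."""
    num, den = fst_components(q, v, m)
    ok = np.isfinite(num) & np.isfinite(den)
    if mask is not None:
        ok &= mask
    if not ok.any() or den[ok].sum() <= 0:
        return 0.0
    return float(num[ok].sum() / den[ok].sum())


def lynch_milligan_mask(band_freq: np.ndarray, n_scored: np.ndarray,
                        min_null: float = 3.0) -> np.ndarray:
    """Locus restriction for dominant-marker FST (Lynch & Milligan style).

    Keeps loci whose pooled band-absence fraction is at least
    min_null / (mean per-population sample size): below that the
    square-root frequency estimator is pinned near its zero-class floor
    and contributes pure noise to variance components.
    """
    scored = np.where(np.isnan(band_freq), 0.0, n_scored.astype(float))
    absent = np.nansum(scored * (1.0 - np.nan_to_num(band_freq)), axis=0)
    total = scored.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_absence = absent / total
        mean_n = total / (scored > 0).sum(axis=0)
    return (total > 0) & (pooled_absence >= min_null / mean_n)


@dataclass
class PairwiseFstMatrix:
    matrix: pd.DataFrame
    source: str  # "dominant" or "sequence"
    negatives_flagged: list[tuple[str, str]] = field(default_factory=list)


def pairwise_fst_dominant(freqs: AlleleFreqEstimate,
                          lm_restrict: bool = True) -> PairwiseFstMatrix:
    """Pairwise multi-locus FST between populations from dominant-marker
    frequency estimates.

    By default the Lynch–Milligan restriction is applied per pair; the
    square-root frequency estimates should be used here (Bayesian
    shrinkage compresses between-population variance and biases FST
    downward).
    """
    pops = freqs.populations
    v = freqs.sampling_variance()
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    negs = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ix = [i, j]
            mask = (lynch_milligan_mask(freqs.band_freq[ix], freqs.n_scored[ix])
                    if lm_restrict else None)
            f = multilocus_fst(freqs.q_hat[ix], v[ix], freqs.n_scored[ix], mask)
            mat.iloc[i, j] = mat.iloc[j, i] = f
            if f < 0:
                negs.append((pops[i], pops[j]))
    return PairwiseFstMatrix(matrix=mat, source="dominant",
                             negatives_flagged=negs)


def per_locus_fst(freqs: AlleleFreqEstimate,
                  lm_restrict: bool = True) -> pd.DataFrame:
    """Per-locus FST (across all populations) plus the between-population
    mean heterozygosity used by the outlier scan.

    Loci failing the Lynch–Milligan restriction get NaN FST (their
    dominant-marker frequency estimates carry no variance information).
    """
    v = freqs.sampling_variance()
    num, den = fst_components(freqs.q_hat, v, freqs.n_scored)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = num / den
    if lm_restrict:
        mask = lynch_milligan_mask(freqs.band_freq, freqs.n_scored)
        fst = np.where(mask, fst, np.nan)
    het = np.nanmean(2.0 * freqs.q_hat * (1.0 - freqs.q_hat), axis=0)
    return pd.DataFrame({"fst": fst, "num": num, "den": den, "H_E": het},
                        index=freqs.locus_ids)


# ---------------------------------------------------------------------------
# Refugium scoring
# ---------------------------------------------------------------------------


@dataclass
class RefugiumScore:
    scores: pd.Series  # mean pairwise FST of each population vs the rest
    candidate: str | None
    tied: bool

    def rank_order(self) -> list[str]:
        return list(self.scores.sort_values(ascending=False).index)


def mean_population_fst(fst: PairwiseFstMatrix) -> RefugiumScore:
    """Mean pairwise FST of each population against the remaining ones.

    The top-scoring population is the refugium candidate; exact ties are
    flagged and leave the candidate unset.
    """
    m = fst.matrix
    if len(m) < 3:
        raise ValueError("refugium scoring needs at least 3 populations")
    r = len(m)
    scores = (m.sum(axis=1)) / (r - 1)
    top = scores.max()
    winners = scores[scores == top]
    tied = len(winners) > 1
    return RefugiumScore(scores=scores,
                         candidate=None if tied else str(winners.index[0]),
                         tied=tied)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    phi_st: float
    p_value: float | None
    permutations: int
    df_among: int
    df_within: int


def _amova_from_d2(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    N = len(labels)
    groups = np.unique(labels)
    r = len(groups)
    iu = np.triu_indices(N, k=1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    for g in groups:
        ix = np.where(labels == g)[0]
        if len(ix) > 1:
            sub = d2[np.ix_(ix, ix)]
            ss_within += sub[np.triu_indices(len(ix), k=1)].sum() / len(ix)
    ss_among = ss_total - ss_within
    df_a, df_w = r - 1, N - r
    ms_w = ss_within / df_w if df_w > 0 else 0.0
    ms_a = ss_among / df_a if df_a > 0 else 0.0
    sizes = np.array([np.sum(labels == g) for g in groups], dtype=float)
    n_c = (N - (sizes**2).sum() / N) / (r - 1)
    sig_w = ms_w
    sig_a = (ms_a - ms_w) / n_c
    tot = sig_a + sig_w
    phi = sig_a / tot if tot > 0 else 0.0
    return sig_a, sig_w, phi


def _marker_sq_distances(calls: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between band profiles; pairs are
    rescaled by the fraction of mutually scored loci."""
    n, L = calls.shape
    filled = np.nan_to_num(calls)
    obs = (~np.isnan(calls)).astype(float)
    sq = filled**2
    cross = filled @ filled.T
    d2 = (sq @ obs.T) + (obs @ sq.T) - 2 * cross
    shared = obs @ obs.T
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = L / shared
    return np.where(shared > 0, d2 * scale, 0.0)


def amova_phist(
    data, labels=None, n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """Two-level AMOVA Phi_ST with a label-permutation test.

    ``data`` may be a BinaryMarkerMatrix or AlignedSequenceSet (labels
    default to its own population map; pass ``labels`` to override, e.g.
    with cluster assignments), or a precomputed squared-distance matrix
    with an explicit label vector.
    p = (1 + #{Phi_perm >= Phi_obs}) / (1 + permutations).
    """
    if n_permutations and n_permutations < 10:
        raise ValueError("fewer than 10 permutations is meaningless")
    if isinstance(data, BinaryMarkerMatrix):
        d2 = _marker_sq_distances(data.calls)
        if labels is None:
            labels = [data.population_of[i] for i in data.individual_ids]
    elif isinstance(data, AlignedSequenceSet):
        from scipy.spatial.distance import squareform
        from .seq_diversity import pairwise_differences
        d2 = squareform(pairwise_differences(data))
        if labels is None:
            labels = [data.population_of[s] for s in data.sample_ids]
    else:
        d2 = np.asarray(data, dtype=float)
        if labels is None:
            raise ValueError("labels are required with a distance matrix")
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2 or (counts < 2).any():
        raise ValueError("AMOVA needs >= 2 populations with >= 2 members each")
    sig_a, sig_w, phi = _amova_from_d2(d2, labels)
    p = None
    if n_permutations:
        if rng is None:
            rng = np.random.default_rng()
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            _, _, phi_p = _amova_from_d2(d2, perm)
            if phi_p >= phi:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    return AmovaResult(sigma_among=sig_a, sigma_within=sig_w, phi_st=phi,
                       p_value=p, permutations=n_permutations or 0,
                       df_among=len(groups) - 1, df_within=len(labels) - len(groups))


def pairwise_phist_sequences(aln: AlignedSequenceSet,
                             policy: SiteFilter = SiteFilter.EXCLUDE_GAP_COLUMNS
                             ) -> PairwiseFstMatrix:
    """Pairwise distance-based Phi_ST between populations from pairwise
    sequence differences (two-population AMOVA per pair)."""
    from scipy.spatial.distance import squareform
    from .seq_diversity import pairwise_differences
    d2 = squareform(pairwise_differences(aln, policy))
    labels = np.array([aln.population_of[s] for s in aln.sample_ids])
    pops = aln.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    negs = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ix = np.where((labels == pops[i]) | (labels == pops[j]))[0]
            _, _, phi = _amova_from_d2(d2[np.ix_(ix, ix)], labels[ix])
            mat.iloc[i, j] = mat.iloc[j, i] = phi
            if phi < 0:
                negs.append((pops[i], pops[j]))
    return PairwiseFstMatrix(matrix=mat, source="sequence",
                             negatives_flagged=negs)


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------


@dataclass
class DapcResult:
    n_pcs: int
    pc_scores: np.ndarray | None = None
    assignments: np.ndarray | None = None
    bic: pd.Series | None = None
    best_K: int | None = None
    ld_coords: np.ndarray | None = None
    ld_var_fractions: np.ndarray | None = None
    percent_first_two: float | None = None


def _impute_center(calls: np.ndarray) -> np.ndarray:
    X = calls.copy()
    col_means = np.nanmean(X, axis=0)
    nan_ix = np.where(np.isnan(X))
    X[nan_ix] = np.take(col_means, nan_ix[1])
    return X - X.mean(axis=0)


def find_clusters(markers: BinaryMarkerMatrix, K_range=range(1, 9),
                  seed: int = 0, var_threshold: float = 0.9,
                  n_restarts: int = 20) -> DapcResult:
    """PCA reduction followed by k-means over a range of K, scored by
    BIC = n ln(WSS/n) + K ln(n); the best K minimizes BIC."""
    K_range = list(K_range)
    n = markers.n_individuals
    if max(K_range) >= n:
        raise ValueError("K_max must be smaller than the number of individuals")
    X = _impute_center(markers.calls)
    pca = PCA(n_components=min(n - 1, X.shape[1]), random_state=seed)
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_pcs = int(np.searchsorted(cum, var_threshold) + 1)
    scores = scores[:, :n_pcs]
    bic = {}
    labels_for = {}
    for K in K_range:
        if K == 1:
            wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
            labels_for[K] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
            labels_for[K] = km.fit_predict(scores)
            wss = float(km.inertia_)
        bic[K] = n * np.log(max(wss, 1e-12) / n) + K * np.log(n)
    bic = pd.Series(bic)
    best_K = int(bic.idxmin())
    return DapcResult(n_pcs=n_pcs, pc_scores=scores,
                      assignments=labels_for[best_K], bic=bic, best_K=best_K)


def dapc_axes(markers: BinaryMarkerMatrix, assignments: np.ndarray,
              n_pcs: int | None = None, seed: int = 0) -> DapcResult:
    """Linear discriminant axes on retained principal components.

    Reports per-axis discriminated-variance fractions and the percent of
    discriminable variation captured by the first two axes.
    """
    assignments = np.asarray(assignments)
    groups, counts = np.unique(assignments, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least two clusters")
    if (counts < 2).any():
        raise ValueError("every cluster needs at least two members")
    X = _impute_center(markers.calls)
    n = X.shape[0]
    pca = PCA(n_components=min(n - 1, X.shape[1]), random_state=seed)
    scores = pca.fit_transform(X)
    if n_pcs is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, 0.9) + 1)
    n_pcs = min(n_pcs, n - len(groups))
    scores = scores[:, :n_pcs]
    lda = LinearDiscriminantAnalysis(solver="eigen")
    coords = lda.fit_transform(scores, assignments)
    fractions = lda.explained_variance_ratio_[: coords.shape[1]]
    fractions = fractions / fractions.sum()
    pct2 = float(100.0 * fractions[: 2].sum())
    return DapcResult(n_pcs=n_pcs, assignments=assignments, ld_coords=coords,
                      ld_var_fractions=fractions, percent_first_two=pct2)
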
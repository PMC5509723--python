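"""Dominant-marker allele-frequency estimation and within-population
diversity.

Band absence is the recessive homozygote, so under Hardy–Weinberg the
band-absence allele frequency q satisfies q^2 = P(no band).  Two
estimators are provided: the square-root estimator with a zero-class
correction, and a Bayesian posterior mean under a Beta prior whose
parameters are fitted per population from the among-locus distribution
of square-root estimates (method of moments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BinaryMarkerMatrix


@dataclass
class AlleleFreqEstimate:
    """Per locus x population estimates of the band-absence allele
    frequency q (band-presence allele p = 1 - q)."""

    populations: list[str]
    locus_ids: list[str]
    q_hat: np.ndarray      # (P, L)
    band_freq: np.ndarray  # (P, L) observed fraction of band presence
    n_scored: np.ndarray   # (P, L) individuals scored
    method: str = "bayes"
    prior_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    dropped_loci: list[str] = field(default_factory=list)

    @property
    def p_hat(self) -> np.ndarray:
        return 1.0 - self.q_hat

    def sampling_variance(self) -> np.ndarray:
        """Delta-method variance of the square-root estimator,
        (1 - q^2) / (4 m); used as the frequency-noise term in
        variance-component FST estimation."""
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (1.0 - self.q_hat**2) / (4.0 * self.n_scored)
        return np.where(self.n_scored > 0, v, np.nan)


def _sqrt_estimate(n_absent: np.ndarray, n_scored: np.ndarray) -> np.ndarray:
    """sqrt(absence fraction), with the zero-class correction
    q = sqrt(1 / (2 (n + 1))) when no absence is observed."""
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.sqrt(n_absent / n_scored)
    zero = (n_absent == 0) & (n_scored > 0)
    q = np.where(zero, np.sqrt(1.0 / (2.0 * (n_scored + 1.0))), q)
    return np.where(n_scored > 0, q, np.nan)


def _fit_beta_moments(values: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Beta fit, floored away from degenerate shapes."""
    v = values[np.isfinite(values)]
    if v.size < 2:
        return 1.0, 1.0
    m = float(np.clip(v.mean(), 1e-3, 1 - 1e-3))
    var = float(v.var())
    var = min(max(var, 1e-6), m * (1 - m) * 0.999)
    common = m * (1 - m) / var - 1.0
    return max(m * common, 0.05), max((1 - m) * common, 0.05)


def _bayes_posterior_mean(n_absent: np.ndarray, n_scored: np.ndarray,
                          a: float, b: float) -> np.ndarray:
    """Posterior mean of q per locus under a Beta(a, b) prior and the
    dominant-genotype likelihood (q^2)^absent (1-q^2)^present.

    The posterior kernel q^(a+2x-1) (1-q)^(b+g-1) (1+q)^g with
    g = n - x integrates exactly as a binomial sum of Beta functions;
    evaluated in log space.
    """
    from scipy.special import betaln, gammaln, logsumexp

    x = np.asarray(n_absent, dtype=float)
    g = np.asarray(n_scored, dtype=float) - x
    g_int = np.round(g).astype(int)
    j = np.arange(int(g_int.max()) + 1)
    valid = j[None, :] <= g_int[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        log_binom = (gammaln(g[:, None] + 1.0) - gammaln(j[None, :] + 1.0)
                     - gammaln(g[:, None] - j[None, :] + 1.0))
    alpha = a + 2.0 * x
    beta = b + g
    log_den = log_binom + betaln(alpha[:, None] + j[None, :], beta[:, None])
    log_num = log_binom + betaln(alpha[:, None] + j[None, :] + 1.0,
                                 beta[:, None])
    log_den = np.where(valid, log_den, -np.inf)
    log_num = np.where(valid, log_num, -np.inf)
    return np.exp(logsumexp(log_num, axis=1) - logsumexp(log_den, axis=1))


def estimate_allele_frequencies(
    markers: BinaryMarkerMatrix, method: str = "bayes",
    drop_empty_loci: bool = True,
) -> AlleleFreqEstimate:
    """Estimate q per locus and population.

    Loci with no band presence in any population are dropped (their
    frequency carries no information for dominant scoring); the dropped
    ids are recorded on the result.
    """
    if method not in ("bayes", "sqrt"):
        raise ValueError("method must be 'bayes' or 'sqrt'")
    pop_ix = markers.population_indices()
    pops = list(pop_ix)
    calls = markers.calls
    keep = np.ones(markers.n_loci, dtype=bool)
    if drop_empty_loci:
        present_any = np.nansum(np.nan_to_num(calls), axis=0) > 0
        keep = present_any
    locus_ids = [lid for lid, k in zip(markers.locus_ids, keep) if k]
    dropped = [lid for lid, k in zip(markers.locus_ids, keep) if not k]
    sub = calls[:, keep]
    P, L = len(pops), sub.shape[1]
    q_hat = np.full((P, L), np.nan)
    band_freq = np.full((P, L), np.nan)
    n_scored = np.zeros((P, L), dtype=int)
    priors: dict[str, tuple[float, float]] = {}
    for pi, pop in enumerate(pops):
        block = sub[pop_ix[pop]]
        scored = (~np.isnan(block)).sum(axis=0)
        absent = np.nansum(1.0 - block, axis=0)
        n_scored[pi] = scored
        with np.errstate(invalid="ignore"):
            band_freq[pi] = np.where(scored > 0,
                                     np.nansum(block, axis=0) / scored, np.nan)
        q_sqrt = _sqrt_estimate(absent, scored.astype(float))
        if method == "sqrt":
            q_hat[pi] = q_sqrt
        else:
            a, b = _fit_beta_moments(q_sqrt)
            priors[pop] = (a, b)
            ok = scored > 0
            q_row = np.full(L, np.nan)
            q_row[ok] = _bayes_posterior_mean(absent[ok], scored[ok].astype(float),
                                              a, b)
            q_hat[pi] = q_row
    return AlleleFreqEstimate(
        populations=pops, locus_ids=locus_ids, q_hat=q_hat,
        band_freq=band_freq, n_scored=n_scored, method=method,
        prior_params=priors, dropped_loci=dropped,
    )


@dataclass
class PopDiversitySummary:
    populations: list[str]
    H_E: np.ndarray
    SE_H_E: np.ndarray
    percent_polymorphic: np.ndarray
    private_bands: np.ndarray | None = None
    fixed_private_bands: np.ndarray | None = None
    n_individuals: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"H_E": self.H_E, "SE_H_E": self.SE_H_E,
             "percent_polymorphic": self.percent_polymorphic}
        if self.n_individuals is not None:
            d["N"] = self.n_individuals
        if self.private_bands is not None:
            d["N_p"] = self.private_bands
            d["N_fp"] = self.fixed_private_bands
        return pd.DataFrame(d, index=self.populations)


def nei_gene_diversity(freqs: AlleleFreqEstimate) -> PopDiversitySummary:
    """Nei's gene diversity per population: mean over loci of
    h = 1 - p^2 - q^2 (= 2pq), with the standard error over loci."""
    h = 2.0 * freqs.p_hat * freqs.q_hat
    H_E = np.nanmean(h, axis=1)
    L_eff = (~np.isnan(h)).sum(axis=1)
    SE = np.nanstd(h, axis=1, ddof=1) / np.sqrt(np.maximum(L_eff, 1))
    return PopDiversitySummary(
        populations=freqs.populations, H_E=H_E, SE_H_E=SE,
        percent_polymorphic=percent_polymorphic(freqs),
    )


def percent_polymorphic(freqs: AlleleFreqEstimate, level: float = 0.05
                        ) -> np.ndarray:
    """Percent of loci whose more common allele frequency is <= 1 - level."""
    major = np.maximum(freqs.p_hat, freqs.q_hat)
    poly = major <= (1.0 - level)
    scored = ~np.isnan(freqs.q_hat)
    with np.errstate(invalid="ignore"):
        return 100.0 * poly.sum(axis=1) / scored.sum(axis=1)


def private_bands(markers: BinaryMarkerMatrix) -> pd.DataFrame:
    """Counts of private bands N_p (band present in exactly one
    population) and fixed private bands N_fp (also present in every
    scored individual of that population)."""
    pop_ix = markers.population_indices()
    pops = list(pop_ix)
    calls = markers.calls
    n_p = dict.fromkeys(pops, 0)
    n_fp = dict.fromkeys(pops, 0)
    for j in range(markers.n_loci):
        col = calls[:, j]
        present_in = [p for p in pops if np.nansum(col[pop_ix[p]]) > 0]
        if len(present_in) == 1:
            p = present_in[0]
            n_p[p] += 1
            vals = col[pop_ix[p]]
            vals = vals[~np.isnan(vals)]
            if vals.size > 0 and np.all(vals == 1):
                n_fp[p] += 1
    return pd.DataFrame({"N_p": pd.Series(n_p), "N_fp": pd.Series(n_fp)})


def population_diversity(markers: BinaryMarkerMatrix,
                         method: str = "bayes") -> pd.DataFrame:
    """Per-population diversity table: N, %P, N_p (N_fp), H_E, SE."""
    freqs = estimate_allele_frequencies(markers, method=method)
    summary = nei_gene_diversity(freqs)
    priv = private_bands(markers)
    df = summary.to_frame()
    df["N"] = [len(markers.population_indices()[p]) for p in freqs.populations]
    df = df.join(priv)
    return df[["N", "percent_polymorphic", "N_p", "N_fp", "H_E", "SE_H_E"]]


def repeatability(replicate_pairs: list[tuple[np.ndarray, np.ndarray]]
                  ) -> float:
    """Percent of locus calls identical across replicate profile pairs.

    Pooled over all pairs and loci; both calls must be non-missing to be
    compared.  Mismatched locus counts raise.
    """
    if not replicate_pairs:
        raise ValueError("need at least one replicate pair")
    same = 0
    total = 0
    for a, b in replicate_pairs:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("replicate profiles have mismatched locus sets")
        ok = ~(np.isnan(a) | np.isnan(b))
        same += int((a[ok] == b[ok]).sum())
        total += int(ok.sum())
    if total == 0:
        raise ValueError("no comparable calls")
    return 100.0 * same / total
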
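"""FST-outlier detection and the adaptive-locus decision rule.

Two scans are provided.  The FDIST-style scan compares each locus's
(heterozygosity, FST) pair against a simulated neutral cloud from a
Balding–Nichols island model calibrated to the trimmed mean FST of the
data, with conditional empirical p-values and Benjamini–Hochberg FDR.
The Bayesian scan is a reversible-jump MCMC over a hierarchical model in
which each locus either shares the genome-wide differentiation of its
populations or carries its own selection effect; evidence is summarized
as posterior odds of the selection model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .aflp import AlleleFreqEstimate, estimate_allele_frequencies
from .datatypes import BinaryMarkerMatrix
from .differentiation import fst_components, lynch_milligan_mask
from .simulate import balding_nichols_freqs

# ---------------------------------------------------------------------------
# FDIST-style scan
# ---------------------------------------------------------------------------


@dataclass
class FdistConfig:
    n_sim_loci: int = 100000
    n_calib_loci: int = 5000
    trim_fraction: float = 0.30
    n_bins: int = 20
    min_per_bin: int = 30
    quantile: float = 0.95       # flag above the 95% conditional level
    fdr: float = 0.05
    max_calib_iter: int = 20
    calib_tol: float = 0.005
    freq_method: str = "sqrt"  # unbiased for variance components
    seed: int | None = None


@dataclass
class NeutralEnvelope:
    het: np.ndarray
    fst: np.ndarray
    fst_target: float
    fst_calibrated: float
    bin_edges: np.ndarray


def trimmed_mean_fst(per_locus_fst: np.ndarray, trim: float = 0.30) -> float:
    """Mean FST after removing the highest and lowest ``trim`` fraction."""
    f = np.sort(per_locus_fst[np.isfinite(per_locus_fst)])
    k = int(np.floor(trim * len(f)))
    core = f[k: len(f) - k] if len(f) - 2 * k > 0 else f
    return float(core.mean())


def _observed_scan_inputs(markers: BinaryMarkerMatrix, method: str):
    freqs = estimate_allele_frequencies(markers, method=method)
    v = freqs.sampling_variance()
    num, den = fst_components(freqs.q_hat, v, freqs.n_scored)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = num / den
    het = np.nanmean(2.0 * freqs.q_hat * (1.0 - freqs.q_hat), axis=0)
    poly = np.array([
        np.nanmax(freqs.band_freq[:, j]) > 0 and np.nanmin(freqs.band_freq[:, j]) < 1
        for j in range(len(freqs.locus_ids))
    ])
    poly &= lynch_milligan_mask(freqs.band_freq, freqs.n_scored)
    return freqs, fst, het, poly


def _simulate_neutral_cloud(
    p_bar_pool: np.ndarray, fst_param: float, sizes: np.ndarray,
    n_loci: int, method: str, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral (H_E, FST) cloud: Balding–Nichols frequencies, binomial
    dominant phenotypes, then the same estimation pipeline as the data."""
    P = len(sizes)
    p_bar = rng.choice(p_bar_pool, size=n_loci)
    freqs = balding_nichols_freqs(p_bar[None, :], fst_param, (P, n_loci), rng)
    band_prob = 1.0 - (1.0 - freqs) ** 2
    absent = np.vstack([
        rng.binomial(sizes[j], 1.0 - band_prob[j]) for j in range(P)
    ]).astype(float)
    scored = np.tile(sizes[:, None].astype(float), (1, n_loci))
    from .aflp import _bayes_posterior_mean, _fit_beta_moments, _sqrt_estimate
    q_sqrt = _sqrt_estimate(absent, scored)
    if method == "sqrt":
        q_hat = q_sqrt
    else:
        q_hat = np.empty_like(q_sqrt)
        for j in range(P):
            a, b = _fit_beta_moments(q_sqrt[j])
            q_hat[j] = _bayes_posterior_mean(absent[j], scored[j], a, b)
    v = (1.0 - q_hat**2) / (4.0 * scored)
    num, den = fst_components(q_hat, v, scored)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = num / den
    het = np.nanmean(2.0 * q_hat * (1.0 - q_hat), axis=0)
    band_freq = 1.0 - absent / scored
    ok = (np.isfinite(fst) & np.isfinite(het)
          & lynch_milligan_mask(band_freq, scored))
    return het[ok], fst[ok]


def fdist_scan(
    markers: BinaryMarkerMatrix, config: FdistConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, NeutralEnvelope]:
    """Per-locus outlier scan against a calibrated neutral envelope.

    Steps: observed per-locus FST and heterozygosity; trimmed mean FST;
    iterative calibration of the Balding–Nichols FST parameter until the
    simulated trimmed mean matches; per-locus empirical p within the
    locus's heterozygosity bin; flags from the conditional quantile plus
    Benjamini–Hochberg FDR.
    """
    if config is None:
        config = FdistConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    freqs, fst_obs, het_obs, poly = _observed_scan_inputs(markers,
                                                          config.freq_method)
    if poly.sum() < 50:
        import warnings
        warnings.warn("fewer than 50 polymorphic loci: envelope unstable")
    sizes = np.array([len(ix) for ix in markers.population_indices().values()])
    target = trimmed_mean_fst(fst_obs[poly], config.trim_fraction)
    target = max(target, 1e-3)
    p_bar_pool = 1.0 - np.nanmean(freqs.q_hat[:, poly], axis=0)
    p_bar_pool = p_bar_pool[np.isfinite(p_bar_pool)]
    p_bar_pool = np.clip(p_bar_pool, 0.02, 0.98)
    # calibrate the island-model parameter on the trimmed mean
    f_param = float(np.clip(target, 0.005, 0.9))
    for _ in range(config.max_calib_iter):
        het_s, fst_s = _simulate_neutral_cloud(
            p_bar_pool, f_param, sizes, config.n_calib_loci,
            config.freq_method, rng)
        sim_mean = trimmed_mean_fst(fst_s, config.trim_fraction)
        if abs(sim_mean - target) < config.calib_tol:
            break
        f_param = float(np.clip(f_param * target / max(sim_mean, 1e-4),
                                0.002, 0.95))
    het_s, fst_s = _simulate_neutral_cloud(
        p_bar_pool, f_param, sizes, config.n_sim_loci, config.freq_method, rng)
    lo, hi = het_s.min(), het_s.max()
    edges = np.linspace(lo, hi + 1e-9, config.n_bins + 1)
    envelope = NeutralEnvelope(het=het_s, fst=fst_s, fst_target=target,
                               fst_calibrated=f_param, bin_edges=edges)
    sim_bin = np.digitize(het_s, edges) - 1
    p_emp = np.full(len(fst_obs), np.nan)
    for j in np.where(poly & np.isfinite(fst_obs) & np.isfinite(het_obs))[0]:
        b = int(np.clip(np.digitize(het_obs[j], edges) - 1, 0, config.n_bins - 1))
        width = 0
        members = np.array([], dtype=int)
        while len(members) < config.min_per_bin and width <= config.n_bins:
            sel = (sim_bin >= b - width) & (sim_bin <= b + width)
            members = np.where(sel)[0]
            width += 1
        cloud = fst_s[members]
        # raw exceedance fraction: an observed FST beyond the whole cloud
        # yields p = 0, as in FDIST-style scans
        p_emp[j] = np.sum(cloud >= fst_obs[j]) / len(cloud)
    q_val = benjamini_hochberg(p_emp)
    with np.errstate(invalid="ignore"):
        flag95 = p_emp <= (1.0 - config.quantile)
        flag = flag95 & (q_val <= config.fdr)
    flag95 = np.where(np.isnan(p_emp), False, flag95)
    flag = np.where(np.isnan(p_emp), False, flag)
    result = pd.DataFrame({
        "fst": fst_obs, "H_E": het_obs, "p_empirical": p_emp,
        "q_value": q_val,
        "outlier_95": flag95.astype(bool),      # conditional 95% level
        "outlier_fdist": flag.astype(bool),     # 95% level AND BH FDR
        "polymorphic": poly,
    }, index=freqs.locus_ids)
    return result, envelope


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up q-values; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.where(~np.isnan(p))[0]
    m = len(ok)
    if m == 0:
        return q
    order = ok[np.argsort(p[ok])]
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------------
# Bayesian (reversible-jump) scan
# ---------------------------------------------------------------------------


@dataclass
class McmcConfig:
    burn_in: int = 1000
    samples: int = 4000
    thin: int = 1
    prior_odds_neutral: float = 10.0
    alpha_prior_sd: float = 1.0
    beta_prior_mean: float = -1.0
    beta_prior_sd: float = 1.8
    step_p: float = 0.4
    step_alpha: float = 0.6
    step_beta: float = 0.25
    n_quad: int = 32
    seed: int | None = None


@dataclass
class BayescanResult:
    table: pd.DataFrame       # per-locus log10_PO, posterior inclusion, flag
    beta: np.ndarray          # posterior mean per-population effects
    diagnostics: dict = field(default_factory=dict)


def _dominant_loglik(
    absent: np.ndarray, scored: np.ndarray, p_anc: np.ndarray,
    alpha: np.ndarray, beta: np.ndarray, nodes: np.ndarray, logw: np.ndarray,
) -> np.ndarray:
    """log-likelihood per (locus, population).

    absent, scored: (L, P) counts; p_anc, alpha: (L,); beta: (P,).
    Integrates the Balding–Nichols frequency prior against the dominant
    binomial likelihood with Gauss–Legendre quadrature on (0, 1).
    """
    L, P = absent.shape
    f = expit(alpha[:, None] + beta[None, :])          # (L, P)
    f = np.clip(f, 1e-4, 1 - 1e-4)
    ratio = (1.0 - f) / f
    a = p_anc[:, None] * ratio                          # (L, P)
    b = (1.0 - p_anc[:, None]) * ratio
    logq = np.log(nodes)                                # q = 1 - p grid
    log1mq = np.log1p(-nodes)
    # Beta density of p = 1-q: p^(a-1) (1-p)^(b-1) -> (1-q)^(a-1) q^(b-1)
    from scipy.special import gammaln
    log_beta_norm = gammaln(a + b) - gammaln(a) - gammaln(b)
    expo_a = (a - 1.0)[:, :, None] * log1mq[None, None, :]
    expo_b = (b - 1.0)[:, :, None] * logq[None, None, :]
    lik = (2.0 * absent[:, :, None] * logq[None, None, :]
           + (scored - absent)[:, :, None]
           * np.log1p(-nodes**2)[None, None, :])
    logint = expo_a + expo_b + lik + logw[None, None, :]
    mx = logint.max(axis=2)
    out = mx + np.log(np.exp(logint - mx[:, :, None]).sum(axis=2))
    return out + log_beta_norm


def bayescan_lite(
    markers: BinaryMarkerMatrix, config: McmcConfig | None = None,
    rng: np.random.Generator | None = None,
) -> BayescanResult:
    """Reversible-jump MCMC over locus selection effects.

    Model: logit(F_ij) = alpha_i + beta_j with alpha_i present only when
    the locus-selection indicator is on (prior odds favour neutrality
    10:1); per-population frequencies are integrated out against their
    Balding–Nichols prior.  Posterior odds PO_i = P(sel)/P(neutral).
    """
    if config is None:
        config = McmcConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop_ix = markers.population_indices()
    pops = list(pop_ix)
    P = len(pops)
    calls = markers.calls
    absent = np.vstack([
        np.nansum(1.0 - calls[pop_ix[p]], axis=0) for p in pops
    ]).T                                               # (L, P)
    scored = np.vstack([
        (~np.isnan(calls[pop_ix[p]])).sum(axis=0) for p in pops
    ]).T.astype(float)
    L = absent.shape[0]
    gl_nodes, gl_w = np.polynomial.legendre.leggauss(config.n_quad)
    nodes = 0.5 * (gl_nodes + 1.0)
    nodes = np.clip(nodes, 1e-9, 1 - 1e-9)
    logw = np.log(0.5 * gl_w)
    # initial values
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_band = np.where(scored > 0, (scored - absent) / scored, 0.5)
    p0 = np.clip(1.0 - np.sqrt(np.clip(1.0 - obs_band.mean(axis=1), 1e-4, 1)),
                 0.02, 0.98)
    logit_p = np.log(p0 / (1 - p0))
    alpha = np.zeros(L)
    delta = np.zeros(L, dtype=bool)
    beta = np.full(P, config.beta_prior_mean)
    prior_incl = 1.0 / (1.0 + config.prior_odds_neutral)

    def full_ll(lp, al, be):
        return _dominant_loglik(absent, scored, expit(lp), al, be,
                                nodes, logw).sum(axis=1)

    ll = full_ll(logit_p, alpha, beta)
    incl_count = np.zeros(L)
    beta_sum = np.zeros(P)
    n_kept = 0
    total_sweeps = config.burn_in + config.samples
    log_prior_odds_on = np.log(prior_incl / (1.0 - prior_incl))
    for sweep in range(total_sweeps):
        # ancestral frequencies (random-walk on logit scale, per locus)
        prop = logit_p + rng.normal(0.0, config.step_p, size=L)
        ll_prop = full_ll(prop, alpha, beta)
        acc = np.log(rng.random(L)) < (ll_prop - ll)
        logit_p = np.where(acc, prop, logit_p)
        ll = np.where(acc, ll_prop, ll)
        # alpha random walk where included
        if delta.any():
            prop_a = np.where(delta, alpha + rng.normal(0, config.step_alpha, L),
                              alpha)
            ll_prop = full_ll(logit_p, prop_a, beta)
            log_ratio = (ll_prop - ll
                         - 0.5 * (prop_a**2 - alpha**2) / config.alpha_prior_sd**2)
            acc = delta & (np.log(rng.random(L)) < log_ratio)
            alpha = np.where(acc, prop_a, alpha)
            ll = np.where(acc, ll_prop, ll)
        # reversible jump: toggle inclusion, proposing alpha from its prior
        a_new = rng.normal(0.0, config.alpha_prior_sd, size=L)
        prop_a = np.where(delta, 0.0, a_new)
        ll_prop = full_ll(logit_p, prop_a, beta)
        log_acc = np.where(
            delta,
            (ll_prop - ll) - log_prior_odds_on,
            (ll_prop - ll) + log_prior_odds_on,
        )
        acc = np.log(rng.random(L)) < log_acc
        alpha = np.where(acc, prop_a, alpha)
        delta = np.where(acc, ~delta, delta)
        ll = np.where(acc, ll_prop, ll)
        # population effects, one at a time (shared across loci)
        for j in range(P):
            prop_b = beta.copy()
            prop_b[j] += rng.normal(0.0, config.step_beta)
            ll_prop = full_ll(logit_p, alpha, prop_b)
            log_ratio = (ll_prop.sum() - ll.sum()
                         - 0.5 * ((prop_b[j] - config.beta_prior_mean) ** 2
                                  - (beta[j] - config.beta_prior_mean) ** 2)
                         / config.beta_prior_sd**2)
            if np.log(rng.random()) < log_ratio:
                beta = prop_b
                ll = ll_prop
        if sweep >= config.burn_in and (sweep - config.burn_in) % config.thin == 0:
            incl_count += delta
            beta_sum += beta
            n_kept += 1
    post_incl = incl_count / n_kept
    # cap posterior odds at +/- n_kept rather than infinity
    clipped = np.clip(post_incl, 1.0 / (n_kept + 1), n_kept / (n_kept + 1.0))
    po = clipped / (1.0 - clipped)
    log10_po = np.log10(po)
    table = pd.DataFrame({
        "posterior_inclusion": post_incl,
        "log10_PO": log10_po,
        "outlier_bayes": log10_po > 1.5,
    }, index=markers.locus_ids)
    # split-sample disagreement on beta as a crude convergence heuristic
    diagnostics = {"beta_mean": beta_sum / n_kept, "samples_kept": n_kept}
    return BayescanResult(table=table, beta=beta_sum / n_kept,
                          diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Adaptive-locus decision rule
# ---------------------------------------------------------------------------


@dataclass
class AdaptiveLocusCall:
    locus: str
    fdist_outlier: bool
    bayes_outlier: bool
    associated_variables: list[str]
    adaptive: bool


def call_adaptive_loci(
    fdist_flags: pd.Series, bayes_flags: pd.Series,
    associations: pd.DataFrame,
) -> list[AdaptiveLocusCall]:
    """Final decision: adaptive = (outlier by either scan) AND (at least
    one significant environmental association).

    ``associations`` needs columns locus / variable / significant.  The
    two flag series must cover the same locus set.
    """
    if set(fdist_flags.index) != set(bayes_flags.index):
        raise ValueError("scan results cover different locus sets")
    assoc_loci = associations["locus"].unique()
    unknown = set(assoc_loci) - set(fdist_flags.index)
    if unknown:
        raise ValueError(f"association table has unknown loci: {sorted(unknown)}")
    sig = associations[associations["significant"]]
    assoc_of: dict[str, list[str]] = {}
    for _, row in sig.iterrows():
        assoc_of.setdefault(row["locus"], []).append(row["variable"])
    calls = []
    for locus in fdist_flags.index:
        fd = bool(fdist_flags[locus])
        by = bool(bayes_flags[locus])
        assoc = assoc_of.get(locus, [])
        calls.append(AdaptiveLocusCall(
            locus=locus, fdist_outlier=fd, bayes_outlier=by,
            associated_variables=assoc,
            adaptive=(fd or by) and len(assoc) > 0,
        ))
    return calls


def adaptive_call_table(calls: list[AdaptiveLocusCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus": c.locus, "fdist_outlier": c.fdist_outlier,
        "bayes_outlier": c.bayes_outlier,
        "associated_variables": ";".join(c.associated_variables),
        "adaptive": c.adaptive,
    } for c in calls]).set_index("locus")
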
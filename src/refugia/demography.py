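"""Demographic inference from sequence variation.

Covers the classical expansion toolkit: Tajima's D, Fu's Fs (exact Ewens
sampling probabilities via unsigned Stirling numbers), the R2 statistic,
coalescent-simulation p-values, mismatch-distribution model fitting
(sudden demographic expansion, with a spatial-expansion variant) with
SSD / raggedness / Kolmogorov–Smirnov goodness-of-fit by parametric
bootstrap, and conversion of the expansion parameter tau to time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaln, logsumexp

from . import simulate as sim
from .seq_diversity import MismatchSpectrum, harmonic


# ---------------------------------------------------------------------------
# Neutrality statistics
# ---------------------------------------------------------------------------


def tajimas_d(n: int, S: int, k_bar: float) -> float:
    """Tajima's normalized difference between pairwise and Watterson
    estimates of theta.
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S < 1:
        raise ValueError("Tajima's D is undefined when S = 0")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return float((k_bar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1)))


@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log |s(n, k)| for k = 0..n (unsigned first kind), exact integers."""
    row = [0] * (n + 1)
    row[0] = 1  # s(0,0) = 1
    for m in range(1, n + 1):
        new = [0] * (n + 1)
        for k in range(1, m + 1):
            new[k] = row[k - 1] + (m - 1) * row[k]
        row = new
    return tuple(-math.inf if v == 0 else math.log(v) for v in row)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) for k = 0..n under the Ewens formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = np.array(_log_stirling_row(n))
    k = np.arange(n + 1)
    log_rising = sum(math.log(theta + i) for i in range(n))
    return logs + k * math.log(theta) - log_rising


def fus_fs(n: int, k_obs: int, theta_hat: float) -> float:
    """Fu's Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta, n).

    Computed from exact Ewens sampling probabilities in log space;
    returns +/- inf when S' hits 0 or 1 to machine precision.
    """
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must lie in [1, n]")
    logp = ewens_log_pmf(n, theta_hat)
    log_sp = logsumexp(logp[k_obs:])
    log_sm = logsumexp(logp[1:k_obs]) if k_obs > 1 else -np.inf
    if log_sm == -np.inf:
        return math.inf if log_sp == 0.0 else float(log_sp - np.log1p(-np.exp(log_sp)))
    return float(log_sp - log_sm)


def r2_statistic(singletons: np.ndarray, k_bar: float, S: int, n: int) -> float:
    """Ramos-Onsins & Rozas R2: sqrt(mean (U_i - k_bar/2)^2) / S."""
    if S < 1:
        raise ValueError("R2 is undefined when S = 0")
    U = np.asarray(singletons, dtype=float)
    if len(U) != n:
        raise ValueError("need one singleton count per sequence")
    return float(np.sqrt(np.mean((U - k_bar / 2.0) ** 2)) / S)


# ---------------------------------------------------------------------------
# Coalescent-simulation p-values
# ---------------------------------------------------------------------------


@dataclass
class CoalescentNullConfig:
    """How the constant-size null for neutrality tests is generated.

    fixed-S draws the conditional distribution given the observed number
    of segregating sites: genealogies are importance-resampled with
    weight Poisson(S; theta_W L/2) before exactly S mutations are placed
    by branch length (plain uniform placement over unweighted genealogies
    is slightly conservative for Fs and R2).  fixed-theta draws Poisson
    mutation numbers at a supplied theta.
    """

    replicates: int = 1000
    conditioning: str = "fixed-S"  # or "fixed-theta"
    theta: float | None = None
    pool_size: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replicates < 100:
            raise ValueError("at least 100 replicates required for p-values")
        if self.conditioning not in ("fixed-S", "fixed-theta"):
            raise ValueError("conditioning must be fixed-S or fixed-theta")


@dataclass
class NeutralityResult:
    n: int
    S: int
    k_bar: float
    n_haplotypes: int
    tajimas_D: float
    fus_Fs: float
    R2: float
    p_D: float | None = None
    p_Fs: float | None = None
    p_R2: float | None = None
    replicates: int = 0


def _stats_from_summary(s: sim.SampleSummary) -> tuple[float, float, float]:
    D = tajimas_d(s.n, s.S, s.k_bar) if s.S >= 1 else np.nan
    theta = max(s.k_bar, 1e-9)
    Fs = fus_fs(s.n, s.n_haplotypes, theta)
    R2 = r2_statistic(s.singletons, s.k_bar, s.S, s.n) if s.S >= 1 else np.nan
    return D, Fs, R2


def genealogy_pool(n: int, size: int, rng: np.random.Generator
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pool of constant-size genealogies, reusable across null tables
    (the standard coalescent genealogy law does not depend on theta)."""
    return [sim.sim_tree(n, rng) for _ in range(size)]


def null_statistic_table(
    n: int, config: CoalescentNullConfig, S: int | None = None,
    rng: np.random.Generator | None = None,
    pool: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """(replicates, 3) array of simulated (D, Fs, R2) under the null."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = np.empty((config.replicates, 3))
    if config.conditioning == "fixed-S":
        from scipy.stats import poisson
        if S is None or S < 1:
            raise ValueError("fixed-S conditioning needs the observed S")
        theta = config.theta if config.theta else S / harmonic(n)
        if pool is None:
            pool = genealogy_pool(n, config.pool_size, rng)
        lengths_tot = np.array([p[1].sum() for p in pool])
        w = poisson.pmf(S, theta * lengths_tot / 2.0)
        if w.sum() <= 0:
            w = np.ones(len(pool))
        w = w / w.sum()
        idx = rng.choice(len(pool), size=config.replicates, p=w)
        for b, i in enumerate(idx):
            sets, lengths = pool[i]
            muts = sim.drop_mutations_fixed_s(sets, lengths, int(S), rng)
            out[b] = _stats_from_summary(sim.summarize_mutations(muts, n))
        return out
    if config.theta is None:
        raise ValueError("fixed-theta conditioning needs theta")
    b = 0
    while b < config.replicates:
        sets, lengths = sim.sim_tree(n, rng)
        muts = sim.drop_mutations_theta(sets, lengths, config.theta, rng)
        out[b] = _stats_from_summary(sim.summarize_mutations(muts, n))
        b += 1
    return out


def neutrality_tests(
    n: int, S: int, k_bar: float, n_haplotypes: int, singletons: np.ndarray,
    config: CoalescentNullConfig | None = None,
    rng: np.random.Generator | None = None,
) -> NeutralityResult:
    """Observed D / Fs / R2 with left-tail coalescent p-values.

    Small values of each statistic indicate expansion, so
    p = P(stat_sim <= stat_obs) with a +1 pseudocount.
    """
    D = tajimas_d(n, S, k_bar)
    Fs = fus_fs(n, n_haplotypes, max(k_bar, 1e-9))
    R2 = r2_statistic(singletons, k_bar, S, n)
    res = NeutralityResult(n=n, S=S, k_bar=k_bar, n_haplotypes=n_haplotypes,
                           tajimas_D=D, fus_Fs=Fs, R2=R2)
    if config is not None:
        table = null_statistic_table(n, config, S=S, rng=rng)
        B = len(table)
        with np.errstate(invalid="ignore"):
            res.p_D = float((np.sum(table[:, 0] <= D) + 1) / (B + 1))
            res.p_Fs = float((np.sum(table[:, 1] <= Fs) + 1) / (B + 1))
            res.p_R2 = float((np.sum(table[:, 2] <= R2) + 1) / (B + 1))
        res.replicates = B
    return res


# ---------------------------------------------------------------------------
# Mismatch-distribution expansion models
# ---------------------------------------------------------------------------


def stationary_mismatch(theta: float, j: np.ndarray) -> np.ndarray:
    """Equilibrium mismatch probabilities theta^j / (1+theta)^(j+1)."""
    theta = max(theta, 1e-12)
    return np.exp(j * math.log(theta) - (j + 1) * math.log1p(theta))


def expected_mismatch_sudden(tau: float, theta0: float, theta1: float,
                             d_max: int) -> np.ndarray:
    """Expected mismatch probabilities for classes 0..d_max under a sudden
    (stepwise) demographic expansion.

    Derivation: a pair coalesces at hazard 1/theta1 in the recent epoch
    (measured in expected-pairwise-difference units), and at hazard
    1/theta0 beyond tau; mutations are Poisson with mean equal to the
    coalescence time on that scale.  Classes are renormalized over
    0..d_max for comparison with an observed spectrum.
    """
    j = np.arange(d_max + 1)
    theta1 = max(theta1, 1e-9)
    theta0 = max(theta0, 1e-12)
    lam1 = 1.0 + 1.0 / theta1
    recent = stationary_mismatch(theta1, j) * gammainc(j + 1, lam1 * tau)
    anc = stationary_mismatch(theta0, j)
    older = np.zeros_like(recent)
    if tau > 0:
        log_tau_pow = j * math.log(tau) - gammaln(j + 1)
        weights = np.exp(log_tau_pow - lam1 * tau)
    else:
        weights = np.zeros(d_max + 1)
        weights[0] = 1.0
    for jj in range(d_max + 1):
        older[jj] = np.sum(weights[: jj + 1][::-1] * anc[: jj + 1])
    probs = recent + older
    total = probs.sum()
    return probs / total if total > 0 else probs


def expected_mismatch_spatial(tau: float, theta: float, M: float,
                              d_max: int) -> np.ndarray:
    """Expected mismatch under an infinite-island spatial expansion.

    A within-deme pair either coalesces (hazard 1/theta) or splits into
    different demes (hazard M/theta, irreversibly under infinite islands)
    during the recent epoch; at tau everything collapses into a single
    ancestral deme of size theta.
    """
    j = np.arange(d_max + 1)
    theta = max(theta, 1e-9)
    M = max(M, 0.0)
    lam = 1.0 + (1.0 + M) / theta
    # coalesced within the deme before tau
    within = (1.0 / theta) * lam ** -(j + 1.0) * gammainc(j + 1, lam * tau)
    # survived to tau (still same deme, or already separated), then the
    # single ancestral deme applies; mutations from the recent epoch are
    # Poisson(tau)
    p_surv_same = math.exp(-(1.0 + M) * tau / theta)
    p_sep = (M / (1.0 + M)) * (1.0 - p_surv_same) if M > 0 else 0.0
    anc = stationary_mismatch(theta, j)
    if tau > 0:
        weights = np.exp(j * math.log(tau) - gammaln(j + 1) - tau)
    else:
        weights = np.zeros(d_max + 1)
        weights[0] = 1.0
    older = np.zeros(d_max + 1)
    for jj in range(d_max + 1):
        older[jj] = np.sum(weights[: jj + 1][::-1] * anc[: jj + 1])
    probs = within + (p_surv_same + p_sep) * older
    total = probs.sum()
    return probs / total if total > 0 else probs


def raggedness(frequencies: np.ndarray) -> float:
    """Harpending's raggedness: sum of squared successive differences of
    the mismatch frequency classes."""
    x = np.asarray(frequencies, dtype=float)
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    SSD: float
    raggedness_rg: float
    model: str = "sudden-demographic"
    M: float | None = None
    p_SSD: float | None = None
    p_rg: float | None = None
    bootstrap_B: int = 0
    expected: np.ndarray | None = None


THETA1_MAX = 1e5


def _model_spectrum(params: np.ndarray, model: str, d_max: int) -> np.ndarray:
    if model == "sudden-demographic":
        tau, th0, th1 = params
        return expected_mismatch_sudden(tau, th0, th1, d_max)
    tau, th, M = params
    return expected_mismatch_spatial(tau, th, M, d_max)


def fit_mismatch_expansion(
    spectrum: MismatchSpectrum,
    model: str = "sudden-demographic",
    bootstrap_B: int = 0,
    rng: np.random.Generator | None = None,
) -> ExpansionFit:
    """Least-squares fit of an expansion model to a mismatch spectrum.

    Minimizes SSD between observed and expected class frequencies from a
    coarse grid start followed by bounded Nelder–Mead refinement.
    Optional parametric bootstrap (coalescent replicates under the fitted
    sudden-expansion model, each refitted) supplies p-values for SSD and
    raggedness.
    """
    f_obs = spectrum.frequencies
    d_max = spectrum.d_max
    if np.count_nonzero(f_obs) < 2:
        raise ValueError("degenerate spectrum: a single occupied class")
    k_bar = spectrum.mean()

    def ssd(params: np.ndarray) -> float:
        return float(np.sum((f_obs - _model_spectrum(params, model, d_max)) ** 2))

    taus = np.linspace(0.1, max(d_max, 1.0), 12)
    if model == "sudden-demographic":
        starts = [(t, th0, th1)
                  for t in taus
                  for th0 in (0.01, max(k_bar, 0.02))
                  for th1 in (max(2 * k_bar, 1.0), 50.0, THETA1_MAX / 10)]
        bounds = [(0.0, 4.0 * max(d_max, 1)), (0.0, THETA1_MAX), (1e-6, THETA1_MAX)]
    elif model == "spatial":
        starts = [(t, th, M)
                  for t in taus
                  for th in (0.5, max(k_bar, 0.05), 10.0)
                  for M in (0.5, 5.0, 50.0)]
        bounds = [(0.0, 4.0 * max(d_max, 1)), (1e-6, THETA1_MAX), (0.0, 1e4)]
    else:
        raise ValueError(f"unknown model {model!r}")
    best = min(starts, key=lambda p: ssd(np.array(p)))
    res = minimize(ssd, np.array(best), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 4000})
    x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    ssd_val = ssd(x)
    rg = raggedness(f_obs)
    if model == "sudden-demographic":
        fit = ExpansionFit(tau=float(x[0]), theta0=float(x[1]), theta1=float(x[2]),
                           SSD=ssd_val, raggedness_rg=rg, model=model,
                           expected=_model_spectrum(x, model, d_max))
    else:
        fit = ExpansionFit(tau=float(x[0]), theta0=float(x[1]), theta1=float(x[1]),
                           M=float(x[2]), SSD=ssd_val, raggedness_rg=rg,
                           model=model, expected=_model_spectrum(x, model, d_max))
    if bootstrap_B > 0:
        if rng is None:
            rng = np.random.default_rng()
        n = _n_from_pairs(spectrum.n_pairs)
        ssd_sim = np.empty(bootstrap_B)
        rg_sim = np.empty(bootstrap_B)
        for b in range(bootstrap_B):
            spec_b = _simulate_fitted_spectrum(fit, n, rng)
            try:
                fit_b = fit_mismatch_expansion(spec_b, model=model)
                ssd_sim[b] = fit_b.SSD
                rg_sim[b] = fit_b.raggedness_rg
            except ValueError:
                ssd_sim[b] = 0.0
                rg_sim[b] = 0.0
        fit.p_SSD = float((np.sum(ssd_sim >= ssd_val) + 1) / (bootstrap_B + 1))
        fit.p_rg = float((np.sum(rg_sim >= rg) + 1) / (bootstrap_B + 1))
        fit.bootstrap_B = bootstrap_B
    return fit


def _n_from_pairs(n_pairs: int) -> int:
    n = int(round((1 + math.sqrt(1 + 8 * n_pairs)) / 2))
    if n * (n - 1) // 2 != n_pairs:
        raise ValueError("pair total does not correspond to an integer n")
    return n


def _simulate_fitted_spectrum(fit: ExpansionFit, n: int,
                              rng: np.random.Generator) -> MismatchSpectrum:
    theta1 = max(fit.theta1, 1e-3)
    growth = min(theta1 / max(fit.theta0, 1e-6), 1e6)
    expansion = (fit.tau / theta1, growth) if fit.tau > 0 else None
    sets, lengths = sim.sim_tree(n, rng, expansion)
    muts = sim.drop_mutations_theta(sets, lengths, theta1, rng)
    return MismatchSpectrum(counts=sim.mismatch_counts_from_mutations(muts, n))


def mismatch_ks_test(
    spectrum: MismatchSpectrum, fitted: ExpansionFit,
    bootstrap_B: int = 0, rng: np.random.Generator | None = None,
) -> tuple[float, float | None]:
    """Maximum CDF distance between observed and fitted mismatch
    distributions, with an optional parametric-bootstrap p-value."""
    f_obs = spectrum.frequencies
    f_exp = fitted.expected
    if f_exp is None:
        raise ValueError("fit carries no expected spectrum")
    d_obs = float(np.max(np.abs(np.cumsum(f_obs) - np.cumsum(f_exp))))
    if bootstrap_B == 0:
        return d_obs, None
    if rng is None:
        rng = np.random.default_rng()
    n = _n_from_pairs(spectrum.n_pairs)
    d_sim = np.empty(bootstrap_B)
    for b in range(bootstrap_B):
        spec_b = _simulate_fitted_spectrum(fitted, n, rng)
        try:
            fit_b = fit_mismatch_expansion(spec_b, model=fitted.model)
            fb = np.asarray(fit_b.expected)
            ob = spec_b.frequencies
            m = max(len(fb), len(ob))
            fb = np.pad(fb, (0, m - len(fb)))
            ob = np.pad(ob, (0, m - len(ob)))
            d_sim[b] = np.max(np.abs(np.cumsum(ob) - np.cumsum(fb)))
        except ValueError:
            d_sim[b] = 0.0
    p = float((np.sum(d_sim >= d_obs) + 1) / (bootstrap_B + 1))
    return d_obs, p


# ---------------------------------------------------------------------------
# Expansion dating
# ---------------------------------------------------------------------------


@dataclass
class DatingResult:
    """t = tau / (2 mu k) on the generation scale, with the year scale
    alongside (t_years = t_generations * generation time)."""

    tau: float
    t_generations: float
    t_years: float
    mu_per_site_per_year: float
    generation_time_years: float
    k_sites: int
    ci_generations: tuple[float, float] | None = None
    ci_years: tuple[float, float] | None = None


def date_expansion(
    tau: float,
    mu_per_site_per_year: float,
    generation_time_years: float,
    k_sites: int,
    tau_ci: tuple[float, float] | None = None,
) -> DatingResult:
    """Convert the expansion parameter tau to elapsed time.

    With a per-generation mutation rate mu_g = mu_per_year * generation
    time, t_generations = tau / (2 mu_g k); a confidence interval for tau
    maps through the same linear transform.
    """
    if mu_per_site_per_year <= 0 or generation_time_years <= 0 or k_sites <= 0:
        raise ValueError("rates, generation time and k must be positive")
    mu_gen = mu_per_site_per_year * generation_time_years
    denom = 2.0 * mu_gen * k_sites
    t_gen = tau / denom
    res = DatingResult(
        tau=tau,
        t_generations=t_gen,
        t_years=t_gen * generation_time_years,
        mu_per_site_per_year=mu_per_site_per_year,
        generation_time_years=generation_time_years,
        k_sites=k_sites,
    )
    if tau_ci is not None:
        lo, hi = tau_ci
        res.ci_generations = (lo / denom, hi / denom)
        res.ci_years = (lo / denom * generation_time_years,
                        hi / denom * generation_time_years)
    return res
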
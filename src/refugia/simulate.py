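"""Synthetic data generators.

Three generators mirror the structure of the real study system:

* an n-coalescent sequence simulator with infinite-sites mutation, under
  constant size or a sudden (stepwise) demographic expansion — the
  substrate for diversity statistics, neutrality tests and mismatch fits;
* a Balding–Nichols island-model dominant-marker (AFLP-style) simulator
  with optional loci whose allele frequencies track an environmental
  gradient — the substrate for FST, outlier scans and association tests;
* a spatially structured environmental-covariate generator.

All generators are deterministic given their seed/rng.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import AlignedSequenceSet, BinaryMarkerMatrix, EnvTable, HaplotypeTable

# ---------------------------------------------------------------------------
# Coalescent machinery
# ---------------------------------------------------------------------------


@dataclass
class CoalescentConfig:
    """Sequence-simulation settings.

    theta is the per-locus scaled mutation rate (4*N_now*u aggregated over
    the locus).  Under ``sudden-expansion`` the population was smaller by
    ``growth_factor`` before ``tau_mut`` (expansion age in mutational
    units, i.e. the expected pairwise differences accumulated since it).
    """

    n: int = 20
    theta: float = 5.0
    sites: int = 500
    demography: str = "constant"  # or "sudden-expansion"
    tau_mut: float = 2.0
    growth_factor: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2 or self.theta <= 0 or self.sites < 1:
            raise ValueError("n >= 2, theta > 0 and sites >= 1 required")
        if self.demography not in ("constant", "sudden-expansion"):
            raise ValueError(f"unknown demography {self.demography!r}")


def sim_tree(
    n: int,
    rng: np.random.Generator,
    expansion: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One coalescent genealogy.

    Returns (branch_sets, branch_lengths): a boolean (2n-2, n) matrix of
    leaf sets subtended by each branch and lengths in coalescent units
    (2*N_now generations).  ``expansion=(t_e, growth)`` multiplies the
    coalescence rate by ``growth`` further back than ``t_e``.
    """
    sets = np.zeros((2 * n - 2, n), dtype=bool)
    lengths = np.zeros(2 * n - 2)
    active: list[np.ndarray] = [np.eye(n, dtype=bool)[i] for i in range(n)]
    birth: list[float] = [0.0] * n
    slots: list[int] = list(range(n))
    for i in range(n):
        sets[i] = active[i]
    next_slot = n
    t = 0.0
    k = n
    while k > 1:
        base_rate = k * (k - 1) / 2.0
        if expansion is None:
            t += rng.exponential(1.0 / base_rate)
        else:
            t_e, growth = expansion
            w = rng.exponential(1.0 / base_rate)
            if t >= t_e:
                t += w / growth
            elif t + w <= t_e:
                t += w
            else:
                # crossed the size change: rescale the residual wait
                t = t_e + (w - (t_e - t)) / growth
        i, j = sorted(rng.choice(k, size=2, replace=False))
        lengths[slots[i]] = t - birth[i]
        lengths[slots[j]] = t - birth[j]
        merged = active[i] | active[j]
        active[i] = merged
        birth[i] = t
        del active[j], birth[j]
        if k > 2:
            slots[i] = next_slot
            sets[next_slot] = merged
            next_slot += 1
        del slots[j]
        k -= 1
    return sets, lengths


def drop_mutations_theta(
    sets: np.ndarray, lengths: np.ndarray, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson(theta * length / 2) infinite-sites mutations per branch.

    Returns a boolean (S, n) matrix; row s marks the leaves carrying
    mutation s.
    """
    counts = rng.poisson(theta * lengths / 2.0)
    if counts.sum() == 0:
        return np.zeros((0, sets.shape[1]), dtype=bool)
    return np.repeat(sets, counts, axis=0)


def drop_mutations_fixed_s(
    sets: np.ndarray, lengths: np.ndarray, S: int, rng: np.random.Generator
) -> np.ndarray:
    """Place exactly S mutations, each on a branch chosen by length."""
    if S == 0:
        return np.zeros((0, sets.shape[1]), dtype=bool)
    probs = lengths / lengths.sum()
    chosen = rng.choice(len(lengths), size=S, p=probs)
    return sets[chosen]


@dataclass
class SampleSummary:
    """Summary statistics of one simulated (or observed) sample."""

    n: int
    S: int
    k_bar: float
    n_haplotypes: int
    singletons: np.ndarray  # U_i per sequence (folded)


def summarize_mutations(muts: np.ndarray, n: int) -> SampleSummary:
    """S, mean pairwise differences, haplotype count and folded singletons
    from a mutation incidence matrix (S, n)."""
    S = muts.shape[0]
    if S == 0:
        return SampleSummary(n=n, S=0, k_bar=0.0, n_haplotypes=1,
                             singletons=np.zeros(n, dtype=int))
    c = muts.sum(axis=1)
    k_bar = float((c * (n - c)).sum() / (n * (n - 1) / 2.0))
    n_hap = len(np.unique(muts.T, axis=0))
    U = np.zeros(n, dtype=int)
    for s in range(S):
        if c[s] == 1:
            U[int(np.argmax(muts[s]))] += 1
        elif c[s] == n - 1:
            U[int(np.argmin(muts[s]))] += 1
    return SampleSummary(n=n, S=int(S), k_bar=k_bar, n_haplotypes=int(n_hap),
                         singletons=U)


def mismatch_counts_from_mutations(muts: np.ndarray, n: int) -> np.ndarray:
    """Pairwise-difference spectrum counts (class 0 upward)."""
    if muts.shape[0] == 0:
        return np.array([n * (n - 1) // 2], dtype=float)
    m = muts.astype(np.int32)
    # differences between i and j = number of rows where entries differ
    same = m.T @ m  # shared mutations
    tot = m.sum(axis=0)
    d = tot[:, None] + tot[None, :] - 2 * same
    iu = np.triu_indices(n, k=1)
    return np.bincount(d[iu].astype(int)).astype(float)


def simulate_coalescent_alignment(config: CoalescentConfig,
                                  rng: np.random.Generator | None = None
                                  ) -> AlignedSequenceSet:
    """Simulate an aligned sample of sequences under the coalescent.

    Mutations land on distinct columns of a monomorphic background
    (infinite sites); raises if the requested length cannot hold the
    realized number of segregating sites.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    expansion = None
    if config.demography == "sudden-expansion":
        expansion = (config.tau_mut / config.theta, config.growth_factor)
    sets, lengths = sim_tree(config.n, rng, expansion)
    muts = drop_mutations_theta(sets, lengths, config.theta, rng)
    S = muts.shape[0]
    if S > config.sites:
        raise ValueError(
            f"{S} segregating sites realized but only {config.sites} columns"
        )
    base = np.full((config.n, config.sites), "A", dtype="U1")
    positions = rng.choice(config.sites, size=S, replace=False)
    alt = rng.choice(np.array(["C", "G", "T"]), size=S)
    for s in range(S):
        base[muts[s], positions[s]] = alt[s]
    ids = [f"s{i + 1}" for i in range(config.n)]
    popmap = {i: "pop1" for i in ids}
    return AlignedSequenceSet(
        sample_ids=ids,
        sequences=["".join(row) for row in base],
        population_of=popmap,
    )


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------


ENV_VARIABLE_NAMES = ["BIO1", "BIO12", "wet_days", "WS_mean", "NDVI",
                      "soil_pH", "TMI"]


@dataclass
class EnvSimConfig:
    """Spatially structured covariates over P sampling localities.

    Each variable is gradient * (standardized position along the sampling
    transect) + Gaussian noise; lon/lat are included as geography.
    """

    n_populations: int = 8
    n_variables: int = 7
    gradient_strength: float = 1.0
    noise_sd: float = 0.5
    coords: np.ndarray | None = None  # (P, 2) lon/lat
    seed: int | None = None


def simulate_env(config: EnvSimConfig,
                 rng: np.random.Generator | None = None) -> EnvTable:
    if rng is None:
        rng = np.random.default_rng(config.seed)
    P = config.n_populations
    if config.coords is not None:
        coords = np.asarray(config.coords, dtype=float)
    else:
        lon = np.linspace(120.2, 121.8, P)
        lat = np.linspace(22.2, 24.9, P)
        coords = np.column_stack([lon, lat])
    pos = coords @ np.array([1.0, 1.0])
    z = (pos - pos.mean()) / pos.std() if pos.std() > 0 else np.zeros(P)
    names = (ENV_VARIABLE_NAMES[: config.n_variables]
             if config.n_variables <= len(ENV_VARIABLE_NAMES)
             else [f"env{i + 1}" for i in range(config.n_variables)])
    data = {}
    for v, name in enumerate(names):
        sign = 1.0 if v % 2 == 0 else -1.0
        data[name] = (sign * config.gradient_strength * z
                      + rng.normal(0.0, config.noise_sd, size=P))
    df = pd.DataFrame(data, index=[f"pop{i + 1}" for i in range(P)])
    df["lon"] = coords[:, 0]
    df["lat"] = coords[:, 1]
    return EnvTable(data=df, variables=names)


# ---------------------------------------------------------------------------
# Dominant markers (AFLP-style)
# ---------------------------------------------------------------------------


@dataclass
class AflpSimConfig:
    """Island-model dominant-marker simulation.

    Neutral loci: ancestral band-allele frequency drawn from
    Beta(prior_a, prior_b) restricted to (0.05, 0.95); per-population
    frequencies follow the Balding–Nichols distribution at
    ``background_fst``.  Planted loci instead track an environmental
    variable: logit(p_j) = logit(p_ancestral) + coeff * standardized env.
    Band phenotype per individual: Bernoulli(1 - (1 - p)^2).
    """

    n_populations: int = 8
    n_per_population: int = 15
    n_loci: int = 500
    background_fst: float = 0.15
    planted: list[tuple[int, str, float]] = field(default_factory=list)
    prior_a: float = 1.0
    prior_b: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.background_fst < 1:
            raise ValueError("background_fst must be in (0, 1)")
        for idx, _, _ in self.planted:
            if not 0 <= idx < self.n_loci:
                raise ValueError("planted locus index out of range")


def balding_nichols_freqs(p_bar: np.ndarray, fst: float,
                          size: tuple[int, ...],
                          rng: np.random.Generator) -> np.ndarray:
    """Per-population allele frequencies around p_bar at a given FST."""
    ratio = (1.0 - fst) / fst
    return rng.beta(np.broadcast_to(p_bar * ratio, size),
                    np.broadcast_to((1.0 - p_bar) * ratio, size))


def _ancestral_band_freqs(L: int, a: float, b: float,
                          rng: np.random.Generator) -> np.ndarray:
    out = np.empty(L)
    filled = 0
    while filled < L:
        draw = rng.beta(a, b, size=L)
        keep = draw[(draw > 0.05) & (draw < 0.95)]
        take = min(L - filled, keep.size)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def simulate_aflp(config: AflpSimConfig, env: EnvTable,
                  rng: np.random.Generator | None = None
                  ) -> tuple[BinaryMarkerMatrix, pd.DataFrame]:
    """Dominant marker matrix plus a truth table of planted loci."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    P, m, L = config.n_populations, config.n_per_population, config.n_loci
    if len(env.unit_ids) != P:
        raise ValueError("environment table rows must match n_populations")
    p_bar = _ancestral_band_freqs(L, config.prior_a, config.prior_b, rng)
    freqs = balding_nichols_freqs(p_bar, config.background_fst, (P, L), rng)
    truth_rows = []
    envdf = env.data
    for idx, var, coeff in config.planted:
        z = envdf[var].to_numpy(dtype=float)
        z = (z - z.mean()) / z.std()
        freqs[:, idx] = expit(logit(p_bar[idx]) + coeff * z)
        truth_rows.append({"locus": f"L{idx + 1}", "variable": var,
                           "coefficient": coeff})
    band_prob = 1.0 - (1.0 - freqs) ** 2
    calls = np.empty((P * m, L))
    ind_ids, popmap = [], {}
    pops = env.unit_ids
    for j in range(P):
        calls[j * m:(j + 1) * m] = (
            rng.random((m, L)) < band_prob[j][None, :]
        ).astype(float)
        for i in range(m):
            sid = f"{pops[j]}_i{i + 1}"
            ind_ids.append(sid)
            popmap[sid] = pops[j]
    markers = BinaryMarkerMatrix(
        individual_ids=ind_ids,
        locus_ids=[f"L{k + 1}" for k in range(L)],
        calls=calls,
        population_of=popmap,
    )
    truth = pd.DataFrame(truth_rows, columns=["locus", "variable", "coefficient"])
    return markers, truth


# ---------------------------------------------------------------------------
# Printed reference table fixture
# ---------------------------------------------------------------------------

_TABLE1_COUNTS: dict[str, dict[str, int]] = {
    "Beishi": {"I": 6, "Id": 2, "IIc": 2, "IId": 2},
    "Guanhu": {"I": 8, "Ig": 2, "IIb": 2},
    "Sandimen": {"I": 12},
    "Shanmai": {"I": 4, "Ic": 2, "Ij": 2, "II": 2},
    "Shitou": {"I": 4, "Ia": 2, "Ib": 2, "Ih": 2, "II": 2},
    "Shouka": {"I": 9, "II": 3},
    "Wufeng": {"I": 4, "Ie": 1, "If": 1, "Ii": 2, "IIa": 2},
    "Wulai": {"I": 8, "II": 4},
}

_TABLE1_SUMMARY = pd.DataFrame(
    {
        "n_sequences": [12, 12, 12, 10, 12, 12, 10, 12],
        "Hd": [0.727, 0.545, 0.0, 0.800, 0.848, 0.409, 0.822, 0.485],
        "theta_pi": [0.00173, 0.00096, 0.0, 0.00141, 0.00144, 0.00097,
                     0.00157, 0.00115],
        "theta_S": [0.00157, 0.00105, 0.0, 0.00140, 0.00157, 0.00079,
                    0.00168, 0.00079],
    },
    index=["Beishi", "Guanhu", "Sandimen", "Shanmai", "Shitou", "Shouka",
           "Wufeng", "Wulai"],
)


def make_table1_fixture() -> HaplotypeTable:
    """Eight-population haplotype count table of the study locus
    (92 sequences, 16 haplotypes), as printed."""
    pops = list(_TABLE1_COUNTS)
    hap_order: list[str] = []
    for counts in _TABLE1_COUNTS.values():
        for h in counts:
            if h not in hap_order:
                hap_order.append(h)
    hap_order = sorted(hap_order, key=lambda h: (len(h.split("I")[0]), h))
    # keep a stable, readable order: I-group then II-group
    ones = [h for h in hap_order if not h.startswith("II")]
    twos = [h for h in hap_order if h.startswith("II")]
    hap_order = sorted(ones) + sorted(twos)
    counts = pd.DataFrame(
        [[_TABLE1_COUNTS[p].get(h, 0) for p in pops] for h in hap_order],
        index=hap_order,
        columns=pops,
    )
    return HaplotypeTable(haplotype_ids=hap_order, counts=counts)


def table1_reference() -> pd.DataFrame:
    """Printed per-population summaries (n, Hd, theta_pi, theta_S) of the
    study locus, used as inputs for desk-scale reproduction checks."""
    return _TABLE1_SUMMARY.copy()
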
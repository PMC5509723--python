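"""Per-locus logistic regression of marker presence on environmental
variables, with Wald and likelihood-ratio tests, Nagelkerke pseudo-R2 and
Bonferroni family-wise control.

Individuals inherit the environmental values of their population (the
sampling design provides covariates per locality).  Fitting uses a
vectorized Newton / iteratively-reweighted-least-squares core so an
entire locus panel is fitted simultaneously for each variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .datatypes import BinaryMarkerMatrix, EnvTable

_MAX_ABS_BETA = 15.0


@dataclass
class LogisticFit:
    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    LL0: float
    LL1: float
    wald_p: float
    g_p: float
    nagelkerke_r2: float
    n: int
    converged: bool
    separated: bool


def _null_loglik(y_sum: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Intercept-only log-likelihood, closed form."""
    p = y_sum / n
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = y_sum * np.log(p) + (n - y_sum) * np.log1p(-p)
    return np.where((y_sum == 0) | (y_sum == n), 0.0, ll)


def _newton_many(Y: np.ndarray, x: np.ndarray, obs: np.ndarray,
                 tol: float = 1e-8, max_iter: int = 60):
    """Simultaneous Newton fits of logit(P(Y=1)) = b0 + b1 x per column.

    Y: (n, L) binary responses (NaN allowed where obs == 0);
    x: (n,) shared predictor; obs: (n, L) 0/1 observation mask.
    Returns (b0, b1, se0, se1, LL1, converged) arrays of length L.
    """
    n, L = Y.shape
    Yf = np.nan_to_num(Y) * obs
    b0 = np.zeros(L)
    b1 = np.zeros(L)
    converged = np.zeros(L, dtype=bool)
    for _ in range(max_iter):
        eta = b0[None, :] + np.outer(x, b1)
        mu = expit(eta)
        W = mu * (1.0 - mu) * obs
        resid = (Yf - mu * obs)
        g0 = resid.sum(axis=0)
        g1 = (resid * x[:, None]).sum(axis=0)
        s00 = W.sum(axis=0)
        s01 = (W * x[:, None]).sum(axis=0)
        s11 = (W * (x**2)[:, None]).sum(axis=0)
        det = s00 * s11 - s01**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        d0 = (s11 * g0 - s01 * g1) / det
        d1 = (s00 * g1 - s01 * g0) / det
        # damp steps so separated fits walk out gracefully
        step = np.sqrt(d0**2 + d1**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(step > 5.0, 5.0 / step, 1.0)
        d0, d1 = d0 * scale, d1 * scale
        d0 = np.nan_to_num(d0)
        d1 = np.nan_to_num(d1)
        active = ~converged
        b0 = b0 + d0 * active
        b1 = b1 + d1 * active
        converged = converged | (np.maximum(np.abs(d0), np.abs(d1)) < tol)
        if converged.all():
            break
    eta = b0[None, :] + np.outer(x, b1)
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    LL1 = (obs * (Yf * np.log(mu) + (obs - Yf) * np.log1p(-mu))).sum(axis=0)
    W = mu * (1.0 - mu) * obs
    s00 = W.sum(axis=0)
    s01 = (W * x[:, None]).sum(axis=0)
    s11 = (W * (x**2)[:, None]).sum(axis=0)
    det = s00 * s11 - s01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se0 = np.sqrt(s11 / det)
        se1 = np.sqrt(s00 / det)
    # complete separation: the ML solution diverges, so a non-converged
    # fit that already classifies every observation perfectly is flagged
    perfect = (np.abs(Yf - mu * obs) < 1e-3).all(axis=0)
    separated = (np.abs(b1) > _MAX_ABS_BETA) | (~converged & perfect) | \
        ~np.isfinite(se1)
    return b0, b1, se0, se1, LL1, converged, separated


def nagelkerke_r2(LL0: float, LL1: float, n: int) -> float:
    """Cox–Snell R2 rescaled to its attainable maximum:
    R2_CS / (1 - exp(2 LL0 / n))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    r2_cs = 1.0 - np.exp(2.0 * (LL0 - LL1) / n)
    denom = 1.0 - np.exp(2.0 * LL0 / n)
    if denom <= 0:
        return 0.0
    return float(r2_cs / denom)


def fit_logistic(y: np.ndarray, x: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary response on one
    predictor, with Wald and likelihood-ratio (G) chi-square tests.

    Complete separation is reported via the ``separated`` flag (the Wald
    test is then meaningless; the G test remains usable).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    obs = np.ones((n, 1))
    b0, b1, se0, se1, LL1, conv, sep = _newton_many(y[:, None], x, obs)
    LL0 = float(_null_loglik(np.array([y.sum()]), np.array([float(n)]))[0])
    separated = bool(sep[0])
    wald = (b1[0] / se1[0]) ** 2 if np.isfinite(se1[0]) and se1[0] > 0 else np.inf
    G = max(2.0 * (LL1[0] - LL0), 0.0)
    return LogisticFit(
        beta0=float(b0[0]), beta1=float(b1[0]),
        se_beta0=float(se0[0]), se_beta1=float(se1[0]),
        LL0=LL0, LL1=float(LL1[0]),
        wald_p=float(chi2.sf(wald, 1)),
        g_p=float(chi2.sf(G, 1)),
        nagelkerke_r2=nagelkerke_r2(LL0, float(LL1[0]), n),
        n=n, converged=bool(conv[0]), separated=separated,
    )


def fit_logistic_firth(y: np.ndarray, x: np.ndarray,
                       max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Penalized-likelihood (Firth) fit — finite estimates under complete
    separation.  Single-model fallback, flagged in scan output."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        W = mu * (1 - mu)
        XtW = X.T * W
        info = XtW @ X
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * W
        U = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ U
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    LL1 = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    LL0 = float(_null_loglik(np.array([y.sum()]), np.array([float(n)]))[0])
    W = mu * (1 - mu)
    info = (X.T * W) @ X
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    wald = (beta[1] / se[1]) ** 2
    G = max(2.0 * (LL1 - LL0), 0.0)
    return LogisticFit(
        beta0=float(beta[0]), beta1=float(beta[1]),
        se_beta0=float(se[0]), se_beta1=float(se[1]),
        LL0=LL0, LL1=LL1,
        wald_p=float(chi2.sf(wald, 1)), g_p=float(chi2.sf(G, 1)),
        nagelkerke_r2=nagelkerke_r2(LL0, LL1, n),
        n=n, converged=True, separated=False,
    )


@dataclass
class SignificanceConfig:
    """Bonferroni control over the whole locus x variable model family."""

    alpha: float = 0.01
    n_models: int | None = None  # default: loci x variables

    def threshold(self, n_loci: int, n_vars: int) -> float:
        models = self.n_models if self.n_models else n_loci * n_vars
        return self.alpha / models


def association_scan(
    markers: BinaryMarkerMatrix, env: EnvTable,
    config: SignificanceConfig | None = None,
) -> pd.DataFrame:
    """One logistic model per locus x environmental variable.

    A row is significant when both the Wald and the likelihood-ratio test
    fall below alpha / (loci x variables).  Monomorphic loci are skipped
    (reason recorded); the Bonferroni divisor still counts every locus.
    """
    if config is None:
        config = SignificanceConfig()
    env_of_pop = env.data
    pops = set(env.unit_ids)
    rows_ok = [i for i, sid in enumerate(markers.individual_ids)
               if markers.population_of[sid] in pops]
    if not rows_ok:
        raise ValueError("no individuals joinable to environment units")
    rows_ok = np.array(rows_ok)
    ind_pops = [markers.population_of[markers.individual_ids[i]] for i in rows_ok]
    Y = markers.calls[rows_ok]
    obs = (~np.isnan(Y)).astype(float)
    y_sum = np.nansum(Y, axis=0)
    n_obs = obs.sum(axis=0)
    polymorphic = (y_sum > 0) & (y_sum < n_obs)
    thr = config.threshold(markers.n_loci, len(env.variables))
    LL0 = _null_loglik(y_sum, n_obs)
    records = []
    for var in env.variables:
        x = np.array([float(env_of_pop.loc[p, var]) for p in ind_pops])
        idx = np.where(polymorphic)[0]
        b0, b1, se0, se1, LL1, conv, seps = _newton_many(Y[:, idx], x,
                                                         obs[:, idx])
        for k, j in enumerate(idx):
            sep = bool(seps[k])
            wald = ((b1[k] / se1[k]) ** 2
                    if np.isfinite(se1[k]) and se1[k] > 0 else np.inf)
            G = max(2.0 * (LL1[k] - LL0[j]), 0.0)
            wp = float(chi2.sf(wald, 1))
            gp = float(chi2.sf(G, 1))
            records.append({
                "locus": markers.locus_ids[j], "variable": var,
                "beta0": b0[k], "beta1": b1[k], "se_beta1": se1[k],
                "LL0": LL0[j], "LL1": LL1[k],
                "wald_p": wp, "g_p": gp,
                "nagelkerke_r2": nagelkerke_r2(LL0[j], LL1[k], int(n_obs[j])),
                "n": int(n_obs[j]),
                "separated": sep, "converged": bool(conv[k]),
                "significant": bool(wp < thr and gp < thr and not sep),
                "skipped_reason": "",
            })
        for j in np.where(~polymorphic)[0]:
            records.append({
                "locus": markers.locus_ids[j], "variable": var,
                "beta0": np.nan, "beta1": np.nan, "se_beta1": np.nan,
                "LL0": np.nan, "LL1": np.nan, "wald_p": np.nan, "g_p": np.nan,
                "nagelkerke_r2": np.nan, "n": int(n_obs[j]),
                "separated": False, "converged": False, "significant": False,
                "skipped_reason": "monomorphic",
            })
    table = pd.DataFrame.from_records(records)
    table.attrs["per_test_threshold"] = thr
    table.attrs["alpha"] = config.alpha
    return table


def significant_associations(table: pd.DataFrame) -> pd.DataFrame:
    """Filtered view mirroring a 'strong associations' report."""
    out = table[table["significant"]].copy()
    return out[["locus", "variable", "nagelkerke_r2", "wald_p", "g_p", "beta1"]]


def logistic_curve_points(fit: LogisticFit, x_grid: np.ndarray) -> pd.DataFrame:
    """Fitted presence probability over a predictor grid (plot data)."""
    return pd.DataFrame({
        "x": x_grid,
        "probability": expit(fit.beta0 + fit.beta1 * np.asarray(x_grid)),
    })
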
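"""Redundancy analysis (RDA) and two-block variation partitioning.

The marker response matrix (centered 0/1 band profiles; Hellinger
transform optional) is regressed on an environment block E and a
geography block G.  Adjusted R-squared fractions decompose explained
variation into pure environment [a], spatially structured environment
[b], pure geography [c] and residual [d]; testable fractions get
permutation p-values (Freedman–Lane residual permutation for the partial
fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RdaModel:
    r2: float
    adj_r2: float
    n: int
    n_predictors: int
    fitted: np.ndarray
    residuals: np.ndarray
    axes: np.ndarray            # canonical axes (site scores)
    eigenvalues: np.ndarray
    dropped_columns: list[int] = field(default_factory=list)


def _prepare_X(X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Center/standardize predictors and drop collinear columns."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 1e-12
    X = X[:, keep] / sd[keep]
    dropped = list(np.where(~keep)[0])
    # greedy removal of linearly dependent columns
    cols: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, cols + [j]]
        if np.linalg.matrix_rank(trial) == len(cols) + 1:
            cols.append(j)
        else:
            dropped.append(j)
    return X[:, cols], dropped


def hellinger(Y: np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of row-normalized abundances."""
    Y = np.asarray(Y, dtype=float)
    rs = Y.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return np.sqrt(Y / rs)


def rda(Y: np.ndarray, X: np.ndarray) -> RdaModel:
    """Multivariate least squares of the centered response on X.

    R2 = trace(fitted' fitted) / trace(Yc' Yc); adjusted R2 uses the
    Ezekiel correction 1 - (1 - R2)(n - 1)/(n - 1 - m).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    Xs, dropped = _prepare_X(X)
    m = Xs.shape[1]
    if m >= n - 1:
        raise ValueError("too many predictors for the number of rows")
    coef, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    fitted = Xs @ coef
    ss_tot = float((Yc**2).sum())
    ss_fit = float((fitted**2).sum())
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - m)
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2 / max(n - 1, 1)
    return RdaModel(r2=r2, adj_r2=adj, n=n, n_predictors=m, fitted=fitted,
                    residuals=Yc - fitted, axes=u * s, eigenvalues=eig,
                    dropped_columns=dropped)


@dataclass
class PartitionResult:
    a: float                # pure environment
    b: float                # spatially structured environment
    c: float                # pure geography
    d: float                # residual
    adj_r2_env: float       # [a+b]
    adj_r2_geo: float       # [b+c]
    adj_r2_full: float      # [a+b+c]
    p_values: dict[str, float] = field(default_factory=dict)
    permutations: int = 0


def varpart(Y: np.ndarray, E: np.ndarray, G: np.ndarray) -> PartitionResult:
    """Two-block adjusted-R2 partition.

    [a+b+c] = adjR2(Y ~ E+G); [a+b] = adjR2(Y ~ E); [b+c] = adjR2(Y ~ G);
    a = [a+b+c] - [b+c]; c = [a+b+c] - [a+b]; b = [a+b] + [b+c] - [a+b+c];
    d = 1 - [a+b+c].  Slightly negative fractions (adjusted-R2 artifacts)
    are reported as computed.
    """
    E = np.atleast_2d(np.asarray(E, dtype=float))
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if E.shape[0] == 1:
        E = E.T
    if G.shape[0] == 1:
        G = G.T
    EG = np.hstack([E, G])
    full = rda(Y, EG).adj_r2
    env = rda(Y, E).adj_r2
    geo = rda(Y, G).adj_r2
    a = full - geo
    c = full - env
    b = env + geo - full
    return PartitionResult(a=a, b=b, c=c, d=1.0 - full,
                           adj_r2_env=env, adj_r2_geo=geo, adj_r2_full=full)


TESTABLE_FRACTIONS = ("a+b+c", "a+b", "b+c", "a", "c")


def _pseudo_f(Y: np.ndarray, X: np.ndarray,
              Z: np.ndarray | None = None) -> float:
    """vegan-style pseudo-F for Y ~ X (conditioned on Z when given)."""
    Yc = Y - Y.mean(axis=0)
    n = Y.shape[0]
    if Z is None:
        model = rda(Yc, X)
        m = model.n_predictors
        ss_fit = float((model.fitted**2).sum())
        ss_res = float((model.residuals**2).sum())
        return (ss_fit / m) / (ss_res / (n - 1 - m))
    full = rda(Yc, np.hstack([X, Z]))
    red = rda(Yc, Z)
    m_x = full.n_predictors - red.n_predictors
    ss_gain = float((full.fitted**2).sum()) - float((red.fitted**2).sum())
    ss_res = float((full.residuals**2).sum())
    return (ss_gain / m_x) / (ss_res / (n - 1 - full.n_predictors))


def permutation_test_fraction(
    Y: np.ndarray, E: np.ndarray, G: np.ndarray, fraction: str,
    n_permutations: int = 9999, rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for a testable fraction.

    Marginal fractions permute rows of Y; the partial fractions [a] and
    [c] use Freedman–Lane permutation of the reduced-model residuals.
    Fraction [b] has no direct test and is refused.
    """
    if fraction == "b":
        raise ValueError("fraction [b] has no direct permutation test")
    if fraction not in TESTABLE_FRACTIONS:
        raise ValueError(f"unknown fraction {fraction!r}")
    if rng is None:
        rng = np.random.default_rng()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    E = np.atleast_2d(np.asarray(E, dtype=float))
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if E.shape[0] == 1:
        E = E.T
    if G.shape[0] == 1:
        G = G.T
    n = Y.shape[0]
    if fraction in ("a+b+c", "a+b", "b+c"):
        X = {"a+b+c": np.hstack([E, G]), "a+b": E, "b+c": G}[fraction]
        f_obs = _pseudo_f(Y, X)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if _pseudo_f(Y[perm], X) >= f_obs:
                count += 1
        return (count + 1) / (n_permutations + 1)
    X, Z = (E, G) if fraction == "a" else (G, E)
    f_obs = _pseudo_f(Y, X, Z)
    reduced = rda(Y, Z)
    fitted_red, resid_red = reduced.fitted, reduced.residuals
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        Y_star = fitted_red + resid_red[perm]
        if _pseudo_f(Y_star, X, Z) >= f_obs:
            count += 1
    return (count + 1) / (n_permutations + 1)
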
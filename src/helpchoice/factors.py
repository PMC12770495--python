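"""Exploratory factor analysis of consensus motivation ratings.

Reduces the 12 motivation dimensions to latent factors (in the study design,
a broad "both benefit" factor and a "self cost" factor), producing the
min-max-normalized benefit/cost scores and the binary urgency indicator that
feed the choice models, plus per-motivation linear mixed models quantifying
each dimension's predictive value for willingness to help.

Extraction is minimum-residual (ULS) on the correlation matrix, rotation
varimax by default (promax available as a robustness check), and factor
scores use the Thurstone regression method. The number of factors is chosen
by Horn-style parallel analysis: retain leading factors whose correlation
eigenvalues exceed the mean eigenvalue of standard-normal data of identical
shape at the same rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
import statsmodels.formula.api as smf

__all__ = [
    "parallel_analysis",
    "FactorModel",
    "FactorSolution",
    "fit_efa",
    "normalize_scores",
    "tucker_congruence",
    "motivation_wth_lmm",
    "LMMResult",
]


def parallel_analysis(X, n_sim: int = 1000, seed=None) -> int:
    """Number of factors to retain by parallel analysis.

    Compares the observed correlation-matrix eigenvalues against the mean
    simulated eigenvalue at the same rank from ``n_sim`` standard-normal
    datasets of identical shape; retention stops at the first rank where the
    observed eigenvalue no longer exceeds the simulated mean.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    sd = X.std(axis=0)
    if np.any(sd == 0):
        cols = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant column(s) at index {cols}: "
                         "correlation undefined")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sim = np.empty((n_sim, p))
    for s in range(n_sim):
        Z = rng.standard_normal((n, p))
        sim[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    thresh = sim.mean(axis=0)
    retained = 0
    for lam, t in zip(obs, thresh):
        if lam > t:
            retained += 1
        else:
            break
    return retained


# ---------------------------------------------------------------------------
# extraction and rotation


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (communality starting values)."""
    Rinv = np.linalg.pinv(R)
    return 1.0 - 1.0 / np.diag(Rinv)


def _loadings_from_psi(R, psi, k):
    Rs = R.copy()
    np.fill_diagonal(Rs, 1.0 - psi)
    vals, vecs = np.linalg.eigh(Rs)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _minres_objective(psi, R, k):
    L = _loadings_from_psi(R, psi, k)
    resid = R - L @ L.T
    np.fill_diagonal(resid, 0.0)
    return 0.5 * np.sum(resid ** 2)


def minres_extract(R: np.ndarray, k: int, max_iter: int = 1000):
    """Minimum-residual factor extraction on a correlation matrix."""
    p = R.shape[0]
    psi0 = np.clip(1.0 - _smc(R), 0.005, 0.995)
    res = minimize(_minres_objective, psi0, args=(R, k), method="L-BFGS-B",
                   bounds=[(0.001, 0.999)] * p,
                   options={"maxiter": max_iter})
    if not res.success and res.fun > 1e-4:
        raise RuntimeError(
            f"minres extraction failed to converge after {res.nit} iterations")
    return _loadings_from_psi(R, res.x, k), res


def varimax(L: np.ndarray, normalize: bool = True, tol: float = 1e-8,
            max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser varimax rotation; returns (rotated loadings, rotation matrix)."""
    L = np.asarray(L, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt(np.sum(L ** 2, axis=1)) if normalize else np.ones(p)
    h[h == 0] = 1.0
    A = L / h[:, None]
    T = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = A @ T
        G = A.T @ (B ** 3 - B @ np.diag(np.mean(B ** 2, axis=0)))
        u, s, vt = np.linalg.svd(G)
        T = u @ vt
        d = np.sum(s)
        if d_old != 0 and d < d_old * (1.0 + tol):
            break
        d_old = d
    return (A @ T) * h[:, None], T


def promax(L: np.ndarray, power: int = 4):
    """Promax oblique rotation from a varimax solution.

    Returns ``(pattern, structure, phi)`` with ``phi`` the factor
    correlation matrix.
    """
    V, _ = varimax(L)
    target = np.abs(V) ** power * np.sign(V)
    T = np.linalg.lstsq(V, target, rcond=None)[0]
    # scale columns of T so that diag of (T'T)^-1 is 1
    d = np.sqrt(np.diag(np.linalg.inv(T.T @ T)))
    T = T * d
    pattern = V @ T
    phi = np.linalg.inv(T.T @ T)
    structure = pattern @ phi
    return pattern, structure, phi


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Tucker congruence matrix between two loading matrices."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    num = A.T @ B
    den = np.sqrt(np.outer(np.sum(A ** 2, axis=0), np.sum(B ** 2, axis=0)))
    return num / den


@dataclass
class FactorSolution:
    """EFA solution: rotated loadings, scores and the item assignment."""

    loadings: pd.DataFrame            # items x factors
    eigenvalues: np.ndarray           # correlation-matrix eigenvalues
    n_factors: int
    rotation: str
    factor_scores: pd.DataFrame       # observations x factors
    variance_explained_total: float
    item_assignment: dict             # item -> factor label or None
    phi: np.ndarray | None = None     # factor correlations (oblique only)
    converged: bool = True

    def assigned_items(self, factor: str) -> list:
        return [i for i, f in self.item_assignment.items() if f == factor]


class FactorModel:
    """EFA model over an observations x items matrix (e.g. consensus
    ratings of scenarios on the 12 motivation dimensions)."""

    def __init__(self, data: pd.DataFrame):
        self.data = pd.DataFrame(data).astype(float)
        if self.data.isna().any().any():
            raise ValueError("factor analysis requires a complete matrix")
        sd = self.data.std(ddof=1)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])
            raise ValueError(f"constant column(s) {bad}: cannot standardize")

    def n_factors(self, n_sim: int = 1000, seed=None) -> int:
        return parallel_analysis(self.data.to_numpy(), n_sim=n_sim, seed=seed)

    def fit(self, n_factors: int, rotation: str = "varimax",
            loading_threshold: float = 0.3) -> FactorSolution:
        if n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        X = self.data.to_numpy()
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        R = np.corrcoef(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(R))[::-1]
        L, opt = minres_extract(R, n_factors)
        phi = None
        if rotation == "varimax" or n_factors == 1:
            Lrot, _ = varimax(L) if n_factors > 1 else (L, None)
            structure = Lrot.copy()   # orthogonal: structure == pattern
        elif rotation == "promax":
            Lrot, structure, phi = promax(L)
        else:
            raise ValueError("rotation must be 'varimax' or 'promax'")
        # sign convention: the maximal-|loading| item of each factor loads +
        for j in range(n_factors):
            i = np.argmax(np.abs(Lrot[:, j]))
            if Lrot[i, j] < 0:
                Lrot[:, j] *= -1
                structure[:, j] *= -1
                if phi is not None:
                    phi[j, :] *= -1
                    phi[:, j] *= -1
        factors = [f"F{j + 1}" for j in range(n_factors)]
        loadings = pd.DataFrame(Lrot, index=self.data.columns,
                                columns=factors)
        # Thurstone regression scores: W = R^-1 S, scores = Z W
        W = np.linalg.solve(R, structure)
        scores = pd.DataFrame(Z @ W, index=self.data.index, columns=factors)
        assignment = {}
        for item, row in loadings.iterrows():
            j = int(np.argmax(np.abs(row.to_numpy())))
            assignment[item] = (factors[j]
                                if abs(row.iloc[j]) > loading_threshold
                                else None)
        var_total = float(np.sum(Lrot ** 2) / Lrot.shape[0])
        return FactorSolution(
            loadings=loadings, eigenvalues=eig, n_factors=n_factors,
            rotation=rotation, factor_scores=scores,
            variance_explained_total=var_total,
            item_assignment=assignment, phi=phi,
            converged=bool(opt.success),
        )


def fit_efa(data: pd.DataFrame, n_factors: int,
            rotation: str = "varimax") -> FactorSolution:
    """Functional wrapper around :class:`FactorModel`."""
    return FactorModel(data).fit(n_factors, rotation=rotation)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("zero range: min-max normalization undefined")
    return (x - lo) / (hi - lo)


def normalize_scores(solution: FactorSolution, urgency_consensus,
                     cost_item: str = "q05") -> pd.DataFrame:
    """Min-max-normalized benefit/cost scores, urgency split and quadrants.

    The factor holding ``cost_item`` (the self-cost question) is taken as the
    cost factor, the other as benefit. Quadrants split at the per-factor
    medians: first letter benefit (L/H), second letter cost; the high side is
    strictly above the median. Urgency is a median split of the consensus
    urgency rating.
    """
    cost_factor = solution.item_assignment.get(cost_item)
    if cost_factor is None:
        raise ValueError(f"{cost_item!r} is not assigned to any factor")
    others = [f for f in solution.factor_scores.columns if f != cost_factor]
    if not others:
        raise ValueError("need at least two factors to split benefit/cost")
    benefit_factor = others[0]
    scores = solution.factor_scores
    benefit = _minmax(scores[benefit_factor].to_numpy())
    cost = _minmax(scores[cost_factor].to_numpy())
    urg = np.asarray(urgency_consensus, dtype=float)
    if urg.shape[0] != len(scores):
        raise ValueError("urgency consensus length mismatch")
    urgency_bin = (urg > np.median(urg)).astype(int)
    bmed, cmed = np.median(benefit), np.median(cost)
    quadrant = np.array([
        ("H" if b > bmed else "L") + ("H" if c > cmed else "L")
        for b, c in zip(benefit, cost)])
    return pd.DataFrame({
        "scenario_id": scores.index,
        "benefit": benefit,
        "cost": cost,
        "urgency_bin": urgency_bin,
        "quadrant": quadrant,
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-motivation mixed models


@dataclass
class LMMResult:
    dimension: str
    slope: float
    intercept: float
    marginal_r2: float
    conditional_r2: float
    singular: bool
    n_obs: int


def motivation_wth_lmm(decisions: pd.DataFrame, motivation: pd.Series,
                       dimension: str = "motivation",
                       wth_col: str = "wth_code",
                       participant_col: str = "participant_id") -> LMMResult:
    """Mixed model WTH ~ motivation with per-participant random intercepts
    and slopes; returns Nakagawa marginal and conditional R-squared.

    ``motivation`` maps scenario_id -> consensus value for one dimension.
    The random-effect variance uses the observation-wise average of
    ``z' G z`` with ``z = (1, x)`` so random slopes contribute correctly.
    """
    df = decisions.copy()
    df["motivation"] = df["scenario_id"].map(motivation)
    df = df.dropna(subset=["motivation", wth_col])
    if df[participant_col].nunique() < 10:
        raise ValueError("need at least 10 participants")
    x = df["motivation"].to_numpy(dtype=float)
    if np.std(x) == 0:
        # constant motivation: no fixed-effect variance by definition
        return LMMResult(dimension=dimension, slope=0.0,
                         intercept=float(df[wth_col].mean()),
                         marginal_r2=0.0,
                         conditional_r2=np.nan, singular=True,
                         n_obs=len(df))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{wth_col} ~ motivation", df,
                            groups=df[participant_col],
                            re_formula="~motivation")
        fit = model.fit(reml=True)
    beta0, beta1 = fit.fe_params["Intercept"], fit.fe_params["motivation"]
    var_fixed = float(np.var(beta0 + beta1 * x))
    G = fit.cov_re.to_numpy()
    Zrow = np.column_stack([np.ones_like(x), x])
    var_random = float(np.mean(np.einsum("ij,jk,ik->i", Zrow, G, Zrow)))
    var_resid = float(fit.scale)
    total = var_fixed + var_random + var_resid
    singular = bool(np.min(np.linalg.eigvalsh(G)) < 1e-10)
    return LMMResult(
        dimension=dimension,
        slope=float(beta1), intercept=float(beta0),
        marginal_r2=var_fixed / total,
        conditional_r2=(var_fixed + var_random) / total,
        singular=singular, n_obs=len(df),
    )
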
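"""Representational spaces over scenarios and their associations.

Three scenario-by-scenario representational dissimilarity matrices (RDMs):

* decision space — for scenarios x and y, with the sum over the n raters who
  rated both, ``F = (1/n) * [0.5 * sum_i |WTH_ix - WTH_iy|
  + 0.5 * |sum_i (WTH_ix - WTH_iy)|]`` (a blend of unsigned per-rater
  disagreement and the signed mean difference);
* motivation space — Euclidean distance on the (benefit, cost) factor
  scores, with per-axis absolute-difference component RDMs;
* semantic space — Euclidean distance on a 2-D UMAP (cosine metric) of the
  scenario text embeddings, with agglomerative (Ward) clusters.

Spaces are linked by representational similarity analysis (Pearson r between
upper-triangle vectors with a scenario-permutation null), by a decomposition
of the decision RDM into a mean-WTH RDM plus residual, and by OLS regressions
of (standardized) RDM vectors on component RDMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.cluster import AgglomerativeClustering
from sklearn.manifold import MDS

__all__ = [
    "validate_rdm",
    "upper_triangle",
    "decision_rdm",
    "motivation_rdms",
    "semantic_space",
    "mds_embed",
    "rsa",
    "RSAResult",
    "decompose_decision_rdm",
    "rdm_regression",
    "quadrant_anova",
    "SpaceEmbedding",
]


def validate_rdm(rdm: np.ndarray, name: str = "rdm") -> np.ndarray:
    rdm = np.asarray(rdm, dtype=float)
    if rdm.ndim != 2 or rdm.shape[0] != rdm.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.isfinite(rdm).all():
        raise ValueError(f"{name} must be finite")
    if not np.allclose(rdm, rdm.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(rdm), 0.0, atol=1e-10):
        raise ValueError(f"{name} must have a zero diagonal")
    if (rdm < -1e-10).any():
        raise ValueError(f"{name} must be non-negative")
    return rdm


def upper_triangle(rdm: np.ndarray) -> np.ndarray:
    rdm = np.asarray(rdm, dtype=float)
    return rdm[np.triu_indices(rdm.shape[0], k=1)]


def decision_rdm(wth: pd.DataFrame, min_overlap: int = 5) -> np.ndarray:
    """Decision-space RDM from a participant x scenario WTH matrix.

    Missing cells are allowed; each pair uses only the raters who rated both
    scenarios, for both the unsigned and the signed term. Raises when a pair
    has no overlapping rater; warns when overlap is below ``min_overlap``.
    """
    M = pd.DataFrame(wth).to_numpy(dtype=float)
    n_scen = M.shape[1]
    mask = np.isfinite(M)
    F = np.zeros((n_scen, n_scen))
    low, missing = [], []
    for x in range(n_scen):
        for y in range(x + 1, n_scen):
            joint = mask[:, x] & mask[:, y]
            n = int(joint.sum())
            if n == 0:
                missing.append((x, y))
                continue
            if n < min_overlap:
                low.append((x, y))
            d = M[joint, x] - M[joint, y]
            F[x, y] = F[y, x] = (0.5 * np.abs(d).sum()
                                 + 0.5 * abs(d.sum())) / n
    if missing:
        raise ValueError(f"scenario pairs with no overlapping raters: "
                         f"{missing[:20]}")
    if low:
        warnings.warn(f"{len(low)} scenario pair(s) have overlap below "
                      f"{min_overlap}", stacklevel=2)
    return F


def decision_matrix(decisions: pd.DataFrame, value_col: str = "wth_code",
                    ) -> pd.DataFrame:
    """Pivot a clean decision table to participant x scenario WTH codes."""
    return decisions.pivot_table(index="participant_id",
                                 columns="scenario_id", values=value_col)


def motivation_rdms(scores: pd.DataFrame):
    """(full, benefit, cost) RDMs from motivation scores.

    Full = 2-D Euclidean distance on (benefit, cost); components are the
    per-axis absolute differences.
    """
    b = scores["benefit"].to_numpy(dtype=float)
    c = scores["cost"].to_numpy(dtype=float)
    benefit_rdm = np.abs(b[:, None] - b[None, :])
    cost_rdm = np.abs(c[:, None] - c[None, :])
    full = np.sqrt(benefit_rdm ** 2 + cost_rdm ** 2)
    return full, benefit_rdm, cost_rdm


@dataclass
class SpaceEmbedding:
    space: str
    coords: pd.DataFrame        # scenario x 2
    method: str
    diagnostics: dict
    seed: object = None


def semantic_space(embeddings: pd.DataFrame, n_clusters: int = 12,
                   n_neighbors: int = 15, min_dist: float = 0.1,
                   seed: int = 0):
    """Semantic space: cosine-metric UMAP to 2-D, Euclidean RDM on the 2-D
    coordinates, and Ward agglomerative cluster labels on those coordinates.

    ``embeddings`` is a scenario x d frame of text-embedding vectors.
    """
    import umap    # deferred: numba compilation is slow at import

    X = pd.DataFrame(embeddings).to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("embedding dimension must be >= 2")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = np.flatnonzero(norms == 0).tolist()
        raise ValueError(f"zero-norm embedding for scenario index {bad}: "
                         "cosine distance undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, metric="cosine",
                            n_neighbors=min(n_neighbors, X.shape[0] - 1),
                            min_dist=min_dist, random_state=seed)
        coords = reducer.fit_transform(X)
    rdm = squareform(pdist(coords))
    labels = AgglomerativeClustering(
        n_clusters=n_clusters, linkage="ward").fit_predict(coords)
    emb = SpaceEmbedding(
        space="semantic",
        coords=pd.DataFrame(coords, index=pd.DataFrame(embeddings).index,
                            columns=["x", "y"]),
        method="UMAP",
        diagnostics={"n_neighbors": n_neighbors, "min_dist": min_dist,
                     "metric": "cosine"},
        seed=seed)
    return emb, rdm, labels


def mds_embed(rdm: np.ndarray, seed: int = 0, n_components: int = 2,
              n_init: int = 4) -> SpaceEmbedding:
    """Metric MDS (SMACOF) of a precomputed dissimilarity matrix."""
    rdm = validate_rdm(rdm)
    mds = MDS(n_components=n_components, metric="precomputed",
              init="random", n_init=n_init, max_iter=500, eps=1e-9,
              random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = mds.fit_transform(rdm)
    return SpaceEmbedding(
        space="mds",
        coords=pd.DataFrame(coords,
                            columns=[f"dim{i+1}" for i in range(n_components)]),
        method="MDS",
        diagnostics={"stress": float(mds.stress_)},
        seed=seed)


@dataclass
class RSAResult:
    space_a: str
    space_b: str
    r: float
    p: float
    n_permutations: int


def rsa(rdm_a, rdm_b, n_perm: int = 5000, seed=None,
        labels=("a", "b"), smoothed: bool = False) -> RSAResult:
    """Representational similarity analysis between two RDMs.

    Pearson r on upper-triangle vectors; the null permutes scenario labels
    of the second RDM (one permutation applied jointly to rows and columns)
    and p is the proportion of null correlations strictly greater than the
    observed one (``smoothed`` adds the +1/(N+1) correction).
    """
    A = validate_rdm(rdm_a, "rdm_a")
    B = validate_rdm(rdm_b, "rdm_b")
    if A.shape != B.shape:
        raise ValueError("RDMs must share shape and scenario order")
    n = A.shape[0]
    if n < 4:
        raise ValueError("need at least 4 scenarios")
    va, vb = upper_triangle(A), upper_triangle(B)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant upper triangle: correlation undefined")
    r_obs = float(pearsonr(va, vb).statistic)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    va_c = va - va.mean()
    va_ss = np.sqrt(np.sum(va_c ** 2))
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        vb_p = B[np.ix_(perm, perm)][iu]
        vb_c = vb_p - vb_p.mean()
        null[i] = float(va_c @ vb_c / (va_ss * np.sqrt(np.sum(vb_c ** 2))))
    exceed = int(np.sum(null > r_obs))
    p = ((exceed + 1) / (n_perm + 1)) if smoothed else exceed / n_perm
    return RSAResult(space_a=labels[0], space_b=labels[1], r=r_obs,
                     p=float(p), n_permutations=n_perm)


def decompose_decision_rdm(rdm: np.ndarray, mean_wth: np.ndarray):
    """Split a decision RDM into a mean-WTH RDM and an OLS residual RDM.

    The WTH RDM is ``|mean_x - mean_y|``; the residual is the upper-triangle
    residual of regressing decision-RDM entries on WTH-RDM entries (with
    intercept), reassembled symmetrically with a zero diagonal.
    """
    rdm = validate_rdm(rdm)
    m = np.asarray(mean_wth, dtype=float)
    if m.shape[0] != rdm.shape[0]:
        raise ValueError("mean_wth length mismatch")
    wth_rdm = np.abs(m[:, None] - m[None, :])
    y = upper_triangle(rdm)
    x = upper_triangle(wth_rdm)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_vec = y - X @ beta
    n = rdm.shape[0]
    resid = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    resid[iu] = resid_vec
    resid = resid + resid.T
    return wth_rdm, resid


def rdm_regression(target, predictors: dict, standardize: bool = True,
                   ) -> pd.DataFrame:
    """OLS of a target RDM's upper triangle on predictor RDMs' triangles.

    With ``standardize`` (default) both sides are z-scored so coefficients
    are standardized betas. Returns a coefficient table with standard
    errors and 95% CIs; warns on collinear predictors.
    """
    import statsmodels.api as sm

    y = upper_triangle(np.asarray(target, dtype=float))
    names = list(predictors)
    cols = []
    for name in names:
        v = upper_triangle(np.asarray(predictors[name], dtype=float))
        if v.shape != y.shape:
            raise ValueError(f"predictor {name!r} shape mismatch")
        cols.append(v)
    X = np.column_stack(cols)
    if standardize:
        y = (y - y.mean()) / y.std(ddof=0)
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    cond = np.linalg.cond(np.column_stack([np.ones_like(y), X]))
    if cond > 1e8:
        warnings.warn(f"collinear predictors (condition number {cond:.3g})",
                      stacklevel=2)
    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int(alpha=0.05)
    rows = []
    for i, name in enumerate(["intercept"] + names):
        rows.append({"predictor": name, "beta": model.params[i],
                     "se": model.bse[i], "ci_low": ci[i, 0],
                     "ci_high": ci[i, 1], "p": model.pvalues[i]})
    out = pd.DataFrame(rows)
    out.attrs["r_squared"] = float(model.rsquared)
    return out


def quadrant_anova(values, groups) -> dict:
    """Welch one-way ANOVA with Games-Howell post-hoc over quadrants.

    Returns the Welch F, Welch-Satterthwaite df, p, partial eta-squared and
    the pairwise Games-Howell table. Groups need >=2 members each.
    """
    import pingouin as pg

    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups)})
    sizes = df.groupby("group").size()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"group(s) with fewer than 2 members: "
                         f"{list(small.index)}")
    if df["value"].nunique() == 1:
        welch = {"F": 0.0, "df1": float(len(sizes) - 1), "df2": np.nan,
                 "p": 1.0, "np2": 0.0}
        posthoc = pg.pairwise_gameshowell(dv="value", between="group",
                                          data=df)
        return {"welch": welch, "posthoc": posthoc}
    aov = pg.welch_anova(dv="value", between="group", data=df)
    posthoc = pg.pairwise_gameshowell(dv="value", between="group", data=df)
    return {
        "welch": {"F": float(aov["F"].iloc[0]),
                  "df1": float(aov["ddof1"].iloc[0]),
                  "df2": float(aov["ddof2"].iloc[0]),
                  "p": float(aov["p_unc"].iloc[0]),
                  "np2": float(aov["np2"].iloc[0])},
        "posthoc": posthoc,
    }
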
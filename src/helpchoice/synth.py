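"""Synthetic data generator for the helping-decision analysis pipeline.

Emulates the structure of a two-survey study design: ~100 short helping
scenarios with latent benefit/cost/urgency, a rater pool scoring each scenario
on 15 five-point motivation dimensions with a planted two-factor structure
(a broad "both benefit" factor and a "self cost" factor), and a participant
sample whose binary help decisions are generated forward from a known softmax
cost-benefit utility model. Trait questionnaire scores are drawn jointly with
the agents' generative parameters through a Gaussian copula so that
trait-parameter correlations can be planted at known values.

Every output is deterministic given ``SyntheticConfig.seed``; each table uses
an independent sub-stream ``default_rng([seed, offset])`` so tables can be
regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .choice import choice_prob, get_model_spec, utility

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "QCViolationSpec",
    "EFA_DIMENSIONS",
    "EFA_QUESTIONS",
    "URGENCY_QUESTION",
    "SUMMARY_QUESTIONS",
    "default_loading_matrix",
    "gen_scenarios",
    "gen_motivation_ratings",
    "gen_agents",
    "gen_decisions",
    "inject_qc_violations",
    "generate_all",
    "write_dataset",
]


class ConfigError(ValueError):
    """Invalid synthetic-data configuration; message names the field."""


#: The 12 motivation dimensions entering the factor analysis, in question
#: order. q02 (urgency) and the two summary questions q11 (of q07-q10) and
#: q15 (of q13-q14) are generated but excluded from the EFA.
EFA_DIMENSIONS = (
    "empathy", "descriptive_norm", "injunctive_norm", "self_cost",
    "other_benefit", "indirect_reciprocity", "mood_management", "reputation",
    "positive_self_concept", "other_cost", "guilt", "negative_self_concept",
)
EFA_QUESTIONS = ("q01", "q03", "q04", "q05", "q06", "q07", "q08", "q09",
                 "q10", "q12", "q13", "q14")
URGENCY_QUESTION = "q02"
SUMMARY_QUESTIONS = {"q11": ("q07", "q08", "q09", "q10"),
                     "q15": ("q13", "q14")}
ALL_QUESTIONS = tuple(f"q{i:02d}" for i in range(1, 16))


def default_loading_matrix() -> np.ndarray:
    """Default 12x2 (benefit, cost) loading matrix.

    Eleven items load primarily on the benefit factor; self cost loads on the
    cost factor. The not-helping-cost items (other cost, guilt, negative
    self-concept) carry secondary cost loadings below their benefit primaries,
    so the cost factor is identified by several indicators while the
    max-loading item assignment remains 11 benefit items vs 1 cost item.
    """
    L = np.array([
        [0.85, 0.00],   # empathy
        [0.80, 0.00],   # descriptive norm
        [0.85, 0.00],   # injunctive norm
        [0.00, 0.90],   # self cost
        [0.90, 0.00],   # other benefit
        [0.80, 0.00],   # indirect reciprocity
        [0.80, 0.00],   # mood management
        [0.75, 0.00],   # reputation
        [0.85, 0.00],   # positive self-concept
        [0.70, 0.45],   # other cost of no help
        [0.80, 0.40],   # guilt
        [0.75, 0.40],   # negative self-concept
    ])
    return L


#: Distribution specs: ("uniform", lo, hi) | ("normal", mean, sd) |
#: ("truncnorm", mean, sd, lo, hi) | ("point", value)
DEFAULT_AGENT_DISTS = {
    "beta": ("uniform", 1.0, 4.0),
    "w_cost": ("uniform", 0.1, 0.9),
    "w_benefit": ("uniform", 0.1, 0.9),
    "b": ("truncnorm", 0.2, 0.4, -0.8, 1.2),
    "alpha": ("uniform", 0.5, 2.0),
    "w_cb": ("uniform", -1.0, 1.0),
    "w_u": ("uniform", 0.0, 1.0),
}

#: Planted trait-parameter correlations mirroring the hypothesised positive
#: link of helping bias with agreeableness/empathy and of cost weight with
#: punishment sensitivity (negative with reward responsiveness through
#: w_benefit = 1 - w_cost).
DEFAULT_TRAIT_CORR = {
    ("agreeableness", "b"): 0.3,
    ("iri_ec", "b"): 0.3,
    ("svo", "b"): 0.2,
    ("bis", "w_cost"): 0.3,
    ("rr", "w_cost"): -0.2,
}

#: Questionnaire-like marginal (mean, sd) per trait score.
TRAIT_MARGINALS = {
    "iri_ec": (3.5, 0.7), "svo": (25.0, 15.0), "rr": (3.4, 0.5),
    "bis": (2.9, 0.6), "agreeableness": (3.6, 0.7),
    "extraversion": (3.0, 0.9), "conscientiousness": (3.7, 0.7),
    "neuroticism": (2.8, 0.9), "openness": (3.5, 0.8),
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_scenarios: int = 100
    n_raters_per_scenario: int = 28
    n_participants: int = 215
    trials_per_participant: int = 50
    scenarios_per_rater: int = 20
    loading_matrix: np.ndarray = field(default_factory=default_loading_matrix)
    rating_noise_sd: float = 0.5
    rater_bias_sd: float = 0.2
    agent_param_dists: dict = field(
        default_factory=lambda: dict(DEFAULT_AGENT_DISTS))
    trait_param_corr: dict = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_CORR))
    generating_model_id: str = "2.0"
    embedding_dim: int = 16
    n_semantic_clusters: int = 14
    cluster_spread: float = 10.0
    embedding_noise_sd: float = 1.0
    n_attention_checks: int = 3
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("n_scenarios", "n_raters_per_scenario", "n_participants",
                     "trials_per_participant", "scenarios_per_rater",
                     "embedding_dim", "n_semantic_clusters"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.trials_per_participant > self.n_scenarios:
            raise ConfigError(
                "trials_per_participant must not exceed n_scenarios")
        if self.scenarios_per_rater > self.n_scenarios:
            raise ConfigError(
                "scenarios_per_rater must not exceed n_scenarios")
        if self.n_semantic_clusters > self.n_scenarios:
            raise ConfigError(
                "n_semantic_clusters must not exceed n_scenarios")
        L = np.asarray(self.loading_matrix, dtype=float)
        if L.shape != (12, 2):
            raise ConfigError("loading_matrix must have shape (12, 2)")
        if not np.isfinite(L).all():
            raise ConfigError("loading_matrix must be finite")
        object.__setattr__(self, "loading_matrix", L)
        if self.rating_noise_sd < 0 or self.rater_bias_sd < 0:
            raise ConfigError("rating_noise_sd/rater_bias_sd must be >= 0")
        for (trait, param), rho in self.trait_param_corr.items():
            if not abs(rho) < 1:
                raise ConfigError(
                    f"trait_param_corr[({trait}, {param})] must be in (-1, 1)")
        get_model_spec(self.generating_model_id)

    def rng(self, offset: int, extra: int | None = None) -> np.random.Generator:
        key = [int(self.seed), int(offset)]
        if extra is not None:
            key.append(int(extra))
        return np.random.default_rng(key)

    @property
    def n_raters(self) -> int:
        total = self.n_scenarios * self.n_raters_per_scenario
        if total % self.scenarios_per_rater:
            raise ConfigError(
                "n_scenarios * n_raters_per_scenario must be divisible by "
                "scenarios_per_rater for a balanced rating design")
        return total // self.scenarios_per_rater


# ---------------------------------------------------------------------------
# scenarios


def gen_scenarios(config: SyntheticConfig) -> pd.DataFrame:
    """Scenario latents: benefit/cost (standard normal), urgency (uniform),
    semantic cluster ids and clustered embedding vectors."""
    rng = config.rng(1)
    n, k = config.n_scenarios, config.n_semantic_clusters
    benefit = rng.standard_normal(n)
    cost = rng.standard_normal(n)
    urgency = rng.random(n)
    # balanced-ish random partition with every cluster non-empty
    cluster = np.arange(n) % k
    rng.shuffle(cluster)
    centroids = rng.standard_normal((k, config.embedding_dim)) \
        * config.cluster_spread
    emb = centroids[cluster] + rng.standard_normal(
        (n, config.embedding_dim)) * config.embedding_noise_sd
    df = pd.DataFrame({
        "scenario_id": np.arange(n),
        "benefit_true": benefit,
        "cost_true": cost,
        "urgency_true": urgency,
        "cluster_id": cluster,
    })
    for j in range(config.embedding_dim):
        df[f"e{j}"] = emb[:, j]
    return df


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        raise ConfigError("degenerate latent with zero range")
    return (x - lo) / (hi - lo)


def normalized_scenario_scores(latents: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalized true benefit/cost and the binary urgency split,
    i.e. the generator-side analogue of the downstream motivation scores."""
    urg = latents["urgency_true"].to_numpy()
    return pd.DataFrame({
        "scenario_id": latents["scenario_id"].to_numpy(),
        "benefit": _minmax(latents["benefit_true"].to_numpy()),
        "cost": _minmax(latents["cost_true"].to_numpy()),
        "urgency_bin": (urg > np.median(urg)).astype(int),
    })


# ---------------------------------------------------------------------------
# motivation ratings


def _discretize(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), 1, 5).astype(int)


def gen_motivation_ratings(latents: pd.DataFrame,
                           config: SyntheticConfig) -> pd.DataFrame:
    """Raw rater x scenario motivation ratings on 1-5 scales.

    Each of the 12 factor-analysed questions is generated as
    ``3 + loading . (benefit, cost) + rater_bias + noise`` and discretized;
    urgency (q02) tracks the latent urgency; the summary questions q11/q15
    are noisy copies of the mean of their constituent questions. The rating
    design is balanced: every scenario receives exactly
    ``n_raters_per_scenario`` raters, each rater scoring
    ``scenarios_per_rater`` distinct scenarios. Attention-check rows
    (``attention_item == 1``) carry a pass flag instead of ratings.
    """
    L = np.asarray(config.loading_matrix, dtype=float)
    if L.shape != (12, 2):
        raise ConfigError("loading_matrix must have shape (12, 2)")
    rng = config.rng(2)
    n, per = config.n_scenarios, config.scenarios_per_rater
    n_raters = config.n_raters
    benefit = latents["benefit_true"].to_numpy()
    cost = latents["cost_true"].to_numpy()
    urgency = latents["urgency_true"].to_numpy()
    bias = rng.normal(0.0, config.rater_bias_sd, n_raters)
    # cyclic balanced assignment, then a random scenario relabelling so the
    # design is balanced but not systematically ordered
    perm = rng.permutation(n)
    rows = []
    for r in range(n_raters):
        scen = perm[(r * per + np.arange(per)) % n]
        signal = L[None, :, :] @ np.stack(
            [benefit[scen], cost[scen]], axis=1)[:, :, None]
        signal = signal[:, :, 0]          # (per, 12)
        noise = rng.normal(0.0, config.rating_noise_sd, (per, 12))
        q = _discretize(3.0 + signal + bias[r] + noise)
        urgency_rating = _discretize(
            1.0 + 4.0 * urgency[scen]
            + rng.normal(0.0, config.rating_noise_sd, per))
        rec = {f: q[:, i] for i, f in enumerate(EFA_QUESTIONS)}
        rec[URGENCY_QUESTION] = urgency_rating
        for summary, parts in SUMMARY_QUESTIONS.items():
            base = np.mean([rec[p] for p in parts], axis=0)
            rec[summary] = _discretize(
                base + rng.normal(0.0, config.rating_noise_sd, per))
        frame = pd.DataFrame({"rater_id": r, "scenario_id": scen})
        for qname in ALL_QUESTIONS:
            frame[qname] = rec[qname]
        frame["attention_item"] = 0
        frame["attention_passed"] = True
        frame["cant_imagine"] = 0
        rows.append(frame)
        att = pd.DataFrame({
            "rater_id": r,
            "scenario_id": -1,
            "attention_item": 1,
            "attention_passed": True,
            "cant_imagine": 0,
        }, index=range(config.n_attention_checks))
        rows.append(att)
    out = pd.concat(rows, ignore_index=True)
    for qname in ALL_QUESTIONS:
        out[qname] = out[qname].astype("float64")
    out.loc[out["attention_item"] == 1, list(ALL_QUESTIONS)] = np.nan
    return out


# ---------------------------------------------------------------------------
# agents and traits


def _marginal_transform(dist, z: np.ndarray) -> np.ndarray:
    kind = dist[0]
    u = stats.norm.cdf(z)
    if kind == "uniform":
        _, lo, hi = dist
        return lo + (hi - lo) * u
    if kind == "normal":
        _, m, s = dist
        return m + s * z
    if kind == "truncnorm":
        _, m, s, lo, hi = dist
        a, b = (lo - m) / s, (hi - m) / s
        return stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b,
                                   loc=m, scale=s)
    if kind == "point":
        return np.full(z.shape, float(dist[1]))
    raise ConfigError(f"unknown distribution kind {kind!r}")


def gen_agents(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Agent parameters and trait scores, coupled by a Gaussian copula.

    Returns ``(agents, traits)``: agents hold the generative parameters for
    ``generating_model_id`` (plus ``w_benefit = 1 - w_cost`` for single-weight
    models); traits hold questionnaire-like scores whose correlations with the
    parameters hit ``trait_param_corr`` up to sampling error and marginal
    transforms.
    """
    spec = get_model_spec(config.generating_model_id)
    params = list(spec.param_names)
    traits = list(TRAIT_MARGINALS)
    names = params + traits
    dim = len(names)
    C = np.eye(dim)
    for (trait, param), rho in config.trait_param_corr.items():
        if trait not in traits:
            raise ConfigError(f"unknown trait {trait!r} in trait_param_corr")
        if param not in params:
            continue   # correlation for a parameter the model does not use
        i, j = names.index(param), names.index(trait)
        C[i, j] = C[j, i] = rho
    eig = np.linalg.eigvalsh(C)
    if eig.min() < -1e-10:
        raise ConfigError("trait_param_corr is not positive semi-definite")
    rng = config.rng(3)
    Z = rng.multivariate_normal(np.zeros(dim), C, size=config.n_participants,
                                method="cholesky" if eig.min() > 1e-10
                                else "svd")
    agents = pd.DataFrame({"participant_id": np.arange(config.n_participants)})
    for i, p in enumerate(params):
        dist = config.agent_param_dists.get(p)
        if dist is None:
            raise ConfigError(f"agent_param_dists missing {p!r}")
        agents[p] = _marginal_transform(dist, Z[:, i])
    if "w_cost" in params and "w_benefit" not in params:
        agents["w_benefit"] = 1.0 - agents["w_cost"]
    agents["model_id"] = spec.model_id
    trait_df = pd.DataFrame(
        {"participant_id": np.arange(config.n_participants)})
    for j, t in enumerate(traits):
        m, s = TRAIT_MARGINALS[t]
        trait_df[t] = m + s * Z[:, len(params) + j]
    n = config.n_participants
    trait_df["sex"] = np.where(rng.random(n) < 0.5, "female", "male")
    trait_df["age"] = rng.integers(18, 66, n)
    return agents, trait_df


# ---------------------------------------------------------------------------
# decisions

_LEVEL_EDGES = np.array([1 / 6, 1 / 3, 1 / 2, 2 / 3, 5 / 6])


def _wth_level(p_help: np.ndarray, help_: np.ndarray) -> np.ndarray:
    """Six equal-probability bins of P_help with the help boundary at 0.5;
    levels are mirrored across the boundary when the Bernoulli draw falls on
    the other side, keeping help == 1 <=> level >= 4."""
    level = 1 + np.searchsorted(_LEVEL_EDGES, p_help, side="right")
    disagree = (help_ == 1) != (level >= 4)
    level = np.where(disagree, 7 - level, level)
    return level.astype(int)


def gen_decisions(agents: pd.DataFrame, latents: pd.DataFrame,
                  config: SyntheticConfig) -> pd.DataFrame:
    """Forward-simulated decision table.

    For each agent: ``trials_per_participant`` scenarios sampled without
    replacement, utilities from the agent's generative model on min-max
    normalized latents, help drawn Bernoulli(P_help) (uniform draw per trial,
    in trial order, from stream ``[seed, 4, participant_id]``), ordinal WTH
    level from the probability bins, plus repeated-scenario rows (identical
    re-ratings by default) and attention-check slots.
    """
    spec = get_model_spec(config.generating_model_id)
    scores = normalized_scenario_scores(latents)
    cost = scores["cost"].to_numpy()
    benefit = scores["benefit"].to_numpy()
    urgency = scores["urgency_bin"].to_numpy()
    n = config.n_scenarios
    frames = []
    for row in agents.itertuples(index=False):
        pid = int(row.participant_id)
        params = {p: float(getattr(row, p)) for p in spec.param_names}
        missing = [p for p in spec.param_names
                   if not np.isfinite(params.get(p, np.nan))]
        if missing:
            raise ConfigError(
                f"agent {pid} missing parameter(s) {missing} for model "
                f"{spec.model_id}")
        rng = config.rng(4, pid)
        scen = rng.choice(n, size=config.trials_per_participant,
                          replace=False)
        U = utility(spec.model_id, params, cost[scen], benefit[scen],
                    urgency[scen])
        P = choice_prob(U, params["beta"])
        u = rng.random(config.trials_per_participant)
        help_ = (u < P).astype(int)
        level = _wth_level(P, help_)
        frame = pd.DataFrame({
            "participant_id": pid,
            "trial": np.arange(config.trials_per_participant),
            "scenario_id": scen,
            "wth_level": level,
            "attention_item": 0,
            "attention_passed": True,
            "repeat_tag": "",
            "cant_imagine": 0,
        })
        # repeated scenarios: identical re-rating by default
        rep_idx = rng.choice(config.trials_per_participant,
                             size=min(config.n_repeats,
                                      config.trials_per_participant),
                             replace=False)
        reps = frame.iloc[rep_idx].copy()
        reps["trial"] = config.trials_per_participant + np.arange(len(reps))
        reps["repeat_tag"] = [f"R{k + 1}" for k in range(len(reps))]
        base = frame.iloc[rep_idx]
        frame.loc[base.index, "repeat_tag"] = [
            f"R{k + 1}" for k in range(len(reps))]
        att = pd.DataFrame({
            "participant_id": pid,
            "trial": config.trials_per_participant + len(reps)
            + np.arange(config.n_attention_checks),
            "scenario_id": -1,
            "wth_level": 0,
            "attention_item": 1,
            "attention_passed": True,
            "repeat_tag": "",
            "cant_imagine": 0,
        })
        frames.append(pd.concat([frame, reps, att], ignore_index=True))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# QC violations


@dataclass(frozen=True)
class QCViolationSpec:
    """Counts of planted violations per exclusion rule."""

    n_attention_failers: int = 0
    n_inconsistent: int = 0
    n_straightliners: int = 0
    n_cant_imagine: int = 0
    n_rater_attention_failers: int = 0
    n_low_variability_pairs: int = 0
    n_outlier_pairs: int = 0


def _oracle_decision_truth(decisions: pd.DataFrame,
                           sd_threshold=0.5, cant_imagine_threshold=10):
    """Plain-loop evaluation of the four decision-survey exclusion rules."""
    out = {}
    code_map = {1: -5, 2: -3, 3: -1, 4: 1, 5: 3, 6: 5}
    for pid, grp in decisions.groupby("participant_id"):
        att = grp[grp["attention_item"] == 1]
        n_fail = int((~att["attention_passed"]).sum())
        rated = grp[grp["attention_item"] == 0]
        n_inconsistent = 0
        for tag, pair in rated[rated["repeat_tag"] != ""].groupby("repeat_tag"):
            if len(pair) == 2:
                h = [lvl >= 4 for lvl in pair["wth_level"]]
                if h[0] != h[1]:
                    n_inconsistent += 1
        codes = [code_map[lv] for lv in rated["wth_level"]]
        sd = float(np.std(codes, ddof=1)) if len(codes) > 1 else 0.0
        n_ci = int(rated["cant_imagine"].sum())
        rules = []
        if n_fail >= 2:
            rules.append("attention")
        if n_inconsistent >= 2:
            rules.append("inconsistent")
        if sd < sd_threshold:
            rules.append("straight_line")
        if n_ci >= cant_imagine_threshold:
            rules.append("cant_imagine")
        if rules:
            out[int(pid)] = rules[0]
    return out


def _oracle_rating_truth(ratings: pd.DataFrame, sd_threshold=0.1,
                         outlier_sd=3.0):
    """Plain-loop evaluation of the rating-survey exclusion rules."""
    excluded_raters = {}
    for rid, grp in ratings.groupby("rater_id"):
        att = grp[grp["attention_item"] == 1]
        if int((~att["attention_passed"]).sum()) >= 2:
            excluded_raters[int(rid)] = "attention"
    rated = ratings[(ratings["attention_item"] == 0)
                    & (ratings["cant_imagine"] == 0)]
    rated = rated[~rated["rater_id"].isin(excluded_raters)]
    pairs = {}
    for q in ALL_QUESTIONS:
        per_rater = {}
        for rid, grp in rated.groupby("rater_id"):
            vals = grp[q].dropna().to_numpy()
            if len(vals) >= 2:
                per_rater[int(rid)] = (float(np.std(vals, ddof=1)),
                                       float(np.mean(vals)))
        means = np.array([m for _, m in per_rater.values()])
        gmean, gsd = float(np.mean(means)), float(np.std(means, ddof=1))
        for rid, (sd, m) in per_rater.items():
            if sd < sd_threshold:
                pairs[(rid, q)] = "low_variability"
            elif gsd > 0 and abs(m - gmean) > outlier_sd * gsd:
                pairs[(rid, q)] = "outlier"
    return excluded_raters, pairs


def inject_qc_violations(decisions: pd.DataFrame, ratings: pd.DataFrame,
                         spec: QCViolationSpec, config: SyntheticConfig):
    """Plant QC violations and return contaminated tables plus ground truth.

    Returns ``(decisions, ratings, truth)``. ``truth`` carries both the
    planted assignments and a rule-level ground truth obtained by a direct
    loop evaluation of the documented exclusion rules on the contaminated
    tables (the planted violations are decisive by construction and are a
    subset of the rule-level truth).
    """
    rng = config.rng(5)
    decisions = decisions.copy()
    ratings = ratings.copy()
    pids = decisions["participant_id"].unique()
    n_dec = (spec.n_attention_failers + spec.n_inconsistent
             + spec.n_straightliners + spec.n_cant_imagine)
    if n_dec > len(pids):
        raise ConfigError("planted decision violations exceed participants")
    chosen = rng.choice(pids, size=n_dec, replace=False)
    cursor = 0
    planted = {"decision": {}, "rater": {}, "rater_question": {}}

    for _ in range(spec.n_attention_failers):
        pid = int(chosen[cursor]); cursor += 1
        mask = ((decisions["participant_id"] == pid)
                & (decisions["attention_item"] == 1))
        idx = decisions.index[mask][:2]
        decisions.loc[idx, "attention_passed"] = False
        planted["decision"][pid] = "attention"
    for _ in range(spec.n_inconsistent):
        pid = int(chosen[cursor]); cursor += 1
        sub = decisions[(decisions["participant_id"] == pid)
                        & (decisions["repeat_tag"] != "")]
        for tag in sorted(sub["repeat_tag"].unique())[:2]:
            pair = sub[sub["repeat_tag"] == tag]
            i = pair.index[-1]
            lvl = int(decisions.loc[pair.index[0], "wth_level"])
            decisions.loc[i, "wth_level"] = 2 if lvl >= 4 else 5
        planted["decision"][pid] = "inconsistent"
    for _ in range(spec.n_straightliners):
        pid = int(chosen[cursor]); cursor += 1
        mask = ((decisions["participant_id"] == pid)
                & (decisions["attention_item"] == 0))
        decisions.loc[mask, "wth_level"] = 4
        planted["decision"][pid] = "straight_line"
    for _ in range(spec.n_cant_imagine):
        pid = int(chosen[cursor]); cursor += 1
        mask = ((decisions["participant_id"] == pid)
                & (decisions["attention_item"] == 0)
                & (decisions["repeat_tag"] == ""))
        idx = decisions.index[mask][:10]
        decisions.loc[idx, "cant_imagine"] = 1
        planted["decision"][pid] = "cant_imagine"

    rids = ratings["rater_id"].unique()
    n_rat = (spec.n_rater_attention_failers + spec.n_low_variability_pairs
             + spec.n_outlier_pairs)
    if n_rat > len(rids):
        raise ConfigError("planted rating violations exceed raters")
    rchosen = rng.choice(rids, size=n_rat, replace=False)
    cursor = 0
    for _ in range(spec.n_rater_attention_failers):
        rid = int(rchosen[cursor]); cursor += 1
        mask = ((ratings["rater_id"] == rid)
                & (ratings["attention_item"] == 1))
        idx = ratings.index[mask][:2]
        ratings.loc[idx, "attention_passed"] = False
        planted["rater"][rid] = "attention"
    q_pool = [q for q in EFA_QUESTIONS]
    for k in range(spec.n_low_variability_pairs):
        rid = int(rchosen[cursor]); cursor += 1
        q = q_pool[k % len(q_pool)]
        mask = ((ratings["rater_id"] == rid)
                & (ratings["attention_item"] == 0))
        ratings.loc[mask, q] = 3.0
        planted["rater_question"][f"{rid}:{q}"] = "low_variability"
    for k in range(spec.n_outlier_pairs):
        rid = int(rchosen[cursor]); cursor += 1
        q = q_pool[(k + 1) % len(q_pool)]
        mask = ratings.index[(ratings["rater_id"] == rid)
                             & (ratings["attention_item"] == 0)]
        vals = np.tile([4.0, 5.0], len(mask) // 2 + 1)[:len(mask)]
        ratings.loc[mask, q] = vals
        planted["rater_question"][f"{rid}:{q}"] = "outlier"

    dec_truth = _oracle_decision_truth(decisions)
    rater_truth, pair_truth = _oracle_rating_truth(ratings)
    truth = {
        "planted": planted,
        "decision_exclusions": dec_truth,
        "rater_exclusions": rater_truth,
        "rater_question_exclusions": {f"{r}:{q}": rule
                                      for (r, q), rule in pair_truth.items()},
    }
    return decisions, ratings, truth


# ---------------------------------------------------------------------------
# one-call generation and CSV export


def generate_all(config: SyntheticConfig,
                 violations: QCViolationSpec | None = None) -> dict:
    """Generate every table; returns a dict of DataFrames plus truth."""
    latents = gen_scenarios(config)
    ratings = gen_motivation_ratings(latents, config)
    agents, traits = gen_agents(config)
    decisions = gen_decisions(agents, latents, config)
    truth = {"planted": {"decision": {}, "rater": {}, "rater_question": {}},
             "decision_exclusions": {}, "rater_exclusions": {},
             "rater_question_exclusions": {}}
    if violations is not None:
        decisions, ratings, truth = inject_qc_violations(
            decisions, ratings, violations, config)
    return {
        "scenarios": latents,
        "ratings": ratings,
        "agents": agents,
        "traits": traits,
        "decisions": decisions,
        "truth": truth,
    }


def write_dataset(data: dict, outdir) -> None:
    """Write the generated tables as UTF-8 RFC-4180 CSVs plus truth.json."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data["decisions"].to_csv(outdir / "decisions.csv", index=False)
    data["ratings"].to_csv(outdir / "ratings.csv", index=False)
    data["traits"].to_csv(outdir / "traits.csv", index=False)
    data["scenarios"].to_csv(outdir / "scenarios.csv", index=False)
    truth = dict(data["truth"])
    truth["agents"] = data["agents"].to_dict(orient="list")
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, default=str)
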
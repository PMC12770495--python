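"""Data-quality exclusion rules, consensus ratings and inter-rater reliability.

The decision survey excludes a participant who (in this precedence order)
(1) failed two or more attention checks, (2) gave two or more inconsistent
binary help decisions across the three repeated scenarios, (3) straight-lined
(standard deviation of the WTH ratings, on the -5..5 code scale, below 0.5),
or (4) flagged ten or more scenarios as impossible to understand or imagine.
Surviving participants' flagged trials are dropped.

The rating survey excludes raters failing two or more attention checks, and
then individual rater-question pairs whose ratings across the rater's
scenarios have standard deviation below 0.1 (low variability) or whose mean
lies more than three standard deviations from the group mean of rater means
on that question (outlier). Consensus ratings are arithmetic means across
surviving raters.

Inter-rater reliability is ICC(A,k): two-way random effects, absolute
agreement, average measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import ALL_QUESTIONS

__all__ = [
    "code_wth",
    "WTH_CODE_MAP",
    "apply_decision_qc",
    "apply_rating_qc",
    "compute_consensus",
    "icc_a_k",
    "QCReport",
]

#: Fixed monotone map from the 6-point level to the -5..5 code scale.
WTH_CODE_MAP = {1: -5, 2: -3, 3: -1, 4: 1, 5: 3, 6: 5}

DECISION_RULES = ("attention", "inconsistent", "straight_line",
                  "cant_imagine")
RATING_RULES = ("attention", "low_variability", "outlier")


def code_wth(wth_level):
    """Map a 6-point WTH level to its -5..5 code and the binary help
    decision (help iff level >= 4, i.e. code > 0)."""
    arr = np.asarray(wth_level)
    if not np.isin(arr, list(WTH_CODE_MAP)).all():
        raise ValueError("wth_level values must be integers 1..6")
    codes = np.vectorize(WTH_CODE_MAP.get)(arr)
    help_ = (arr >= 4).astype(int)
    if np.isscalar(wth_level) or np.ndim(wth_level) == 0:
        return int(codes), int(help_)
    return codes.astype(int), help_


@dataclass
class QCReport:
    """Exclusions from one QC pass; each exclusion names the first rule
    (in documented order) that it hit."""

    excluded_participants: dict = field(default_factory=dict)
    excluded_raters: dict = field(default_factory=dict)
    excluded_rater_questions: dict = field(default_factory=dict)
    n_excluded_trials: int = 0
    warnings: list = field(default_factory=list)

    @property
    def counts(self) -> dict:
        out = {}
        for rule in DECISION_RULES:
            out[f"participants_{rule}"] = sum(
                1 for r in self.excluded_participants.values() if r == rule)
        for rule in RATING_RULES:
            out[f"raters_{rule}"] = sum(
                1 for r in self.excluded_raters.values() if r == rule)
            out[f"rater_questions_{rule}"] = sum(
                1 for r in self.excluded_rater_questions.values()
                if r == rule)
        out["excluded_trials"] = self.n_excluded_trials
        return out

    def to_dict(self) -> dict:
        return {
            "excluded_participants": {str(k): v for k, v
                                      in self.excluded_participants.items()},
            "excluded_raters": {str(k): v for k, v
                                in self.excluded_raters.items()},
            "excluded_rater_questions": {
                f"{r}:{q}": rule for (r, q), rule
                in self.excluded_rater_questions.items()},
            "n_excluded_trials": self.n_excluded_trials,
            "counts": self.counts,
        }


_REQUIRED_DECISION_COLS = {"participant_id", "scenario_id", "wth_level",
                           "attention_item", "attention_passed",
                           "repeat_tag", "cant_imagine"}


def apply_decision_qc(raw: pd.DataFrame, sd_threshold: float = 0.5,
                      cant_imagine_threshold: int = 10,
                      ) -> tuple[pd.DataFrame, QCReport]:
    """Apply the four decision-survey exclusion rules.

    Returns the cleaned per-trial dataset (with ``wth_code`` and ``help``
    added, attention rows and duplicate repeat rows removed, and flagged
    trials dropped) and a :class:`QCReport`.
    """
    missing = _REQUIRED_DECISION_COLS - set(raw.columns)
    if missing:
        raise ValueError(f"decision table missing columns: {sorted(missing)}")
    raw = raw.copy()
    raw["repeat_tag"] = raw["repeat_tag"].fillna("").astype(str)
    report = QCReport()
    rated_all = raw[raw["attention_item"] == 0]
    if not rated_all["wth_level"].isin(list(WTH_CODE_MAP)).all():
        raise ValueError("wth_level values must be integers 1..6")

    att = raw[raw["attention_item"] == 1]
    att_fail = (~att["attention_passed"].astype(bool)).groupby(
        att["participant_id"]).sum()

    rep = rated_all[rated_all["repeat_tag"] != ""]
    inconsistent = {}
    for (pid, tag), pair in rep.groupby(["participant_id", "repeat_tag"]):
        if len(pair) >= 2:
            helps = (pair["wth_level"] >= 4).to_numpy()
            if helps.min() != helps.max():
                inconsistent[pid] = inconsistent.get(pid, 0) + 1

    codes = rated_all["wth_level"].map(WTH_CODE_MAP)
    sd = codes.groupby(rated_all["participant_id"]).std(ddof=1).fillna(0.0)
    n_ci = rated_all.groupby("participant_id")["cant_imagine"].sum()

    for pid in raw["participant_id"].unique():
        if att_fail.get(pid, 0) >= 2:
            report.excluded_participants[pid] = "attention"
        elif inconsistent.get(pid, 0) >= 2:
            report.excluded_participants[pid] = "inconsistent"
        elif sd.get(pid, 0.0) < sd_threshold:
            report.excluded_participants[pid] = "straight_line"
        elif n_ci.get(pid, 0) >= cant_imagine_threshold:
            report.excluded_participants[pid] = "cant_imagine"

    keep = rated_all[~rated_all["participant_id"].isin(
        report.excluded_participants)]
    flagged = keep["cant_imagine"].astype(bool)
    report.n_excluded_trials = int(flagged.sum())
    keep = keep[~flagged]
    # one row per repeated scenario: keep the first occurrence of each tag
    is_rep = keep["repeat_tag"] != ""
    first = keep[is_rep].groupby(["participant_id", "repeat_tag"],
                                 sort=False).head(1)
    keep = pd.concat([keep[~is_rep], first]).sort_index()
    codes, help_ = code_wth(keep["wth_level"].to_numpy())
    clean = keep.assign(wth_code=codes, help=help_)
    clean = clean.drop(columns=["attention_item", "attention_passed"])
    return clean.reset_index(drop=True), report


_REQUIRED_RATING_COLS = {"rater_id", "scenario_id", "attention_item",
                         "attention_passed", "cant_imagine"}


def apply_rating_qc(raw: pd.DataFrame, questions=ALL_QUESTIONS,
                    sd_threshold: float = 0.1, outlier_sd: float = 3.0,
                    ) -> tuple[pd.DataFrame, QCReport]:
    """Apply the rating-survey exclusion rules.

    Rater-level: >=2 attention failures. Pair-level (rater x question, after
    dropping flagged scenarios): low variability (SD < ``sd_threshold``)
    first, then group-mean outlier (>= ``outlier_sd`` SD from the group mean
    of rater means). Excluded pairs are set to missing; excluded raters are
    dropped entirely.
    """
    missing = _REQUIRED_RATING_COLS - set(raw.columns)
    if missing:
        raise ValueError(f"rating table missing columns: {sorted(missing)}")
    questions = [q for q in questions if q in raw.columns]
    report = QCReport()
    att = raw[raw["attention_item"] == 1]
    att_fail = (~att["attention_passed"].astype(bool)).groupby(
        att["rater_id"]).sum()
    for rid, n in att_fail.items():
        if n >= 2:
            report.excluded_raters[rid] = "attention"

    rated = raw[(raw["attention_item"] == 0)].copy()
    flagged = rated["cant_imagine"].astype(bool)
    report.n_excluded_trials = int(flagged.sum())
    rated = rated[~flagged]
    rated = rated[~rated["rater_id"].isin(report.excluded_raters)]

    for q in questions:
        stats_ = rated.groupby("rater_id")[q].agg(["std", "mean", "count"])
        few = stats_[stats_["count"] < 2]
        for rid in few.index:
            report.warnings.append(
                f"rater {rid} has <2 ratings on {q}; SD rule skipped")
        usable = stats_[stats_["count"] >= 2]
        gmean = usable["mean"].mean()
        gsd = usable["mean"].std(ddof=1)
        for rid, row in usable.iterrows():
            if row["std"] < sd_threshold:
                report.excluded_rater_questions[(rid, q)] = "low_variability"
            elif gsd > 0 and abs(row["mean"] - gmean) > outlier_sd * gsd:
                report.excluded_rater_questions[(rid, q)] = "outlier"

    clean = rated.copy()
    for (rid, q), _rule in report.excluded_rater_questions.items():
        clean.loc[clean["rater_id"] == rid, q] = np.nan
    return clean.reset_index(drop=True), report


def compute_consensus(clean_ratings: pd.DataFrame, decisions=None,
                      questions=ALL_QUESTIONS, min_raters: int = 25,
                      ) -> pd.DataFrame:
    """Per-scenario consensus: mean rating and rater count per dimension,
    plus mean WTH and % help when a clean decision table is supplied.

    Raises when any scenario-dimension cell has zero surviving raters; warns
    when a scenario has fewer than ``min_raters`` raters overall.
    """
    questions = [q for q in questions if q in clean_ratings.columns]
    g = clean_ratings.groupby("scenario_id")
    means = g[questions].mean()
    counts = g[questions].count()
    empty = [(sid, q) for q in questions
             for sid in counts.index[counts[q] == 0]]
    if empty:
        raise ValueError(f"cells with zero surviving raters: {empty[:20]}")
    low = counts.min(axis=1)
    for sid in low.index[low < min_raters]:
        warnings.warn(f"scenario {sid} has fewer than {min_raters} raters "
                      f"({int(low[sid])})", stacklevel=2)
    out = means.copy()
    out.columns = [f"{q}_mean" for q in questions]
    for q in questions:
        out[f"{q}_n"] = counts[q]
    if decisions is not None:
        d = decisions.groupby("scenario_id")
        out["wth_mean"] = d["wth_code"].mean()
        out["pct_help"] = d["help"].mean() * 100.0
    return out.reset_index()


# ---------------------------------------------------------------------------
# inter-rater reliability


def _icc_from_ms(ms_scenario, ms_rater, ms_error, n_scenarios):
    return ((ms_scenario - ms_error)
            / (ms_scenario + (ms_rater - ms_error) / n_scenarios))


def icc_a_k(matrix, method: str = "auto") -> float:
    """ICC(A,k): two-way random effects, absolute agreement, average
    measures, for a raters x scenarios matrix (NaN = missing).

    ``method='complete'`` drops raters with missing cells and computes the
    balanced two-way mean squares; ``method='ems'`` estimates the mean
    squares from all available cells through an unbalanced two-way ANOVA
    (OLS with scenario and rater effects); ``'auto'`` uses the complete-case
    path when the complete sub-matrix spans >=2 raters and >=2 scenarios.
    """
    X = pd.DataFrame(matrix).astype(float)
    X = X.dropna(axis=1, how="all").dropna(axis=0, how="all")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >=2 raters and >=2 scenarios with ratings")
    complete = X.dropna(axis=0, how="any")
    if method not in ("auto", "complete", "ems"):
        raise ValueError("method must be 'auto', 'complete' or 'ems'")
    if method == "auto":
        method = "complete" if complete.shape[0] >= 2 else "ems"
    if method == "complete":
        if complete.shape[0] < 2:
            raise ValueError("complete sub-matrix has fewer than 2 raters")
        A = complete.to_numpy()
        k, n = A.shape
        grand = A.mean()
        ms_scn = k * np.sum((A.mean(axis=0) - grand) ** 2) / (n - 1)
        ms_rat = n * np.sum((A.mean(axis=1) - grand) ** 2) / (k - 1)
        sse = np.sum((A - A.mean(axis=0)[None, :]
                      - A.mean(axis=1)[:, None] + grand) ** 2)
        ms_err = sse / ((n - 1) * (k - 1))
        return float(_icc_from_ms(ms_scn, ms_rat, ms_err, n))
    # expected-mean-squares on all available cells
    long = X.stack().rename("y").reset_index()
    long.columns = ["rater", "scenario", "y"]
    y = long["y"].to_numpy()
    n = long["scenario"].nunique()
    k = long["rater"].nunique()
    if n < 2 or k < 2:
        raise ValueError("need >=2 raters and >=2 scenarios with overlap")
    Ds = pd.get_dummies(long["scenario"], drop_first=True, dtype=float)
    Dr = pd.get_dummies(long["rater"], drop_first=True, dtype=float)
    ones = np.ones((len(y), 1))

    def rss(M):
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    rss_s = rss(np.column_stack([ones, Ds]))
    rss_r = rss(np.column_stack([ones, Dr]))
    rss_full = rss(np.column_stack([ones, Ds, Dr]))
    df_err = len(y) - 1 - (n - 1) - (k - 1)
    if df_err < 1:
        raise ValueError("not enough overlapping ratings for the two-way "
                         "decomposition")
    ms_err = rss_full / df_err
    ms_scn = (rss_r - rss_full) / (n - 1)   # scenario SS adjusted for raters
    ms_rat = (rss_s - rss_full) / (k - 1)   # rater SS adjusted for scenarios
    return float(_icc_from_ms(ms_scn, ms_rat, ms_err, n))


def icc_table(clean_ratings: pd.DataFrame, questions=ALL_QUESTIONS,
              method: str = "auto") -> pd.DataFrame:
    """ICC(A,k) per motivation dimension from a clean rating table."""
    rows = []
    for q in questions:
        if q not in clean_ratings.columns:
            continue
        mat = clean_ratings.pivot_table(index="rater_id",
                                        columns="scenario_id", values=q)
        rows.append({
            "dimension": q,
            "icc_a_k": icc_a_k(mat, method=method),
            "n_raters": mat.notna().any(axis=1).sum(),
            "n_scenarios": mat.notna().any(axis=0).sum(),
        })
    return pd.DataFrame(rows)
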
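"""End-to-end orchestration: simulate -> QC -> consensus -> EFA -> choice
models -> representational spaces -> trait statistics.

A :class:`PipelineConfig` (JSON on disk, sections per stage) either points at
existing input CSVs or requests synthetic data; :func:`run` executes the
requested stages in dependency order, writes every artifact under the output
directory, and returns a manifest (config echo, seeds, input hashes, outputs,
versions). All randomness derives from the global seed, so a rerun with the
same config reproduces identical outputs (the timing log file aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .choice import MODEL_IDS, compare_models, fit_participant
from .factors import FactorModel, motivation_wth_lmm, normalize_scores
from .qc import apply_decision_qc, apply_rating_qc, compute_consensus, icc_table
from .spaces import (decision_matrix, decision_rdm, decompose_decision_rdm,
                     mds_embed, motivation_rdms, quadrant_anova,
                     rdm_regression, rsa, semantic_space)
from .stats import correlate, group_compare, trait_effect_grid
from .synth import (EFA_QUESTIONS, QCViolationSpec, SyntheticConfig,
                    generate_all, write_dataset)

__all__ = ["PipelineConfig", "run", "ALL_STAGES"]

ALL_STAGES = ("simulate", "qc", "consensus", "factors", "fit", "spaces",
              "traits")

log = logging.getLogger("helpchoice")

#: Trait-parameter and trait-WTH test families (Bonferroni applied within
#: each family separately).
TRAIT_FAMILY = ("iri_ec", "svo", "rr", "bis", "agreeableness")
PARAM_HYPOTHESES = (("b", "agreeableness"), ("b", "iri_ec"), ("b", "svo"),
                    ("w_cost", "bis"), ("w_cost", "rr"))


@dataclass
class PipelineConfig:
    out_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"
    synthetic: bool = True
    synth: SyntheticConfig | None = None
    inputs: dict = field(default_factory=dict)   # stage -> csv path
    stages: tuple = ALL_STAGES
    models: tuple = ("1.0", "2.0")
    n_restarts: int = 10
    run_loo: bool = False
    run_lmm: bool = True
    n_factors: int | None = None                 # None: parallel analysis
    n_perm: int = 5000
    n_parallel_sim: int = 500
    umap_seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for m in self.models:
            if str(m) not in MODEL_IDS:
                raise ValueError(f"unknown model id {m!r}")
        if not self.synthetic and "simulate" in self.stages:
            raise ValueError("stage 'simulate' requires synthetic=True")
        if not self.synthetic:
            for key in ("decisions", "ratings", "scenarios", "traits"):
                if key not in self.inputs:
                    raise ValueError(f"inputs missing path for {key!r}")
        if self.synth is None and self.synthetic:
            self.synth = SyntheticConfig(seed=self.seed)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        synth = raw.pop("synth", None)
        if synth is not None:
            if "loading_matrix" in synth:
                synth["loading_matrix"] = np.asarray(synth["loading_matrix"])
            synth = SyntheticConfig(**synth)
        for key in ("stages", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synth=synth, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def _load_decisions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "scenario_id", "wth_level"}
    if not required <= set(df.columns):
        raise ValueError(
            f"decision file {path} missing columns "
            f"{sorted(required - set(df.columns))}")
    att = (df["attention_item"] if "attention_item" in df.columns
           else pd.Series(0, index=df.index))
    levels = df.loc[att == 0, "wth_level"]
    if not levels.isin(range(1, 7)).all():
        raise ValueError(f"decision file {path} has wth_level outside 1..6")
    return df


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns and writes the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper()),
                        format="%(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    stages = [s for s in ALL_STAGES if s in config.stages]
    manifest = {
        "config": {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                       else v)
                   for k, v in dataclasses.asdict(config).items()},
        "seed": config.seed,
        "version": __version__,
        "stages": stages,
        "inputs": {},
        "outputs": {},
    }
    if config.synth is not None:
        manifest["config"]["synth"]["loading_matrix"] = np.asarray(
            config.synth.loading_matrix).tolist()
        manifest["config"]["synth"]["trait_param_corr"] = {
            f"{t}:{p}": rho
            for (t, p), rho in config.synth.trait_param_corr.items()}
    state: dict = {}

    def finish(stage, t0, *paths):
        log.info("stage %s finished in %.1fs", stage, time.time() - t0)
        manifest["outputs"][stage] = sorted(str(p.name) for p in paths)

    # ----- inputs / simulate
    t0 = time.time()
    if config.synthetic:
        data = generate_all(config.synth,
                            violations=QCViolationSpec())
        state.update(data)
        if "simulate" in stages:
            write_dataset(data, out)
            finish("simulate", t0, *(out / f for f in (
                "decisions.csv", "ratings.csv", "traits.csv",
                "scenarios.csv", "truth.json")))
    else:
        state["decisions"] = _load_decisions(config.inputs["decisions"])
        state["ratings"] = pd.read_csv(config.inputs["ratings"])
        state["scenarios"] = pd.read_csv(config.inputs["scenarios"])
        state["traits"] = pd.read_csv(config.inputs["traits"])
        for key, path in config.inputs.items():
            manifest["inputs"][key] = _sha256(Path(path))

    # ----- qc
    if "qc" in stages:
        t0 = time.time()
        clean_dec, dec_report = apply_decision_qc(state["decisions"])
        clean_rat, rat_report = apply_rating_qc(state["ratings"])
        state["clean_decisions"] = clean_dec
        state["clean_ratings"] = clean_rat
        report = {"decisions": dec_report.to_dict(),
                  "ratings": rat_report.to_dict()}
        _write_json(report, out / "qc_report.json")
        clean_dec.to_csv(out / "decisions_clean.csv", index=False)
        log.info("excluded %d participants, %d rater-question pairs",
                 len(dec_report.excluded_participants),
                 len(rat_report.excluded_rater_questions))
        finish("qc", t0, out / "qc_report.json", out / "decisions_clean.csv")

    # ----- consensus + reliability
    if "consensus" in stages:
        t0 = time.time()
        consensus = compute_consensus(state["clean_ratings"],
                                      decisions=state.get("clean_decisions"))
        state["consensus"] = consensus
        consensus.to_csv(out / "consensus.csv", index=False)
        icc = icc_table(state["clean_ratings"])
        icc.to_csv(out / "icc.csv", index=False)
        finish("consensus", t0, out / "consensus.csv", out / "icc.csv")

    # ----- factors
    if "factors" in stages:
        t0 = time.time()
        consensus = state["consensus"].set_index("scenario_id")
        efa_matrix = consensus[[f"{q}_mean" for q in EFA_QUESTIONS]]
        efa_matrix.columns = list(EFA_QUESTIONS)
        fm = FactorModel(efa_matrix)
        n_pa = fm.n_factors(n_sim=config.n_parallel_sim,
                            seed=config.seed + 101)
        n_factors = config.n_factors or max(2, n_pa)
        solution = fm.fit(n_factors)
        state["solution"] = solution
        scores = normalize_scores(solution,
                                  consensus["q02_mean"].to_numpy())
        scores["scenario_id"] = efa_matrix.index
        state["scores"] = scores
        _write_json({
            "n_factors_parallel": n_pa,
            "n_factors_used": n_factors,
            "loadings": solution.loadings.round(6).to_dict(),
            "eigenvalues": solution.eigenvalues.round(6).tolist(),
            "variance_explained_total":
                round(solution.variance_explained_total, 6),
            "item_assignment": solution.item_assignment,
        }, out / "factors.json")
        scores.to_csv(out / "motivation_scores.csv", index=False)
        outputs = [out / "factors.json", out / "motivation_scores.csv"]
        if config.run_lmm:
            rows = []
            dec = state["clean_decisions"]
            for q in EFA_QUESTIONS:
                res = motivation_wth_lmm(
                    dec, consensus[f"{q}_mean"], dimension=q)
                rows.append(dataclasses.asdict(res))
            pd.DataFrame(rows).to_csv(out / "lmm_results.csv", index=False)
            outputs.append(out / "lmm_results.csv")
        finish("factors", t0, *outputs)

    # ----- choice model fitting
    if "fit" in stages:
        t0 = time.time()
        dec = state["clean_decisions"].merge(state["scores"],
                                             on="scenario_id")
        rows = []
        rng = np.random.default_rng([config.seed, 7])
        for model_id in config.models:
            for pid, grp in dec.groupby("participant_id"):
                res = fit_participant(grp, model_id=str(model_id),
                                      n_restarts=config.n_restarts,
                                      seed=int(rng.integers(2**31 - 1)),
                                      participant_id=pid)
                row = res.to_row()
                if config.run_loo:
                    row["loo_accuracy"] = res.loo_accuracy(
                        n_restarts=2, seed=int(rng.integers(2**31 - 1)))
                rows.append(row)
        fits = pd.DataFrame(rows)
        state["fits"] = fits
        fits.to_csv(out / "fits.csv", index=False)
        comparison = compare_models(fits)
        comparison.to_csv(out / "comparison.csv")
        best = comparison["BIC_mean"].idxmin()
        log.info("best model by group-mean BIC: %s", best)
        finish("fit", t0, out / "fits.csv", out / "comparison.csv")

    # ----- representational spaces
    if "spaces" in stages:
        t0 = time.time()
        dec = state["clean_decisions"]
        scores = state["scores"].sort_values("scenario_id")
        wth_matrix = decision_matrix(dec)
        # drop scenarios until every pair has at least one common rater
        while True:
            present = wth_matrix.notna().to_numpy()
            overlap = present.T.astype(int) @ present.astype(int)
            zero = (overlap == 0).sum(axis=0)
            if not zero.any():
                break
            worst = wth_matrix.columns[int(np.argmax(zero))]
            log.warning("dropping scenario %s from the spaces stage "
                        "(no rater overlap with %d scenarios)",
                        worst, int(zero.max()))
            wth_matrix = wth_matrix.drop(columns=worst)
        scen_order = wth_matrix.columns.to_numpy()
        rdm_dec = decision_rdm(wth_matrix)
        scores_o = scores.set_index("scenario_id").loc[scen_order]
        rdm_mot, rdm_ben, rdm_cost = motivation_rdms(scores_o)
        scen = state["scenarios"].set_index("scenario_id").loc[scen_order]
        emb_cols = [c for c in scen.columns if c.startswith("e")
                    and c[1:].isdigit()]
        sem_emb, rdm_sem, sem_labels = semantic_space(
            scen[emb_cols], seed=(config.umap_seed
                                  if config.umap_seed is not None
                                  else config.seed))
        state["semantic_labels"] = pd.Series(sem_labels, index=scen_order)
        mds = mds_embed(rdm_dec, seed=config.seed)
        names = {"decision": rdm_dec, "motivation": rdm_mot,
                 "benefit": rdm_ben, "cost": rdm_cost, "semantic": rdm_sem}
        outputs = []
        for name, rdm in names.items():
            p = out / f"rdm_{name}.csv"
            pd.DataFrame(rdm, index=scen_order,
                         columns=scen_order).to_csv(p)
            outputs.append(p)
        mds.coords.assign(scenario_id=scen_order).to_csv(
            out / "coords_decision.csv", index=False)
        sem_emb.coords.assign(scenario_id=scen_order,
                              cluster=sem_labels).to_csv(
            out / "coords_semantic.csv", index=False)
        rsa_results = []
        rng = np.random.default_rng([config.seed, 8])
        for a, b in (("decision", "motivation"), ("decision", "semantic"),
                     ("motivation", "semantic")):
            res = rsa(names[a], names[b], n_perm=config.n_perm,
                      seed=int(rng.integers(2**31 - 1)), labels=(a, b))
            rsa_results.append(dataclasses.asdict(res))
        _write_json(rsa_results, out / "rsa_results.json")
        mean_wth = dec.groupby("scenario_id")["wth_code"].mean() \
            .loc[scen_order].to_numpy()
        rdm_wth, rdm_resid = decompose_decision_rdm(rdm_dec, mean_wth)
        regs = {}
        for target_name, target in (("wth", rdm_wth),
                                    ("residual", rdm_resid)):
            tab = rdm_regression(target, {"benefit": rdm_ben,
                                          "cost": rdm_cost,
                                          "semantic": rdm_sem})
            regs[target_name] = {
                "r_squared": tab.attrs["r_squared"],
                "coefficients": tab.round(6).to_dict(orient="records")}
        _write_json(regs, out / "rdm_regressions.json")
        anova = quadrant_anova(mean_wth,
                               scores_o["quadrant"].to_numpy())
        _write_json({"welch": anova["welch"],
                     "posthoc": anova["posthoc"].round(6).to_dict(
                         orient="records")},
                    out / "quadrant_anova.json")
        finish("spaces", t0, *outputs, out / "rsa_results.json",
               out / "rdm_regressions.json", out / "quadrant_anova.json")

    # ----- trait statistics
    if "traits" in stages:
        t0 = time.time()
        dec = state["clean_decisions"]
        traits = state["traits"]
        wth = dec.groupby("participant_id")["wth_code"].mean()
        merged = traits.set_index("participant_id").join(
            wth.rename("wth"), how="inner")
        rng = np.random.default_rng([config.seed, 9])
        rows = []
        for trait in TRAIT_FAMILY:
            res = correlate(merged[trait], merged["wth"],
                            n_perm=config.n_perm, n_boot=config.n_perm,
                            family_size=len(TRAIT_FAMILY),
                            seed=int(rng.integers(2**31 - 1)),
                            pair=(trait, "wth"))
            rows.append(dataclasses.asdict(res))
        if "fits" in state:
            best = state["fits"]
            sel = best[best["model_id"] == "2.0"] if \
                (best["model_id"] == "2.0").any() else best
            par = sel.set_index("participant_id")
            for param, trait in PARAM_HYPOTHESES:
                if param not in par.columns:
                    continue
                joined = par[[param]].join(
                    traits.set_index("participant_id")[trait],
                    how="inner").dropna()
                res = correlate(joined[param], joined[trait],
                                n_perm=config.n_perm, n_boot=config.n_perm,
                                family_size=len(PARAM_HYPOTHESES),
                                seed=int(rng.integers(2**31 - 1)),
                                pair=(param, trait))
                rows.append(dataclasses.asdict(res))
        pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)
        outputs = [out / "correlations.csv"]
        gc_rows = []
        for demo in ("sex",):
            if demo in merged.columns:
                res = group_compare(merged["wth"], merged[demo])
                gc_rows.append({"variable": demo, "test": res.test,
                                "statistic": res.statistic,
                                "df": list(res.df), "p": res.p})
        if gc_rows:
            pd.DataFrame(gc_rows).to_csv(out / "group_tests.csv",
                                         index=False)
            outputs.append(out / "group_tests.csv")
        if "semantic_labels" in state:
            cat = state["semantic_labels"]
            dec_cat = dec.assign(
                category=dec["scenario_id"].map(cat))
            trait_grid_src = traits[["participant_id", *TRAIT_FAMILY]]
            if "fits" in state:
                pars = sel.reset_index()[
                    ["participant_id"]
                    + [c for c in ("w_cost", "b") if c in sel.columns]]
                trait_grid_src = trait_grid_src.merge(pars,
                                                      on="participant_id")
            grid = trait_effect_grid(dec_cat, trait_grid_src,
                                     n_boot=min(config.n_perm, 2000),
                                     seed=int(rng.integers(2**31 - 1)))
            grid.to_csv(out / "effect_grid.csv", index=False)
            outputs.append(out / "effect_grid.csv")
        finish("traits", t0, *outputs)

    _write_json(manifest, out / "manifest.json")
    log.removeHandler(fh)
    fh.close()
    return manifest
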
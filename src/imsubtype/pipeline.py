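"""End-to-end orchestration: simulate/load -> score -> screen -> cluster ->
validate -> characterize -> co-express, with a reproducible run manifest.

A single structured config drives the run. One global seed is expanded
into per-stage seeds through ``numpy.random.SeedSequence`` spawn keys so
any stage can be re-run in isolation with the same stream. Every stage
writes plain TSV outputs and registers their SHA-256 hashes in
``manifest.json``; identical config + seed reproduce bitwise-identical
outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import characterize, coexpr, consensus, io, scoring, screen, simulate, validate

logger = logging.getLogger("imsubtype")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},            # SimulationConfig overrides; seeds per cohort added
    "scoring": {"alpha": 0.25, "normalize": True},
    "screen": {"p_thresh": 0.05, "min_days": 30, "min_cohorts": 2},
    "consensus": {"k_range": [2, 10], "n_resamples": 500, "frac": 0.8, "k": 3},
    "validation": {"metric": "pearson", "mode": "project"},
    "characterize": {"min_days": 30, "min_count": 3},
    "coexpression": {
        "enabled": True,
        "beta": 10, "signed": False, "min_size": 60, "deep_split": 4,
        "merge_height": 0.25, "mad_top": 0.5, "kme_thresh": 0.85,
        "p_thresh": 0.05, "max_genes": 1000,
    },
}


def merge_config(user: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _stage_seed(global_seed: int, stage_index: int) -> int:
    ss = np.random.SeedSequence(entropy=int(global_seed),
                                spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Book-keeping for one pipeline invocation."""

    def __init__(self, config: dict, outdir: Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config": config,
            "seed": config["seed"],
            "stages": [],
            "decisions": {
                "alpha": config["scoring"]["alpha"],
                "normalize": config["scoring"]["normalize"],
                "k": config["consensus"]["k"],
                "metric": config["validation"]["metric"],
                "mode": config["validation"]["mode"],
            },
        }

    def register(self, stage: str, seed: int | None, outputs: dict) -> None:
        self.manifest["stages"].append({
            "stage": stage,
            "seed": seed,
            "outputs": {name: _sha256(Path(p)) for name, p in outputs.items()},
        })

    def write_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return path


def _prepare_cohort(cohort: simulate.SyntheticCohort, alpha: float,
                    normalize: bool) -> scoring.SignatureScoreMatrix:
    filtered = io.filter_expressed_genes(cohort.expression)
    logged = io.log_transform(filtered)
    return scoring.ssgsea_scores(logged, cohort.signature_sets, alpha=alpha,
                                 normalize=normalize)


def run_pipeline(config: dict | None, outdir) -> Path:
    """Execute the full synthetic-cohort analysis; returns the output dir.

    Stages: simulate a discovery/validation cohort pair, expression filter
    + log transform + signature scoring, per-cohort Cox screen and
    cross-cohort overlap, consensus clustering of the discovery cohort with
    prognosis-ordered labels, nearest-centroid projection + IGP + centroid
    correlation on the validation cohort, survival/mutation/score
    characterization, and co-expression modules. On stage failure an
    INCOMPLETE marker naming the stage is left in the output directory.
    """
    cfg = merge_config(config)
    run = PipelineRun(cfg, Path(outdir))
    marker = run.outdir / "INCOMPLETE"
    stage = "setup"
    try:
        # --- simulate ---------------------------------------------------
        stage = "simulate"
        sim_seed = _stage_seed(cfg["seed"], 0)
        sim_cfg = simulate.SimulationConfig(
            **{**cfg["simulate"], "seed": sim_seed})
        disc, val = simulate.simulate_pair(sim_cfg, seed_a=sim_seed,
                                           seed_b=sim_seed + 1)
        paths_d = simulate.write_cohort(disc, run.outdir, "discovery")
        paths_v = simulate.write_cohort(val, run.outdir, "validation")
        run.register("simulate", sim_seed,
                     {f"discovery_{k}": v for k, v in paths_d.items()}
                     | {f"validation_{k}": v for k, v in paths_v.items()})

        # --- score ------------------------------------------------------
        stage = "score"
        alpha = cfg["scoring"]["alpha"]
        normalize = cfg["scoring"]["normalize"]
        scores = {"discovery": _prepare_cohort(disc, alpha, normalize),
                  "validation": _prepare_cohort(val, alpha, normalize)}
        outs = {}
        for name, mat in scores.items():
            p = run.outdir / f"{name}_scores.tsv"
            mat.scores.to_csv(p, sep="\t", index_label="signature")
            outs[name] = p
        run.register("score", None, outs)

        # --- screen + overlap --------------------------------------------
        stage = "screen"
        reports = []
        outs = {}
        survs = {"discovery": disc.survival, "validation": val.survival}
        for name in ("discovery", "validation"):
            rep = screen.screen_cohort(
                scores[name], survs[name],
                p_thresh=cfg["screen"]["p_thresh"],
                min_days=cfg["screen"]["min_days"], cohort_id=name)
            reports.append(rep)
            p = run.outdir / f"screen_{name}.tsv"
            rep.to_frame().to_csv(p, sep="\t", index=False)
            outs[name] = p
        selected = screen.overlap_filter(
            reports, min_cohorts=cfg["screen"]["min_cohorts"])
        if not selected:
            warnings.warn("overlap filter selected no features; falling back "
                          "to all scored signatures", stacklevel=2)
            selected = list(scores["discovery"].scores.index)
        p = run.outdir / "selected_features.txt"
        p.write_text("\n".join(selected) + "\n")
        outs["selected"] = p
        run.register("screen", None, outs)

        # --- consensus ---------------------------------------------------
        stage = "consensus"
        cons_seed = _stage_seed(cfg["seed"], 1)
        lo, hi = cfg["consensus"]["k_range"]
        result = consensus.consensus_run(
            scores["discovery"].scores.loc[selected].T,
            k_range=range(lo, hi + 1),
            n_resamples=cfg["consensus"]["n_resamples"],
            frac=cfg["consensus"]["frac"], seed=cons_seed)
        k = cfg["consensus"]["k"]
        assign = consensus.final_labels(result, k)
        assign = consensus.order_by_prognosis(assign, disc.survival)
        outs = {}
        p = run.outdir / "consensus_metrics.tsv"
        metrics = result.metrics_frame()
        metrics["suggested_k"] = result.suggest_k()
        metrics.to_csv(p, sep="\t", index=False)
        outs["metrics"] = p
        p = run.outdir / "consensus_matrix.tsv"
        pd.DataFrame(result.consensus[k], index=result.sample_ids,
                     columns=result.sample_ids).to_csv(
            p, sep="\t", index_label="sample_id")
        outs["matrix"] = p
        p = run.outdir / "discovery_assignment.tsv"
        assign.labels.to_frame().to_csv(p, sep="\t", index_label="sample_id")
        outs["assignment"] = p
        run.register("consensus", cons_seed, outs)

        # --- validation ---------------------------------------------------
        stage = "validate"
        proj = validate.NearestCentroidProjector().fit(
            scores["discovery"], assign)
        assign_val = proj.predict(scores["validation"])
        igp_rep = validate.igp(scores["validation"], assign_val,
                               metric=cfg["validation"]["metric"])
        cents_val = validate.subtype_centroids(scores["validation"], assign_val)
        corr, matching = validate.centroid_correlation(proj.centroids_,
                                                       cents_val)
        outs = {}
        p = run.outdir / "validation_assignment.tsv"
        assign_val.labels.to_frame().to_csv(p, sep="\t",
                                            index_label="sample_id")
        outs["assignment"] = p
        p = run.outdir / "validation_igp.tsv"
        igp_rep.to_frame().to_csv(p, sep="\t", index=False)
        outs["igp"] = p
        p = run.outdir / "centroid_correlation.tsv"
        corr.to_csv(p, sep="\t", index_label="label")
        outs["correlation"] = p
        run.register("validate", None, outs)

        # --- characterize --------------------------------------------------
        stage = "characterize"
        km = characterize.km_logrank(disc.survival, assign,
                                     min_days=cfg["characterize"]["min_days"])
        outs = {}
        km_rows = []
        for lab, curve in km.curves.items():
            c = curve.copy()
            c.insert(0, "subtype", lab)
            km_rows.append(c)
        p = run.outdir / "km_curves.tsv"
        pd.concat(km_rows).to_csv(p, sep="\t", index=False)
        outs["km"] = p
        p = run.outdir / "logrank.tsv"
        pd.DataFrame([{"statistic": km.statistic, "df": km.df,
                       "p": km.p_value}]).to_csv(p, sep="\t", index=False)
        outs["logrank"] = p
        burden = characterize.tmb(disc.mutations, assign.sample_ids)
        p = run.outdir / "tmb.tsv"
        burden.to_frame().to_csv(p, sep="\t", index_label="sample_id")
        outs["tmb"] = p
        mut_rows = characterize.mutation_frequency_test(
            disc.mutations, assign, min_count=cfg["characterize"]["min_count"])
        p = run.outdir / "mutation_screen.tsv"
        pd.DataFrame([
            {"gene": r.gene, **{f"mut_{k_}": v for k_, v in r.mutated.items()},
             "chi_square_p": r.chi_square_p, "passes": r.passes_min_count}
            for r in mut_rows
        ]).to_csv(p, sep="\t", index=False)
        outs["mutation_screen"] = p
        comps = characterize.compare_across_subtypes(
            scores["discovery"], list(scores["discovery"].scores.index), assign)
        p = run.outdir / "score_comparisons.tsv"
        pd.DataFrame([
            {"feature": c.feature_id, "kw_stat": c.kruskal_wallis_stat,
             "kw_p": c.kruskal_wallis_p}
            for c in comps
        ]).to_csv(p, sep="\t", index=False)
        outs["comparisons"] = p
        run.register("characterize", None, outs)

        # --- coexpression --------------------------------------------------
        if cfg["coexpression"]["enabled"]:
            stage = "coexpress"
            cx = cfg["coexpression"]
            logged = io.log_transform(io.filter_expressed_genes(disc.expression))
            filtered = coexpr.mad_filter(logged, top_prop=cx["mad_top"])
            frame = filtered.data
            if frame.shape[0] > cx["max_genes"]:
                mads = frame.sub(frame.median(axis=1), axis=0).abs().median(axis=1)
                frame = frame.loc[mads.sort_values(ascending=False)
                                  .index[:cx["max_genes"]]].sort_index()
            est = coexpr.CoexpressionModules(
                beta=cx["beta"], signed=cx["signed"], min_size=cx["min_size"],
                deep_split=cx["deep_split"], merge_height=cx["merge_height"],
            ).fit(frame)
            modules = est.modules_
            outs = {}
            p = run.outdir / "modules.tsv"
            modules.assignments.to_frame().to_csv(p, sep="\t",
                                                  index_label="gene")
            outs["modules"] = p
            p = run.outdir / "eigengenes.tsv"
            modules.eigengenes.to_csv(p, sep="\t", index_label="module")
            outs["eigengenes"] = p
            if modules.module_names:
                indicators = pd.get_dummies(assign.labels)
                trait_corr = coexpr.module_trait_correlation(modules,
                                                             indicators)
                p = run.outdir / "module_trait_correlation.tsv"
                trait_corr.to_csv(p, sep="\t", index=False)
                outs["trait_correlation"] = p
            run.register("coexpress", None, outs)

        run.write_manifest()
        if marker.exists():
            marker.unlink()
        return run.outdir
    except Exception as exc:
        marker.write_text(f"stage {stage!r} failed: {exc}\n")
        run.write_manifest()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
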
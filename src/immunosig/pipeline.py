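"""End-to-end orchestration: simulate -> preprocess/train -> rank -> score ->
stratify -> associate -> enrich, with a machine-readable run manifest.

Each stage writes its outputs under the run directory and registers them in
the manifest with content hashes, parameters and wall-clock time, so a rerun
with identical config and seeds reproduces identical hashes. A stage failure
halts the run; the manifest (written on the way out) marks the last stage
that completed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as iio
from .cohort import attach_scores, dichotomize
from .exceptions import ImmunosigError
from .gsea import enrichment_frame, gsea_preranked, rank_genes
from .models import (NormalizationSpec, TrainingConfig, encode,
                     orient_signatures, preprocess, save_model,
                     train_signature_model)
from .ranking import (GeneSetCollection, SUBCATEGORIES, make_immuno_collection,
                      rank_all_signatures, subcategory_profile)
from .simulate import SimulationConfig, simulate_cohort, simulate_single_cells
from .stats import (COX_COVARIATES, LOGISTIC_COVARIATES, SCORE_COLUMN,
                    compare_groups_wilcoxon, cox_adjusted, fisher_or,
                    km_logrank, logistic_adjusted, results_frame)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train", "rank", "score", "stratify", "associate", "gsea")


@dataclass
class RunConfig:
    """Single-file configuration of a full pipeline run."""

    outdir: str = "run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    k: int = 8
    epochs: int = 300
    alpha: float = 0.05
    top_k: int = 5
    stratify_method: str = "median"
    signature: str = "auto"       # "auto" = best-ranked signature
    n_perm: int = 500
    n_top_genes: int | None = None
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(**raw, simulation=sim)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {**asdict(cfg), "simulation": asdict(cfg.simulation)},
                      "stages": {}, "last_good_stage": None}
    sim = cfg.simulation
    if sim.seed != cfg.seed:
        sim.seed = cfg.seed

    state: dict = {}
    try:
        for stage in cfg.stages:
            t0 = time.perf_counter()
            outputs = _STAGE_FN[stage](cfg, out, state)
            manifest["stages"][stage] = {
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
                "seconds": round(time.perf_counter() - t0, 3),
            }
            manifest["last_good_stage"] = stage
            logger.info("stage %s done (%.1fs)", stage,
                        manifest["stages"][stage]["seconds"])
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    cells, truth = simulate_single_cells(cfg.simulation)
    bulk, cohort = simulate_cohort(cfg.simulation, truth)
    state.update(cells=cells, truth=truth, bulk=bulk, cohort=cohort)
    cells_clean = cells.copy()
    cells_clean.uns.pop("expected_mean", None)
    iio.write_mtx(cells_clean, out / "cells")
    iio.write_dense_tsv(bulk, out / "bulk.tsv")
    iio.write_cohort(cohort, out / "cohort.tsv")
    iio.write_truth(truth, out / "truth.json")
    # subcategory labels for the planted set: deterministic round-robin
    subcats = {g: SUBCATEGORIES[i % len(SUBCATEGORIES)]
               for i, g in enumerate(truth.immuno_genes)}
    state["gsc"] = make_immuno_collection(truth.immuno_genes, subcats)
    iio.write_gmt(state["gsc"].sets, out / "immuno.gmt")
    (out / "subcategories.tsv").write_text(
        "".join(f"{g}\t{s}\n" for g, s in subcats.items()))
    return [out / "cells" / f for f in ("matrix.mtx", "genes.tsv", "barcodes.tsv",
                                        "obs_meta.tsv")] + \
           [out / f for f in ("bulk.tsv", "cohort.tsv", "truth.json",
                              "immuno.gmt", "subcategories.tsv")]


def _stage_train(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    pp = preprocess(state["cells"], NormalizationSpec(n_top_genes=cfg.n_top_genes))
    model = train_signature_model(pp, cfg.k, TrainingConfig(epochs=cfg.epochs,
                                                            seed=cfg.seed))
    state["model"] = model
    save_model(model, str(out / "model.h5"))
    return []  # HDF5 is binary scratch; hashes tracked for text outputs only


def _stage_rank(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    gsc: GeneSetCollection = state["gsc"]
    model = orient_signatures(state["model"], gsc.genes("immunomodulators"))
    state["model"] = model
    ranking = rank_all_signatures(model, gsc, alpha=cfg.alpha, top_k=cfg.top_k)
    state["ranking"] = ranking
    ranking.table.to_csv(out / "ranking.tsv", sep="\t")
    subcategory_profile(ranking, model, gsc).to_csv(out / "subcategory_profile.tsv",
                                                    sep="\t", index=False)
    summary = {"n_significant": ranking.n_significant, "n_total": ranking.n_total,
               "fraction_significant": ranking.fraction_significant,
               "top_k": ranking.top_k, "alpha": ranking.alpha}
    (out / "ranking_summary.json").write_text(json.dumps(summary, indent=2))
    return [out / "ranking.tsv", out / "subcategory_profile.tsv",
            out / "ranking_summary.json"]


def _stage_score(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    scores = encode(state["bulk"], state["model"])
    state["scores"] = scores
    iio.write_scores(scores, out / "bulk_scores.tsv")
    return [out / "bulk_scores.tsv"]


def _stage_stratify(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    sig = cfg.signature
    if sig == "auto":
        sig = state["ranking"].top_k[0]
    state["signature"] = sig
    scored = attach_scores(state["cohort"], state["scores"], sig)
    strat = dichotomize(scored, method=cfg.stratify_method)
    state["strat"] = strat
    iio.write_cohort(strat.table, out / "stratified.tsv")
    report = {"signature": sig, "method": strat.method,
              "threshold": strat.threshold,
              "n_high": strat.n_high, "n_low": strat.n_low}
    (out / "stratification.json").write_text(json.dumps(report, indent=2))
    return [out / "stratified.tsv", out / "stratification.json"]


def _stage_associate(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    strat = state["strat"]
    top_scores = state["scores"].loc[strat.table["patient_id"],
                                     [s for s in state["ranking"].top_k]]
    top_scores.index = strat.table.index
    results = compare_groups_wilcoxon(top_scores, strat.table["response"],
                                      seed=cfg.seed)
    results.append(fisher_or(strat))
    results.append(logistic_adjusted(strat.table, SCORE_COLUMN,
                                     LOGISTIC_COVARIATES))
    curves, lr = km_logrank(strat)
    results.append(lr)
    results.append(cox_adjusted(strat.table, covariates=COX_COVARIATES))
    results_frame(results).to_csv(out / "associations.tsv", sep="\t", index=False)
    rows = []
    for c in curves:
        for t, s, r in zip(c.times, c.survival, c.at_risk):
            rows.append(f"{c.group}\t{t}\t{s}\t{r}\n")
    (out / "survival_curves.tsv").write_text("group\ttime\tsurvival\tat_risk\n"
                                             + "".join(rows))
    return [out / "associations.tsv", out / "survival_curves.tsv"]


def _stage_gsea(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    bulk_norm = preprocess(state["bulk"])
    ranked = rank_genes(bulk_norm, state["strat"])
    gsc: GeneSetCollection = state["gsc"]
    # test the planted set and each subcategory as its own set
    sets = {"immunomodulators": gsc.genes("immunomodulators")}
    for sub in SUBCATEGORIES:
        members = gsc.subcategory_members(sub)
        if members:
            sets[f"subcat:{sub}"] = members
    res = gsea_preranked(ranked, GeneSetCollection(sets=sets),
                         n_perm=cfg.n_perm, seed=cfg.seed)
    enrichment_frame(res).to_csv(out / "gsea.tsv", sep="\t", index=False)
    return [out / "gsea.tsv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "train": _stage_train,
    "rank": _stage_rank,
    "score": _stage_score,
    "stratify": _stage_stratify,
    "associate": _stage_associate,
    "gsea": _stage_gsea,
}
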
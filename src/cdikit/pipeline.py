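"""End-to-end orchestration: simulate -> harmonize -> DEG -> train -> robustness
-> attribution -> enrichment, from a single declarative config.

Every stage writes plain-text artifacts (TSV/JSON/GMT) into a run directory
together with a manifest recording the config hash, seeds and stage outputs.
Reruns with the same config and seeds are deterministic; with ``resume=True``
stages whose outputs already exist under a matching config hash are skipped.
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
import yaml

from . import attribution, deg, ensemble, harmonize, pathways, robustness, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_cohorts"]


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis in one place."""

    cohort: synthetic.CohortSpec = field(default_factory=synthetic.CohortSpec)
    fdr_max: float = 0.05
    lfc_min: float = 0.5
    cv_folds: int = 5
    search_iterations: int = 80
    search: bool = True
    permutation_iterations: int = 200
    bootstrap_iterations: int = 1000
    n_pathway_sets: int = 30
    enriched_fraction: float = 0.2
    kernel_coalitions: int = 600
    background_size: int = 40
    mechano_cut_low: float = 0.3
    mechano_cut_high: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        for name in ("fdr_max", "lfc_min", "enriched_fraction"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must lie in (0, 1)")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = synthetic.CohortSpec(**raw.pop("cohort", {}))
        cfg = cls(cohort=cohort, **raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_done(manifest: dict, stage: str, outdir: Path) -> bool:
    files = manifest.get("stages", {}).get(stage, [])
    return bool(files) and all((outdir / f).exists() for f in files)


def run_pipeline(config: PipelineConfig, outdir, resume: bool = False) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == manifest["config_hash"]:
            manifest = old
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31 - 1)) for name in
             ("simulate", "train", "perm", "boot", "explain", "pathways")}

    def record(stage, files):
        manifest["stages"][stage] = files
        manifest_path.write_text(json.dumps(manifest, indent=1))

    def timed(stage):
        logger.info("stage %s (seed %s)", stage, seeds.get(stage, config.seed))
        return time.time()

    # -- simulate ----------------------------------------------------------
    spec = dataclasses.replace(config.cohort, seed=seeds["simulate"])
    expression, metadata, truth = synthetic.generate_multibatch_expression(spec)
    if not (resume and _stage_done(manifest, "simulate", outdir)):
        t0 = timed("simulate")
        synthetic.write_expression_tsv(expression, outdir / "expression_raw.tsv")
        synthetic.write_metadata_tsv(metadata, outdir / "metadata.tsv")
        truth.to_json(outdir / "ground_truth.json")
        record("simulate", ["expression_raw.tsv", "metadata.tsv", "ground_truth.json"])
        logger.info("simulate done in %.1fs", time.time() - t0)

    # -- harmonize ---------------------------------------------------------
    if resume and _stage_done(manifest, "harmonize", outdir):
        corrected = synthetic.read_expression_tsv(outdir / "expression_corrected.tsv")
    else:
        t0 = timed("harmonize")
        per_batch = [expression.loc[:, (metadata["batch"] == b).to_numpy()]
                     for b in metadata["batch"].unique()]
        corrected, report = harmonize.harmonize_cohorts(
            per_batch, list(metadata["batch"].unique())
        )
        corrected = corrected.loc[:, expression.columns]
        synthetic.write_expression_tsv(corrected, outdir / "expression_corrected.tsv")
        report.to_json(outdir / "harmonization_report.json")
        record("harmonize", ["expression_corrected.tsv", "harmonization_report.json"])
        logger.info("harmonize done in %.1fs", time.time() - t0)

    train_mask = (metadata["role"] == "train").to_numpy()
    train_samples = metadata.index[train_mask]
    y_train = metadata.loc[train_samples, "class"].to_numpy()

    # -- DEG ---------------------------------------------------------------
    t0 = timed("deg")
    table = deg.deg_table(
        corrected.loc[:, train_samples],
        metadata.loc[train_samples, "class"],
        fdr_max=config.fdr_max,
        lfc_min=config.lfc_min,
    )
    table.to_csv(outdir / "deg_table.tsv", sep="\t")
    record("deg", ["deg_table.tsv"])
    features = table.index[table["selected"]].tolist()
    if len(features) < 2:
        raise RuntimeError("deg stage selected fewer than 2 genes; cannot train")
    logger.info("deg done in %.1fs (%d selected)", time.time() - t0, len(features))

    # -- train -------------------------------------------------------------
    t0 = timed("train")
    X_train = corrected.loc[features, train_samples].T
    cv = ensemble.run_cv(
        X_train, y_train, k=config.cv_folds, seed=seeds["train"],
        n_iter=config.search_iterations, search=config.search,
    )
    metrics_table = pd.DataFrame({k: v.as_dict() for k, v in cv.metrics.items()}).T
    metrics_table.to_csv(outdir / "cv_metrics.tsv", sep="\t")
    ensemble.ablation(cv).to_csv(outdir / "ablation.tsv", sep="\t", index=False)
    # refit on the full training cohort for downstream scoring
    model = ensemble.fit_fold(
        X_train, y_train,
        n_iter=config.search_iterations, seed=seeds["train"], search=config.search,
    )
    cdi_all = ensemble.compute_cdi(model, corrected.loc[features].T,
                                   conditions=metadata["condition"])
    cdi_all["role"] = metadata["role"]
    cdi_all.to_csv(outdir / "cdi_records.tsv", sep="\t", index_label="sample_id")
    ensemble.summarize_cdi(cdi_all).to_csv(outdir / "cdi_summary.tsv", sep="\t",
                                           index=False)
    record("train", ["cv_metrics.tsv", "ablation.tsv", "cdi_records.tsv",
                     "cdi_summary.tsv"])
    logger.info("train done in %.1fs", time.time() - t0)

    # -- robustness --------------------------------------------------------
    t0 = timed("perm")
    perm = robustness.permutation_test(
        X_train, y_train, n_iter=config.permutation_iterations,
        seed=seeds["perm"], k=config.cv_folds, search=False,
    )
    boot = robustness.bootstrap_ci(
        cv.y.to_numpy(), cv.oof["ensemble"].to_numpy(),
        n_iter=config.bootstrap_iterations, seed=seeds["boot"],
    )
    (outdir / "robustness.json").write_text(json.dumps(
        {"permutation": perm.as_dict(),
         "bootstrap": [b.as_dict() for b in boot]}, indent=1))
    record("robustness", ["robustness.json"])
    logger.info("robustness done in %.1fs", time.time() - t0)

    # -- attribution -------------------------------------------------------
    t0 = timed("explain")
    background = attribution.stratified_background(
        X_train, y_train, size=config.background_size, seed=seeds["explain"])
    cohort_rankings = {}
    consensus_by_cohort = {}
    for role in ("train", "validation", "strain"):
        mask = (metadata["role"] == role).to_numpy()
        if mask.sum() == 0:
            continue
        Xc = corrected.loc[features, metadata.index[mask]].T
        attribs = attribution.explain_ensemble(
            model, Xc, background,
            n_coalitions=config.kernel_coalitions, seed=seeds["explain"],
        )
        consensus_by_cohort[role] = attribs["consensus"]
        cohort_rankings[role] = attribution.global_importance(attribs["consensus"])
        attribs["consensus"].values.to_csv(
            outdir / f"shap_consensus_{role}.tsv", sep="\t")
    ranking = cohort_rankings["train"]
    ranking.to_csv(outdir / "importance_ranking.tsv", sep="\t")
    consistency = attribution.cross_cohort_consistency(cohort_rankings, k=20)
    consistency["spearman"].to_csv(outdir / "consistency_spearman.tsv", sep="\t")
    strain_meta = metadata[metadata["role"] == "strain"]
    mech = attribution.mechanosensitivity(
        consensus_by_cohort["strain"],
        (strain_meta["condition"] == "strain").to_numpy(),
    )
    mech.to_csv(outdir / "mechanosensitivity.tsv", sep="\t")
    record("attribution", ["importance_ranking.tsv", "consistency_spearman.tsv",
                           "mechanosensitivity.tsv"]
           + [f"shap_consensus_{r}.tsv" for r in consensus_by_cohort])
    logger.info("attribution done in %.1fs", time.time() - t0)

    # -- pathways ----------------------------------------------------------
    t0 = timed("pathways")
    collection = synthetic.generate_pathway_collection(
        corrected.index.tolist(), truth, n_sets=config.n_pathway_sets,
        enriched_fraction=config.enriched_fraction, seed=seeds["pathways"],
    )
    pathways.write_gmt(collection, outdir / "genesets.gmt")
    universe = corrected.index.tolist()
    ora = pathways.enrich_collection(features, collection, universe,
                                     fdr_max=config.fdr_max)
    up = table.index[table["direction"] == "up"]
    down = table.index[table["direction"] == "down"]
    up_res, down_res = pathways.directional_enrichment(up, down, collection, universe)
    shap_scores = pathways.score_collection(collection, ranking, features)
    ora.merge(shap_scores, on="term").to_csv(outdir / "pathway_enrichment.tsv",
                                             sep="\t", index=False)
    if not up_res.empty:
        up_res.to_csv(outdir / "pathway_up.tsv", sep="\t", index=False)
    if not down_res.empty:
        down_res.to_csv(outdir / "pathway_down.tsv", sep="\t", index=False)
    record("pathways", ["genesets.gmt", "pathway_enrichment.tsv"])
    logger.info("pathways done in %.1fs", time.time() - t0)

    return manifest


def validate_cohorts(model, cohorts: dict, label_of_condition=None) -> dict:
    """Score held-out cohorts with a fitted ensemble; no refitting.

    ``cohorts`` maps name -> (expression genes x samples, metadata).  For each
    cohort the CDI is computed from the model alone; if the cohort's metadata
    carries a binary ``class`` column with both classes present, AUC/F1 of the
    CDI against it are reported.
    """
    out = {}
    for name, (expression, metadata) in cohorts.items():
        missing = [g for g in model.feature_names if g not in expression.index]
        if missing:
            raise ValueError(f"cohort {name!r} lacks model genes: {missing[:5]}")
        X = expression.loc[model.feature_names].T
        records = ensemble.compute_cdi(model, X, conditions=metadata["condition"])
        summary = ensemble.summarize_cdi(records)
        entry = {"cdi": records, "summary": summary}
        y = metadata.loc[X.index, "class"].to_numpy() if "class" in metadata else None
        if y is not None and len(np.unique(y)) == 2:
            entry["metrics"] = ensemble.compute_metrics(y, records["cdi"].to_numpy())
        out[name] = entry
    return out
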
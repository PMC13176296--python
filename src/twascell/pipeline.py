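"""End-to-end pipeline driver: TWAS -> QC -> scoring -> stratification ->
consensus selection -> patient-aware benchmark, with every intermediate
artifact and a reproducibility manifest written to the output directory."""

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

from . import __version__, io, twas
from .evaluate import evaluate_signature, lopo_cv, nested_cv_benchmark, patient_grouped_split
from .features import build_task, run_selectors
from .genesets import GeneSet
from .preprocess import lognormalize, qc_filter
from .scoring import score_correlation, score_panel
from .simulate import SimConfig, simulate_dataset, simulate_twas_fixture
from .stratify import roe_enrichment, stratify_quartiles

log = logging.getLogger("twascell")


@dataclass
class PipelineConfig:
    """Inputs, parameters, and output location of one pipeline run.

    When ``expression_path`` is None the synthetic cohort defined by
    ``sim`` is generated in place; likewise a TWAS fixture is simulated
    when ``twas_fixture_dir`` is None, and its significant genes define
    the risk set unless ``gene_set_path`` points to a GMT file.
    """

    outdir: str = "twascell_out"
    seed: int = 0
    expression_path: str | None = None
    gene_set_path: str | None = None
    twas_fixture_dir: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    twas_sim: dict = field(default_factory=lambda: {
        "n_genes": 300, "snps_per_gene": 3, "n_causal": 20, "causal_z_shift": 6.0})
    alpha: float = 0.05
    qc: dict = field(default_factory=lambda: {"min_genes": 200, "max_genes": 6000,
                                              "max_mito": 0.15})
    train_fraction: float = 0.8
    inner_folds: int = 5
    outer_folds: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "sim" in raw and isinstance(raw["sim"], dict):
            raw["sim"] = SimConfig(**raw["sim"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order; returns the output directory.

    Any stage failure aborts with the stage name in the raised error.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": config.to_dict(), "inputs": {}, "stages": []}

    def _run(name, fn):
        nonlocal stage
        stage = name
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        manifest["stages"].append(name)
        return result

    # ---- TWAS: risk-gene set -------------------------------------------
    def _twas():
        if config.twas_fixture_dir is not None:
            fixture = io.read_twas_fixture(config.twas_fixture_dir)
            manifest["inputs"]["twas_fixture_dir"] = str(config.twas_fixture_dir)
        else:
            fixture = simulate_twas_fixture(seed=config.seed, **config.twas_sim)
            io.write_twas_fixture(fixture, out / "twas_fixture")
        results = twas.twas_associate(fixture, alpha=config.alpha)
        twas.write_twas_results(results, out / "twas_results.tsv")
        risk = twas.select_risk_genes(results, alpha=config.alpha)
        io.write_gmt(risk, out / "risk_genes.gmt")
        (out / "risk_genes.txt").write_text("\n".join(risk.genes) + "\n")
        return fixture, results, risk

    fixture, twas_results, risk_from_twas = _run("twas", _twas)

    # ---- expression + risk set alignment --------------------------------
    def _load():
        if config.expression_path is not None:
            adata = io.read_expression(config.expression_path)
            manifest["inputs"]["expression_path"] = str(config.expression_path)
            sim = None
        else:
            sim = simulate_dataset(config.sim)
            adata = sim.adata
            io.write_expression(adata, out / "expression")
        if config.gene_set_path is not None:
            risk = io.read_gmt(config.gene_set_path)[0]
            manifest["inputs"]["gene_set_path"] = str(config.gene_set_path)
        elif sim is not None:
            # the fixture's gene universe is synthetic; on simulated
            # expression the planted risk set is the meaningful input
            risk = sim.truth_risk_genes
        else:
            risk = risk_from_twas
        return adata, risk, sim

    adata, risk_genes, sim = _run("load_expression", _load)

    # ---- QC + normalization ---------------------------------------------
    def _qc():
        filtered, report = qc_filter(adata, **config.qc)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        return lognormalize(filtered)

    lognorm = _run("qc_preprocess", _qc)

    # ---- activity scoring ------------------------------------------------
    def _score():
        usable = risk_genes.intersect(lognorm.var_names)
        panel = score_panel(lognorm, usable, seed=config.seed)
        panel.to_frame().to_csv(out / "activity_panel.tsv", sep="\t")
        score_correlation(panel.raw).to_csv(out / "score_correlation.tsv", sep="\t")
        return panel, usable

    panel, usable_risk = _run("activity_scoring", _score)

    # ---- stratification + Ro/e ------------------------------------------
    def _strat():
        labeling = stratify_quartiles(panel.scoring)
        meta = lognorm.obs.copy()
        meta["twas_activity"] = labeling.strata
        meta.reset_index(names="cell_id").to_csv(out / "cells_stratified.tsv",
                                                 sep="\t", index=False)
        roe = roe_enrichment(labeling, lognorm.obs["group"])
        roe.to_csv(out / "roe.tsv", sep="\t")
        return labeling, roe

    labeling, roe = _run("stratification", _strat)

    # ---- consensus selection --------------------------------------------
    def _select():
        task = build_task(lognorm, labeling, usable_risk)
        report = run_selectors(task, seed=config.seed)
        payload = {
            "seed": config.seed,
            "selections": report.selections,
            "importances": {m: {k: float(v) for k, v in s.items()}
                            for m, s in report.importances.items()},
            "consensus": report.consensus,
        }
        (out / "selection_report.json").write_text(json.dumps(payload, indent=2,
                                                              sort_keys=True))
        (out / "consensus_signature.txt").write_text("\n".join(report.consensus) + "\n")
        io.write_gmt(GeneSet("consensus_signature", tuple(report.consensus)),
                     out / "consensus_signature.gmt")
        return task, report

    task, selection = _run("consensus_select", _select)

    # ---- benchmark + LOPO -----------------------------------------------
    def _bench():
        train, test = patient_grouped_split(task, config.train_fraction, seed=config.seed)
        bench = nested_cv_benchmark(train, inner_folds=config.inner_folds,
                                    outer_folds=config.outer_folds, seed=config.seed)
        signature = selection.consensus or list(task.X.columns)
        test_eval = evaluate_signature(train, test, signature, seed=config.seed)
        lopo = lopo_cv(task, signature, seed=config.seed)
        test_eval.roc.to_csv(out / "test_roc.tsv", sep="\t", index=False)
        test_eval.pr.to_csv(out / "test_pr.tsv", sep="\t", index=False)
        payload = {
            "train_cells": train.n_cells, "test_cells": test.n_cells,
            "achieved_train_fraction": train.n_cells / task.n_cells,
            "fold_aucs": bench.fold_aucs, "mean_aucs": bench.mean_aucs,
            "best_model": bench.best_model,
            "signature": signature,
            "test_auc": test_eval.auc,
            "lopo": {"per_patient_auc": lopo.per_patient_auc,
                     "excluded": lopo.excluded,
                     "median_auc": lopo.median_auc, "iqr": list(lopo.iqr)},
        }
        (out / "eval_report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        return bench, test_eval, lopo

    bench, test_eval, lopo = _run("benchmark_eval", _bench)

    # ---- manifest --------------------------------------------------------
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["inputs"].setdefault("outputs_sha256", {})[
                str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str))
    return out
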
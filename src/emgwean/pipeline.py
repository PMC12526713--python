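"""End-to-end pipeline: simulate -> preprocess -> derive -> parameterise ->
features -> select -> classify, reproducible from one config and one seed.

The library surface is :func:`patient_parameters` (one recording to its 80
parameter time series), :func:`cohort_feature_matrix` (a cohort to the
patients x 320 matrix) and :func:`run_all` (full run with artifacts and a
manifest).  One global seed fans out to per-stage/per-patient seeds via
``numpy.random.SeedSequence`` spawning, so any subset of the cohort is
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import classify as clf
from .complexity import windowed_entropy
from .derive import derive_signals
from .features import build_feature_matrix, select_features
from .io import PipelineConfig, write_features
from .preprocess import preprocess_recording
from .spectral import windowed_params
from .synth import CohortSpec, generate_cohort

logger = logging.getLogger("emgwean")


def patient_parameters(rec, cfg: PipelineConfig | None = None):
    """Raw recording -> (group, {base parameter name -> ParamSeries})."""
    cfg = cfg or PipelineConfig()
    clean = preprocess_recording(rec, cfg)
    dset = derive_signals(clean, cfg)
    params = windowed_params(dset, cfg)
    params.update(windowed_entropy(dset, cfg))
    return rec.group, params, dset, clean


def cohort_feature_matrix(recordings, cfg: PipelineConfig | None = None
                          ) -> pd.DataFrame:
    """Run the per-patient pipeline over a cohort and assemble features."""
    cfg = cfg or PipelineConfig()
    cohort = {}
    for rec in recordings:
        group, params, _, _ = patient_parameters(rec, cfg)
        cohort[rec.patient_id] = (group, params)
    return build_feature_matrix(cohort)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(spec: CohortSpec | None = None,
            cfg: PipelineConfig | None = None,
            out_dir="run", seed: int | None = None,
            eliminate: bool = False) -> dict:
    """Full reproducible run; writes artifacts under ``out_dir``.

    Artifacts: feature matrix CSV, selection result (JSON + p-value CSV),
    one evaluation report per classifier, a cross-classifier comparison on
    the NB-selected feature set, and a manifest with config snapshot,
    output hashes and per-stage wall-clock.
    """
    cfg = cfg or PipelineConfig()
    spec = spec or CohortSpec()
    if seed is not None:
        spec = dataclasses.replace(spec, seed=seed)
        cfg = dataclasses.replace(cfg, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "config": dataclasses.asdict(cfg),
                "cohort_spec": dataclasses.asdict(spec),
                "stages": {}, "outputs": {}}

    t0 = time.perf_counter()
    recs = generate_cohort(spec)
    manifest["stages"]["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    matrix = cohort_feature_matrix(recs, cfg)
    feat_path = out / "features.csv"
    write_features(matrix, feat_path)
    manifest["stages"]["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sel = select_features(matrix, cfg)
    sel_path = out / "selection.json"
    sel_path.write_text(json.dumps(
        {"significant": sel["significant"], "retained": sel["retained"]},
        indent=2))
    sel["p_values"].to_csv(out / "p_values.csv", header=["p_value"])
    manifest["stages"]["select"] = time.perf_counter() - t0

    feats = sel["retained"] or sel["significant"]
    if not feats:
        raise RuntimeError("no features survived selection")
    reports = {}
    specs = {
        "naive_bayes": clf.ClassifierSpec("naive_bayes"),
        "knn": clf.ClassifierSpec("knn", knn_k=cfg.knn_k,
                                  knn_metric=cfg.knn_metric),
        "svm": clf.ClassifierSpec("svm", svm_degree=cfg.svm_degree,
                                  svm_c=cfg.svm_c),
    }
    t0 = time.perf_counter()
    nb_best = feats
    for name, cspec in specs.items():
        use = feats
        if eliminate:
            elim = clf.sequential_backward_elimination(
                matrix, cspec, feats, n_runs=cfg.elim_runs,
                train_frac=cfg.train_frac, seed=cfg.seed)
            use = elim["best_features"]
            (out / f"elimination_{name}.json").write_text(
                json.dumps(elim["trace"], indent=2))
            if name == "naive_bayes":
                nb_best = use
        rep = clf.evaluate(matrix, cspec, use, n_runs=cfg.n_runs,
                           train_frac=cfg.train_frac, seed=cfg.seed)
        reports[name] = rep
        (out / f"eval_{name}.json").write_text(
            json.dumps(rep.as_dict(), indent=2))
    # cross-classifier comparison on the NB-selected set
    comparison = {}
    for name, cspec in specs.items():
        rep = clf.evaluate(matrix, cspec, nb_best, n_runs=cfg.n_runs,
                           train_frac=cfg.train_frac, seed=cfg.seed)
        comparison[name] = rep.as_dict()
    (out / "comparison.json").write_text(json.dumps(comparison, indent=2))
    manifest["stages"]["classify"] = time.perf_counter() - t0

    for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %d patients, %d features, %d selected",
                matrix.shape[0], matrix.shape[1] - 2, len(feats))
    return {"matrix": matrix, "selection": sel, "reports": reports,
            "comparison": comparison, "manifest": manifest}
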
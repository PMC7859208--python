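"""End-to-end runner: simulate (optional) -> filter -> train -> classify ->
statistics -> DE stand-in -> report, with a manifest for reproducibility.

Every artifact is a TSV or JSON file; rerunning with the same configuration
produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, stage_seed
from .de import de_test
from .pipeline import (TrainedClassifier, classify_samples, compare_gene_sets,
                       compare_qr_timepoints, fit_phenotype_models,
                       phenotype_queenness, train_caste_classifier)
from .preprocess import (read_counts, read_samples, write_gene_set)
from .rfe import SelectedModel
from .simulate import LatentState, SimulationConfig, simulate_dataset, simulate_phenotypes
from .svm import KernelSpec, SVRModel, default_refined_grid

__all__ = ["run_all", "load_trained_classifier"]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _kernel_from_config(cfg: PipelineConfig, n_genes: int) -> KernelSpec:
    from .svm import study_scaled_gamma

    gamma = cfg.svm.gamma
    if cfg.svm.kernel != "linear" and gamma is None:
        gamma = study_scaled_gamma(n_genes)
    return KernelSpec(kind=cfg.svm.kernel, gamma=gamma, degree=cfg.svm.degree,
                      coef0=cfg.svm.coef0)


def run_all(cfg: PipelineConfig) -> Path:
    """Execute every stage and write the artifact directory with a manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -------------------------------------------------------------
    if cfg.simulate.enabled:
        sim_cfg = SimulationConfig(
            n_genes=cfg.simulate.n_genes, n_informative=cfg.simulate.n_informative,
            n_age_genes=cfg.simulate.n_age_genes, n_queens=cfg.simulate.n_queens,
            n_workers=cfg.simulate.n_workers, n_qr=cfg.simulate.n_qr,
            caste_effect=cfg.simulate.caste_effect, age_effect=cfg.simulate.age_effect,
            dispersion=cfg.simulate.dispersion, depth_mean=cfg.simulate.depth_mean,
            depth_cv=cfg.simulate.depth_cv,
            t_age_correlation=cfg.simulate.t_age_correlation,
            seed=stage_seed(cfg.seed, "simulate"))
        dataset = simulate_dataset(sim_cfg)
        dataset.samples = simulate_phenotypes(
            dataset.truth, noise_sd=cfg.simulate.phenotype_noise_sd,
            seed=stage_seed(cfg.seed, "phenotypes"), samples=dataset.samples)
        dataset.write(out / "data")
        counts, samples = dataset.counts, dataset.samples
        truth: LatentState | None = dataset.truth
        informative = dataset.informative_genes
        age_genes = dataset.age_genes
    else:
        if not (cfg.paths.counts and cfg.paths.samples):
            raise ValueError("paths.counts and paths.samples required when "
                             "simulate.enabled is false")
        counts = read_counts(cfg.paths.counts)
        samples = read_samples(cfg.paths.samples)
        truth, informative, age_genes = None, None, None

    # --- phenotype queenness -----------------------------------------------
    samples = phenotype_queenness(samples, ridge=cfg.phenotypes.ridge)
    qmodel = samples.attrs.get("queenness_model")
    samples.to_csv(out / "samples_with_queenness.tsv", sep="\t", index=False)

    # --- training (filter/normalize/standardize/grid?/rfe/select) ----------
    grid = default_refined_grid(cfg.grid.n_points_c, cfg.grid.n_points_gamma) \
        if cfg.grid.enabled else None
    kernel = None if (cfg.svm.gamma is None and cfg.svm.kernel == "radial") else \
        _kernel_from_config(cfg, cfg.simulate.n_genes)
    trained = train_caste_classifier(
        counts, samples, kernel=kernel, C=cfg.svm.C, epsilon=cfg.svm.epsilon,
        k=cfg.rfe.k, repeats=cfg.rfe.repeats, stop_size=cfg.rfe.stop_size,
        seed=stage_seed(cfg.seed, "rfe"), grid=grid,
        pseudocount=cfg.preprocessing_pseudocount)
    trained.trace.to_frame().to_csv(out / "rfe_trace.tsv", sep="\t", index=False)
    write_gene_set(trained.selected.genes, out / "selected_genes.txt")
    write_gene_set(trained.universe, out / "universe_genes.txt")
    (out / "model.json").write_text(trained.selected.model.to_json() + "\n")
    trained.training_estimates.rename_axis("sample_id").reset_index().to_csv(
        out / "training_estimates.tsv", sep="\t", index=False)

    # --- classification of all groups ---------------------------------------
    report = classify_samples(trained, counts, samples)
    report.estimates.to_csv(out / "classification.tsv", sep="\t", index=False)
    report.summaries.to_csv(out / "classification_summary.tsv", sep="\t",
                            index_label="group")

    qr_groups = {"qr_day3", "qr_day12"}
    qr_stats = None
    if qr_groups <= set(report.estimates["group"]):
        qr_stats = compare_qr_timepoints(report)
        _json_dump(qr_stats, out / "qr_comparison.json")

    # --- phenotype models (QR individuals, as in the study) -----------------
    qr_est = report.estimates.loc[report.estimates["group"].isin(qr_groups)]
    pheno = None
    if not qr_est.empty:
        from .pipeline import ClassificationReport
        pheno = fit_phenotype_models(ClassificationReport.build(qr_est), samples)
        pheno.to_csv(out / "phenotype_models.tsv", sep="\t", index=False)

    # --- DE stand-in and gene-set overlap -----------------------------------
    de_out = de_test(counts.loc[trained.universe], samples, "control_worker",
                     "queen", lfc_threshold=cfg.de.lfc_threshold,
                     alpha=cfg.de.alpha)
    de_out.to_csv(out / "de_standin_queen_vs_worker.tsv", sep="\t",
                  index_label="gene")
    de_genes = set(de_out.index[de_out["significant"]])
    overlaps = {
        "selected_vs_de": compare_gene_sets(
            trained.selected.genes, de_genes, trained.universe).to_dict(),
    }
    if informative is not None:
        planted_in_universe = [g for g in informative if g in trained.universe]
        age_in_universe = [g for g in age_genes if g in trained.universe]
        overlaps["selected_vs_planted_informative"] = compare_gene_sets(
            trained.selected.genes, planted_in_universe, trained.universe).to_dict()
        overlaps["selected_vs_planted_age"] = compare_gene_sets(
            trained.selected.genes, age_in_universe, trained.universe).to_dict()
    _json_dump(overlaps, out / "overlaps.json")

    # --- report -------------------------------------------------------------
    summary = {
        "config": cfg.model_dump(),
        "version": __version__,
        "n_genes_after_filter": len(trained.universe),
        "all_genes_cv_error": trained.all_genes_cv_error,
        "selected_cv_error": trained.selected.cv_error,
        "selected_n_genes": len(trained.selected.genes),
        "classification_summary": json.loads(
            report.summaries.to_json(orient="index")),
        "qr_comparison": qr_stats,
        "queenness_model": qmodel,
        "de_standin_significant": int(de_out["significant"].sum()),
        "overlaps": overlaps,
        "phenotype_models": json.loads(pheno.to_json(orient="records"))
        if pheno is not None else None,
    }
    _json_dump(summary, out / "report.json")

    manifest = {
        "seed": cfg.seed,
        "config": cfg.model_dump(),
        "version": __version__,
        "artifacts": {p.name: _sha256(p) for p in sorted(out.glob("*"))
                      if p.is_file() and p.name != "manifest.json"},
        "data": {p.name: _sha256(p) for p in sorted((out / "data").glob("*"))}
        if (out / "data").is_dir() else {},
    }
    _json_dump(manifest, out / "manifest.json")
    return out


def load_trained_classifier(model_path, universe_path) -> TrainedClassifier:
    """Rebuild a minimal classifier handle from serialized artifacts."""
    from .preprocess import read_gene_set

    model = SVRModel.from_json(Path(model_path).read_text())
    universe = read_gene_set(universe_path)
    selected = SelectedModel(genes=list(model.gene_ids), model=model,
                             cv_error=float("nan"), iteration_index=-1)
    return TrainedClassifier(
        selected=selected, trace=None, scaler=model.scaler, universe=universe,
        pseudocount=float(model.normalization.get("pseudocount", 1.0)),
        train_sample_ids=[], all_genes_cv_error=float("nan"),
        training_estimates=pd.Series(dtype=float))
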
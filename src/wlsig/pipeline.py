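"""End-to-end orchestration: simulate -> discover -> aggregate -> evaluate -> diagnose.

One global seed fans out deterministically to stage seeds (cohort
simulation, resampling plan, random-gene null), so any stage can be
reproduced in isolation and the whole study report is bit-stable for a
fixed configuration.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .clinical import ClinicalTable, adjust_for_sex_age, paired_auc_comparison, transform_skewed
from .diagnostics import pearson_corr, regainer_trend_test, trajectory_stats
from .nullmodel import empirical_pvalue, null_model_aucs, sample_random_genesets
from .predict import (ModelConfig, RunFeatureExtractor, discover_features,
                      evaluate_gene_sets, make_resamples)
from .signature import SelectionParams, aggregate_signature, combine_signatures
from .synthdata import CohortBundle, SynthConfig, generate_annotation, generate_cohort, generate_null_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Study configuration; all analysis constants surfaced as named keys."""

    synth: SynthConfig | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    clinical_path: str | None = None
    null_cohort: bool = False

    n_runs: int = 100
    train_fraction: float = 0.8
    seed: int = 0

    selection: SelectionParams = field(default_factory=SelectionParams)
    model: ModelConfig = field(default_factory=ModelConfig)

    alpha_nominal: float = 0.01
    min_total_reads: int = 5
    enrich_p_cut: float = 0.05
    enrich_q_cut: float = 0.2
    enrich_fdr_cut: float = 0.05
    redundancy_cut: float = 0.7
    edge_cut: float = 0.2

    null_n_sets: int = 100
    null_set_size: int = 10

    auc_threshold: float = 0.6
    regain_cutoff: float = -4.0
    delta_auc: float = 0.1
    n_hybrid_factors: int | None = None   # None = all clinical factors

    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.synth is None and self.counts_path is None:
            raise ValueError("supply either a synthetic config or real-data paths")
        if self.synth is not None and self.counts_path is not None:
            raise ValueError("synthetic config and real-data paths are exclusive")

    # seed fan-out: one child per stage
    def stage_seeds(self) -> dict:
        names = ["synth", "plan", "null"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {nm: int(c.generate_state(1)[0] % (2 ** 31))
                for nm, c in zip(names, children)}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synth" in raw and raw["synth"] is not None:
            synth = dict(raw["synth"])
            if "planted_modules" in synth:
                synth["planted_modules"] = [tuple(m) for m in synth["planted_modules"]]
            raw["synth"] = SynthConfig(**synth)
        if "selection" in raw:
            raw["selection"] = SelectionParams(**raw["selection"])
        if "model" in raw:
            raw["model"] = ModelConfig(**raw["model"])
        return cls(**raw)


def load_bundle(config: PipelineConfig) -> tuple[CohortBundle, dict]:
    """Materialise the cohort and annotation, synthetic or from files."""
    if config.synth is not None:
        synth = dataclasses.replace(config.synth, seed=config.stage_seeds()["synth"]) \
            if config.synth.seed == 0 else config.synth
        bundle = (generate_null_cohort if config.null_cohort else generate_cohort)(synth)
        annotation = generate_annotation(synth)
        return bundle, annotation
    counts = io.read_counts_tsv(config.counts_path)
    samples = io.read_table_tsv(config.samples_path)
    clinical = (io.read_table_tsv(config.clinical_path)
                if config.clinical_path else pd.DataFrame(index=samples.index))
    annotation = io.read_gmt(config.annotation_path) if config.annotation_path else {}
    return CohortBundle(counts, samples.loc[list(counts.sample_ids)],
                        clinical.loc[list(counts.sample_ids)], None), annotation


def run_discovery_phase(config: PipelineConfig, bundle=None, annotation=None,
                        plan=None, extractor=None):
    """Fig-style discovery loop: per-run DE -> enrichment map -> PCA genes.

    Returns (signatures per class, DiscoveryResult, plan, extractor).
    """
    if bundle is None:
        bundle, annotation = load_bundle(config)
    seeds = config.stage_seeds()
    if plan is None:
        plan = make_resamples(bundle.counts.sample_ids, config.n_runs,
                              config.train_fraction, seeds["plan"])
    extractor = extractor or RunFeatureExtractor(bundle, plan)
    result = discover_features(
        bundle, plan, annotation, config.selection,
        alpha_nominal=config.alpha_nominal, min_total=config.min_total_reads,
        p_cut=config.enrich_p_cut, q_cut=config.enrich_q_cut,
        fdr_cut=config.enrich_fdr_cut, redundancy_cut=config.redundancy_cut,
        edge_cut=config.edge_cut, extractor=extractor)
    signatures = {
        cls: aggregate_signature(runs, cls, config.selection, plan.n_runs)
        for cls, runs in result.selections.items()}
    if not signatures:
        log.warning("no pathway class discovered in any run")
    return signatures, result, plan, extractor


def _clinical_features(bundle: CohortBundle) -> ClinicalTable:
    table = transform_skewed(ClinicalTable(bundle.clinical.copy()))
    return adjust_for_sex_age(table, bundle.samples["sex"], bundle.samples["age"])


def run_evaluation_phase(config: PipelineConfig, bundle: CohortBundle,
                         signatures: dict, plan, extractor=None) -> dict:
    """Evaluate signatures, their combinations, clinical and hybrid models.

    Every model shares the resampling plan and the random-gene null
    ensemble; per-model failures are isolated. Returns the study report
    as a JSON-serialisable dict.
    """
    extractor = extractor or RunFeatureExtractor(bundle, plan)
    seeds = config.stage_seeds()
    report: dict = {"seed": config.seed, "n_runs": plan.n_runs, "models": {},
                    "errors": {}}

    # combined signatures over the pair of classes sharing the most genes
    # (the motivation for set-algebra models is inter-class gene overlap);
    # with no overlap anywhere, fall back to the two most-discovered classes
    models = {name: sig for name, sig in signatures.items() if sig.genes}
    names = sorted(models)
    if len(names) >= 2:
        pairs = [(len(set(models[x].genes) & set(models[y].genes)), x, y)
                 for i, x in enumerate(names) for y in names[i + 1:]]
        overlap, x, y = max(pairs)
        if overlap == 0:
            by_runs = sorted(names, key=lambda c: (-len(models[c].provenance), c))
            x, y = sorted(by_runs[:2])
        a, b = models[x], models[y]
        for combo, mode in ((combine_signatures(a, b, "union"), "union"),
                            (combine_signatures(a, b, "a_minus_b"), "diff"),
                            (combine_signatures(b, a, "a_minus_b"), "diff")):
            if combo.genes:
                models[combo.class_name] = combo

    # shared random-gene null
    ensemble = sample_random_genesets(bundle.counts, config.null_n_sets,
                                      config.null_set_size,
                                      config.min_total_reads, seeds["null"])
    ensemble = null_model_aucs(bundle, ensemble, plan, config.model, extractor)
    report["null"] = {"medians": list(map(float, ensemble.medians))}

    gene_sets = {name: list(sig.genes) for name, sig in models.items()}
    reports = evaluate_gene_sets(bundle, gene_sets, plan, config.model, extractor)
    for name, rep in reports.items():
        rep.empirical_p = empirical_pvalue(rep.median_auc, ensemble.medians)
        report["models"][name] = rep.to_dict()

    # clinical-only model + per-factor hybrids of the discovered signatures
    if bundle.clinical.shape[1] > 0:
        clin = _clinical_features(bundle)
        try:
            clin_rep = evaluate_gene_sets(bundle, {"Clinical": []}, plan,
                                          config.model, extractor,
                                          extra_features=clin.data)["Clinical"]
            clin_rep.empirical_p = empirical_pvalue(clin_rep.median_auc,
                                                    ensemble.medians)
            report["models"]["Clinical"] = clin_rep.to_dict()
        except Exception as exc:  # pragma: no cover - isolation path
            report["errors"]["Clinical"] = str(exc)
        factors = list(clin.data.columns)
        if config.n_hybrid_factors is not None:
            factors = factors[: config.n_hybrid_factors]
        hybrids: dict = {}
        for name in sorted(signatures):
            base = report["models"].get(name)
            if base is None or not signatures[name].genes:
                continue
            base_aucs = np.array([np.nan if a is None else a for a in base["aucs"]])
            for fac in factors:
                try:
                    rep = evaluate_gene_sets(
                        bundle, {f"{name}+{fac}": list(signatures[name].genes)},
                        plan, config.model, extractor,
                        extra_features=clin.data[[fac]])[f"{name}+{fac}"]
                    mask = ~np.isnan(base_aucs) & ~np.isnan(rep.aucs)
                    t, p, classes = paired_auc_comparison(
                        rep.aucs[mask], base_aucs[mask], config.delta_auc)
                    hybrids[f"{name}+{fac}"] = {
                        "median_auc": rep.median_auc, "max_auc": rep.max_auc,
                        "paired_t": t, "paired_p": p,
                        "n_improved": int((classes == "improved").sum()),
                        "n_worsened": int((classes == "worsened").sum()),
                        "n_unchanged": int((classes == "unchanged").sum())}
                except Exception as exc:  # pragma: no cover
                    report["errors"][f"{name}+{fac}"] = str(exc)
        report["hybrids"] = hybrids
    return report


def run_diagnostics(config: PipelineConfig, bundle: CohortBundle, plan,
                    report: dict) -> dict:
    """Trajectory diagnostics keyed to the evaluated models."""
    stats_table = trajectory_stats(bundle.samples, config.regain_cutoff)
    r, p = pearson_corr(stats_table["overall_wl_pct"],
                        stats_table["maintenance_wl_pct"])
    out = {"n_regainers": int(stats_table["regainer"].sum()),
           "overall_vs_maintenance_r": r, "overall_vs_maintenance_p": p,
           "trend_tests": {}}
    regainers = set(stats_table.index[stats_table["regainer"]])
    for name, rep in report.get("models", {}).items():
        aucs = np.array([np.nan if a is None else a for a in rep["aucs"]])
        res = regainer_trend_test(aucs, [tr for tr, _te in plan.splits],
                                  regainers, config.auc_threshold)
        if res is not None:
            out["trend_tests"][name] = {"statistic": res[0], "pvalue": res[1]}
    return out


def write_report(report: dict, outdir, config: PipelineConfig | None = None) -> Path:
    """Persist the master JSON, per-run AUC TSV, and a config snapshot."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_json(report, outdir / "study_report.json")
    models = report.get("models", {})
    if models:
        frame = pd.DataFrame({name: rep["aucs"] for name, rep in models.items()})
        frame.index.name = "run"
        io.write_table_tsv(frame, outdir / "per_run_aucs.tsv")
    if config is not None:
        snapshot = dataclasses.asdict(config)
        io.write_json(snapshot, outdir / "config_snapshot.json")
    return outdir / "study_report.json"


def run_all(config: PipelineConfig) -> dict:
    """simulate -> discover -> evaluate -> diagnose -> report, in one call."""
    bundle, annotation = load_bundle(config)
    signatures, discovery, plan, extractor = run_discovery_phase(
        config, bundle, annotation)
    report = run_evaluation_phase(config, bundle, signatures, plan, extractor)
    report["discovery"] = {
        "class_counts": discovery.class_counts,
        "runs_without_significant": discovery.runs_without_significant,
        "signatures": {c: s.to_dict() for c, s in signatures.items()}}
    report["diagnostics"] = run_diagnostics(config, bundle, plan, report)
    write_report(report, config.outdir, config)
    return report
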
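"""Shared study configuration for the numbered analysis scripts.

One deterministic configuration defines the synthetic study: a
200-sample, 2,000-gene cohort from 8 centers with three planted pathway
modules (a 20-gene lipid-metabolism-like module and a 10-gene
response-to-virus-like module sharing 4 genes, plus a weaker 20-gene
mitosis-like module), evaluated with 100 Monte-Carlo 80/20 resamples
and a 100-set random-gene null. Scripts re-derive everything from this
config, so each can be run standalone; later scripts reuse artifacts
written by earlier ones when present.
"""
from pathlib import Path

from wlsig.pipeline import PipelineConfig
from wlsig.signature import SelectionParams
from wlsig.synthdata import SynthConfig

RESULTS = Path(__file__).resolve().parents[1] / "results"

GLOBAL_SEED = 20230324


def study_config(outdir: Path | None = None) -> PipelineConfig:
    synth = SynthConfig(
        n_samples=200, n_genes=2000, n_centers=8,
        planted_modules=[("lipid", 20, 1.0), ("virus", 10, 1.0),
                         ("mitosis", 20, 0.5)],
        module_overlap_fraction=0.4, regainer_fraction=0.05,
        clinical_n_factors=30, seed=GLOBAL_SEED)
    selection = SelectionParams(class_keywords={
        "Lipid": ["lipid"], "Virus": ["virus"], "Mitosis": ["mitosis"]})
    return PipelineConfig(synth=synth, n_runs=100, seed=GLOBAL_SEED,
                          selection=selection, null_n_sets=100,
                          n_hybrid_factors=5,
                          outdir=str(outdir or RESULTS))
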
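"""Synthetic dietary-intervention cohorts with matched ground truth.

Emulates the statistical structure of a multicenter low-calorie-diet
(LCD) study with baseline adipose-tissue RNA-seq: negative-binomial
counts with a gene-wise mean-dispersion trend, multiplicative center
(batch), sex and age effects, planted "pathway" gene modules whose
expression shifts with the weight-loss class (including genes shared
between the first two modules), two-phase weight trajectories (LCD loss
followed by maintenance, with a configurable regainer subpopulation),
and a panel of weakly informative clinical covariates, some of them
right-skewed. Every generated object carries the ground truth needed for
parameter-recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix


@dataclass
class SynthConfig:
    """Generator settings.

    planted_modules is a list of (module_name, gene_count, log2_effect_size);
    the log2 effect is the expression shift in the high-weight-loss class.
    module_overlap_fraction is the fraction of the smaller of the first
    two modules shared between them. nb_dispersion_model = (a0, a1) gives
    dispersion = a0 + a1/mean. batch_sd is the log2-scale SD of gene-wise
    center effects.
    """

    n_samples: int = 200
    n_genes: int = 2000
    n_centers: int = 8
    planted_modules: list = field(default_factory=lambda: [
        ("lipid", 20, 1.0), ("virus", 10, 1.0), ("mitosis", 20, 0.5),
    ])
    module_overlap_fraction: float = 0.4
    regainer_fraction: float = 0.05
    clinical_n_factors: int = 30
    nb_dispersion_model: tuple = (0.05, 2.0)
    batch_sd: float = 0.1
    seed: int = 0
    # secondary knobs (kept at field defaults throughout the analyses)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    depth_log2_sd: float = 0.25
    sex_effect_sd: float = 0.1
    age_effect_sd: float = 0.005
    female_fraction: float = 0.65
    # two-phase weight model, % of baseline weight: (high-WL, low-WL)
    lcd_wl_mean: tuple = (12.3, 10.0)
    lcd_wl_sd: tuple = (2.9, 1.9)
    maint_wl_mean: tuple = (3.1, -4.2)
    maint_wl_sd: tuple = (2.5, 2.8)
    regainer_lcd_mean: float = 16.5
    regainer_maint_mean: float = -5.5
    clinical_informative: int = 5
    clinical_r: float = 0.25
    clinical_skewed_fraction: float = 0.3

    def validate(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        for name, size, eff in self.planted_modules:
            if size > self.n_genes:
                raise ValueError(f"module {name!r} larger than n_genes")
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")
        for prop in (self.module_overlap_fraction, self.regainer_fraction,
                     self.clinical_skewed_fraction, self.female_fraction):
            if not 0.0 <= prop <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        a0, a1 = self.nb_dispersion_model
        if a0 < 0 or a1 < 0 or (a0 == 0 and a1 == 0):
            raise ValueError("dispersion model must be non-negative and not all zero")
        total = sum(size for _, size, _ in self.planted_modules)
        if total > self.n_genes:
            raise ValueError("n_genes too small to host the requested modules")


@dataclass
class SynthTruth:
    """Ground truth record written alongside every synthetic cohort."""

    module_gene_ids: dict
    true_class: pd.Series          # label driving the weight trajectories
    regainer_ids: set
    informative_clinical_ids: set
    expr_class: pd.Series = None   # label driving expression (== true_class unless null)
    null: bool = False

    def to_dict(self) -> dict:
        return {
            "module_gene_ids": {k: sorted(v) for k, v in self.module_gene_ids.items()},
            "true_class": self.true_class.astype(int).to_dict(),
            "regainer_ids": sorted(self.regainer_ids),
            "informative_clinical_ids": sorted(self.informative_clinical_ids),
            "null": self.null,
        }


@dataclass
class CohortBundle:
    """Counts + sample metadata + clinical table (+ truth when synthetic)."""

    counts: CountMatrix
    samples: pd.DataFrame
    clinical: pd.DataFrame
    truth: SynthTruth | None = None

    def __post_init__(self) -> None:
        ids = list(self.counts.sample_ids)
        if list(self.samples.index) != ids or list(self.clinical.index) != ids:
            raise ValueError("sample ids differ or are ordered inconsistently")
        w = self.samples[["weight_0m", "weight_2m", "weight_8m"]].to_numpy(float)
        if (w <= 0).any():
            raise ValueError("weights must be strictly positive")

    def wl_percent(self) -> pd.Series:
        """Overall weight loss, % of baseline weight (0 -> 8 months)."""
        w = self.samples
        return 100.0 * (w["weight_0m"] - w["weight_8m"]) / w["weight_0m"]


# ---------------------------------------------------------------------
def _children(config: SynthConfig, n: int = 8):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def _gene_ids(config: SynthConfig) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(config.n_genes)], dtype=object)


def module_gene_map(config: SynthConfig) -> dict:
    """Deterministic module -> gene-id assignment shared by counts and annotation."""
    config.validate()
    rng = _children(config)[0]
    genes = _gene_ids(config)
    order = rng.permutation(config.n_genes)
    modules: dict[str, list] = {}
    cursor = 0
    for mi, (name, size, _eff) in enumerate(config.planted_modules):
        if mi == 1 and len(config.planted_modules) >= 2:
            first = modules[config.planted_modules[0][0]]
            n_shared = int(round(config.module_overlap_fraction
                                 * min(size, len(first))))
            shared = list(first[:n_shared])
            fresh = [genes[order[cursor + i]] for i in range(size - n_shared)]
            cursor += size - n_shared
            modules[name] = shared + fresh
        else:
            modules[name] = [genes[order[cursor + i]] for i in range(size)]
            cursor += size
    return modules


def generate_annotation(config: SynthConfig, n_terms: int = 60) -> dict:
    """Term -> gene-set annotation with planted-module terms and siblings.

    Each planted module appears as a dedicated term plus two partially
    overlapping sibling terms (Jaccard >= 0.7 with the module term), the
    remainder are background terms of random genes (>= 3 genes each).
    """
    config.validate()
    rng = _children(config)[1]
    genes = _gene_ids(config)
    modules = module_gene_map(config)
    terms: dict[str, dict] = {}
    for name, members in modules.items():
        terms[f"T_{name}"] = {"name": f"{name} pathway process", "genes": set(members)}
        m = len(members)
        for k in (1, 2):
            drop = max(0, min(k, m - 3, int(np.floor(0.3 * m))))
            dropped = set(rng.choice(members, size=drop, replace=False)) if drop else set()
            # Jaccard with the module term is (m - drop) / m >= 0.7 by construction
            terms[f"T_{name}_sib{k}"] = {
                "name": f"{name} related process {k}",
                "genes": set(members) - dropped}
    n_background = max(n_terms - len(terms), 50 - len(terms))
    for i in range(n_background):
        size = int(rng.integers(5, 41))
        members = rng.choice(genes, size=size, replace=False)
        terms[f"T_bg{i:03d}"] = {"name": f"background process {i:03d}",
                                 "genes": set(members.tolist())}
    assert all(len(t["genes"]) >= 3 for t in terms.values())
    return terms


def _weights(config: SynthConfig, rng, wl_class: np.ndarray):
    """Two-phase weight trajectories driven by the binary class label."""
    n = len(wl_class)
    w0 = rng.normal(100.0, 15.0, size=n)
    while (w0 < 50).any():  # truncate baseline weight at 50 kg
        bad = w0 < 50
        w0[bad] = rng.normal(100.0, 15.0, size=int(bad.sum()))
    hi = wl_class == 1
    lcd = np.where(hi,
                   rng.normal(config.lcd_wl_mean[0], config.lcd_wl_sd[0], n),
                   rng.normal(config.lcd_wl_mean[1], config.lcd_wl_sd[1], n))
    maint = np.where(hi,
                     rng.normal(config.maint_wl_mean[0], config.maint_wl_sd[0], n),
                     rng.normal(config.maint_wl_mean[1], config.maint_wl_sd[1], n))
    # regainers: high-loss individuals who rebound during maintenance yet
    # keep an above-median overall loss thanks to a strong LCD phase
    hi_idx = np.where(hi)[0]
    n_regain = int(round(config.regainer_fraction * len(hi_idx)))
    regain_idx = rng.choice(hi_idx, size=n_regain, replace=False) if n_regain else np.array([], int)
    lcd[regain_idx] = rng.normal(config.regainer_lcd_mean, 1.5, size=n_regain)
    maint[regain_idx] = np.minimum(
        rng.normal(config.regainer_maint_mean, 1.0, size=n_regain), -4.1)
    if config.regainer_fraction == 0.0:
        maint = np.maximum(maint, 0.05)  # regainer_fraction=0 means no rebound at all
    w2 = w0 * (1.0 - lcd / 100.0)
    w8 = w0 * (1.0 - (lcd + maint) / 100.0)
    return w0, w2, w8, regain_idx


def _clinical(config: SynthConfig, rng, z: np.ndarray):
    n = len(z)
    p = config.clinical_n_factors
    ids = np.array([f"clin_{i:02d}" for i in range(p)], dtype=object)
    n_inf = min(config.clinical_informative, p)
    informative = set(ids[:n_inf])
    r = config.clinical_r
    x = rng.normal(size=(n, p))
    x[:, :n_inf] = r * z[:, None] + np.sqrt(1 - r * r) * x[:, :n_inf]
    n_skew = int(round(config.clinical_skewed_fraction * p))
    skew_cols = rng.choice(p, size=n_skew, replace=False)
    x[:, skew_cols] = np.exp(0.9 * x[:, skew_cols])  # log-normal, skewness > 1
    return pd.DataFrame(x, columns=ids), informative


def _generate(config: SynthConfig, null: bool) -> CohortBundle:
    config.validate()
    rngs = _children(config)
    rng_cohort, rng_weights, rng_clin, rng_null = rngs[2], rngs[3], rngs[4], rngs[5]

    n, G = config.n_samples, config.n_genes
    genes = _gene_ids(config)
    sample_ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    modules = module_gene_map(config)

    # covariates: balanced center assignment, sex, age
    center = np.array([f"C{i + 1}" for i in
                       (np.arange(n) % config.n_centers)], dtype=object)
    center = center[rng_cohort.permutation(n)]
    sex = np.where(rng_cohort.random(n) < config.female_fraction, "F", "M")
    age = np.clip(rng_cohort.normal(42.0, 6.0, size=n), 20.0, 65.0)

    # class driving expression: balanced then permuted
    expr_class = np.zeros(n, dtype=int)
    expr_class[: n // 2] = 1
    expr_class = expr_class[rng_cohort.permutation(n)]

    # gene-level parameters
    base = rng_cohort.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=G)
    batch_eff = rng_cohort.normal(0.0, config.batch_sd, size=(G, config.n_centers))
    sex_eff = rng_cohort.normal(0.0, config.sex_effect_sd, size=G)
    age_eff = rng_cohort.normal(0.0, config.age_effect_sd, size=G)
    depth = rng_cohort.normal(0.0, config.depth_log2_sd, size=n)
    effect = np.zeros(G)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for name, size, eff in config.planted_modules:
        for g in modules[name]:
            effect[gene_pos[g]] += eff

    center_idx = np.array([int(c[1:]) - 1 for c in center])
    log2mu = (base[:, None]
              + batch_eff[:, center_idx]
              + sex_eff[:, None] * (sex == "F")[None, :]
              + age_eff[:, None] * (age - 42.0)[None, :]
              + effect[:, None] * expr_class[None, :]
              + depth[None, :])
    mu = np.exp2(np.clip(log2mu, -10, 25))
    a0, a1 = config.nb_dispersion_model
    alpha = a0 + a1 / np.exp2(base)
    r_param = 1.0 / np.maximum(alpha, 1e-12)
    p_param = r_param[:, None] / (r_param[:, None] + mu)
    counts = rng_cohort.negative_binomial(r_param[:, None], p_param)

    # weight trajectories: driven by expr_class, or independently when null
    wl_class = rng_null.permutation(expr_class) if null else expr_class
    w0, w2, w8, regain_idx = _weights(config, rng_weights, wl_class)
    clin, informative = _clinical(config, rng_clin, 2.0 * wl_class - 1.0)
    clin.index = pd.Index(sample_ids, name="sample_id")

    samples = pd.DataFrame({
        "sex": sex, "age": age, "center": center,
        "weight_0m": w0, "weight_2m": w2, "weight_8m": w8,
    }, index=pd.Index(sample_ids, name="sample_id"))
    truth = SynthTruth(
        module_gene_ids={k: set(v) for k, v in modules.items()},
        true_class=pd.Series(wl_class, index=samples.index),
        regainer_ids=set(sample_ids[regain_idx]),
        informative_clinical_ids=informative,
        expr_class=pd.Series(expr_class, index=samples.index),
        null=null,
    )
    return CohortBundle(CountMatrix(genes, sample_ids, counts), samples, clin, truth)


def generate_cohort(config: SynthConfig) -> CohortBundle:
    """Cohort whose weight-loss class drives the planted expression modules."""
    return _generate(config, null=False)


def generate_null_cohort(config: SynthConfig) -> CohortBundle:
    """Cohort whose weight trajectories are independent of expression.

    Expression keeps its own (hidden) module structure, but the label that
    generates the weights is an independent permutation, so any gene/WL
    association is a false positive by construction.
    """
    return _generate(config, null=True)
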
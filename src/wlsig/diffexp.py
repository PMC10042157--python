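"""Per-gene NB Wald tests of high-WL vs low-WL, adjusted for sex/age/center.

For each gene a negative-binomial log-link GLM with class + sex + age +
center terms is fitted (dispersion estimated by moments and shrunk
toward a mean-dispersion trend), and the class coefficient is tested by
a two-sided Wald z-test. Genes with nominal P below the configured
cutoff form the DEG set that seeds enrichment.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CountMatrix
from .nbglm import dispersion_trend, fit_nb_glm, moment_dispersion

_LN2 = np.log(2.0)


@dataclass
class DesignSpec:
    """Binary weight-loss outcome plus the adjustment covariates."""

    wl_class: pd.Series              # 1 = high-WL, 0 = low-WL, indexed by sample
    sex: pd.Series = None
    age: pd.Series = None
    center: pd.Series = None
    alpha_nominal: float = 0.01
    dispersion_shrinkage: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_nominal <= 1.0:
            raise ValueError("alpha_nominal must lie in (0, 1]")
        classes = set(pd.Series(self.wl_class).unique())
        if not classes.issuperset({0, 1}):
            raise ValueError("both weight-loss classes must be present")

    def design_matrix(self, sample_ids) -> tuple[np.ndarray, list[str]]:
        """Intercept + class + optional sex, age, center-indicator columns."""
        ids = list(sample_ids)
        cols = {"intercept": np.ones(len(ids)),
                "class": pd.Series(self.wl_class).reindex(ids).to_numpy(float)}
        if self.sex is not None:
            sx = pd.Series(self.sex).reindex(ids)
            cols["sexF"] = (sx == "F").to_numpy(float)
        if self.age is not None:
            a = pd.Series(self.age).reindex(ids).to_numpy(float)
            sd = a.std() if a.std() > 0 else 1.0
            cols["age"] = (a - a.mean()) / sd
        if self.center is not None:
            c = pd.Series(self.center).reindex(ids)
            levels = sorted(c.unique())          # reference = first level
            for lev in levels[1:]:
                cols[f"center[{lev}]"] = (c == lev).to_numpy(float)
        X = np.column_stack(list(cols.values()))
        return X, list(cols)


def estimate_dispersion(counts: CountMatrix, design: DesignSpec,
                        floor: float = 1e-8) -> np.ndarray:
    """Per-gene NB2 dispersion: moments shrunk toward an a0 + a1/mean trend."""
    lib = counts.library_sizes().astype(float)
    s = lib / np.exp(np.mean(np.log(lib)))
    raw = moment_dispersion(counts.values, s, floor=floor)
    mean_norm = (counts.values / s[None, :]).mean(axis=1)
    a0, a1 = dispersion_trend(mean_norm, raw)
    trend = a0 + a1 / np.maximum(mean_norm, 1e-8)
    w = design.dispersion_shrinkage
    return np.maximum((1.0 - w) * raw + w * trend, floor)


def nb_wald_test(counts_g: np.ndarray, design: DesignSpec, dispersion: float,
                 offsets: np.ndarray, sample_ids) -> tuple[float, float, float]:
    """Wald test of the class coefficient for a single gene.

    Returns (log2 fold change high-WL vs low-WL, its SE, two-sided P).
    """
    X, names = design.design_matrix(sample_ids)
    fit = fit_nb_glm(np.asarray(counts_g, float)[None, :], X,
                     np.array([dispersion]), offset=offsets)
    j = names.index("class")
    beta = fit["coef"][0, j]
    se = np.sqrt(fit["cov"][0, j, j])
    if not fit["converged"][0] or not np.isfinite(se) or se == 0:
        return np.nan, np.nan, np.nan
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return beta / _LN2, se / _LN2, p


def run_de(counts: CountMatrix, design: DesignSpec,
           dispersions: np.ndarray | None = None) -> pd.DataFrame:
    """NB Wald DE over all genes; returns the DEG table.

    Columns: lfc (log2), se, stat, pvalue, significant (P < alpha_nominal).
    Genes whose fit fails get missing statistics and are never significant.
    """
    if dispersions is None:
        dispersions = estimate_dispersion(counts, design)
    lib = counts.library_sizes().astype(float)
    offsets = np.log(lib / np.exp(np.mean(np.log(lib))))
    X, names = design.design_matrix(counts.sample_ids)
    fit = fit_nb_glm(counts.values, X, dispersions, offset=offsets)
    j = names.index("class")
    beta = fit["coef"][:, j]
    se = np.sqrt(fit["cov"][:, j, j])
    ok = fit["converged"] & np.isfinite(se) & (se > 0)
    z = np.where(ok, beta / np.where(se > 0, se, 1.0), np.nan)
    p = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    table = pd.DataFrame({
        "lfc": np.where(ok, beta / _LN2, np.nan),
        "se": np.where(ok, se / _LN2, np.nan),
        "stat": z,
        "pvalue": p,
    }, index=pd.Index(counts.gene_ids, name="gene_id"))
    table["significant"] = table["pvalue"] < design.alpha_nominal
    return table
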
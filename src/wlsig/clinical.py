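"""Clinical-covariate handling and group-comparison statistics.

Covers the clinical side of the pipeline: skewness screening with log_e
transformation of heavily skewed factors, non-parametric sex/age
adjustment (median/MAD alignment across sex strata plus linear age
residualisation), augmentation of expression feature matrices with
clinical columns, paired comparison of per-run AUCs between hybrid and
expression-only models, and a participant-characteristics table with
two-group tests (unpaired t for continuous variables, chi-square for
sex).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ClinicalTable:
    """Sample x factor matrix plus the set of log-transformed factors."""

    data: pd.DataFrame
    transformed: set = field(default_factory=set)
    shifts: dict = field(default_factory=dict)   # factor -> additive shift before log

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate factor ids")


def skewness(values) -> float:
    """Adjusted Fisher-Pearson standardized third moment (bias-corrected)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 3 or np.std(v) == 0:
        warnings.warn("skewness undefined (n < 3 or zero variance)")
        return np.nan
    return float(stats.skew(v, bias=False))


def transform_skewed(table: ClinicalTable, cutoff: float = 1.0) -> ClinicalTable:
    """log_e-scale the factors with |skewness| > cutoff.

    Non-positive flagged factors are shifted by 1 - min before the log
    (recorded in ``shifts``); already-transformed factors are left alone.
    """
    data = table.data.copy()
    transformed = set(table.transformed)
    shifts = dict(table.shifts)
    for col in data.columns:
        if col in transformed:
            continue
        sk = skewness(data[col])
        if np.isnan(sk) or abs(sk) <= cutoff:
            continue
        v = data[col].to_numpy(float)
        shift = 0.0
        if np.nanmin(v) <= 0:
            shift = 1.0 - np.nanmin(v)
            warnings.warn(f"factor {col!r} shifted by {shift:g} before log")
        data[col] = np.log(v + shift)
        transformed.add(col)
        shifts[col] = shift
    return ClinicalTable(data, transformed, shifts)


def adjust_for_sex_age(table: ClinicalTable, sex, age) -> ClinicalTable:
    """Remove sex location/scale differences and the linear age trend.

    Per factor: each sex stratum is aligned to the pooled median and MAD
    (a non-parametric location/scale correction), then the linear age
    trend is residualised out; the overall median is preserved. Strata
    with fewer than 3 samples leave the factor unadjusted with a warning.
    """
    sex = pd.Series(np.asarray(sex), index=table.data.index)
    age = pd.Series(np.asarray(age, dtype=float), index=table.data.index)
    strata = {lev: sex.index[sex == lev] for lev in sex.unique()}
    if len(strata) < 2:
        raise ValueError("both sexes must be present")
    data = table.data.copy()
    small = any(len(ix) < 3 for ix in strata.values())
    a = age - age.mean()
    denom = float((a ** 2).sum())
    for col in data.columns:
        if small:
            warnings.warn(f"factor {col!r} left unadjusted: degenerate sex stratum")
            continue
        v = data[col].astype(float)
        # 1) residualise the linear age trend, estimated on sex-centred
        #    values so a sex offset cannot masquerade as an age effect
        centred = v.copy()
        for lev, ix in strata.items():
            centred.loc[ix] = v.loc[ix] - v.loc[ix].median()
        if denom > 0:
            slope = float((a * (centred - centred.mean())).sum() / denom)
            v = v - slope * a
        # 2) align sex strata to the pooled median and the pooled
        #    within-stratum MAD (last, so stratum medians end up equal)
        pooled_med = float(v.median())
        resid = v.copy()
        for lev, ix in strata.items():
            resid.loc[ix] = v.loc[ix] - v.loc[ix].median()
        target_mad = float(stats.median_abs_deviation(resid, scale="normal"))
        out = v.copy()
        for lev, ix in strata.items():
            med = float(v.loc[ix].median())
            mad = float(stats.median_abs_deviation(v.loc[ix], scale="normal"))
            scale = (target_mad / mad) if (mad > 0 and target_mad > 0) else 1.0
            out.loc[ix] = (v.loc[ix] - med) * scale + pooled_med
        data[col] = out
    return ClinicalTable(data, set(table.transformed), dict(table.shifts))


def augment_features(expr_features: pd.DataFrame, table: ClinicalTable,
                     factor_ids) -> pd.DataFrame:
    """Column-append clinical factors to an expression feature matrix.

    Samples with missing values in the requested factors are dropped
    with a warning. Standardisation happens downstream with training
    statistics, like any other feature.
    """
    factor_ids = list(factor_ids)
    if not factor_ids:
        return expr_features
    add = table.data.loc[expr_features.index, factor_ids]
    missing = add.isna().any(axis=1)
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} sample(s) with missing factors")
    out = pd.concat([expr_features, add], axis=1)
    return out[~missing.to_numpy()]


def paired_auc_comparison(aucs_a, aucs_b, delta: float = 0.1):
    """Paired t-test of per-run AUCs plus the |dAUC| < delta run classification.

    Returns (t statistic, two-sided P, classification Series with values
    'unchanged' (|d| < delta), 'improved' (d >= delta), 'worsened'
    (d <= -delta)) where d = a - b per run.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need equal-length paired AUC vectors with n >= 2")
    d = a - b
    if np.allclose(d, 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, b)
    labels = np.where(np.abs(d) < delta, "unchanged",
                      np.where(d >= delta, "improved", "worsened"))
    return float(t), float(p), pd.Series(labels)


def baseline_group_table(variables: pd.DataFrame, sex: pd.Series, labels: pd.Series,
                         skew_cutoff: float = 1.0,
                         yates_correction: bool = False) -> pd.DataFrame:
    """Group mean +- SD per variable with two-group tests.

    Continuous variables are compared by an unpaired two-sided t-test
    (log_e-transformed first when |skewness| > cutoff, as in the
    clinical preprocessing); sex by a chi-square test on the 2x2 count
    table (no continuity correction by default). Zero-variance variables
    are skipped.
    """
    labels = pd.Series(labels).astype(int)
    hi, lo = labels == 1, labels == 0
    if hi.sum() == 0 or lo.sum() == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in variables.columns:
        v = variables[col].astype(float)
        mean_hi, sd_hi = v[hi.to_numpy()].mean(), v[hi.to_numpy()].std(ddof=1)
        mean_lo, sd_lo = v[lo.to_numpy()].mean(), v[lo.to_numpy()].std(ddof=1)
        t_input = v.copy()
        sk = skewness(v)
        if not np.isnan(sk) and abs(sk) > skew_cutoff and (v > 0).all():
            t_input = np.log(v)
        if np.std(t_input) == 0:
            rows.append((col, mean_hi, sd_hi, mean_lo, sd_lo, np.nan, np.nan))
            continue
        t, p = stats.ttest_ind(t_input[hi.to_numpy()], t_input[lo.to_numpy()])
        rows.append((col, mean_hi, sd_hi, mean_lo, sd_lo, float(t), float(p)))
    # sex: chi-square on the 2x2 table
    sex = pd.Series(np.asarray(sex), index=labels.index)
    contingency = pd.crosstab(sex, labels)
    chi2, p, _dof, _exp = stats.chi2_contingency(contingency,
                                                 correction=yates_correction)
    f_hi = 100.0 * (sex[hi.to_numpy()] == "F").mean()
    f_lo = 100.0 * (sex[lo.to_numpy()] == "F").mean()
    rows.insert(0, ("female_pct", f_hi, np.nan, f_lo, np.nan, float(chi2), float(p)))
    return pd.DataFrame(rows, columns=["variable", "mean_high", "sd_high",
                                       "mean_low", "sd_low", "stat", "pvalue"]
                        ).set_index("variable")
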
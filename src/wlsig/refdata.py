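"""Published reference values from the DiOGenes dietary-intervention cohort.

The multicenter DiOGenes study (GEO accession GSE95640 for the baseline
adipose-tissue RNA-seq) reported group-level participant
characteristics for the 281 individuals split at the median 8-month
weight-loss percentage. Those printed summary statistics are shipped as
package data and serve as inputs: the synthetic-cohort generator is
parameterised to reproduce their orders of magnitude, and derived
quantities (e.g. the 2-month group difference in mean weight-loss
percentage) are computed from this table rather than hard-coded.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

_TABLE = "diogenes_characteristics.tsv"


def load_reference_characteristics() -> pd.DataFrame:
    """Group mean +- SD participant characteristics (high-WL vs low-WL)."""
    with resources.files("wlsig.data").joinpath(_TABLE).open() as fh:
        return pd.read_csv(fh, sep="\t")


def lcd_wl_group_difference() -> float:
    """High-WL minus low-WL mean weight-loss % at the end of the LCD (2 months)."""
    table = load_reference_characteristics()
    row = table[(table["variable"] == "weight_loss_pct") & (table["timepoint"] == "2m")]
    if len(row) != 1:
        raise ValueError("reference table lacks the 2-month weight-loss row")
    return float(row["high_wl_mean"].iloc[0] - row["low_wl_mean"].iloc[0])
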
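"""Fusobacterium nucleatum relative quantification by qPCR delta-Ct.

The F. nucleatum 16S signal is normalised to the pan-bacterial 16S signal of
the same DNA extract: dCt = Ct_fn - Ct_pan, and the relative quantity is
efficiency^(-dCt) (efficiency 2 assumes perfect doubling per cycle).  Ct is
inversely proportional to log copy number, so the smaller the difference the
greater the relative amount of F. nucleatum.  Site comparison uses a paired
Wilcoxon signed-rank test (tumour vs 10 cm), one-sided by default to match
the directional over-representation claim.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_ct", "site_comparison"]


def delta_ct(
    records: pd.DataFrame, efficiency: float = 2.0
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample dCt and relative quantity from a long Ct table.

    ``records`` needs columns sample_id, target in {fn, pan}, ct.  Samples
    missing either target are excluded and reported in the second return
    value.
    """
    required = {"sample_id", "target", "ct"}
    if not required <= set(records.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    bad_targets = set(records["target"]) - {"fn", "pan"}
    if bad_targets:
        raise ValueError(f"unknown qPCR targets {sorted(bad_targets)}")
    if (records["ct"] <= 0).any():
        bad = records.loc[records["ct"] <= 0, "sample_id"].tolist()
        raise ValueError(f"nonpositive Ct values for samples {bad}")
    wide = records.pivot_table(index="sample_id", columns="target", values="ct")
    excluded = sorted(wide.index[wide.isna().any(axis=1)])
    wide = wide.dropna()
    dct = wide["fn"] - wide["pan"]
    out = pd.DataFrame(
        {"delta_ct": dct, "rel_quantity": efficiency ** (-dct)}
    )
    return out, excluded


def site_comparison(
    rel_quantity: pd.Series,
    sites: pd.Series,
    patient_ids: pd.Series,
    site_a: str = "tumour",
    site_b: str = "10cm",
    alternative: str = "greater",
) -> tuple[float, float, int]:
    """Paired Wilcoxon signed-rank test of site_a vs site_b per patient.

    Pairs patients' values at the two sites; patients missing either site are
    dropped with a warning.  ``alternative="greater"`` tests for
    over-representation at ``site_a`` (on tumour).  Returns (statistic, p,
    n_pairs).
    """
    df = pd.DataFrame(
        {"value": rel_quantity, "site": sites.loc[rel_quantity.index],
         "patient": patient_ids.loc[rel_quantity.index]}
    )
    wide = df.pivot_table(index="patient", columns="site", values="value")
    for s in (site_a, site_b):
        if s not in wide.columns:
            raise ValueError(f"no samples at site {s!r}")
    pairs = wide[[site_a, site_b]].dropna()
    dropped = sorted(set(wide.index) - set(pairs.index))
    if dropped:
        warnings.warn(f"patients without a complete {site_a}/{site_b} pair: {dropped}")
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete pairs")
    diff = pairs[site_a] - pairs[site_b]
    if (diff == 0).all():
        return 0.0, 1.0, len(pairs)
    res = stats.wilcoxon(pairs[site_a], pairs[site_b], alternative=alternative)
    return float(res.statistic), float(res.pvalue), len(pairs)
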
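"""Relative quantification from qPCR cycle thresholds (2^-ddCt against a
reference gene and a calibrator condition) and cross-platform agreement
between sequencing and qPCR log2 fold changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import linregress

CT_COLUMNS = ("mirna", "timepoint", "replicate", "ct_target", "ct_reference")


def delta_delta_ct(records: pd.DataFrame, calibrator) -> pd.DataFrame:
    """Per (miRNA, timepoint) relative expression 2^-ddCt.

    dCt = mean(ct_target) - mean(ct_reference) over replicates; ddCt =
    dCt(condition) - dCt(calibrator); relative expression = 2^-ddCt and
    log2 relative expression = -ddCt.  Every miRNA must have the calibrator
    timepoint.
    """
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    for col in ("ct_target", "ct_reference"):
        vals = records[col]
        if ((vals <= 0) | (vals >= 45)).any():
            raise ValueError(f"{col} values must lie in (0, 45) cycles")
    grouped = records.groupby(["mirna", "timepoint"])[["ct_target", "ct_reference"]].mean()
    dct = grouped["ct_target"] - grouped["ct_reference"]
    out_rows = []
    for mirna, sub in dct.groupby(level="mirna"):
        sub = sub.droplevel("mirna")
        if calibrator not in sub.index:
            raise ValueError(f"calibrator {calibrator!r} missing for miRNA {mirna}")
        ddct = sub - sub.loc[calibrator]
        for tp, v in ddct.items():
            out_rows.append(
                {"mirna": mirna, "timepoint": tp, "ddct": v,
                 "rel_expr": 2.0 ** (-v), "log2_rel_expr": -v}
            )
    return pd.DataFrame(out_rows).set_index(["mirna", "timepoint"]).sort_index()


def platform_correlation(log2fc_seq, log2fc_qpcr) -> tuple[float, float, float]:
    """OLS of sequencing log2 fold changes on qPCR log2 fold changes:
    (slope, intercept, R^2), with R^2 the squared Pearson correlation."""
    y = np.asarray(log2fc_seq, dtype=float)
    x = np.asarray(log2fc_qpcr, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired fold-change values")
    if np.allclose(x.var(), 0) or np.allclose(y.var(), 0):
        raise ValueError("zero variance in fold-change vector")
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
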
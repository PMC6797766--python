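"""Digital differential expression between two sequencing libraries.

Counts are normalized to reads per million (count / library clean total x
10^6); exact zeros are floored to 0.01 so ratios stay defined; miRNAs below
1 RPM in every library are excluded.  Significance uses the exact
tag-sampling statistic

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

for the treatment count y given the control count x, with library depths N1
(control) and N2 (treatment); lower/upper tail sums C = sum_{y <= y_obs}
p(y|x) and D = sum_{y >= y_obs} p(y|x) give a two-sided p-value
min(1, 2*min(C, D)), corrected per comparison with Bonferroni.

All factorial terms are evaluated with log-gamma, so counts up to ~10^7 are
handled without overflow; tails are accumulated smallest-term-first and the
complementary tail is recovered through the exact identity
C + D = 1 + p(y_obs | x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp


@dataclass
class DETestResult:
    mirna: str
    x: int
    y: int
    n1: int
    n2: int
    log2fc: float
    lower_tail: float  # C
    upper_tail: float  # D
    p_raw: float
    p_bonferroni: float = math.nan
    call: str = "ns"


def normalize(counts: pd.DataFrame, totals: dict[str, int] | pd.Series) -> pd.DataFrame:
    """Reads-per-million matrix: count / library clean total x 10^6."""
    totals = pd.Series(totals)
    missing = [c for c in counts.columns if c not in totals.index]
    if missing:
        raise ValueError(f"no clean-read total for libraries {missing}")
    if (totals[counts.columns] <= 0).any():
        raise ValueError("library totals must be positive")
    return counts / totals[counts.columns] * 1e6


def floor_zeros(normalized: pd.DataFrame, floor: float = 0.01) -> pd.DataFrame:
    """Replace exact zeros with ``floor`` (0.01); all other values unchanged.
    Negative inputs are an error (normalized expression cannot be negative)."""
    if (normalized.values < 0).any():
        raise ValueError("normalized expression cannot be negative")
    return normalized.mask(normalized == 0, floor)


def low_expression_filter(normalized: pd.DataFrame, min_rpm: float = 1.0) -> pd.Series:
    """Boolean keep-mask: a miRNA is excluded iff its normalized expression is
    below ``min_rpm`` in every library."""
    if normalized.shape[1] < 1:
        raise ValueError("need at least one library")
    return (normalized >= min_rpm).any(axis=1)


def log2fc(treatment_norm, control_norm):
    """log2(treatment / control); inputs must be positive (flooring guarantees
    this for normalized expression)."""
    t = np.asarray(treatment_norm, dtype=float)
    c = np.asarray(control_norm, dtype=float)
    if (t <= 0).any() or (c <= 0).any():
        raise ValueError("log2fc requires positive values (apply floor_zeros first)")
    out = np.log2(t / c)
    return float(out) if out.ndim == 0 else out


def _log_pmf(y, x: int, n1: float, n2: float):
    """log p(y | x) for scalar x and array-like y, via log-gamma."""
    y = np.asarray(y, dtype=float)
    log_s = math.log(n2) - math.log(n1)
    log_1ps = math.log1p(n2 / n1)
    return (
        y * log_s
        + gammaln(x + y + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y + 1.0)
        - (x + y + 1.0) * log_1ps
    )


def ac_pmf(y: int, x: int, n1: float, n2: float) -> float:
    """The conditional probability p(y | x) of observing count y in the second
    library given count x in the first, at depths N1, N2."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library depths must be positive")
    return float(np.exp(_log_pmf(y, x, n1, n2)))


def _tail_sum(logs: np.ndarray) -> float:
    """Numerically careful sum of exp(logs), accumulated ascending."""
    if logs.size == 0:
        return 0.0
    return float(np.exp(logsumexp(np.sort(logs))))


def ac_tails(x: int, y_obs: int, n1: float, n2: float) -> tuple[float, float, float]:
    """Lower tail C = sum_{y <= y_obs} p(y|x), upper tail D = sum_{y >= y_obs}
    p(y|x) and the two-sided p-value min(1, 2 min(C, D)).

    The shorter tail is summed directly (terms beyond 40 conditional standard
    deviations are dropped as < 1e-16 of the total); the longer tail follows
    from C + D = 1 + p(y_obs | x).
    """
    if x < 0 or y_obs < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library depths must be positive")
    s = n2 / n1
    mean = (x + 1) * s
    sd = math.sqrt((x + 1) * s * (1 + s))
    pmf_obs = ac_pmf(y_obs, x, n1, n2)
    if y_obs <= mean:
        ys = np.arange(0, y_obs + 1)
        c = _tail_sum(_log_pmf(ys, x, n1, n2))
        d = min(1.0, 1.0 - c + pmf_obs)
    else:
        y_hi = int(math.ceil(mean + 40.0 * sd)) + 50
        y_hi = max(y_hi, y_obs)
        ys = np.arange(y_obs, y_hi + 1)
        d = _tail_sum(_log_pmf(ys, x, n1, n2))
        c = min(1.0, 1.0 - d + pmf_obs)
    c = min(c, 1.0)
    d = min(d, 1.0)
    p_two = min(1.0, 2.0 * min(c, d))
    return c, d, p_two


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment min(1, m * p); m defaults to the number of
    p-values in the comparison."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)


def call_de(log2fc_value: float, p_adj: float, fc_cut: float = 1.0, p_cut: float = 0.05) -> str:
    """Volcano-style call: up/down when |log2fc| reaches ``fc_cut`` and the
    adjusted p-value is below ``p_cut``; otherwise ns."""
    if p_adj < p_cut:
        if log2fc_value >= fc_cut:
            return "up"
        if log2fc_value <= -fc_cut:
            return "down"
    return "ns"


def de_table(
    counts: pd.DataFrame,
    totals: dict[str, int] | pd.Series,
    control: str,
    treatment: str,
    fc_cut: float = 1.0,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Full differential-expression table for one treatment-vs-control
    comparison: normalization, flooring, low-expression filter, log2 fold
    change, exact tail p-values and Bonferroni correction over the tested
    miRNAs."""
    totals = pd.Series(totals)
    norm = normalize(counts, totals)
    keep = low_expression_filter(norm[[control, treatment]])
    floored = floor_zeros(norm)
    tested = counts.index[keep]
    n1 = float(totals[control])
    n2 = float(totals[treatment])
    rows = []
    for mirna in tested:
        x = int(counts.at[mirna, control])
        y = int(counts.at[mirna, treatment])
        c, d, p = ac_tails(x, y, n1, n2)
        rows.append(
            DETestResult(
                mirna=mirna,
                x=x,
                y=y,
                n1=int(n1),
                n2=int(n2),
                log2fc=log2fc(floored.at[mirna, treatment], floored.at[mirna, control]),
                lower_tail=c,
                upper_tail=d,
                p_raw=p,
            )
        )
    p_adj = bonferroni([r.p_raw for r in rows])
    for r, pa in zip(rows, p_adj):
        r.p_bonferroni = float(pa)
        r.call = call_de(r.log2fc, r.p_bonferroni, fc_cut, p_cut)
    df = pd.DataFrame(
        [
            {
                "mirna": r.mirna, "x": r.x, "y": r.y, "N1": r.n1, "N2": r.n2,
                "log2fc": r.log2fc, "C": r.lower_tail, "D": r.upper_tail,
                "p_raw": r.p_raw, "p_bonferroni": r.p_bonferroni, "call": r.call,
            }
            for r in rows
        ]
    )
    return df.set_index("mirna")


def volcano_frame(de: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: log2fc vs -log10 adjusted p, with the call."""
    out = de[["log2fc", "p_bonferroni", "call"]].copy()
    out["neg_log10_p"] = -np.log10(out["p_bonferroni"].clip(lower=1e-300))
    return out[["log2fc", "neg_log10_p", "call", "p_bonferroni"]]
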
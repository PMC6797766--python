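"""Hypergeometric term enrichment of a study gene set against an annotation
table (gene -> term), with Benjamini-Hochberg (default) or Bonferroni
correction and a corrected-p significance threshold of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

SIG_THRESHOLD = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # study genes annotated to the term
    n: int  # study size
    K: int  # background genes annotated to the term
    N: int  # background size
    p_raw: float
    p_corrected: float
    significant: bool


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n): the chance that a
    random size-n draw from N background genes hits at least k of the K genes
    carrying the term."""
    if not (0 <= k <= n <= N) or not (0 <= K <= N) or k > K:
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    study_genes,
    annotation: pd.DataFrame,
    correction: str = "bh",
    background=None,
) -> pd.DataFrame:
    """One enrichment row per term with at least one study hit, sorted by
    ascending corrected p (ties by term id).

    ``annotation`` needs columns ``gene`` and ``term``; the background
    defaults to every gene in the table.  Study genes outside the background
    are an error (listed).
    """
    if correction not in ("bh", "bonferroni"):
        raise ValueError("correction must be 'bh' or 'bonferroni'")
    study = sorted(set(study_genes))
    bg = set(background) if background is not None else set(annotation["gene"])
    stray = sorted(set(study) - bg)
    if stray:
        raise ValueError(f"study genes absent from background: {stray}")
    ann = annotation[annotation["gene"].isin(bg)]
    n, N = len(study), len(bg)
    study_set = set(study)
    rows = []
    for term, genes in ann.groupby("term")["gene"]:
        members = set(genes)
        k = len(members & study_set)
        if k == 0:
            continue
        K = len(members)
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N,
                     "p_raw": hypergeom_upper(k, n, K, N)})
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "p_raw", "p_corrected", "significant"]
        )
    df = pd.DataFrame(rows)
    method = "fdr_bh" if correction == "bh" else "bonferroni"
    df["p_corrected"] = multipletests(df["p_raw"], method=method)[1]
    df["significant"] = df["p_corrected"] <= SIG_THRESHOLD
    return df.sort_values(["p_corrected", "term"]).reset_index(drop=True)
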
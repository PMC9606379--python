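"""Group-wise meta-analyses of the apical and basal transcript sets.

Once transcripts are classed as bona fide apical or basal (contaminants
excluded), external per-gene metrics are compared between the two sets:

* EJC enrichment — a published log2 fold change of exon-junction-complex
  immunoprecipitation over control per gene;
* translation efficiency (TE) — ribosome-footprint TPM divided by
  RNA-seq TPM per gene.

Both comparisons use the two-sided Wilcoxon rank-sum test: exact p by
enumeration for small tie-free samples, normal approximation with
midranks, tie correction and continuity correction otherwise.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from apicobasal.enrichment import BONA_FIDE_APICAL, BONA_FIDE_BASAL
from apicobasal.polarity import TestResult

logger = logging.getLogger(__name__)

#: largest combined sample size for which the tie-free exact p is used
_EXACT_N_MAX = 12

TRANSLATION_EFFICIENCY = "translation_efficiency"
EJC_LFC = "ejc_lfc"


def translation_efficiency(rfp_tpm: float, rna_tpm: float) -> float:
    """Ribosome-footprint TPM over RNA-seq TPM for one gene."""
    if rna_tpm <= 0:
        raise ValueError("rna_tpm must be > 0")
    if rfp_tpm < 0:
        raise ValueError("rfp_tpm must be >= 0")
    return rfp_tpm / rna_tpm


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact two-sided p by enumeration when the combined sample has at
    most 12 observations and no ties; otherwise the normal
    approximation with midranks, tie correction and continuity
    correction.  Two identical tied groups return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # all observations tied: no evidence in either direction
        return TestResult(
            method="wilcoxon_rank_sum",
            statistic=float(a.size * b.size / 2.0),
            df=float("nan"),
            p_value=1.0,
            estimate=0.0,
            n=(int(a.size), int(b.size)),
            degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= _EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        method=f"wilcoxon_rank_sum_{method}",
        statistic=float(res.statistic),
        df=float("nan"),
        p_value=float(min(res.pvalue, 1.0)),
        estimate=float(np.median(a) - np.median(b)),
        n=(int(a.size), int(b.size)),
    )


def compare_groups(
    table: pd.DataFrame, metric: str = TRANSLATION_EFFICIENCY
) -> tuple[dict[str, float], TestResult]:
    """Compare a per-gene metric between apical and basal transcript sets.

    Parameters
    ----------
    table
        Annotation table with columns ``gene_id``, ``loc_class`` and,
        depending on ``metric``, either ``ejc_lfc`` or ``rfp_tpm`` +
        ``rna_tpm``.  Only bona fide apical/basal rows enter the
        comparison; contaminant classes are excluded by construction.
    metric
        ``"translation_efficiency"`` (RFP TPM / RNA TPM, genes with
        rna_tpm <= 0 dropped and logged) or ``"ejc_lfc"``.

    Returns
    -------
    (medians, test)
        Median metric per class and the two-sided Wilcoxon rank-sum
        result.
    """
    if "loc_class" not in table.columns:
        raise ValueError("table needs a loc_class column")
    sub = table[table["loc_class"].isin([BONA_FIDE_APICAL, BONA_FIDE_BASAL])].copy()

    if metric == TRANSLATION_EFFICIENCY:
        for col in ("rfp_tpm", "rna_tpm"):
            if col not in sub.columns:
                raise ValueError(f"table needs a {col!r} column for TE comparisons")
        usable = sub["rna_tpm"] > 0
        n_dropped = int((~usable).sum())
        if n_dropped:
            logger.info("dropping %d genes with rna_tpm <= 0 from TE comparison", n_dropped)
        sub = sub[usable]
        sub["_metric"] = sub["rfp_tpm"] / sub["rna_tpm"]
    elif metric == EJC_LFC:
        if "ejc_lfc" not in sub.columns:
            raise ValueError("table needs an 'ejc_lfc' column")
        sub = sub[sub["ejc_lfc"].notna()]
        sub["_metric"] = sub["ejc_lfc"].astype(float)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    values = {}
    for cls in (BONA_FIDE_APICAL, BONA_FIDE_BASAL):
        vals = sub.loc[sub["loc_class"] == cls, "_metric"].to_numpy()
        if vals.size == 0:
            raise ValueError(f"no usable genes in class {cls!r}")
        values[cls] = vals
    medians = {cls: float(np.median(v)) for cls, v in values.items()}
    test = wilcoxon_rank_sum(values[BONA_FIDE_APICAL], values[BONA_FIDE_BASAL])
    return medians, test


def summarize_comparison(
    medians: dict[str, float], test: TestResult, metric: str
) -> pd.DataFrame:
    """One-row summary table (medians, n per group, statistic, p)."""
    n_a, n_b = test.n if isinstance(test.n, tuple) else (test.n, test.n)
    return pd.DataFrame(
        [
            {
                "metric": metric,
                "median_apical": medians[BONA_FIDE_APICAL],
                "median_basal": medians[BONA_FIDE_BASAL],
                "n_apical": n_a,
                "n_basal": n_b,
                "statistic": test.statistic,
                "p_value": test.p_value,
                "method": test.method,
            }
        ]
    )
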
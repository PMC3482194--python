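"""Gene stratification by length quantile and exon count.

Genes are split at the lower-tail 20% length quantile (inclusive: length <=
cutoff is short) and by single vs multi exon, giving four strata. Per-gene
log2 expression changes between two conditions (with a pseudo-signal added
to both) are compared across strata by two-sample K-S tests on their
empirical CDFs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import KsResult, ks_two_sample

STRATA = ("long_multi_exon", "short_multi_exon", "short_single_exon",
          "long_single_exon")

DEFAULT_QUANTILE = 0.20
DEFAULT_PSEUDO_SIGNAL = 1.0

# the contrasts reported by the cumulative-distribution comparison
DEFAULT_PAIRS = (
    ("short_single_exon", "short_multi_exon"),
    ("long_multi_exon", "short_multi_exon"),
)


class StrataError(ValueError):
    pass


@dataclass(frozen=True)
class KsComparison:
    stratum_a: str
    stratum_b: str
    n_a: int
    n_b: int
    statistic: float
    pvalue: float


def stratify_genes(
    gene_info: pd.DataFrame, quantile: float = DEFAULT_QUANTILE
) -> Tuple[float, pd.DataFrame]:
    """Assign each gene a stratum from its length and exon count.

    Returns the length cutoff (the ``quantile``-th empirical quantile,
    linear interpolation) and a copy of ``gene_info`` with a ``stratum``
    column. Genes with length <= cutoff are short.
    """
    if len(gene_info) < 5:
        raise StrataError("stratification needs at least 5 genes")
    lengths = gene_info["length"].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise StrataError("gene lengths must be positive")
    cutoff = float(np.quantile(lengths, quantile))
    out = gene_info.copy()
    short = out["length"] <= cutoff
    single = out["n_exons"] == 1
    stratum = np.where(
        short,
        np.where(single, "short_single_exon", "short_multi_exon"),
        np.where(single, "long_single_exon", "long_multi_exon"),
    )
    out["stratum"] = stratum
    return cutoff, out


def expression_changes(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    pseudo_signal: float = DEFAULT_PSEUDO_SIGNAL,
) -> Tuple[pd.DataFrame, int]:
    """Per-gene log2((b + eps) / (a + eps)); genes missing in one table are
    excluded with their count reported."""
    if pseudo_signal <= 0:
        raise StrataError("pseudo_signal must be positive")
    a = expr_a.set_index("gene_id")["value"]
    b = expr_b.set_index("gene_id")["value"]
    common = a.index.intersection(b.index)
    n_excluded = (len(a) - len(common)) + (len(b) - len(common))
    change = np.log2((b.loc[common] + pseudo_signal)
                     / (a.loc[common] + pseudo_signal))
    df = pd.DataFrame({"gene_id": common, "expr_a": a.loc[common].values,
                       "expr_b": b.loc[common].values,
                       "log2_change": change.values})
    return df, int(n_excluded)


def cdf_compare(
    changes: pd.DataFrame,
    strata: pd.DataFrame,
    pairs: Sequence[tuple] = DEFAULT_PAIRS,
) -> Tuple[Dict[str, np.ndarray], List[KsComparison], List[str]]:
    """ECDFs per stratum and pairwise K-S tests.

    Returns (ecdf values per stratum, K-S results for each requested pair,
    strata excluded for having fewer than 2 genes).
    """
    merged = changes.merge(strata[["gene_id", "stratum"]], on="gene_id")
    groups = {
        name: np.sort(grp["log2_change"].to_numpy())
        for name, grp in merged.groupby("stratum")
    }
    excluded = [name for name, vals in groups.items() if vals.size < 2]
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise StrataError("need >= 2 strata with >= 2 genes each")
    results = []
    for sa, sb in pairs:
        if sa not in groups or sb not in groups:
            continue
        ks = ks_two_sample(groups[sa], groups[sb])
        results.append(
            KsComparison(sa, sb, groups[sa].size, groups[sb].size,
                         ks.statistic, ks.pvalue)
        )
    return groups, results, excluded
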
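"""Expression-level summaries: CPM, correlation screening, DE bias.

CPM values are plain ratios (count * 1e6 / sample total) with no
model-based shrinkage, so that within-group variability stays visible.
The correlation screen looks for the largest gene set whose pairwise
CPM correlations all exceed a threshold — a maximum clique in the
thresholded correlation graph, solved exactly for the small candidate
sets this analysis produces.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Dict, List, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def cpm(counts) -> pd.DataFrame:
    """Counts-per-million per sample: ``count * 1e6 / column total``."""
    mat = counts.counts if hasattr(counts, "counts") else counts
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total count: {bad}")
    return mat * 1e6 / totals


def pairwise_correlation(cpm_values: pd.DataFrame,
                         genes: Sequence[str] | None = None,
                         log: bool = False,
                         method: str = "pearson") -> pd.DataFrame:
    """Gene-by-gene correlation of CPM values across samples.

    Zero-variance genes get NaN correlations (logged).  ``log=True``
    correlates log2(CPM + 1) instead of raw CPM.
    """
    x = cpm_values if genes is None else cpm_values.loc[list(genes)]
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if log:
        x = np.log2(x + 1.0)
    flat = x.std(axis=1, ddof=1) == 0
    if flat.any():
        logger.info("pairwise_correlation: %d zero-variance genes -> NaN",
                    int(flat.sum()))
    corr = x.T.corr(method=method)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    corr.loc[flat, :] = np.nan
    corr.loc[:, flat] = np.nan
    return corr


def correlated_set(correlations: pd.DataFrame,
                   threshold: float = 0.8) -> List[str]:
    """Largest gene set with all pairwise correlations > threshold.

    Exact maximum clique of the graph whose edges join gene pairs with
    ``r > threshold`` (strict).  Among maximum cliques the
    lexicographically smallest sorted gene-id tuple is returned; a
    singleton (first gene id) is returned when no pair passes.
    """
    c = correlations
    if c.shape[0] != c.shape[1] or not c.index.equals(c.columns):
        raise ValueError("correlation matrix must be square with matching "
                         "index and columns")
    genes = list(c.index)
    if not genes:
        return []
    g = nx.Graph()
    g.add_nodes_from(genes)
    vals = c.to_numpy()
    for i, j in combinations(range(len(genes)), 2):
        if vals[i, j] > threshold:
            g.add_edge(genes[i], genes[j])
    best: tuple = ()
    best_size = 0
    for clique in nx.find_cliques(g):
        key = tuple(sorted(clique))
        if len(key) > best_size or (len(key) == best_size and key < best):
            best, best_size = key, len(key)
    return list(best)


def bias_summary(results: pd.DataFrame,
                 pos_label: str = "male", neg_label: str = "female",
                 fdr_threshold: float = 0.1) -> Dict[str, float]:
    """Direction counts and rounded percentages among significant genes.

    Genes with ``fdr < fdr_threshold`` are split by the sign of their
    log2 fold change (positive = higher in ``pos_label``).  Percentages
    are of the significant total, rounded to the nearest integer.  With
    no significant genes an empty summary is returned.
    """
    sig = results[results["fdr"] < fdr_threshold] if "fdr" in results \
        else results
    n_pos = int((sig["log2_fold_change"] > 0).sum())
    n_neg = int((sig["log2_fold_change"] < 0).sum())
    total = n_pos + n_neg
    if total == 0:
        return {}
    return {
        "n_significant": total,
        f"n_{pos_label}_biased": n_pos,
        f"n_{neg_label}_biased": n_neg,
        f"pct_{pos_label}_biased": round(100.0 * n_pos / total),
        f"pct_{neg_label}_biased": round(100.0 * n_neg / total),
    }


def de_counts_by_chromosome(results: pd.DataFrame,
                            chrom_col: str = "chrom",
                            fdr_threshold: float = 0.1) -> pd.Series:
    """Number of significant DE genes per chromosome (plain groupby)."""
    sig = results[results["fdr"] < fdr_threshold]
    return sig.groupby(chrom_col).size().sort_index()
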
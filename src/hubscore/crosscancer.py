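"""Analytics over one or more per-cancer ranked results.

Covers top-N hub extraction, cross-cancer hub intersection, the min-max
normalized gene-by-cancer score matrix, score/mutation/Z correlation
diagnostics, high-score counts, outlier calling, and overlap with external
cancer-gene lists. Network scores scale with each cohort's mutation rate,
so raw scores are only comparable within a cancer; the min-max normalized
matrix is what supports cross-cancer comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import CancerResult, ScoredGene

logger = logging.getLogger(__name__)

GeneTypeFilter = Literal["seed", "interactor", "both"]


def _select(result: CancerResult, gene_type: GeneTypeFilter) -> list[ScoredGene]:
    if gene_type == "seed":
        return list(result.seeds)
    if gene_type == "interactor":
        return list(result.interactors)
    if gene_type == "both":
        return result.all_genes
    raise ValueError(f"unknown gene_type {gene_type!r}")


def top_n(
    result: CancerResult, n: int, gene_type: GeneTypeFilter = "seed"
) -> list[str]:
    """First *n* genes of the requested ranked list(s).

    For ``both`` the union of the two lists is re-sorted by the ranking key
    (score desc, mutated-interactor count desc, symbol asc) and truncated.
    Short lists return fewer than *n* genes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sel = _select(result, gene_type)
    sel.sort(key=lambda sg: (-sg.network_score, -sg.mutated_interactors, sg.gene))
    return [sg.gene for sg in sel[:n]]


@dataclass
class HubTable:
    """Genes that are top-*n* hubs in at least one cancer, with membership."""

    membership: dict[str, set[str]]  # gene -> cancers where rank <= n
    n: int
    gene_type: GeneTypeFilter

    def restricted(self, k: int) -> "HubTable":
        """Genes that are top-n hubs in at least *k* cancers."""
        return HubTable(
            {g: c for g, c in self.membership.items() if len(c) >= k},
            self.n,
            self.gene_type,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            self.membership.items(), key=lambda gc: (-len(gc[1]), gc[0])
        )
        return pd.DataFrame(
            {
                "gene": [g for g, _ in rows],
                "n_cancers": [len(c) for _, c in rows],
                "cancers": [",".join(sorted(c)) for _, c in rows],
            }
        )


def shared_hubs(
    results: Iterable[CancerResult],
    n: int = 50,
    k: int = 3,
    gene_type: GeneTypeFilter = "seed",
) -> HubTable:
    """Genes appearing in the top-*n* list of at least *k* cancers."""
    results = list(results)
    if not results:
        raise ValueError("shared_hubs needs at least one result")
    if k < 1 or n < 1:
        raise ValueError("n and k must be >= 1")
    membership: dict[str, set[str]] = {}
    for res in results:
        for gene in top_n(res, n, gene_type):
            membership.setdefault(gene, set()).add(res.cancer)
    return HubTable(membership, n, gene_type).restricted(k)


@dataclass
class ScoreMatrix:
    """Gene-by-cancer network-score matrix; absent pairs are 0."""

    genes: list[str]
    cancers: list[str]
    values: np.ndarray
    normalized: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cancers)


def minmax_normalize_columns(values: np.ndarray) -> np.ndarray:
    """Map each column to [0, 1]; an all-equal column maps to all 0."""
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=0, keepdims=True)
    hi = values.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.zeros_like(values)
    nz = (span > 0).ravel()
    out[:, nz] = (values[:, nz] - lo[:, nz]) / span[:, nz]
    return out


def build_score_matrix(
    results: Iterable[CancerResult],
    gene_type: GeneTypeFilter = "both",
    normalize: bool = True,
) -> ScoreMatrix:
    """Assemble the gene-by-cancer score matrix over the union of genes."""
    results = list(results)
    if not results:
        raise ValueError("build_score_matrix needs at least one result")
    cancers = [r.cancer for r in results]
    genes = sorted({sg.gene for r in results for sg in _select(r, gene_type)})
    idx = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(genes), len(cancers)))
    for j, res in enumerate(results):
        for sg in _select(res, gene_type):
            values[idx[sg.gene], j] = sg.network_score
    if normalize:
        values = minmax_normalize_columns(values)
    return ScoreMatrix(genes, cancers, values, normalized=normalize)


CORRELATION_VARIABLES = ("mutation_count", "meta_z", "network_score")


def score_correlations(
    result: CancerResult,
    method: Literal["pearson", "spearman"] = "pearson",
) -> pd.DataFrame:
    """Pairwise correlations between mutation count, Meta-Z and score.

    Uses pairwise-complete observations; Meta-Z is only defined for seed
    genes, so its pairs are restricted to seeds. A zero-variance variable
    yields NaN (undefined, not 0) in its row/column, logged. Low
    off-diagonal values mean the three quantities carry non-redundant
    information.
    """
    corr_fn = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]
    rows = []
    for sg in result.all_genes:
        rows.append(
            {
                "mutation_count": float(sg.status.profile.total_count),
                "meta_z": math.nan if sg.status.meta_z is None else sg.status.meta_z,
                "network_score": sg.network_score,
            }
        )
    df = pd.DataFrame(rows, columns=list(CORRELATION_VARIABLES))
    if len(df) < 3:
        raise ValueError("need at least 3 genes for correlation analysis")
    out = pd.DataFrame(
        np.eye(3), index=CORRELATION_VARIABLES, columns=CORRELATION_VARIABLES
    )
    for i, a in enumerate(CORRELATION_VARIABLES):
        for b in CORRELATION_VARIABLES[i + 1:]:
            pair = df[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() == 1 or pair[b].nunique() == 1:
                logger.warning(
                    "score_correlations: %s vs %s undefined (constant or <3 obs)", a, b
                )
                r = math.nan
            else:
                r = float(corr_fn(pair[a], pair[b]).statistic)
            out.loc[a, b] = out.loc[b, a] = r
    return out


def count_high_scores(result: CancerResult, threshold: float) -> int:
    """Number of genes (seeds + interactors) scoring strictly above *threshold*."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return sum(1 for sg in result.all_genes if sg.network_score > threshold)


def detect_outliers(
    result: CancerResult,
    k_sd: float = 1.96,
    gene_type: GeneTypeFilter = "both",
) -> set[str]:
    """Genes whose score exceeds mean + k_sd * sample SD of the selected list."""
    sel = _select(result, gene_type)
    scores = np.array([sg.network_score for sg in sel], dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least 2 genes for outlier detection")
    sd = scores.std(ddof=1)
    if sd == 0:
        logger.warning("detect_outliers: zero score variance, no outliers")
        return set()
    cutoff = scores.mean() + k_sd * sd
    return {sg.gene for sg in sel if sg.network_score > cutoff}


def external_overlap(
    hubs: set[str], external: set[str]
) -> tuple[set[str], float]:
    """Intersection with an external cancer-gene list and % of it covered."""
    if not external:
        raise ValueError("external gene set must be non-empty")
    inter = hubs & external
    return inter, 100.0 * len(inter) / len(external)
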
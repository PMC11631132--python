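"""Network-score computation and per-cancer ranked lists.

The network score of a gene is the total number of interaction partners of
its protein (``T``, the full interactome degree) multiplied by the fraction
of those partners encoded by cancer-mutated genes (``M/T``). Algebraically
the product collapses to ``M``, the count of mutated neighbours; it is still
evaluated as the literal product, and ``T`` and ``M`` are reported
separately so downstream consumers can form any variant (e.g. ``M**2/T``)
without rescoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .errors import ConsistencyError
from .filters import FilterThresholds, GeneStatus, GeneType
from .io import Interactome


@dataclass(frozen=True)
class ScoredGene:
    """A retained gene with its interactor counts, score and list rank."""

    status: GeneStatus
    total_interactors: int
    mutated_interactors: int
    network_score: float
    rank: int = 0

    @property
    def gene(self) -> str:
        return self.status.gene


@dataclass
class CancerResult:
    """Ranked seed and interactor lists for one cancer."""

    cancer: str
    seeds: list[ScoredGene]
    interactors: list[ScoredGene]
    thresholds: FilterThresholds
    mutated_set: set[str] = field(default_factory=set)

    @property
    def all_genes(self) -> list[ScoredGene]:
        return self.seeds + self.interactors


def neighbour_counts(
    gene: str, interactome: Interactome, mutated_set: set[str]
) -> tuple[int, int]:
    """(total, mutated) interactor counts for *gene*.

    ``T`` is the gene's degree in the full interactome (0 when absent);
    ``M`` counts neighbours in *mutated_set*. The gene itself never counts:
    self-loops were removed at ingest.
    """
    neigh = interactome.neighbours(gene)
    return len(neigh), sum(1 for n in neigh if n in mutated_set)


def network_score(T: int, M: int, mode: Literal["literal"] = "literal") -> float:
    """Literal score: total interactors times the mutated fraction.

    Equals the number of mutated neighbours; 0 for an isolated protein.
    """
    if mode != "literal":
        raise ValueError(f"unknown score mode {mode!r}")
    if not 0 <= M <= T:
        raise ValueError(f"need 0 <= M <= T, got T={T}, M={M}")
    if T == 0:
        return 0.0
    # (T*M)/T rather than T*(M/T): the exact quotient is the integer M, so
    # IEEE division returns it exactly, with no intermediate rounding.
    return (T * M) / T


def _sort_key(sg: ScoredGene) -> tuple:
    return (-sg.network_score, -sg.mutated_interactors, sg.gene)


def score_and_rank(
    statuses: Iterable[GeneStatus],
    interactome: Interactome,
    mutated_set: set[str],
    thresholds: FilterThresholds | None = None,
) -> CancerResult:
    """Score every retained gene and build the two ranked lists.

    Seeds and interactors are separated by gene type, each list sorted by
    (score desc, mutated-interactor count desc, symbol asc) and assigned
    1-based ranks. Genes absent from the interactome keep score 0 and rank
    at the bottom rather than being dropped.
    """
    statuses = [s for s in statuses if s.retained]
    cancers = {s.cancer for s in statuses if s.cancer}
    if len(cancers) > 1:
        raise ConsistencyError(f"statuses span multiple cancers: {sorted(cancers)}")
    genes = [s.gene for s in statuses]
    if len(genes) != len(set(genes)):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ConsistencyError(f"duplicate gene symbols in statuses: {dupes}")

    scored = {GeneType.SEED: [], GeneType.INTERACTOR: []}
    th = thresholds
    for st in statuses:
        T, M = neighbour_counts(st.gene, interactome, mutated_set)
        scored[st.gene_type].append(
            ScoredGene(st, T, M, network_score(T, M))
        )
    ranked = {}
    for gtype, lst in scored.items():
        lst.sort(key=_sort_key)
        ranked[gtype] = [
            ScoredGene(sg.status, sg.total_interactors, sg.mutated_interactors,
                       sg.network_score, rank=i + 1)
            for i, sg in enumerate(lst)
        ]
    if th is None:
        th = FilterThresholds()
    return CancerResult(
        cancer=cancers.pop() if cancers else "",
        seeds=ranked[GeneType.SEED],
        interactors=ranked[GeneType.INTERACTOR],
        thresholds=th,
        mutated_set=set(mutated_set),
    )
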
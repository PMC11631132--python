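"""Survival-score labelling and mutation-frequency retention rules.

A gene is kept for scoring when its mutation burden or its survival
association (Precog Meta-Z) marks it as plausibly cancer relevant. The
retention thresholds are anchored on two per-cancer order statistics of the
per-gene mutation counts: the median ``md`` and the minimum ``min``. This
range-based scheme adapts the cutoffs to each cohort's size and mutation
rate, because mutation counts per gene are strongly right-skewed.

Rule table (f = a gene's total mutation count; "effect" = |Z| significant at
the ``z_sig`` level):

=============  =========  =====================
location       effect     retained when
=============  =========  =====================
NON_ORF        yes        f >= md + min
NON_ORF        no         f >  3*md + min
ORF            any        f >= md - min
BOTH           yes        f >= md - min
BOTH           no         f >  3*md
NONE           --         |Z| >= z_strong
=============  =========  =====================

Unmutated genes with no survival effect are discarded before evaluation.
Retained genes are clustered as MUT (mutated only), PRECOG (unmutated,
significant Z) or MUT+PRECOG (both); the latter two are "seed" genes, the
first "interactor" genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from statistics import median
from typing import Iterable, Mapping

from .classify import GeneMutationProfile, LocationClass
from .errors import ConsistencyError
from .io import PrecogRecord


class PrecogLabel(str, Enum):
    ONCOGENE = "oncogene"
    TUMOUR_SUPPRESSOR = "tumour_suppressor"
    NONE = "none"


class Cluster(str, Enum):
    MUT = "MUT"
    PRECOG = "PRECOG"
    MUT_PRECOG = "MUT+PRECOG"


class GeneType(str, Enum):
    SEED = "seed"
    INTERACTOR = "interactor"


@dataclass(frozen=True)
class FilterThresholds:
    """Retention thresholds for one cancer.

    ``z_sig`` (default 1.96, 95% confidence) defines a significant survival
    effect; ``z_strong`` (default 2.58, 99%) rescues unmutated genes. ``md``
    and ``min_`` are the median and minimum per-gene mutation counts,
    computed over genes with at least one mutation. The three rule
    multipliers are exposed for sensitivity analyses; defaults implement the
    table in the module docstring.
    """

    z_sig: float = 1.96
    z_strong: float = 2.58
    md: float = 0.0
    min_: float = 0.0
    non_orf_no_effect_mult: float = 3.0
    both_no_effect_mult: float = 3.0

    def __post_init__(self):
        if not (self.z_strong >= self.z_sig > 0):
            raise ValueError("need z_strong >= z_sig > 0")
        if not (self.md >= self.min_ >= 0):
            raise ValueError("need md >= min_ >= 0")


@dataclass(frozen=True)
class GeneStatus:
    """A gene's retention decision, cluster and gene type in one cancer."""

    gene: str
    cancer: str
    profile: GeneMutationProfile
    meta_z: float | None
    precog_label: PrecogLabel
    retained: bool
    cluster: Cluster | None = None
    gene_type: GeneType | None = None


def precog_label(meta_z: float | None, z_sig: float = 1.96) -> PrecogLabel:
    """Oncogene / tumour-suppressor call from a survival Meta-Z score.

    ``Z >= z_sig`` reads as oncogene-like (high expression, worse outcome),
    ``Z <= -z_sig`` as tumour-suppressor-like; both boundaries inclusive.
    """
    if meta_z is None:
        return PrecogLabel.NONE
    if not math.isfinite(meta_z):
        raise ValueError(f"meta_z must be finite, got {meta_z}")
    if meta_z >= z_sig:
        return PrecogLabel.ONCOGENE
    if meta_z <= -z_sig:
        return PrecogLabel.TUMOUR_SUPPRESSOR
    return PrecogLabel.NONE


def mutation_stats(profiles: Iterable[GeneMutationProfile]) -> tuple[float, float]:
    """Median and minimum per-gene mutation count over mutated genes.

    Genes absent from the mutation data (zero counts) do not enter the
    statistics. Median of an even-length sample is the mean of the two
    middle order statistics, so ``md`` may be non-integer.
    """
    counts = [p.total_count for p in profiles if p.total_count > 0]
    if not counts:
        raise ValueError("no mutated gene: md/min statistics undefined")
    return float(median(counts)), float(min(counts))


def is_retained(
    profile: GeneMutationProfile,
    label: PrecogLabel,
    meta_z: float | None,
    th: FilterThresholds,
) -> bool:
    """Evaluate the class-specific retention rule for one gene."""
    f = profile.total_count
    effect = label is not PrecogLabel.NONE
    cls = profile.location_class
    if cls is LocationClass.NONE:
        return meta_z is not None and abs(meta_z) >= th.z_strong
    if cls is LocationClass.ORF:
        return f >= th.md - th.min_
    if cls is LocationClass.NON_ORF:
        if effect:
            return f >= th.md + th.min_
        return f > th.non_orf_no_effect_mult * th.md + th.min_
    # BOTH
    if effect:
        return f >= th.md - th.min_
    return f > th.both_no_effect_mult * th.md


def assign_cluster(profile: GeneMutationProfile, label: PrecogLabel) -> Cluster:
    """MUT / PRECOG / MUT+PRECOG cluster for a retained gene."""
    mutated = profile.total_count > 0
    effect = label is not PrecogLabel.NONE
    if mutated and not effect:
        return Cluster.MUT
    if not mutated and effect:
        return Cluster.PRECOG
    if mutated and effect:
        return Cluster.MUT_PRECOG
    raise ConsistencyError(
        "unmutated gene without survival effect reached cluster assignment"
    )


def gene_type_of(cluster: Cluster) -> GeneType:
    return GeneType.INTERACTOR if cluster is Cluster.MUT else GeneType.SEED


def filter_genes(
    profiles: Mapping[str, GeneMutationProfile],
    precog: Iterable[PrecogRecord],
    thresholds: FilterThresholds | None = None,
) -> list[GeneStatus]:
    """Label, filter and cluster the union of mutated and Precog-listed genes.

    Unmutated genes with Precog label ``none`` are dropped before evaluation;
    ``md``/``min`` are computed once from the mutated subset. Returns one
    :class:`GeneStatus` per evaluated gene, retained or not, sorted by gene
    symbol for determinism.
    """
    th = thresholds or FilterThresholds()
    z_by_gene = {r.gene: r.meta_z for r in precog}
    cancers = {p.cancer for p in profiles.values() if p.cancer}
    if len(cancers) > 1:
        raise ConsistencyError(f"profiles span multiple cancers: {sorted(cancers)}")
    cancer = cancers.pop() if cancers else ""

    mutated = {g: p for g, p in profiles.items() if p.total_count > 0}
    if mutated and (th.md == 0.0 and th.min_ == 0.0):
        md, min_ = mutation_stats(mutated.values())
        th = replace(th, md=md, min_=min_)

    statuses: list[GeneStatus] = []
    for gene in sorted(set(profiles) | set(z_by_gene)):
        profile = profiles.get(gene) or GeneMutationProfile(gene, cancer, 0, 0)
        meta_z = z_by_gene.get(gene)
        label = precog_label(meta_z, th.z_sig)
        if profile.total_count == 0 and label is PrecogLabel.NONE:
            continue  # discarded before evaluation
        kept = is_retained(profile, label, meta_z, th)
        cluster = gtype = None
        if kept:
            cluster = assign_cluster(profile, label)
            gtype = gene_type_of(cluster)
        statuses.append(
            GeneStatus(gene, cancer, profile, meta_z, label, kept, cluster, gtype)
        )
    return statuses
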
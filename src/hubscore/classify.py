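"""Aggregate mutation events into per-gene profiles and location classes.

Each gene is classed by where its mutations fall: exclusively in the coding
sequence (``ORF``), exclusively outside it (``NON_ORF``), in both (``BOTH``),
or nowhere (``NONE``, no mutation detected). Counts are raw event counts,
one per mutation-table row.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .errors import ConsistencyError
from .io import MutationRecord, Region


class LocationClass(str, Enum):
    ORF = "ORF"
    NON_ORF = "NON_ORF"
    BOTH = "BOTH"
    NONE = "NONE"


def classify_location(orf_count: int, non_orf_count: int) -> LocationClass:
    """Four-way mutation-location class from the two region counts."""
    if orf_count < 0 or non_orf_count < 0:
        raise ValueError("mutation counts must be non-negative")
    if orf_count and non_orf_count:
        return LocationClass.BOTH
    if orf_count:
        return LocationClass.ORF
    if non_orf_count:
        return LocationClass.NON_ORF
    return LocationClass.NONE


@dataclass(frozen=True)
class GeneMutationProfile:
    """Per-gene ORF / non-ORF mutation counts and derived location class."""

    gene: str
    cancer: str
    orf_count: int
    non_orf_count: int

    @property
    def total_count(self) -> int:
        return self.orf_count + self.non_orf_count

    @property
    def location_class(self) -> LocationClass:
        return classify_location(self.orf_count, self.non_orf_count)


def build_gene_profiles(
    records: Iterable[MutationRecord],
    universe: set[str] | None = None,
    cancer: str | None = None,
) -> dict[str, GeneMutationProfile]:
    """Tally mutation records into one profile per gene.

    Genes listed in *universe* but absent from *records* receive a zero-count
    ``NONE`` profile, so genes known only from survival data flow through the
    same downstream path. All records must share one cancer id; *cancer* must
    be given when *records* is empty and a universe is supplied.
    """
    records = list(records)
    cancers = {r.cancer for r in records}
    if len(cancers) > 1:
        raise ConsistencyError(f"records span multiple cancers: {sorted(cancers)}")
    if cancers:
        cancer = cancers.pop()
    elif cancer is None:
        cancer = ""
    counts: dict[str, list[int]] = {}
    for r in records:
        c = counts.setdefault(r.gene, [0, 0])
        c[0 if r.region is Region.ORF else 1] += 1
    profiles = {
        g: GeneMutationProfile(g, cancer, orf, non) for g, (orf, non) in counts.items()
    }
    for g in universe or ():
        g = g.strip().upper()
        if g not in profiles:
            profiles[g] = GeneMutationProfile(g, cancer, 0, 0)
    return profiles
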
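"""Shared builders for in-memory fixtures used across the suite."""

from __future__ import annotations

import pytest

from hubscore import (
    CancerResult,
    FilterThresholds,
    GeneMutationProfile,
    GeneStatus,
    Cluster,
    GeneType,
    PrecogLabel,
    ScoredGene,
    precog_label,
)


def make_status(
    gene: str,
    orf: int = 0,
    non: int = 0,
    z: float | None = None,
    cancer: str = "C",
    retained: bool = True,
) -> GeneStatus:
    """Build a retained GeneStatus with cluster derived from counts and Z."""
    profile = GeneMutationProfile(gene, cancer, orf, non)
    label = precog_label(z)
    mutated = orf + non > 0
    effect = label is not PrecogLabel.NONE
    if mutated and effect:
        cluster = Cluster.MUT_PRECOG
    elif mutated:
        cluster = Cluster.MUT
    else:
        cluster = Cluster.PRECOG
    gtype = GeneType.INTERACTOR if cluster is Cluster.MUT else GeneType.SEED
    return GeneStatus(gene, cancer, profile, z, label, retained, cluster, gtype)


def make_result(
    cancer: str,
    seed_scores: dict[str, float] | None = None,
    interactor_scores: dict[str, float] | None = None,
) -> CancerResult:
    """Build a ranked CancerResult directly from gene→score maps.

    T is set to score+1 and M to the integer score so the ScoredGene
    invariants hold; ranking uses the documented (score desc, M desc,
    symbol asc) key.
    """

    def build(scores: dict[str, float], gtype: GeneType) -> list[ScoredGene]:
        out = []
        for gene, s in scores.items():
            z = 3.0 if gtype is GeneType.SEED else None
            orf = 1 if gtype is GeneType.INTERACTOR else 0
            st = make_status(gene, orf=orf, z=z, cancer=cancer)
            out.append(ScoredGene(st, int(s) + 1, int(s), float(s)))
        out.sort(key=lambda sg: (-sg.network_score, -sg.mutated_interactors, sg.gene))
        return [
            ScoredGene(sg.status, sg.total_interactors, sg.mutated_interactors,
                       sg.network_score, i + 1)
            for i, sg in enumerate(out)
        ]

    return CancerResult(
        cancer,
        build(seed_scores or {}, GeneType.SEED),
        build(interactor_scores or {}, GeneType.INTERACTOR),
        FilterThresholds(),
    )


@pytest.fixture
def tsv_writer(tmp_path):
    """Write a header+rows TSV into the test tmp dir and return its path."""

    def write(name: str, header: list[str], rows: list[list]) -> str:
        lines = ["\t".join(header)]
        lines += ["\t".join(str(c) for c in row) for row in rows]
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return str(p)

    return write
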
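"""Synthetic cohort generator with planted ground truth.

Emits the three input files the pipeline consumes — a MAF-like mutation
table, a Precog-style Meta-Z table and a BioGRID TAB3 interaction table —
together with a machine-readable truth record. The generator emulates the
salient structure of the real inputs:

* per-gene mutation counts drawn from a geometric law (right-skewed, like
  real per-gene mutation burdens);
* a sparse set of genes with survival-significant Meta-Z scores on a
  standard-normal background;
* an Erdős–Rényi background interactome, plus ``n_hubs`` planted hub genes
  each wired to ``hub_degree`` distinct mutated genes and given a strong
  Meta-Z so each survives filtering as a seed.

Planting wires hubs to *mutated* genes specifically because the network
score counts mutated neighbours: the expected ranking is then analytically
transparent. Identical seeds produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .classify import classify_location
from .errors import ConfigError, ConsistencyError
from .io import DEFAULT_NON_ORF_LABELS, DEFAULT_ORF_LABELS
from .scoring import CancerResult

_ORF_LABELS = sorted(DEFAULT_ORF_LABELS)
_NON_ORF_LABELS = sorted(DEFAULT_NON_ORF_LABELS)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    Defaults give a 500-gene cohort with 3 planted hubs wired to 25 mutated
    genes each over a mean-degree-3 background — strong enough planting to
    make recovery expected, weak enough that the background is not trivial.
    """

    n_genes: int = 500
    n_mutated: int = 300
    mutation_count_law: float = 0.3  # geometric p; smaller = heavier tail
    frac_orf: float = 0.8
    n_precog_sig: int = 40
    z_law: float = 1.0  # SD of background Meta-Z
    background_degree: float = 3.0
    n_hubs: int = 3
    hub_degree: int = 25
    seed: int = 0
    cancer: str = "SIM"

    def __post_init__(self):
        if self.n_mutated > self.n_genes:
            raise ConfigError("n_mutated cannot exceed n_genes")
        if self.n_hubs > self.n_genes:
            raise ConfigError("n_hubs cannot exceed n_genes")
        if self.hub_degree > self.n_mutated:
            raise ConfigError("hub_degree cannot exceed n_mutated (infeasible wiring)")
        if self.n_hubs and self.hub_degree < 1:
            raise ConfigError("hub_degree must be >= 1")
        for name in ("mutation_count_law", "frac_orf"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0,1), got {v}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, keyed by gene symbol."""

    hub_genes: set[str]
    planted_T: dict[str, int]
    planted_M: dict[str, int]
    location_class: dict[str, str]
    meta_z: dict[str, float]
    mutated_genes: set[str]
    config: SimConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hub_genes": sorted(self.hub_genes),
            "planted_T": self.planted_T,
            "planted_M": self.planted_M,
            "location_class": self.location_class,
            "meta_z": self.meta_z,
            "mutated_genes": sorted(self.mutated_genes),
            "config": asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            hub_genes=set(d["hub_genes"]),
            planted_T=d["planted_T"],
            planted_M=d["planted_M"],
            location_class=d["location_class"],
            meta_z=d["meta_z"],
            mutated_genes=set(d["mutated_genes"]),
            config=SimConfig(**d["config"]),
        )


@dataclass
class CohortPaths:
    mutations: Path
    precog: Path
    interactome: Path
    truth: Path


def _gene_symbols(n: int) -> list[str]:
    # synthetic symbols guarantee no collision with real gene lists
    return [f"G{i + 1:06d}" for i in range(n)]


def _er_pairs(n: int, p: float, rng: np.random.Generator):
    """Erdős–Rényi G(n, p) edge sampling by geometric gap skipping.

    O(expected edges) time and memory; pairs are indexed in upper-triangular
    row-major order and decoded on the fly.
    """
    if p <= 0 or n < 2:
        return
    n_pairs = n * (n - 1) // 2
    if p >= 1:
        for t in range(n_pairs):
            yield _pair_from_index(t, n)
        return
    lnq = math.log1p(-p)
    t = -1
    while True:
        gap = int(math.log(1.0 - rng.random()) / lnq)
        t += 1 + gap
        if t >= n_pairs:
            return
        yield _pair_from_index(t, n)


def _pair_from_index(t: int, n: int) -> tuple[int, int]:
    # row i is the largest with i*(2n-i-1)/2 <= t
    i = int(((2 * n - 1) - math.sqrt((2 * n - 1) ** 2 - 8 * t)) / 2)
    off = i * (2 * n - i - 1) // 2
    if off > t:  # guard float rounding at row boundaries
        i -= 1
        off = i * (2 * n - i - 1) // 2
    j = i + 1 + (t - off)
    return i, j


def generate_cohort(
    config: SimConfig, out_dir: str | Path
) -> tuple[CohortPaths, SyntheticTruth]:
    """Write the three synthetic input files plus truth JSON into *out_dir*.

    Sub-streams of the RNG are derived deterministically per file, so the
    same seed always yields byte-identical output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = _gene_symbols(config.n_genes)

    rng_mut = np.random.default_rng([config.seed, 1])
    rng_z = np.random.default_rng([config.seed, 2])
    rng_net = np.random.default_rng([config.seed, 3])

    # --- mutation table -----------------------------------------------------
    mutated_idx = sorted(
        rng_mut.choice(config.n_genes, size=config.n_mutated, replace=False)
    )
    mutated = [genes[i] for i in mutated_idx]
    counts = rng_mut.geometric(config.mutation_count_law, size=config.n_mutated)
    mut_lines = ["Hugo_Symbol\tVariant_Classification"]
    orf_counts: dict[str, int] = {}
    non_orf_counts: dict[str, int] = {}
    for gene, c in zip(mutated, counts):
        is_orf = rng_mut.random(int(c)) < config.frac_orf
        orf_counts[gene] = int(is_orf.sum())
        non_orf_counts[gene] = int(c) - orf_counts[gene]
        for flag in is_orf:
            pool = _ORF_LABELS if flag else _NON_ORF_LABELS
            label = pool[int(rng_mut.integers(len(pool)))]
            mut_lines.append(f"{gene}\t{label}")
    mut_path = out_dir / "mutations.tsv"
    mut_path.write_text("\n".join(mut_lines) + "\n", encoding="utf-8", newline="\n")

    # --- Meta-Z table -------------------------------------------------------
    z = rng_z.normal(0.0, config.z_law, size=config.n_genes)
    sig_idx = rng_z.choice(config.n_genes, size=config.n_precog_sig, replace=False)
    half = config.n_precog_sig // 2
    for j, gi in enumerate(sig_idx):
        lo, hi = (2.58, 4.0) if j < half else (1.96, 2.58)
        z[gi] = rng_z.uniform(lo, hi) * (1 if rng_z.random() < 0.5 else -1)

    # --- interactome: ER background + planted hubs --------------------------
    unmutated = [g for g in genes if g not in set(mutated)]
    hub_pool = unmutated if len(unmutated) >= config.n_hubs else genes
    hubs = sorted(
        hub_pool[i]
        for i in rng_net.choice(len(hub_pool), size=config.n_hubs, replace=False)
    )
    gene_idx = {g: i for i, g in enumerate(genes)}
    for h in hubs:  # strong survival signal so each hub survives as a seed
        z[gene_idx[h]] = rng_net.uniform(2.7, 4.0) * (
            1 if rng_net.random() < 0.5 else -1
        )

    edges: set[tuple[str, str]] = set()
    p_edge = min(1.0, config.background_degree / max(1, config.n_genes - 1))
    for i, j in _er_pairs(config.n_genes, p_edge, rng_net):
        edges.add((genes[i], genes[j]))
    for h in hubs:
        pool = [g for g in mutated if g != h]
        targets = [pool[i] for i in rng_net.choice(len(pool), size=config.hub_degree,
                                                   replace=False)]
        for t in targets:
            edges.add(tuple(sorted((h, t))))

    net_path = out_dir / "interactome.tab3.tsv"
    header = (
        "BioGRID Interaction ID\tOfficial Symbol Interactor A\t"
        "Official Symbol Interactor B\tExperimental System Type"
    )
    net_lines = [header]
    for eid, (a, b) in enumerate(sorted(edges), start=1):
        net_lines.append(f"{eid}\t{a}\t{b}\tphysical")
    net_path.write_text("\n".join(net_lines) + "\n", encoding="utf-8", newline="\n")

    precog_path = out_dir / "precog.tsv"
    z_lines = [f"Gene\t{config.cancer}"]
    z_lines += [f"{g}\t{z[i]:.6f}" for i, g in enumerate(genes)]
    precog_path.write_text("\n".join(z_lines) + "\n", encoding="utf-8", newline="\n")

    # --- ground truth -------------------------------------------------------
    mutated_set = set(mutated)
    neigh: dict[str, set[str]] = {g: set() for g in genes}
    for a, b in edges:
        neigh[a].add(b)
        neigh[b].add(a)
    truth = SyntheticTruth(
        hub_genes=set(hubs),
        planted_T={g: len(neigh[g]) for g in genes},
        planted_M={g: sum(1 for x in neigh[g] if x in mutated_set) for g in genes},
        location_class={
            g: classify_location(orf_counts.get(g, 0), non_orf_counts.get(g, 0)).value
            for g in genes
        },
        meta_z={g: float(f"{z[i]:.6f}") for i, g in enumerate(genes)},
        mutated_genes=mutated_set,
        config=config,
    )
    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)
    return CohortPaths(mut_path, precog_path, net_path, truth_path), truth


@dataclass
class RecoveryReport:
    """Planted-hub recovery of one pipeline run."""

    recovered: float  # fraction of planted hubs with seed rank <= top_k
    hub_ranks: dict[str, int | None] = field(default_factory=dict)


def recovery_report(
    truth: SyntheticTruth, result: CancerResult, top_k: int
) -> RecoveryReport:
    """Fraction of planted hubs ranked within the top *top_k* seeds.

    A cohort with no planted hubs reports 1.0 (vacuous success) with empty
    detail. Raises if the result does not come from the matching cohort.
    """
    result_genes = {sg.gene for sg in result.all_genes}
    known = set(truth.planted_T)
    if result_genes - known:
        raise ConsistencyError(
            "result contains genes absent from the synthetic truth: "
            f"{sorted(result_genes - known)[:5]}"
        )
    if not truth.hub_genes:
        return RecoveryReport(1.0, {})
    seed_rank = {sg.gene: sg.rank for sg in result.seeds}
    ranks = {h: seed_rank.get(h) for h in sorted(truth.hub_genes)}
    hit = sum(1 for r in ranks.values() if r is not None and r <= top_k)
    return RecoveryReport(hit / len(truth.hub_genes), ranks)
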
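"""End-to-end orchestration: read → classify → filter → score → write.

One :class:`RunConfig` describes a multi-cancer run; every threshold and
decision is recorded in a machine-readable run-metadata JSON written next to
the outputs, including per-cancer md/min statistics and gene counts at each
stage boundary (so no silent drops can occur unnoticed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import GeneMutationProfile, build_gene_profiles
from .crosscancer import (
    build_score_matrix,
    external_overlap,
    detect_outliers,
    shared_hubs,
)
from .errors import ConfigError, FormatError
from .filters import (
    Cluster,
    FilterThresholds,
    GeneStatus,
    GeneType,
    PrecogLabel,
    filter_genes,
    mutation_stats,
)
from .io import (
    ColumnConfig,
    Interactome,
    UnknownPolicy,
    VariantMap,
    _file_sha256,
    read_biogrid_tab3,
    read_gene_list,
    read_mutation_table,
    read_precog_table,
    read_results_tsv,
    write_results,
)
from .scoring import CancerResult, ScoredGene, score_and_rank

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, column names, thresholds and switches for one pipeline run.

    ``mutation_tables`` maps cancer id → mutation TSV path; the Meta-Z
    column read from ``precog_table`` for each cancer is the cancer id.
    ``mutated_reference`` selects the mutated gene set the score counts
    against: ``filtered`` (retained genes with at least one mutation) or
    ``raw`` (every gene in the mutation table).
    """

    mutation_tables: dict[str, Path] = field(default_factory=dict)
    precog_table: Path | None = None
    interactome: Path | None = None
    out_dir: Path = Path("hubscore_out")
    gene_column: str = "Hugo_Symbol"
    variant_column: str = "Variant_Classification"
    precog_gene_column: str = "Gene"
    unknown_policy: str = "error"
    orf_labels: list[str] | None = None
    non_orf_labels: list[str] | None = None
    z_sig: float = 1.96
    z_strong: float = 2.58
    non_orf_no_effect_mult: float = 3.0
    both_no_effect_mult: float = 3.0
    mutated_reference: str = "filtered"
    score_mode: str = "literal"
    outlier_k_sd: float = 1.96
    top_n: int = 50
    shared_k: int = 3
    formats: list[str] = field(default_factory=lambda: ["tsv", "json"])

    def variant_map(self) -> VariantMap:
        kwargs = {"unknown_policy": UnknownPolicy(self.unknown_policy)}
        if self.orf_labels is not None:
            kwargs["orf_labels"] = frozenset(self.orf_labels)
        if self.non_orf_labels is not None:
            kwargs["non_orf_labels"] = frozenset(self.non_orf_labels)
        return VariantMap(**kwargs)

    def column_config(self) -> ColumnConfig:
        return ColumnConfig(self.gene_column, self.variant_column)

    def base_thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            z_sig=self.z_sig,
            z_strong=self.z_strong,
            non_orf_no_effect_mult=self.non_orf_no_effect_mult,
            both_no_effect_mult=self.both_no_effect_mult,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat YAML config; keyword *overrides* (CLI flags) win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.mutation_tables = {c: Path(p) for c, p in cfg.mutation_tables.items()}
        if cfg.precog_table:
            cfg.precog_table = Path(cfg.precog_table)
        if cfg.interactome:
            cfg.interactome = Path(cfg.interactome)
        cfg.out_dir = Path(cfg.out_dir)
        return cfg

    def validate(self) -> None:
        if not self.mutation_tables:
            raise ConfigError("no mutation tables configured")
        if self.precog_table is None or self.interactome is None:
            raise ConfigError("precog_table and interactome paths are required")
        for p in [self.precog_table, self.interactome, *self.mutation_tables.values()]:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if self.mutated_reference not in ("filtered", "raw"):
            raise ConfigError("mutated_reference must be 'filtered' or 'raw'")


def run_single_cancer(
    cancer: str,
    records,
    precog,
    interactome: Interactome,
    thresholds: FilterThresholds,
    mutated_reference: str = "filtered",
) -> tuple[CancerResult, dict]:
    """Classify, filter and score one cancer; returns result + stage counts."""
    precog_genes = {r.gene for r in precog}
    profiles = build_gene_profiles(records, universe=precog_genes, cancer=cancer)
    statuses = filter_genes(profiles, precog, thresholds)
    retained = [s for s in statuses if s.retained]
    raw_mutated = {p.gene for p in profiles.values() if p.total_count > 0}
    if mutated_reference == "filtered":
        mutated_set = {s.gene for s in retained if s.profile.total_count > 0}
    else:
        mutated_set = raw_mutated
    # filter_genes computed md/min internally; mirror them here for metadata
    eff_th = thresholds
    mut_profiles = [p for p in profiles.values() if p.total_count > 0]
    if mut_profiles and thresholds.md == 0 and thresholds.min_ == 0:
        md, min_ = mutation_stats(mut_profiles)
        eff_th = replace(thresholds, md=md, min_=min_)
    result = score_and_rank(retained, interactome, mutated_set, eff_th)
    counts = {
        "mutation_records": len(records),
        "mutated_genes": len(raw_mutated),
        "precog_genes": len(precog_genes),
        "evaluated_genes": len(statuses),
        "retained_genes": len(retained),
        "seeds": len(result.seeds),
        "interactors": len(result.interactors),
        "mutated_reference_size": len(mutated_set),
        "md": eff_th.md,
        "min": eff_th.min_,
    }
    assert counts["seeds"] + counts["interactors"] == counts["retained_genes"]
    return result, counts


def run_pipeline(config: RunConfig) -> dict[str, CancerResult]:
    """Execute all stages for every configured cancer and write outputs."""
    config.validate()
    vmap = config.variant_map()
    cols = config.column_config()
    interactome = read_biogrid_tab3(config.interactome)
    results: dict[str, CancerResult] = {}
    metadata = {
        "tool": "hubscore",
        "version": __version__,
        "mutated_reference": config.mutated_reference,
        "score_mode": config.score_mode,
        "z_sig": config.z_sig,
        "z_strong": config.z_strong,
        "input_checksums": {
            "precog": _file_sha256(config.precog_table),
            "interactome": _file_sha256(config.interactome),
        },
        "cancers": {},
    }
    for cancer, mut_path in sorted(config.mutation_tables.items()):
        logger.info("stage read: %s", cancer)
        records = read_mutation_table(mut_path, cancer, vmap, cols)
        precog = read_precog_table(
            config.precog_table, cancer, config.precog_gene_column
        )
        result, counts = run_single_cancer(
            cancer, records, precog, interactome,
            config.base_thresholds(), config.mutated_reference,
        )
        results[cancer] = result
        out_sub = Path(config.out_dir) / cancer
        write_results(result, out_sub, config.formats, metadata={"counts": counts})
        metadata["cancers"][cancer] = {
            "mutation_table": str(mut_path),
            "mutation_checksum": _file_sha256(mut_path),
            "counts": counts,
        }
        logger.info("stage write: %s (%d seeds, %d interactors)",
                    cancer, counts["seeds"], counts["interactors"])
    meta_path = Path(config.out_dir) / "run_metadata.json"
    meta_path.parent.mkdir(parents=True, exist_ok=True)
    meta_path.write_text(json.dumps(metadata, indent=1, sort_keys=True) + "\n",
                         encoding="utf-8")
    return results


def load_result_dir(path: str | Path) -> CancerResult:
    """Rebuild a :class:`CancerResult` from the TSV files of one run subdir."""
    path = Path(path)
    cancer = path.name
    lists: dict[str, list[ScoredGene]] = {"seeds": [], "interactors": []}
    for name in lists:
        tsv = path / f"{cancer}_{name}.tsv"
        if not tsv.exists():
            raise FormatError(f"missing result file {tsv}")
        df = read_results_tsv(tsv)
        for row in df.itertuples(index=False):
            meta_z = None if pd.isna(row.meta_z) else float(row.meta_z)
            orf = int(row.mutation_count) if row.location_class == "ORF" else 0
            non = int(row.mutation_count) - orf
            profile = GeneMutationProfile(str(row.gene), cancer, orf, non)
            status = GeneStatus(
                gene=str(row.gene),
                cancer=cancer,
                profile=profile,
                meta_z=meta_z,
                precog_label=PrecogLabel(row.precog_label),
                retained=True,
                cluster=Cluster(row.cluster),
                gene_type=GeneType(row.gene_type),
            )
            lists[name].append(
                ScoredGene(status, int(row.total_interactors),
                           int(row.mutated_interactors),
                           float(row.network_score), int(row.rank))
            )
    return CancerResult(cancer, lists["seeds"], lists["interactors"],
                        FilterThresholds())


def compare_results(
    result_dirs: list[str | Path],
    out_dir: str | Path,
    n: int = 50,
    k: int = 3,
    gene_type: str = "seed",
    external_lists: dict[str, str | Path] | None = None,
    outlier_k_sd: float = 1.96,
) -> dict[str, Path]:
    """Cross-cancer analytics over previously written result directories.

    Writes the shared-hub table, the min-max normalized score matrix and
    (when external gene lists are given) an outlier-overlap report.
    """
    results = [load_result_dir(d) for d in result_dirs]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    table = shared_hubs(results, n=n, k=k, gene_type=gene_type)
    p = out_dir / "shared_hubs.tsv"
    table.to_frame().to_csv(p, sep="\t", index=False, lineterminator="\n")
    written["shared_hubs"] = p

    matrix = build_score_matrix(results, gene_type="both", normalize=True)
    p = out_dir / "score_matrix_normalized.tsv"
    matrix.to_frame().to_csv(p, sep="\t", index_label="gene", lineterminator="\n")
    written["score_matrix"] = p

    if external_lists:
        rows = []
        for res in results:
            outliers = detect_outliers(res, k_sd=outlier_k_sd, gene_type="both")
            for name, lp in sorted(external_lists.items()):
                ext = read_gene_list(lp)
                inter, pct = external_overlap(outliers, ext)
                rows.append({
                    "cancer": res.cancer, "external_list": name,
                    "n_external": len(ext), "n_overlap": len(inter),
                    "pct_external_covered": round(pct, 2),
                    "overlap_genes": ",".join(sorted(inter)),
                })
        p = out_dir / "external_overlap.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False, lineterminator="\n")
        written["external_overlap"] = p
    return written
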
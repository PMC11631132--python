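"""Readers and writers for the three tabular input formats and ranked outputs.

Inputs are plain tab-separated text:

* a MAF-like mutation table (one row per mutation event; gene-symbol and
  variant-classification columns, names configurable);
* a Precog Meta-Z table (``Gene`` column plus one numeric column per cancer
  type, holding survival meta-analysis Z-scores);
* a protein-protein interaction table in BioGRID TAB3 dialect (official gene
  symbol columns for the two interactors).

Everything downstream consumes only the in-memory types defined here.
Gene symbols are uppercased and whitespace-stripped at ingest; no alias or
identifier mapping is attempted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import networkx as nx
import pandas as pd

from .errors import FormatError, ParseError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .scoring import CancerResult

logger = logging.getLogger(__name__)

#: Output columns written for every ranked gene, in order.
RESULT_COLUMNS = [
    "gene",
    "gene_type",
    "cluster",
    "precog_label",
    "meta_z",
    "mutation_count",
    "location_class",
    "total_interactors",
    "mutated_interactors",
    "network_score",
    "rank",
]


class Region(str, Enum):
    """Where a mutation falls relative to the open reading frame."""

    ORF = "ORF"
    NON_ORF = "NON_ORF"


class UnknownPolicy(str, Enum):
    """What to do with a variant-classification label absent from the map."""

    ERROR = "error"
    SKIP = "skip"
    NON_ORF = "non_orf"


#: Variant-classification labels treated as coding-sequence (ORF) events.
#: Silent/synonymous changes are deliberately ORF: synonymous mutations can
#: still affect transcript stability and are treated as potentially functional.
DEFAULT_ORF_LABELS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Silent",
        "Synonymous",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)

#: Labels treated as non-coding (NON_ORF) events.
DEFAULT_NON_ORF_LABELS = frozenset(
    {
        "3'UTR",
        "5'UTR",
        "Intron",
        "5'Flank",
        "3'Flank",
        "IGR",
        "RNA",
        "Splice_Site",
        "Splice_Region",
    }
)


@dataclass(frozen=True)
class VariantMap:
    """Case-insensitive mapping from variant-classification labels to regions.

    ``orf_labels`` and ``non_orf_labels`` must be disjoint (checked after
    case folding). ``unknown_policy`` controls rows whose label matches
    neither set: fail, drop the row, or treat it as non-coding.
    """

    orf_labels: frozenset[str] = DEFAULT_ORF_LABELS
    non_orf_labels: frozenset[str] = DEFAULT_NON_ORF_LABELS
    unknown_policy: UnknownPolicy = UnknownPolicy.ERROR

    def __post_init__(self):
        orf = {s.upper() for s in self.orf_labels}
        non = {s.upper() for s in self.non_orf_labels}
        if orf & non:
            raise ValueError(f"labels in both ORF and NON_ORF sets: {sorted(orf & non)}")
        object.__setattr__(self, "_orf_upper", orf)
        object.__setattr__(self, "_non_orf_upper", non)

    def resolve(self, label: str) -> Region | None:
        """Return the region for *label*, or ``None`` if unmapped."""
        up = label.strip().upper()
        if up in self._orf_upper:
            return Region.ORF
        if up in self._non_orf_upper:
            return Region.NON_ORF
        return None


@dataclass(frozen=True)
class MutationRecord:
    """One mutation event: gene symbol, harmonized region, original label."""

    gene: str
    region: Region
    raw_label: str
    cancer: str


@dataclass(frozen=True)
class PrecogRecord:
    """A gene's Precog Meta-Z score in one cancer type (unitless)."""

    gene: str
    cancer: str
    meta_z: float


@dataclass
class Interactome:
    """Undirected, symbol-keyed protein-protein interaction graph.

    Backed by a :class:`networkx.Graph`; self-loops are never stored and
    unordered duplicate edges collapse to one.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_edge(self, a: str, b: str) -> None:
        a, b = a.strip().upper(), b.strip().upper()
        if a and b and a != b:
            self.graph.add_edge(a, b)

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0

    def neighbours(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene)) if gene in self.graph else set()


@dataclass(frozen=True)
class ColumnConfig:
    """Column names of the MAF-like mutation table."""

    gene: str = "Hugo_Symbol"
    variant: str = "Variant_Classification"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kwargs)


def read_mutation_table(
    path: str | Path,
    cancer: str,
    variant_map: VariantMap | None = None,
    column_config: ColumnConfig | None = None,
) -> list[MutationRecord]:
    """Read a MAF-like mutation table into :class:`MutationRecord` objects.

    One record is emitted per input row, in row order. Gene symbols are
    uppercased and stripped; variant labels are resolved through
    *variant_map* and unresolved labels are handled per its policy.
    """
    variant_map = variant_map or VariantMap()
    cols = column_config or ColumnConfig()
    df = _read_tsv(path)
    for col in (cols.gene, cols.variant):
        if col not in df.columns:
            raise FormatError(f"column {col!r} missing from {path} header")
    records: list[MutationRecord] = []
    for i, (gene, label) in enumerate(zip(df[cols.gene], df[cols.variant])):
        region = variant_map.resolve(label)
        if region is None:
            if variant_map.unknown_policy is UnknownPolicy.ERROR:
                # +2: 1-based and header line
                raise ParseError(f"unknown variant label {label!r}", line=i + 2)
            if variant_map.unknown_policy is UnknownPolicy.SKIP:
                continue
            region = Region.NON_ORF
        sym = str(gene).strip().upper()
        if not sym:
            raise ParseError("empty gene symbol", line=i + 2)
        records.append(MutationRecord(sym, region, str(label), cancer))
    return records


def read_precog_table(
    path: str | Path,
    cancer_column: str,
    gene_column: str = "Gene",
) -> list[PrecogRecord]:
    """Read one cancer's Meta-Z column from a Precog-style table.

    Non-numeric or empty cells are skipped (count logged). Duplicate gene
    symbols keep the entry with the largest ``|meta_z|`` so a significance
    call in either direction is preserved.
    """
    df = _read_tsv(path)
    if gene_column not in df.columns:
        raise FormatError(f"gene column {gene_column!r} missing from {path} header")
    if cancer_column not in df.columns:
        raise FormatError(f"cancer column {cancer_column!r} missing from {path} header")
    z = pd.to_numeric(df[cancer_column], errors="coerce")
    n_bad = int(z.isna().sum())
    if n_bad:
        logger.info("read_precog_table: skipped %d non-numeric cells in %s", n_bad, path)
    best: dict[str, float] = {}
    for gene, val in zip(df[gene_column], z):
        if pd.isna(val):
            continue
        sym = str(gene).strip().upper()
        if not sym:
            continue
        if sym not in best or abs(val) > abs(best[sym]):
            best[sym] = float(val)
    if not best:
        raise FormatError(f"no parsable rows in {path} column {cancer_column!r}")
    return [PrecogRecord(g, cancer_column, v) for g, v in best.items()]


#: Default official-symbol column names of the BioGRID TAB3 dialect.
TAB3_SYMBOL_COLUMNS = (
    "Official Symbol Interactor A",
    "Official Symbol Interactor B",
)


def read_biogrid_tab3(
    path: str | Path,
    symbol_columns: tuple[str, str] = TAB3_SYMBOL_COLUMNS,
) -> Interactome:
    """Load a BioGRID TAB3 interaction table as an undirected graph.

    Self-interactions are dropped; duplicated pairs (either orientation,
    repeated evidence lines) collapse to a single edge; symbols uppercase.
    """
    col_a, col_b = symbol_columns
    df = _read_tsv(path)
    for col in (col_a, col_b):
        if col not in df.columns:
            raise FormatError(f"column {col!r} missing from {path} header")
    net = Interactome()
    for a, b in zip(df[col_a], df[col_b]):
        net.add_edge(str(a), str(b))
    if net.n_edges == 0:
        logger.warning("read_biogrid_tab3: empty edge set after filtering %s", path)
    return net


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list (one symbol per line, ``#`` comments)."""
    symbols: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.add(line.upper())
    return symbols


def _file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _result_rows(scored: Iterable) -> list[dict]:
    rows = []
    for sg in scored:
        st = sg.status
        rows.append(
            {
                "gene": st.gene,
                "gene_type": st.gene_type.value,
                "cluster": st.cluster.value,
                "precog_label": st.precog_label.value,
                "meta_z": "" if st.meta_z is None else repr(st.meta_z),
                "mutation_count": st.profile.total_count,
                "location_class": st.profile.location_class.value,
                "total_interactors": sg.total_interactors,
                "mutated_interactors": sg.mutated_interactors,
                "network_score": repr(sg.network_score),
                "rank": sg.rank,
            }
        )
    return rows


def write_results(
    result: "CancerResult",
    out_dir: str | Path,
    formats: Iterable[str] = ("tsv",),
    metadata: dict | None = None,
) -> list[Path]:
    """Write one seed file and one interactor file per requested format.

    TSV uses '.' decimals, UTF-8 and LF line endings for reproducible diffs;
    JSON mirrors the same records under a run-metadata header.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    formats = set(formats)
    unknown = formats - {"tsv", "json"}
    if unknown:
        raise ValueError(f"unknown output formats: {sorted(unknown)}")
    written: list[Path] = []
    lists = {"seeds": result.seeds, "interactors": result.interactors}
    meta = {
        "cancer": result.cancer,
        "z_sig": result.thresholds.z_sig,
        "z_strong": result.thresholds.z_strong,
        "md": result.thresholds.md,
        "min": result.thresholds.min_,
        **(metadata or {}),
    }
    for name, scored in lists.items():
        rows = _result_rows(scored)
        if "tsv" in formats:
            p = out_dir / f"{result.cancer}_{name}.tsv"
            lines = ["\t".join(RESULT_COLUMNS)]
            lines += ["\t".join(str(r[c]) for c in RESULT_COLUMNS) for r in rows]
            p.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
            written.append(p)
        if "json" in formats:
            p = out_dir / f"{result.cancer}_{name}.json"
            p.write_text(
                json.dumps({"metadata": meta, "genes": rows}, indent=1) + "\n",
                encoding="utf-8",
            )
            written.append(p)
    return written


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    """Re-read a ranked-result TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path} lacks result columns {sorted(missing)}")
    return df
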
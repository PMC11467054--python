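"""pgsrank: trait-specific variant and gene rank databases from PGS Catalog scoring files.

Workflow: parse a trait's harmonized scoring files (``pgs_io``), merge them
under canonical variant keys (``harmonize``), aggregate per-score Dowdall
reciprocal ranks into mean reciprocal ranks (``rank_aggregate``), roll
variant scores up to genes via an annotation table (``annotate``),
summarize the weight distribution (``trait_stats``), and materialize
everything into a queryable SQLite file (``rankdb``).  ``synthetic_fixtures``
generates seeded test corpora with known ground truth and
``catalog_client`` optionally discovers and downloads real scoring files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from .annotate import GeneRankRecord, gene_scores, write_gene_table
from .catalog_client import CatalogClient, CatalogError, CatalogQuery
from .harmonize import (
    MergedRow,
    MergeError,
    TraitDataset,
    UnkeyableRecordError,
    merge_trait_files,
    normalize_chrom,
    normalize_rsid,
    variant_key,
)
from .pgs_io import (
    AnnotationTableError,
    EmptyScoringFileError,
    ScoringFile,
    ScoringFileError,
    ScoringRecord,
    load_annotation_table,
    parse_scoring_file,
    write_scoring_file,
)
from .rank_aggregate import (
    RankEntry,
    VariantRankRecord,
    aggregate_mrr,
    aggregate_mrr_present_only,
    rank_within_pgs,
    write_rank_table,
)
from .rankdb import (
    RankDatabase,
    RankDatabaseError,
    UnknownTraitError,
    build_db,
)
from .synthetic_fixtures import FixtureSpec, generate_corpus, oracle_mrr
from .trait_stats import NoWeightsError, SummaryStats, trait_summary

__version__ = "0.1.0"

__all__ = [
    "AnnotationTableError",
    "CatalogClient",
    "CatalogError",
    "CatalogQuery",
    "EmptyScoringFileError",
    "FixtureSpec",
    "GeneRankRecord",
    "MergeError",
    "MergedRow",
    "NoWeightsError",
    "RankDatabase",
    "RankDatabaseError",
    "RankEntry",
    "ScoringFile",
    "ScoringFileError",
    "ScoringRecord",
    "SummaryStats",
    "TraitDataset",
    "UnkeyableRecordError",
    "UnknownTraitError",
    "VariantRankRecord",
    "aggregate_mrr",
    "aggregate_mrr_present_only",
    "build_db",
    "build_trait_database",
    "gene_scores",
    "generate_corpus",
    "load_annotation_table",
    "merge_trait_files",
    "normalize_chrom",
    "normalize_rsid",
    "oracle_mrr",
    "parse_scoring_file",
    "rank_within_pgs",
    "trait_summary",
    "variant_key",
    "write_gene_table",
    "write_rank_table",
    "write_scoring_file",
]


def build_trait_database(
    trait_files: Mapping[str, Sequence[str | Path]],
    out_path: str | Path,
    annotations: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    overwrite: bool = False,
) -> RankDatabase:
    """End-to-end build: scoring-file paths per trait → rank database file.

    ``trait_files`` maps each trait name to the paths of its scoring files.
    If ``annotations`` (a variant-key → gene assignments mapping) is given,
    gene rollups are materialized as well.
    """
    datasets: list[TraitDataset] = []
    ranks: list[VariantRankRecord] = []
    genes: list[GeneRankRecord] = []
    summaries: list[SummaryStats] = []
    for trait, paths in trait_files.items():
        ds = merge_trait_files(trait, [parse_scoring_file(p) for p in paths])
        datasets.append(ds)
        trait_ranks = aggregate_mrr(ds)
        ranks.extend(trait_ranks)
        if annotations:
            genes.extend(gene_scores(trait_ranks, annotations))
        summaries.append(trait_summary(ds))
    return build_db(
        datasets, ranks, genes, summaries, path=out_path, overwrite=overwrite
    )
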
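"""Gene-level rollup of variant MRR scores.

A gene's score is the maximum MRR among its annotated variants: a gene is
prioritized by its best variant, which keeps the score in [0, 1] and avoids
the long-gene bias a sum would introduce.  Variants without an annotation
contribute to no gene (their count is logged); a variant annotated to
several genes contributes to all of them.  Gene symbols are unique in the
output by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .rank_aggregate import VariantRankRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRankRecord:
    """Gene-level rollup: best member-variant MRR and provenance."""

    trait: str
    gene: str
    score: float
    n_variants: int
    best_variant: str


def gene_scores(
    ranks: Sequence[VariantRankRecord],
    ann: Mapping[str, Sequence[tuple[str, str]]],
) -> list[GeneRankRecord]:
    """Roll variant MRRs up to genes via an annotation mapping.

    ``ann`` maps variant keys to ``(gene, functional_category)`` pairs, as
    produced by :func:`pgsrank.pgs_io.load_annotation_table`.  All ranks
    must share one trait.  Output is sorted by score descending, gene
    ascending.
    """
    traits = {r.trait for r in ranks}
    if len(traits) > 1:
        raise ValueError(f"rank records span multiple traits: {sorted(traits)}")
    if not ann:
        logger.warning("empty annotation mapping: no gene scores produced")
        return []
    trait = next(iter(traits)) if traits else ""

    best: dict[str, tuple[float, str]] = {}
    n_variants: dict[str, int] = {}
    n_skipped = 0
    for r in ranks:
        assignments = ann.get(r.variant_key)
        if not assignments:
            n_skipped += 1
            continue
        for gene, _func in assignments:
            n_variants[gene] = n_variants.get(gene, 0) + 1
            incumbent = best.get(gene)
            if (
                incumbent is None
                or r.mrr > incumbent[0]
                or (r.mrr == incumbent[0] and r.variant_key < incumbent[1])
            ):
                best[gene] = (r.mrr, r.variant_key)
    if n_skipped:
        logger.info("%d variants without annotation skipped in gene rollup", n_skipped)

    records = [
        GeneRankRecord(
            trait=trait,
            gene=gene,
            score=score,
            n_variants=n_variants[gene],
            best_variant=key,
        )
        for gene, (score, key) in best.items()
    ]
    records.sort(key=lambda g: (-g.score, g.gene))
    return records


def write_gene_table(records: Iterable[GeneRankRecord], path: str | Path) -> None:
    """Export gene ranks as deterministic tab-separated text."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("trait\tgene\tscore\tn_variants\tbest_variant\n")
        for g in records:
            fh.write(f"{g.trait}\t{g.gene}\t{g.score!r}\t{g.n_variants}\t{g.best_variant}\n")
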
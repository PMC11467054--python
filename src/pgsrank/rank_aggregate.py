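"""Dowdall reciprocal-rank aggregation of variant effect weights.

Each polygenic score is treated as one ballot ranking its variants by the
absolute value of their effect weights.  The Dowdall positional rule (a
Borda-family method) gives the variant at position ``i`` a reciprocal rank
(RR) of ``1/i``: the top variant receives 1, the second 1/2, the third 1/3,
and so forth.  A variant's trait-level score is its mean reciprocal rank
(MRR): the sum of its per-score RRs divided by the number of the trait's
scoring files, with files where the variant is absent — or present with a
missing weight — contributing 0.  A variant with no usable weight anywhere
therefore has MRR 0, and MRR 1 is attained only by a variant that is the
unique top-weighted variant in every file.

Ties in |weight| are resolved by sharing: every member of a tied block
receives the mean of ``1/position`` over the block's positions, which keeps
the per-file conservation law Σ RR = H(n) (the n-th harmonic number) exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .harmonize import MergedRow, TraitDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankEntry:
    """A variant's position and reciprocal rank within one scoring file."""

    pgs_id: str
    variant_key: str
    rank: int
    rr: float


@dataclass(frozen=True)
class VariantRankRecord:
    """A variant's aggregated MRR for one trait.

    ``n_present`` counts the trait's files in which the variant carries a
    non-missing weight; ``n_pgs`` is the trait's total file count (the MRR
    denominator).
    """

    trait: str
    variant_key: str
    mrr: float
    n_present: int
    n_pgs: int


def rank_within_pgs(file_rows: Sequence[MergedRow]) -> list[RankEntry]:
    """Dowdall-rank the rows of a single scoring file.

    Rows with missing weight are excluded.  Remaining rows are ordered by
    |weight| descending; a block of tied |weight| shares the mean of
    ``1/position`` over its positions.  Output order is rank ascending with
    ties broken by variant key, which never affects the shared ``rr``.

    An all-missing file yields an empty ranking with a warning: that ballot
    contributes nothing.
    """
    if not file_rows:
        return []
    pgs_ids = {row.pgs_id for row in file_rows}
    if len(pgs_ids) != 1:
        raise ValueError(f"rows span multiple scores: {sorted(pgs_ids)}")
    (pgs_id,) = pgs_ids

    scored = [row for row in file_rows if row.effect_weight is not None]
    if not scored:
        logger.warning("%s: all weights missing; file contributes no ranks", pgs_id)
        return []
    # |weight| descending, key ascending for a deterministic listing order
    scored.sort(key=lambda row: (-abs(row.effect_weight), row.variant_key))

    entries: list[RankEntry] = []
    i = 0
    n = len(scored)
    while i < n:
        j = i
        while j < n and abs(scored[j].effect_weight) == abs(scored[i].effect_weight):
            j += 1
        # positions i+1 .. j share the mean of their reciprocals
        shared_rr = sum(1.0 / p for p in range(i + 1, j + 1)) / (j - i)
        for k in range(i, j):
            entries.append(
                RankEntry(
                    pgs_id=pgs_id,
                    variant_key=scored[k].variant_key,
                    rank=i + 1,
                    rr=shared_rr,
                )
            )
        i = j
    return entries


def aggregate_mrr(ds: TraitDataset) -> list[VariantRankRecord]:
    """Aggregate per-file reciprocal ranks into per-variant MRR records.

    For every distinct variant key in the merged rows::

        MRR = (Σ over the trait's files of the variant's RR, 0 where
               absent or weight-missing) / n_pgs

    Every key yields exactly one record, including keys seen only with
    missing weights (MRR 0).  Records are sorted by MRR descending, then
    variant key ascending, so "top N" queries are reproducible.
    """
    if ds.n_pgs < 1:
        raise ValueError("trait dataset has no scoring files")
    n_pgs = ds.n_pgs

    rows_by_file: dict[str, list[MergedRow]] = {}
    for row in ds.merged_rows:
        rows_by_file.setdefault(row.pgs_id, []).append(row)

    rr_sum: dict[str, float] = {}
    n_present: dict[str, int] = {}
    for row in ds.merged_rows:
        rr_sum.setdefault(row.variant_key, 0.0)
        n_present.setdefault(row.variant_key, 0)
    # accumulate in sorted pgs_id order: MRR is then bitwise identical
    # regardless of the order files were supplied
    for pgs_id in sorted(rows_by_file):
        for entry in rank_within_pgs(rows_by_file[pgs_id]):
            rr_sum[entry.variant_key] += entry.rr
            n_present[entry.variant_key] += 1

    records = [
        VariantRankRecord(
            trait=ds.trait,
            variant_key=key,
            mrr=total / n_pgs,
            n_present=n_present[key],
            n_pgs=n_pgs,
        )
        for key, total in rr_sum.items()
    ]
    records.sort(key=lambda r: (-r.mrr, r.variant_key))
    return records


def aggregate_mrr_present_only(ds: TraitDataset) -> list[VariantRankRecord]:
    """MRR variant averaging only over files where the variant has a weight.

    Offered for comparison with :func:`aggregate_mrr`, whose denominator is
    the trait's total file count.  Variants with no usable weight still
    score 0.  Same output ordering.
    """
    base = aggregate_mrr(ds)
    records = [
        VariantRankRecord(
            trait=r.trait,
            variant_key=r.variant_key,
            mrr=(r.mrr * r.n_pgs / r.n_present) if r.n_present else 0.0,
            n_present=r.n_present,
            n_pgs=r.n_pgs,
        )
        for r in base
    ]
    records.sort(key=lambda r: (-r.mrr, r.variant_key))
    return records


def write_rank_table(records: Iterable[VariantRankRecord], path: str | Path) -> None:
    """Export variant ranks as deterministic tab-separated text."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("trait\tvariant_key\tmrr\tn_present\tn_pgs\n")
        for r in records:
            fh.write(f"{r.trait}\t{r.variant_key}\t{r.mrr!r}\t{r.n_present}\t{r.n_pgs}\n")
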
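"""Canonical variant keys and per-trait merging of scoring files.

Scoring files label the same variant in several ways: a dbSNP rsID
(author-submitted or harmonized), or GRCh38 chromosome/position
coordinates.  Every record is mapped to one canonical key before any
ranking, with the precedence harmonized rsID > raw rsID > harmonized
coordinates > raw coordinates.  Keys of different forms are taken at face
value: an rsID-keyed row and a coordinate-keyed row are never unified even
if they denote the same locus, because that would require an external
rsID↔position map.

Merging concatenates the rows of all of a trait's scoring files (the
bind-rows semantics of the source workflow); each file acts as one ballot
in the downstream rank aggregation, so within a single file a variant may
occupy only one position — duplicate keys inside one file are collapsed to
the occurrence with the largest absolute weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .pgs_io import ScoringFile, ScoringRecord

logger = logging.getLogger(__name__)


class UnkeyableRecordError(ValueError):
    """A record carries no usable variant identifier."""


class MergeError(ValueError):
    """The set of files offered for merging is inconsistent."""


class MergedRow(NamedTuple):
    """One (ballot, candidate, weight) row of a merged trait dataset."""

    pgs_id: str
    variant_key: str
    effect_weight: float | None


def normalize_rsid(rsid: str) -> str:
    """Lower-case an rsID and enforce the ``rs`` prefix (``"123"`` → ``"rs123"``)."""
    s = rsid.strip().lower()
    return s if s.startswith("rs") else "rs" + s


def normalize_chrom(chrom: str) -> str:
    """Strip any ``chr`` prefix and upper-case X/Y/MT labels."""
    s = chrom.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper()


def variant_key(r: ScoringRecord) -> str:
    """Canonical key for a record.

    Precedence: ``hm_rsid`` > ``rsid`` > ``hm_chr:hm_pos`` > ``chr:pos``.
    Deterministic: equal inputs yield equal keys.
    """
    if r.hm_rsid is not None:
        return normalize_rsid(r.hm_rsid)
    if r.rsid is not None:
        return normalize_rsid(r.rsid)
    if r.hm_chr is not None and r.hm_pos is not None:
        return f"{normalize_chrom(r.hm_chr)}:{r.hm_pos}"
    if r.chr is not None and r.pos is not None:
        return f"{normalize_chrom(r.chr)}:{r.pos}"
    raise UnkeyableRecordError("record has no rsID and no complete chr:pos pair")


@dataclass
class TraitDataset:
    """All scoring files mapped to one trait, plus their merged row set."""

    trait: str
    files: list[ScoringFile]
    merged_rows: list[MergedRow] = field(default_factory=list)

    @property
    def n_pgs(self) -> int:
        return len({f.pgs_id for f in self.files})

    def rows_for(self, pgs_id: str) -> list[MergedRow]:
        return [row for row in self.merged_rows if row.pgs_id == pgs_id]


def _dedup_file_rows(sf: ScoringFile) -> list[MergedRow]:
    """One row per distinct key: keep the max-|weight| occurrence.

    A non-missing weight always beats a missing one; among equal |weight|
    the earliest occurrence is kept.  Each file is one ballot, so a variant
    may hold only one position on it.
    """
    best: dict[str, MergedRow] = {}
    order: list[str] = []
    n_dropped = 0
    for record in sf.records:
        key = variant_key(record)
        w = record.effect_weight
        if key not in best:
            best[key] = MergedRow(sf.pgs_id, key, w)
            order.append(key)
            continue
        n_dropped += 1
        incumbent = best[key].effect_weight
        if w is None:
            continue
        if incumbent is None or abs(w) > abs(incumbent):
            best[key] = MergedRow(sf.pgs_id, key, w)
    if n_dropped:
        logger.warning(
            "%s: %d duplicate variant rows within file collapsed (kept max |weight|)",
            sf.pgs_id,
            n_dropped,
        )
    return [best[key] for key in order]


def merge_trait_files(trait: str, files: Iterable[ScoringFile]) -> TraitDataset:
    """Merge one trait's scoring files into a :class:`TraitDataset`.

    Row-concatenation semantics: the union of all files' rows, with no
    deduplication across files (the same key appearing in two files is two
    rows — two ballots scoring the same candidate).  Rows with missing
    weight are retained; they witness a variant's presence but never
    participate in ranking.

    Raises
    ------
    MergeError
        Empty file list, or the same ``pgs_id`` supplied twice (one ballot
        may not be cast twice).
    """
    files = list(files)
    if not files:
        raise MergeError(f"no scoring files supplied for trait {trait!r}")
    seen: set[str] = set()
    for sf in files:
        if sf.pgs_id in seen:
            raise MergeError(f"duplicate pgs_id {sf.pgs_id} for trait {trait!r}")
        seen.add(sf.pgs_id)
    merged: list[MergedRow] = []
    for sf in files:
        merged.extend(_dedup_file_rows(sf))
    return TraitDataset(trait=trait, files=files, merged_rows=merged)
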
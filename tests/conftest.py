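"""Shared fixtures: in-memory scoring files and on-disk minimal corpora."""

from __future__ import annotations

import pytest

from pgsrank import ScoringFile, ScoringRecord


def make_record(key: str, weight: float | None) -> ScoringRecord:
    """A record keyed by ``chr:pos`` coordinates or (default) an rsID."""
    if ":" in key:
        chrom, _, pos = key.partition(":")
        return ScoringRecord(
            effect_allele="A", other_allele="G", chr=chrom, pos=int(pos), effect_weight=weight
        )
    return ScoringRecord(effect_allele="A", other_allele="G", rsid=key, effect_weight=weight)


def make_file(pgs_id: str, rows: dict[str, float | None], trait: str = "test trait") -> ScoringFile:
    return ScoringFile(
        pgs_id=pgs_id,
        records=[make_record(k, w) for k, w in rows.items()],
        trait_label=trait,
        genome_build="GRCh38",
    )


MINIMAL_TEXT = (
    "#pgs_id=PGS000001\n"
    "#genome_build=GRCh38\n"
    "rsID\teffect_allele\tother_allele\teffect_weight\n"
    "rs111\tA\tG\t0.5\n"
    "rs222\tC\tT\t-0.25\n"
)


@pytest.fixture
def minimal_scoring_path(tmp_path):
    path = tmp_path / "PGS000001.txt"
    path.write_text(MINIMAL_TEXT)
    return path


@pytest.fixture
def annotation_path(tmp_path):
    path = tmp_path / "annotations.tsv"
    path.write_text(
        "rsid\tgene\tfunc\n"
        "rs429358\tAPOE\texonic\n"
        "rs111\tGENE1\tintronic\n"
        "rs111\tGENE2\tintronic\n"
        "rs222\tGENE1\texonic\n"
        "19:44908684\tAPOC1\tupstream\n"
    )
    return path
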
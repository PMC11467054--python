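"""Reading and writing PGS Catalog scoring files and variant annotation tables.

PGS Catalog distributes each polygenic score as a (usually gzipped)
tab-separated text file: a block of ``#key=value`` metadata header lines,
one tab-separated column-name row, then one data row per variant.  Files
"harmonized" to a reference build carry ``hm_``-prefixed identifier columns
(``hm_rsID``, ``hm_chr``, ``hm_pos``) alongside — or instead of — the
author-submitted ``rsID`` / ``chr_name`` / ``chr_position`` columns.

The reader here is deliberately tolerant (several missing-value tokens,
both raw and harmonized column dialects, scientific-notation weights) while
the writer is strict: missing cells are always emitted as ``"NA"`` so that
a write → parse round trip is the identity on every record field.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

#: Cell values parsed as "missing" on input.  Only "NA" is ever written.
MISSING_TOKENS = frozenset({"NA", "", "."})

#: PGS Catalog score accession pattern.
PGS_ID_PATTERN = re.compile(r"^PGS\d{6}$")

# Column-name dialects: author-submitted and harmonized spellings both map
# onto the canonical ScoringRecord field names.
_RAW_COLUMN_MAP = {
    "rsID": "rsid",
    "chr_name": "chr",
    "chr_position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_weight": "effect_weight",
}
_HM_COLUMN_MAP = {
    "hm_rsID": "hm_rsid",
    "hm_chr": "hm_chr",
    "hm_pos": "hm_pos",
}
_COLUMN_MAP = {**_RAW_COLUMN_MAP, **_HM_COLUMN_MAP}

# Canonical column order used by the writer.
_WRITE_COLUMNS = [
    "rsID",
    "chr_name",
    "chr_position",
    "effect_allele",
    "other_allele",
    "effect_weight",
    "hm_rsID",
    "hm_chr",
    "hm_pos",
]


class ScoringFileError(ValueError):
    """A scoring file violates the format contract."""


class EmptyScoringFileError(ScoringFileError):
    """The data section of a scoring file holds no usable rows."""


class AnnotationTableError(ValueError):
    """The annotation table violates the format contract."""


@dataclass
class ScoringRecord:
    """One variant row of a scoring file.

    ``effect_weight`` is the signed per-allele score weight (dimensionless);
    ``None`` encodes a missing weight.  ``weight_text`` keeps the original
    cell text for provenance (weights are compared and ranked as floats but
    re-serialized from the parsed value).
    """

    effect_allele: str
    rsid: str | None = None
    chr: str | None = None
    pos: int | None = None
    other_allele: str | None = None
    effect_weight: float | None = None
    hm_rsid: str | None = None
    hm_chr: str | None = None
    hm_pos: int | None = None
    weight_text: str | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def has_identifier(self) -> bool:
        """True if the record is locatable by rsID or a chr+pos pair."""
        return (
            self.rsid is not None
            or self.hm_rsid is not None
            or (self.chr is not None and self.pos is not None)
            or (self.hm_chr is not None and self.hm_pos is not None)
        )


@dataclass
class ScoringFile:
    """One polygenic score: header metadata plus ordered variant records."""

    pgs_id: str
    records: list[ScoringRecord]
    trait_label: str = ""
    genome_build: str = ""
    source_path: str = ""
    metadata: dict[str, str] = field(default_factory=dict)
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if not PGS_ID_PATTERN.match(self.pgs_id):
            raise ScoringFileError(
                f"invalid PGS accession {self.pgs_id!r} (expected PGS + 6 digits)"
            )


def _is_gzipped(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _parse_weight(text: str, row_index: int, path: Path) -> float | None:
    cell = text.strip()
    if cell in MISSING_TOKENS:
        return None
    try:
        value = float(cell)
    except ValueError:
        value = math.nan
    if not math.isfinite(value):
        raise ScoringFileError(
            f"{path}: unparseable effect_weight {text!r} at data row {row_index}"
        )
    return value


def _parse_pos(text: str) -> int | None:
    cell = text.strip()
    if cell in MISSING_TOKENS:
        return None
    try:
        value = int(cell)
    except ValueError:
        return None
    return value if value >= 1 else None


def _parse_str(text: str) -> str | None:
    cell = text.strip()
    return None if cell in MISSING_TOKENS else cell


def parse_scoring_file(path: str | Path, gzipped: bool | str = "auto") -> ScoringFile:
    """Parse a PGS Catalog scoring file into a :class:`ScoringFile`.

    Parameters
    ----------
    path
        Scoring file, plain or gzipped tab-separated text.
    gzipped
        ``True``/``False`` to force, or ``"auto"`` (default) to sniff the
        gzip magic bytes.

    Raises
    ------
    ScoringFileError
        Missing ``effect_weight`` column, malformed weight cell (with its
        row index), or invalid accession.
    EmptyScoringFileError
        No data rows, or every data row lacked a usable identifier.
    """
    path = Path(path)
    if gzipped == "auto":
        gzipped = _is_gzipped(path)
    opener = gzip.open if gzipped else open
    with opener(path, "rt", encoding="utf-8") as fh:
        return _parse_stream(fh, path)


def _parse_stream(fh: io.TextIOBase, path: Path) -> ScoringFile:
    metadata: dict[str, str] = {}
    header: list[str] | None = None
    for line in fh:
        line = line.rstrip("\n").rstrip("\r")
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = value.strip()
            continue
        header = line.split("\t")
        break
    if header is None:
        raise EmptyScoringFileError(f"{path}: no column-name row found")
    if "effect_weight" not in header:
        raise ScoringFileError(f"{path}: required column 'effect_weight' is absent")
    if "effect_allele" not in header:
        raise ScoringFileError(f"{path}: required column 'effect_allele' is absent")

    known_idx = {name: i for i, name in enumerate(header) if name in _COLUMN_MAP}
    extra_idx = {name: i for i, name in enumerate(header) if name not in _COLUMN_MAP}

    records: list[ScoringRecord] = []
    n_rejected = 0
    n_rows = 0
    for row_index, line in enumerate(fh):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        n_rows += 1
        cells = line.split("\t")
        if len(cells) < len(header):
            cells += [""] * (len(header) - len(cells))

        def cell(name: str) -> str:
            i = known_idx.get(name)
            return cells[i] if i is not None else ""

        record = ScoringRecord(
            effect_allele=cell("effect_allele").strip(),
            rsid=_parse_str(cell("rsID")),
            chr=_parse_str(cell("chr_name")),
            pos=_parse_pos(cell("chr_position")),
            other_allele=_parse_str(cell("other_allele")),
            effect_weight=_parse_weight(cell("effect_weight"), row_index, path),
            hm_rsid=_parse_str(cell("hm_rsID")),
            hm_chr=_parse_str(cell("hm_chr")),
            hm_pos=_parse_pos(cell("hm_pos")),
            weight_text=cell("effect_weight").strip() or None,
            extra={name: cells[i] for name, i in extra_idx.items()},
        )
        if not record.effect_allele:
            n_rejected += 1
            continue
        if not record.has_identifier():
            n_rejected += 1
            continue
        records.append(record)

    if n_rows == 0:
        raise EmptyScoringFileError(f"{path}: data section is empty")
    if not records:
        raise EmptyScoringFileError(
            f"{path}: all {n_rows} data rows were rejected (no usable identifier)"
        )
    if n_rejected:
        logger.warning("%s: rejected %d unlocatable/invalid rows", path, n_rejected)

    pgs_id = metadata.get("pgs_id", "")
    genome_build = metadata.get("HmPOS_build", metadata.get("genome_build", ""))
    trait = metadata.get("trait_mapped", metadata.get("trait_reported", ""))
    return ScoringFile(
        pgs_id=pgs_id,
        records=records,
        trait_label=trait,
        genome_build=genome_build,
        source_path=str(path),
        metadata=metadata,
        n_rejected=n_rejected,
    )


def _format_cell(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return repr(value)  # shortest text that round-trips the float
    return str(value)


def write_scoring_file(sf: ScoringFile, path: str | Path) -> None:
    """Serialize ``sf`` so that a subsequent parse reproduces it exactly.

    Missing cells are written as ``"NA"``; weights use the shortest decimal
    text that round-trips the stored float.  Gzip compression is chosen by a
    ``.gz`` suffix.  Writing an empty score is refused.
    """
    if not sf.records:
        raise ScoringFileError(f"refusing to write empty scoring file {sf.pgs_id}")
    path = Path(path)
    lines = [f"#pgs_id={sf.pgs_id}"]
    if sf.trait_label:
        lines.append(f"#trait_mapped={sf.trait_label}")
    if sf.genome_build:
        lines.append(f"#genome_build={sf.genome_build}")
    for key, value in sf.metadata.items():
        if key not in {"pgs_id", "trait_mapped", "genome_build"}:
            lines.append(f"#{key}={value}")
    lines.append("\t".join(_WRITE_COLUMNS))
    for r in sf.records:
        lines.append(
            "\t".join(
                _format_cell(v)
                for v in (
                    r.rsid,
                    r.chr,
                    r.pos,
                    r.effect_allele,
                    r.other_allele,
                    r.effect_weight,
                    r.hm_rsid,
                    r.hm_chr,
                    r.hm_pos,
                )
            )
        )
    payload = ("\n".join(lines) + "\n").encode("utf-8")
    if path.suffix == ".gz":
        # mtime=0 and no stored filename keep same-content writes byte-stable
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                gz.write(payload)
    else:
        path.write_bytes(payload)


# ---------------------------------------------------------------------------
# Annotation tables (ANNOVAR-multianno-like)
# ---------------------------------------------------------------------------

_ANN_ID_COLUMNS = ("variant_id", "rsid", "avsnp150", "avsnp147", "snp")
_ANN_GENE_COLUMNS = ("gene", "gene.refgene", "gene_symbol", "gene.refgenewithver")
_ANN_FUNC_COLUMNS = ("func", "func.refgene", "function", "func.refgenewithver")


def load_annotation_table(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Load a variant→gene annotation table.

    The table is tab-separated text in the shape of ANNOVAR ``multianno``
    output (ANNOVAR itself is never executed here): one row per variant–gene
    assignment with a variant identifier (rsID or ``chr:pos``), a gene
    symbol, and a functional category.  A variant may map to several genes;
    every assignment is retained.  Exact duplicate rows are dropped with a
    logged count.

    Returns a mapping from the normalized variant key to a list of
    ``(gene_symbol, functional_category)`` pairs.
    """
    from .harmonize import normalize_chrom, normalize_rsid

    path = Path(path)
    opener = gzip.open if _is_gzipped(path) else open
    mapping: dict[str, list[tuple[str, str]]] = {}
    n_dup = 0
    seen: set[tuple[str, str, str]] = set()
    with opener(path, "rt", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise AnnotationTableError(f"{path}: empty annotation table")
        header = [h.strip() for h in header_line.split("\t")]
        lower = [h.lower() for h in header]

        def find(names: tuple[str, ...], what: str) -> int:
            for name in names:
                if name in lower:
                    return lower.index(name)
            raise AnnotationTableError(f"{path}: no {what} column (tried {names})")

        try:
            id_col: int | None = find(_ANN_ID_COLUMNS, "variant identifier")
        except AnnotationTableError:
            id_col = None
        gene_col = find(_ANN_GENE_COLUMNS, "gene symbol")
        func_col = find(_ANN_FUNC_COLUMNS, "functional category")
        chr_col = lower.index("chr") if "chr" in lower else None
        pos_col = None
        for cand in ("pos", "start"):
            if cand in lower:
                pos_col = lower.index(cand)
                break
        if id_col is None and (chr_col is None or pos_col is None):
            raise AnnotationTableError(
                f"{path}: no variant identifier column (rsID or chr+pos)"
            )

        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            key = None
            if id_col is not None and id_col < len(cells):
                ident = cells[id_col].strip()
                if ident and ident not in MISSING_TOKENS:
                    if ":" in ident:
                        chrom, _, pos = ident.partition(":")
                        key = f"{normalize_chrom(chrom)}:{pos.strip()}"
                    else:
                        key = normalize_rsid(ident)
            if key is None and chr_col is not None and pos_col is not None:
                chrom = cells[chr_col].strip()
                pos = cells[pos_col].strip()
                if chrom and pos:
                    key = f"{normalize_chrom(chrom)}:{pos}"
            if key is None:
                continue
            gene = cells[gene_col].strip() if gene_col < len(cells) else ""
            func = cells[func_col].strip() if func_col < len(cells) else ""
            if not gene:
                continue
            fingerprint = (key, gene, func)
            if fingerprint in seen:
                n_dup += 1
                continue
            seen.add(fingerprint)
            mapping.setdefault(key, []).append((gene, func))
    if n_dup:
        logger.info("%s: deduplicated %d identical annotation rows", path, n_dup)
    return mapping
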
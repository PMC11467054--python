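"""Seeded synthetic scoring-file corpora with known ground truth.

The generator emulates the structure of a trait's PGS Catalog input: several
scoring files whose variant sets partially overlap, signed effect weights
whose magnitudes differ by orders of magnitude between files (each file gets
its own scale factor), a fraction of weights missing ("NA" cells), and a mix
of rsID-keyed and coordinate-keyed variants.  It does NOT simulate LD
structure, allele frequencies, or genotypes — only scoring-file structure
matters for rank aggregation.

Determinism: the corpus is a pure function of the spec's seed.  Each file
draws from its own child stream (seeded by ``[seed, file_index]``), so
increasing ``n_files`` extends a corpus without perturbing earlier files.

:func:`oracle_mrr` is an independent brute-force reference for the mean
reciprocal rank, computed from the manifest's true weights by counting
comparisons (no sorting, no shared code with ``rank_aggregate``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .pgs_io import ScoringFile, ScoringRecord, write_scoring_file

_ALLELES = ["A", "C", "G", "T"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic trait corpus.

    ``overlap`` is the fraction of each file's variants drawn from a pool
    shared by every file; ``weight_sd`` the standard deviation of the
    per-variant normal weights before the per-file scale factor
    ``10**U(scale_log10_range)`` is applied; ``coordinate_fraction`` the
    fraction of variants keyed by chr:pos instead of rsID;
    ``planted_top``, if set, names a variant forced to carry the largest
    absolute weight in every file.
    """

    n_files: int = 5
    n_variants_per_file: int = 100
    overlap: float = 0.5
    weight_sd: float = 0.04
    scale_log10_range: tuple[float, float] = (-2.0, 1.0)
    missing_rate: float = 0.05
    coordinate_fraction: float = 0.3
    planted_top: str | None = None
    trait: str = "synthetic trait"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap", "missing_rate", "coordinate_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_files < 1:
            raise ValueError("n_files must be >= 1")
        if self.n_variants_per_file < 1:
            raise ValueError("n_variants_per_file must be >= 1")


def _draw_identifier(rng: np.random.Generator, coordinate_fraction: float, used: set[str]) -> tuple[str, dict]:
    """A fresh variant identity: canonical key plus record fields."""
    while True:
        if rng.random() < coordinate_fraction:
            chrom = str(int(rng.integers(1, 23)))
            pos = int(rng.integers(1, 250_000_000))
            key = f"{chrom}:{pos}"
            fields = {"chr": chrom, "pos": pos, "hm_chr": chrom, "hm_pos": pos}
        else:
            rsid = f"rs{int(rng.integers(1, 100_000_000))}"
            key = rsid
            fields = {"rsid": rsid, "hm_rsid": rsid}
        if key not in used:
            used.add(key)
            return key, fields


def _identity_from_key(key: str) -> dict:
    if key.startswith("rs"):
        return {"rsid": key, "hm_rsid": key}
    chrom, _, pos = key.partition(":")
    return {"chr": chrom, "pos": int(pos), "hm_chr": chrom, "hm_pos": int(pos)}


def generate_corpus(spec: FixtureSpec, outdir: str | Path) -> tuple[list[Path], dict]:
    """Write ``spec.n_files`` parseable scoring files plus a truth manifest.

    Returns the file paths and the manifest dict; the manifest is also
    written to ``outdir/manifest.json``.  It records, per file, every
    variant's canonical key and true weight (``None`` where the cell was
    emitted as "NA"), and the planted-top key if any.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n_shared = int(round(spec.overlap * spec.n_variants_per_file))
    pool_rng = np.random.default_rng([spec.seed, 0])
    pool_used: set[str] = set()
    if spec.planted_top is not None:
        pool_used.add(spec.planted_top)
    shared = [
        _draw_identifier(pool_rng, spec.coordinate_fraction, pool_used)
        for _ in range(n_shared)
    ]

    paths: list[Path] = []
    manifest_files = []
    for i in range(spec.n_files):
        rng = np.random.default_rng([spec.seed, i + 1])
        pgs_id = f"PGS{900000 + i:06d}"
        scale = 10.0 ** rng.uniform(*spec.scale_log10_range)
        file_used = {key for key, _ in shared} | (
            {spec.planted_top} if spec.planted_top else set()
        )
        variants: list[tuple[str, dict]] = list(shared)
        while len(variants) < spec.n_variants_per_file:
            variants.append(
                _draw_identifier(rng, spec.coordinate_fraction, file_used)
            )

        weights: list[float | None] = []
        for _key, _fields in variants:
            w = float(rng.normal(0.0, spec.weight_sd) * scale)
            weights.append(None if rng.random() < spec.missing_rate else w)
        if spec.planted_top is not None:
            cap = max((abs(w) for w in weights if w is not None), default=1.0)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            variants.append((spec.planted_top, _identity_from_key(spec.planted_top)))
            weights.append(sign * (10.0 * cap + 1.0))

        records = []
        rows = []
        for (key, fields), w in zip(variants, weights):
            ea, oa = rng.choice(_ALLELES, size=2, replace=False)
            records.append(
                ScoringRecord(effect_allele=str(ea), other_allele=str(oa), effect_weight=w, **fields)
            )
            rows.append({"key": key, "weight": w})
        sf = ScoringFile(
            pgs_id=pgs_id,
            records=records,
            trait_label=spec.trait,
            genome_build="GRCh38",
        )
        path = outdir / f"{pgs_id}_hmPOS_GRCh38.txt.gz"
        write_scoring_file(sf, path)
        paths.append(path)
        manifest_files.append({"pgs_id": pgs_id, "path": path.name, "variants": rows})

    manifest = {
        "trait": spec.trait,
        "spec": {**asdict(spec), "scale_log10_range": list(spec.scale_log10_range)},
        "planted_top": spec.planted_top,
        "files": manifest_files,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths, manifest


def oracle_mrr(manifest: dict) -> dict[str, float]:
    """Brute-force mean reciprocal rank from a corpus manifest.

    Independent reference: for every variant with a usable weight in a
    file, its rank is ``1 + (number of weights with strictly larger
    absolute value)``, counted pairwise; a block of ``t`` variants tied at
    that rank shares the mean of ``1/position`` over its ``t`` consecutive
    positions.  Per-file reciprocal ranks are summed (0 where the variant
    is absent or its weight missing) and divided by the number of files.
    """
    n_files = len(manifest["files"])
    totals: dict[str, float] = {}
    for file_entry in manifest["files"]:
        rows = file_entry["variants"]
        for row in rows:
            totals.setdefault(row["key"], 0.0)
        usable = [row for row in rows if row["weight"] is not None]
        for row in usable:
            a = abs(row["weight"])
            n_greater = sum(1 for other in usable if abs(other["weight"]) > a)
            n_tied = sum(1 for other in usable if abs(other["weight"]) == a)
            first = n_greater + 1
            rr = sum(1.0 / p for p in range(first, first + n_tied)) / n_tied
            totals[row["key"]] += rr
    return {key: total / n_files for key, total in totals.items()}
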
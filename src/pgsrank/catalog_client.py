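"""Optional online discovery and download of PGS Catalog scoring files.

A minimal client for the PGS Catalog REST API, used to reproduce a
database build from real data: list the score accessions mapped to a trait
term, filtered to those released on or before a pinned cutoff date
(default 2023-08-04), and download their GRCh38-harmonized scoring files.

The API serves current state, so release pinning is a best-effort
publication-date filter on score metadata; exact reproduction of a
historical snapshot is reported, not guaranteed.  All network access goes
through an injectable ``transport`` callable (``url -> bytes``), so the
client is fully testable offline; everything else in the package works
without it.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

logger = logging.getLogger(__name__)

API_BASE = "https://www.pgscatalog.org/rest"
FTP_BASE = "https://ftp.ebi.ac.uk/pub/databases/spot/pgs/scores"
DEFAULT_CUTOFF = "2023-08-04"

Transport = Callable[[str], bytes]


class CatalogError(RuntimeError):
    """A catalog request failed (retriable: network or remote error)."""


def _urllib_transport(url: str) -> bytes:
    try:
        with urllib.request.urlopen(url, timeout=60) as response:
            return response.read()
    except OSError as exc:
        raise CatalogError(f"request failed for {url}: {exc}") from exc


@dataclass(frozen=True)
class CatalogQuery:
    """A trait-term lookup pinned to a catalog release cutoff date."""

    trait_term: str
    release_cutoff: str = DEFAULT_CUTOFF
    build: str = "GRCh38"

    def __post_init__(self) -> None:
        datetime.date.fromisoformat(self.release_cutoff)  # validates
        if self.build != "GRCh38":
            raise ValueError("only GRCh38 harmonized files are supported")


class CatalogClient:
    """PGS Catalog REST client with on-disk caching of trait queries."""

    def __init__(self, cache_dir: str | Path | None = None, transport: Transport | None = None):
        self.cache_dir = Path(cache_dir) if cache_dir else None
        if self.cache_dir:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.transport = transport or _urllib_transport

    def _cache_path(self, q: CatalogQuery) -> Path | None:
        if not self.cache_dir:
            return None
        digest = hashlib.sha256(
            f"{q.trait_term}|{q.release_cutoff}".encode()
        ).hexdigest()[:16]
        return self.cache_dir / f"scores_{digest}.json"

    def list_score_ids(self, q: CatalogQuery) -> list[str]:
        """Accessions of scores mapped to ``q.trait_term``, released by the cutoff.

        Results are cached on disk keyed by (trait, cutoff); a repeated call
        is served from cache without touching the network.  An unknown
        trait term yields an empty list with a warning.
        """
        cache = self._cache_path(q)
        if cache and cache.exists():
            return json.loads(cache.read_text())
        url = (
            f"{API_BASE}/score/search?"
            + urllib.parse.urlencode({"trait": q.trait_term, "limit": 100})
        )
        ids: list[str] = []
        while url:
            payload = json.loads(self.transport(url).decode("utf-8"))
            for score in payload.get("results", []):
                released = score.get("date_release") or ""
                if released and released <= q.release_cutoff:
                    ids.append(score["id"])
            url = payload.get("next")
        if not ids:
            logger.warning("no scores found for trait term %r", q.trait_term)
        ids = sorted(set(ids))
        if cache:
            cache.write_text(json.dumps(ids))
        return ids

    def harmonized_url(self, pgs_id: str) -> str:
        return f"{FTP_BASE}/{pgs_id}/ScoringFiles/Harmonized/{pgs_id}_hmPOS_GRCh38.txt.gz"

    def fetch_scoring_files(self, ids: list[str], outdir: str | Path) -> list[Path]:
        """Download the GRCh38-harmonized scoring file for each accession.

        Existing non-empty local copies are kept (their checksum is logged
        for provenance); an accession whose harmonized file is unavailable
        produces a warning while the others proceed.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: list[Path] = []
        for pgs_id in ids:
            dest = outdir / f"{pgs_id}_hmPOS_GRCh38.txt.gz"
            if dest.exists() and dest.stat().st_size > 0:
                logger.info("%s: cached (md5 %s)", pgs_id, _md5(dest))
                paths.append(dest)
                continue
            try:
                payload = self.transport(self.harmonized_url(pgs_id))
            except CatalogError as exc:
                logger.warning("%s: harmonized file unavailable (%s)", pgs_id, exc)
                continue
            dest.write_bytes(payload)
            logger.info("%s: downloaded %d bytes (md5 %s)", pgs_id, len(payload), _md5(dest))
            paths.append(dest)
        return paths


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()
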
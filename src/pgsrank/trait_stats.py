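"""Per-trait summary statistics of effect weights.

Statistics are computed over all merged occurrence rows with a non-missing
weight — a variant appearing in k of a trait's files contributes k weights,
mirroring a bind-rows-then-summarize workflow (within-file duplicates have
already been collapsed upstream).  The standard deviation uses the sample
(n−1) denominator; a single observation reports sd 0 with a flag rather
than NA, for schema simplicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harmonize import TraitDataset


class NoWeightsError(ValueError):
    """A trait dataset holds no non-missing weights to summarize."""


@dataclass(frozen=True)
class SummaryStats:
    """Weight-distribution summary for one trait (range, mean, median, sd)."""

    trait: str
    n_files: int
    w_min: float
    w_max: float
    mean: float
    median: float
    sd: float
    n_rows: int
    single_observation: bool = False


def trait_summary(ds: TraitDataset) -> SummaryStats:
    """Summarize the non-missing effect weights of a merged trait dataset."""
    weights = np.array(
        [row.effect_weight for row in ds.merged_rows if row.effect_weight is not None],
        dtype=float,
    )
    if weights.size == 0:
        raise NoWeightsError(f"trait {ds.trait!r} has no non-missing weights")
    single = weights.size == 1
    return SummaryStats(
        trait=ds.trait,
        n_files=ds.n_pgs,
        w_min=float(weights.min()),
        w_max=float(weights.max()),
        mean=float(weights.mean()),
        median=float(np.median(weights)),
        sd=0.0 if single else float(weights.std(ddof=1)),
        n_rows=int(weights.size),
        single_observation=single,
    )
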
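"""Presence/absence analysis across production years.

Detection is threshold-based (default: any nonzero count in at least one
replicate of a year), which makes the Venn partition invariant to sample
order and to any strictly monotone transform of the abundances. The core
virome combines the abundance filter with presence in every year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .abundance import NormalizationConfig, filter_mean_abundance
from .catalog import round_half_up
from .io import CountMatrix, SampleFrame

logger = logging.getLogger("rindvirome")


@dataclass
class VennPartition:
    """Counts of the 7 nonempty membership subsets of three year groups."""

    counts: dict[frozenset, int]
    total: int
    pct_all: float        # detected in all three years
    pct_at_least_two: float

    def count(self, *years: str) -> int:
        return self.counts.get(frozenset(years), 0)


def presence_absence(
    m: CountMatrix, meta: SampleFrame, threshold: float = 0.0
) -> pd.DataFrame:
    """Year x feature presence table: value > threshold in >= 1 sample of the year."""
    groups = meta.groups(m.sample_ids)
    present = (m.data > threshold).groupby(groups).any()
    present.index.name = "group"
    return present


def venn_partition(binary: pd.DataFrame) -> VennPartition:
    """Exact membership-subset counts for exactly three groups."""
    if len(binary.index) != 3:
        raise ValueError("venn partition requires exactly three groups")
    years = list(binary.index)
    detected = binary.any(axis=0)
    total = int(detected.sum())
    counts: dict[frozenset, int] = {}
    for r in (1, 2, 3):
        for combo in combinations(years, r):
            in_combo = binary.loc[list(combo)].all(axis=0)
            out_combo = (
                ~binary.loc[[y for y in years if y not in combo]].any(axis=0)
                if r < 3 else pd.Series(True, index=binary.columns)
            )
            counts[frozenset(combo)] = int((in_combo & out_combo).sum())
    assert sum(counts.values()) == total
    n_all = counts[frozenset(years)]
    n_two_plus = n_all + sum(counts[frozenset(c)] for c in combinations(years, 2))
    pct_all = round_half_up(100.0 * n_all / total) if total else 0.0
    pct_two = round_half_up(100.0 * n_two_plus / total) if total else 0.0
    logger.info("venn partition over %s: %d features, %.1f%% in all, %.1f%% in >= 2",
                years, total, pct_all, pct_two)
    return VennPartition(counts, total, pct_all, pct_two)


def core_virome(
    relative: CountMatrix,
    binary: pd.DataFrame,
    cfg: NormalizationConfig = NormalizationConfig(),
) -> list[str]:
    """Abundant vOTUs (mean relative abundance above the filter) present in all years."""
    filtered = filter_mean_abundance(relative, cfg)
    abundant = set(filtered.feature_ids)
    everywhere = set(binary.columns[binary.all(axis=0)])
    core = sorted(abundant & everywhere)
    logger.info("core virome: %d features (abundant: %d, in all years: %d)",
                len(core), len(abundant), len(everywhere))
    return core
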
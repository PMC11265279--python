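"""Normalization of raw per-sample vOTU counts.

The chain mirrors standard virome practice: rarefaction to the minimum
per-sample depth of the arm, division by contig length (mean coverage),
total-sum scaling to relative abundances, and a mean-relative-abundance
filter (default 0.005%) selecting the abundant fraction of the community.
Each step asserts the normalization state it requires and stamps the state
it produces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger("rindvirome")


@dataclass(frozen=True)
class NormalizationConfig:
    rarefaction_depth: int | str = "min_sample"
    abundance_filter: float = 5e-5   # 0.005% mean relative abundance, strict >
    pseudo_log_offset: float | None = None  # None: smallest nonzero / 10
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.rarefaction_depth, int) and self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")
        if not 0 <= self.abundance_filter < 1:
            raise ValueError("abundance filter must be in [0, 1)")


def rarefy(
    m: CountMatrix,
    cfg: NormalizationConfig = NormalizationConfig(),
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Subsample every sample without replacement to a common depth.

    With ``rarefaction_depth="min_sample"`` the target is the smallest
    per-sample total of the table (each study arm is rarefied
    independently, so rarefy the arms separately). Sampling uses the
    multivariate hypergeometric distribution, i.e. exact draw-without-
    replacement from the observed reads, and is reproducible for a fixed
    seed.
    """
    m.require_state("raw")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    totals = m.data.sum(axis=1)
    depth = int(totals.min()) if cfg.rarefaction_depth == "min_sample" else int(cfg.rarefaction_depth)
    too_small = totals[totals < depth]
    if len(too_small):
        raise ValueError(
            f"rarefaction depth {depth} exceeds sample totals: {list(too_small.index)}"
        )
    out = {}
    for sample_id in m.sample_ids:
        row = m.data.loc[sample_id].to_numpy()
        if row.sum() == depth:
            out[sample_id] = row
        else:
            out[sample_id] = rng.multivariate_hypergeometric(row, depth, method="marginals")
    result = CountMatrix(
        pd.DataFrame.from_dict(out, orient="index", columns=m.feature_ids), "rarefied"
    )
    logger.info("rarefied %d samples to depth %d", len(out), depth)
    return result


def length_normalize(m: CountMatrix, lengths: Mapping[str, float] | pd.Series) -> CountMatrix:
    """Counts divided by contig length: mean read coverage per vOTU."""
    m.require_state("rarefied", "raw")
    lengths = pd.Series(lengths, dtype=float)
    missing = sorted(set(m.feature_ids) - set(lengths.index))
    if missing:
        raise ValueError(f"no length for features: {missing[:5]}")
    lv = lengths.loc[m.feature_ids]
    if (lv <= 0).any():
        raise ValueError("contig lengths must be positive")
    return CountMatrix(m.data / lv, "coverage")


def tss(m: CountMatrix) -> CountMatrix:
    """Total-sum scaling: each sample's vector divided by its sum."""
    m.require_state("coverage", "raw", "rarefied")
    sums = m.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero samples cannot be scaled: {list(zero.index)}")
    return CountMatrix(m.data.div(sums, axis=0), "relative")


def filter_mean_abundance(
    m: CountMatrix, cfg: NormalizationConfig = NormalizationConfig()
) -> CountMatrix:
    """Keep features whose mean relative abundance is strictly above the cutoff.

    The retained columns keep their original relative-scale values; since
    the sliced rows no longer sum to 1 the result travels with state
    "coverage" until re-scaled with :func:`tss`.
    """
    m.require_state("relative")
    means = m.data.mean(axis=0)
    kept = means.index[means > cfg.abundance_filter]
    logger.info(
        "abundance filter (> %g mean): kept %d / %d features",
        cfg.abundance_filter, len(kept), m.shape[1],
    )
    return CountMatrix(m.data[list(kept)], "coverage")


def sparsity(m: CountMatrix) -> float:
    """Fraction of zero cells in the table (any normalization state)."""
    values = m.data.to_numpy()
    return float((values == 0).mean())


def aggregate_by_group(
    m: CountMatrix, labels: Mapping[str, str], unassigned: str = "unassigned"
) -> CountMatrix:
    """Sum relative abundances of features sharing a label; rows still sum to 1.

    Features missing from ``labels`` fall into the ``unassigned`` group
    (the "non-dairy" remainder of group-level abundance tables).
    """
    m.require_state("relative")
    mapped = pd.Series({f: labels.get(f, unassigned) for f in m.feature_ids})
    grouped = m.data.T.groupby(mapped).sum().T
    return CountMatrix(grouped, "relative")


def log_transform(m: CountMatrix, cfg: NormalizationConfig = NormalizationConfig()) -> pd.DataFrame:
    """Heatmap transform: log10(relative + offset), offset = min nonzero / 10."""
    m.require_state("relative", "coverage")
    values = m.data.to_numpy()
    offset = cfg.pseudo_log_offset
    if offset is None:
        nonzero = values[values > 0]
        if nonzero.size == 0:
            raise ValueError("all-zero table cannot be log-transformed")
        offset = float(nonzero.min()) / 10.0
    return pd.DataFrame(np.log10(values + offset), index=m.data.index, columns=m.data.columns)


def succession_profiles(
    raw: CountMatrix,
    lengths: Mapping[str, float] | pd.Series,
    cfg: NormalizationConfig = NormalizationConfig(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-vOTU log abundance trajectories for succession clustering.

    Rows are the abundant vOTUs (those passing the mean-relative-abundance
    filter of the coverage-normalized chain), columns are ripening stages.
    Three choices tame noise that would otherwise swamp the temporal
    patterns: (a) trajectories use the read-proportion scale (rarefied
    counts -> total-sum scaling, no genome-size division, whose per-vOTU
    length offsets carry no temporal information); (b) replicates are
    averaged per stage *before* the log, which suppresses the heavy upper
    tail of replicate variation in rare vOTUs; (c) the log pseudo-count is
    pinned at the abundance-filter value (default 0.005%), so everything
    below the filter's resolution maps to a common detection floor.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    tables = normalize_chain(raw, lengths, cfg, rng)
    abundant = tables["filtered"].feature_ids
    proportions = tss(tables["rarefied"]).data
    stage_means = proportions.groupby(proportions.index.str[:2]).mean()
    offset = cfg.pseudo_log_offset if cfg.pseudo_log_offset is not None else cfg.abundance_filter
    return pd.DataFrame(
        np.log10(stage_means[abundant].to_numpy() + offset),
        index=stage_means.index,
        columns=abundant,
    ).T


def normalize_chain(
    raw: CountMatrix,
    lengths: Mapping[str, float] | pd.Series,
    cfg: NormalizationConfig = NormalizationConfig(),
    rng: np.random.Generator | None = None,
) -> dict[str, CountMatrix]:
    """Full chain: rarefy -> coverage -> relative -> abundance-filtered.

    Returns every intermediate state keyed by name ("rarefied", "coverage",
    "relative", "filtered"). The filtered table keeps the original relative
    scale of the retained features (state flag "coverage" since its rows no
    longer sum to 1).
    """
    rarefied = rarefy(raw, cfg, rng)
    coverage = length_normalize(rarefied, lengths)
    relative = tss(coverage)
    filtered = filter_mean_abundance(relative, cfg)
    return {
        "rarefied": rarefied,
        "coverage": coverage,
        "relative": relative,
        "filtered": filtered,
    }
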
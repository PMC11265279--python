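"""vOTU catalog construction.

Fixed pipeline order: length filter -> chimera removal -> species-level
greedy clustering -> viral selection -> PhiX removal -> lifestyle flagging
-> dairy-database matching -> host assignment. Every input contig ends in
exactly one fate (discarded_short, discarded_chimera, member_of_votu,
discarded_nonviral, discarded_phix).

Thresholds follow common virome dereplication practice: contigs strictly
longer than 2 kb are retained, contigs whose self-alignment exceeds 110%
of their length are chimeras, species clusters form at >= 90%
identity x coverage with the longest contig as representative, and dairy
matches require >= 30% identity x coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

from .align import AlignParams, align_pair, pair_score, score_lookup, self_alignment_fraction
from .io import ContigRecord, DairyPhageDB, ToolReport

logger = logging.getLogger("rindvirome")

QUALIFYING_TIERS = ("complete", "high", "medium")
_TIER_RANK = {"complete": 0, "high": 1, "medium": 2, "low": 3, "not_determined": 4, None: 5}


@dataclass(frozen=True)
class CatalogThresholds:
    min_length: int = 2_000          # strict >: the smallest retained vOTU is 2,002 bp
    species_score: float = 0.90
    chimera_fraction: float = 1.10   # strict >
    dairy_score: float = 0.30
    phix_label: str = "PhiX174"


@dataclass
class VOTURecord:
    """A species-level viral operational taxonomic unit."""

    representative_id: str
    member_ids: list[str]
    length: int
    quality: str = "not_determined"
    lifestyle: str = "virulent_or_unknown"
    host_genus: str | None = None
    dairy_match: tuple[str, float] | None = None
    phage_group: str | None = None


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------

def filter_min_length(
    contigs: Sequence[ContigRecord], thresholds: CatalogThresholds = CatalogThresholds()
) -> list[ContigRecord]:
    kept = [c for c in contigs if c.length > thresholds.min_length]
    logger.info(
        "length filter (> %d bp): kept %d / %d contigs",
        thresholds.min_length, len(kept), len(contigs),
    )
    return kept


def remove_chimeras(
    contigs: Sequence[ContigRecord],
    thresholds: CatalogThresholds = CatalogThresholds(),
    params: AlignParams = AlignParams(),
    fractions: Mapping[str, float] | None = None,
) -> list[ContigRecord]:
    """Drop contigs whose self-alignment fraction strictly exceeds the threshold.

    ``fractions`` may carry precomputed self-alignment fractions (keyed by
    contig id); anything missing is computed internally.
    """
    kept, removed = [], []
    for c in contigs:
        frac = (fractions or {}).get(c.id)
        if frac is None:
            frac = self_alignment_fraction(c, params)
        (removed if frac > thresholds.chimera_fraction else kept).append(c.id)
    if removed:
        logger.info("chimera removal (> %.0f%%): removed %s", 100 * thresholds.chimera_fraction, removed)
    removed_set = set(removed)
    return [c for c in contigs if c.id not in removed_set]


def cluster_species(
    contigs: Sequence[ContigRecord],
    scores: Mapping[tuple[str, str], float],
    thresholds: CatalogThresholds = CatalogThresholds(),
) -> list[VOTURecord]:
    """Greedy longest-first clustering at the species score threshold.

    Contigs are visited by decreasing length (ties broken by id); each
    joins the first existing representative it scores >= the threshold
    against, otherwise it founds a new cluster. Representatives are
    cluster-longest by construction, and the visiting order makes the
    result invariant to input order.
    """
    ordered = sorted(contigs, key=lambda c: (-c.length, c.id))
    votus: list[VOTURecord] = []
    for c in ordered:
        for v in votus:
            if score_lookup(scores, c.id, v.representative_id) >= thresholds.species_score:
                v.member_ids.append(c.id)
                break
        else:
            votus.append(VOTURecord(representative_id=c.id, member_ids=[c.id], length=c.length))
    logger.info("species clustering (>= %.2f): %d clusters from %d contigs",
                thresholds.species_score, len(votus), len(ordered))
    return votus


def _best_tier(*tiers: str | None) -> str | None:
    present = [t for t in tiers if t is not None]
    if not present:
        return None
    return min(present, key=lambda t: _TIER_RANK.get(t, 5))


def select_viral(
    votus: Sequence[VOTURecord],
    reports: Mapping[str, ToolReport],
    thresholds: CatalogThresholds = CatalogThresholds(),
    contigs_by_id: Mapping[str, ContigRecord] | None = None,
    phix_sequence: ContigRecord | None = None,
    params: AlignParams = AlignParams(),
) -> list[VOTURecord]:
    """Keep vOTUs declared viral by at least one detection tool, then drop PhiX.

    Qualifying evidence: complete/high/medium quality from VIBRANT or
    CheckV, or a "full" VirSorter2 label, on the representative contig.
    The quality tier recorded on the vOTU prefers CheckV over VIBRANT.
    The PhiX174 sequencing control qualifies as viral but is removed
    afterwards, either by its label or, when ``phix_sequence`` is given,
    by a dairy-style alignment at the dairy score cutoff.
    """
    kept: list[VOTURecord] = []
    n_nonviral = n_phix = 0
    for v in votus:
        rep = reports.get(v.representative_id)
        vibrant = rep.vibrant_quality if rep else None
        checkv = rep.checkv_quality if rep else None
        virsorter = rep.virsorter2_label if rep else None
        is_viral = (
            vibrant in QUALIFYING_TIERS
            or checkv in QUALIFYING_TIERS
            or virsorter == "full"
        )
        if not is_viral:
            n_nonviral += 1
            continue
        is_phix = v.representative_id == thresholds.phix_label
        if not is_phix and phix_sequence is not None and contigs_by_id is not None:
            rep_contig = contigs_by_id[v.representative_id]
            hits = align_pair(rep_contig, phix_sequence, params)
            is_phix = pair_score(hits, rep_contig.length, phix_sequence.length) >= thresholds.dairy_score
        if is_phix:
            n_phix += 1
            continue
        quality = _best_tier(checkv) or _best_tier(vibrant) or "not_determined"
        kept.append(replace(v, member_ids=list(v.member_ids), quality=quality))
    logger.info("viral selection: kept %d vOTUs (%d non-viral, %d PhiX removed)",
                len(kept), n_nonviral, n_phix)
    return kept


def flag_lifestyle(
    votus: Sequence[VOTURecord], reports: Mapping[str, ToolReport]
) -> list[VOTURecord]:
    """Temperate iff VIBRANT flagged the representative temperate."""
    out = []
    for v in votus:
        rep = reports.get(v.representative_id)
        temperate = rep is not None and rep.vibrant_lifestyle == "temperate"
        out.append(replace(v, member_ids=list(v.member_ids),
                           lifestyle="temperate" if temperate else "virulent_or_unknown"))
    return out


def match_dairy_db(
    votus: Sequence[VOTURecord],
    contigs_by_id: Mapping[str, ContigRecord],
    db: DairyPhageDB,
    thresholds: CatalogThresholds = CatalogThresholds(),
    params: AlignParams = AlignParams(),
    precomputed: Mapping[tuple[str, str], float] | None = None,
) -> list[VOTURecord]:
    """Best dairy-database relative at >= the 30% identity x coverage cutoff.

    Ties on score break by alphabetical phage name. The phage group (and,
    downstream, the host genus) is copied from the matched entry.
    ``precomputed`` may carry (votu_representative, phage_name) -> score.
    """
    out = []
    for v in votus:
        best: tuple[float, str] | None = None
        for entry in sorted(db, key=lambda e: e.name):
            if precomputed is not None and (v.representative_id, entry.name) in precomputed:
                s = precomputed[(v.representative_id, entry.name)]
            else:
                rep = contigs_by_id[v.representative_id]
                hits = align_pair(rep, ContigRecord(entry.name, entry.sequence), params)
                s = pair_score(hits, rep.length, len(entry.sequence))
            if s >= thresholds.dairy_score and (best is None or s > best[0]):
                best = (s, entry.name)
        v2 = replace(v, member_ids=list(v.member_ids))
        if best is not None:
            entry = db.get(best[1])
            v2.dairy_match = (best[1], best[0])
            v2.phage_group = entry.phage_group
            if entry.lifestyle == "temperate":
                v2.lifestyle = "temperate"
        out.append(v2)
    n_matched = sum(1 for v in out if v.dairy_match)
    logger.info("dairy-db matching (>= %.2f): %d / %d vOTUs matched",
                thresholds.dairy_score, n_matched, len(out))
    return out


def assign_host(
    votus: Sequence[VOTURecord],
    reports: Mapping[str, ToolReport],
    db: DairyPhageDB,
) -> list[VOTURecord]:
    """Host genus: the dairy match's verified host overrides the iPHoP prediction."""
    out = []
    for v in votus:
        v2 = replace(v, member_ids=list(v.member_ids))
        if v.dairy_match is not None:
            v2.host_genus = db.get(v.dairy_match[0]).host_genus
        else:
            rep = reports.get(v.representative_id)
            v2.host_genus = rep.iphop_genus if rep else None
        out.append(v2)
    return out


def summarize_catalog(votus: Sequence[VOTURecord]) -> dict:
    """Headline catalog statistics (counts and rounded percentages)."""
    n = len(votus)
    if n == 0:
        raise ValueError("empty catalog")

    def pct(k: int, decimals: int = 1) -> float:
        return round_half_up(100.0 * k / n, decimals)

    genus_counts: dict[str, int] = {}
    for v in votus:
        if v.host_genus:
            genus_counts[v.host_genus] = genus_counts.get(v.host_genus, 0) + 1
    summary = {
        "n_votus": n,
        "n_over_10kb": sum(v.length > 10_000 for v in votus),
        "pct_over_10kb": pct(sum(v.length > 10_000 for v in votus), 0),
        "n_complete": sum(v.quality == "complete" for v in votus),
        "pct_complete": pct(sum(v.quality == "complete" for v in votus)),
        "n_high": sum(v.quality == "high" for v in votus),
        "pct_high": pct(sum(v.quality == "high" for v in votus)),
        "n_temperate": sum(v.lifestyle == "temperate" for v in votus),
        "pct_temperate": pct(sum(v.lifestyle == "temperate" for v in votus)),
        "n_hosted": sum(v.host_genus is not None for v in votus),
        "pct_hosted": pct(sum(v.host_genus is not None for v in votus)),
        "n_dairy_matched": sum(v.dairy_match is not None for v in votus),
        "pct_dairy_matched": pct(sum(v.dairy_match is not None for v in votus)),
        "genus_counts": dict(sorted(genus_counts.items(), key=lambda kv: (-kv[1], kv[0]))),
    }
    return summary


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def build_catalog(
    contigs: Sequence[ContigRecord],
    reports: Mapping[str, ToolReport],
    db: DairyPhageDB,
    thresholds: CatalogThresholds = CatalogThresholds(),
    params: AlignParams = AlignParams(),
    scores: Mapping[tuple[str, str], float] | None = None,
    self_fractions: Mapping[str, float] | None = None,
) -> tuple[list[VOTURecord], dict[str, str]]:
    """Run the full ordered catalog pipeline.

    Returns the final vOTU list and an accounting dict mapping every input
    contig id to its fate: discarded_short, discarded_chimera,
    member_of_votu, discarded_nonviral or discarded_phix.
    """
    from .align import all_vs_all

    fate: dict[str, str] = {}
    sized = filter_min_length(contigs, thresholds)
    sized_ids = {c.id for c in sized}
    for c in contigs:
        if c.id not in sized_ids:
            fate[c.id] = "discarded_short"

    clean = remove_chimeras(sized, thresholds, params, self_fractions)
    clean_ids = {c.id for c in clean}
    for c in sized:
        if c.id not in clean_ids:
            fate[c.id] = "discarded_chimera"

    if scores is None:
        scores = all_vs_all(clean, params)
    votus = cluster_species(clean, scores, thresholds)
    rep_of = {m: v.representative_id for v in votus for m in v.member_ids}

    viral = select_viral(votus, reports, thresholds)
    viral_reps = {v.representative_id for v in viral}
    for c in clean:
        rep = rep_of[c.id]
        if rep in viral_reps:
            fate[c.id] = "member_of_votu"
        elif rep == thresholds.phix_label:
            fate[c.id] = "discarded_phix"
        else:
            fate[c.id] = "discarded_nonviral"

    viral = flag_lifestyle(viral, reports)
    contigs_by_id = {c.id: c for c in contigs}
    viral = match_dairy_db(viral, contigs_by_id, db, thresholds, params)
    viral = assign_host(viral, reports, db)
    logger.info("catalog complete: %d vOTUs", len(viral))
    return viral, fate
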
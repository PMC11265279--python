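"""Catalog pipeline rules: filters, clustering, selection, matching, summary."""

import numpy as np
import pytest

from rindvirome.catalog import (
    CatalogThresholds,
    VOTURecord,
    assign_host,
    cluster_species,
    filter_min_length,
    flag_lifestyle,
    match_dairy_db,
    select_viral,
    summarize_catalog,
)
from rindvirome.io import ContigRecord, DairyPhageDB, DairyPhageEntry, ToolReport
from rindvirome.synthetic import _random_seq


def _contig(rng, name, n):
    return ContigRecord(name, _random_seq(rng, n))


class TestLengthFilter:
    def test_strictly_greater_than_2kb(self, rng):
        contigs = [_contig(rng, f"c{n}", n) for n in (1_999, 2_000, 2_002)]
        kept = filter_min_length(contigs)
        assert [c.length for c in kept] == [2_002]

    def test_empty_input(self):
        assert filter_min_length([]) == []

    def test_zero_threshold_is_identity(self, rng):
        contigs = [_contig(rng, "a", 100)]
        assert filter_min_length(contigs, CatalogThresholds(min_length=0)) == contigs


class TestClustering:
    def _scores(self, pairs):
        return {tuple(sorted(k)): v for k, v in pairs.items()}

    def test_longest_is_representative(self, rng):
        big, small = _contig(rng, "big", 10_000), _contig(rng, "small", 8_000)
        scores = self._scores({("big", "small"): 1.0})
        (votu,) = cluster_species([small, big], scores)
        assert votu.representative_id == "big"
        assert sorted(votu.member_ids) == ["big", "small"]

    def test_input_order_invariance(self, rng):
        contigs = [_contig(rng, f"c{i}", 3_000 + 100 * i) for i in range(6)]
        scores = self._scores({("c0", "c5"): 0.95, ("c1", "c4"): 0.92})
        a = cluster_species(contigs, scores)
        b = cluster_species(contigs[::-1], scores)
        assert [(v.representative_id, sorted(v.member_ids)) for v in a] == [
            (v.representative_id, sorted(v.member_ids)) for v in b
        ]

    def test_greedy_equals_bruteforce_on_separated_instances(self):
        """With all cross-cluster scores < 0.80 the greedy longest-first result
        must equal the brute-force best-representative partition."""
        for seed in range(8):
            rng = np.random.default_rng(9_000 + seed)
            n_clusters = rng.integers(2, 8)
            contigs, scores = [], {}
            truth = {}
            for g in range(n_clusters):
                size = int(rng.integers(1, 6))
                ids = []
                for j in range(size):
                    cid = f"g{g}_m{j}"
                    contigs.append(ContigRecord(cid, "A" * int(rng.integers(2_100, 9_000))))
                    truth[cid] = g
                    ids.append(cid)
                for x in range(len(ids)):
                    for y in range(x + 1, len(ids)):
                        scores[tuple(sorted((ids[x], ids[y])))] = float(rng.uniform(0.90, 1.0))
            # sparse sub-threshold noise between clusters
            all_ids = [c.id for c in contigs]
            for _ in range(10):
                x, y = rng.choice(all_ids, 2, replace=False)
                if truth[x] != truth[y]:
                    scores[tuple(sorted((x, y)))] = float(rng.uniform(0.0, 0.79))
            votus = cluster_species(contigs, scores)
            got = {frozenset(v.member_ids) for v in votus}
            want = {
                frozenset(cid for cid in truth if truth[cid] == g)
                for g in set(truth.values())
            }
            assert got == want
            # brute-force check of the representative rule
            lengths = {c.id: c.length for c in contigs}
            for v in votus:
                assert lengths[v.representative_id] == max(lengths[m] for m in v.member_ids)


class TestViralSelection:
    def _votu(self, rep="v1", length=5_000):
        return VOTURecord(representative_id=rep, member_ids=[rep], length=length)

    @pytest.mark.parametrize(
        "report,kept",
        [
            (ToolReport("v1", checkv_quality="medium"), True),
            (ToolReport("v1", vibrant_quality="high"), True),
            (ToolReport("v1", virsorter2_label="full"), True),
            (ToolReport("v1", vibrant_quality="low", checkv_quality="low"), False),
            (ToolReport("v1", virsorter2_label="partial"), False),
        ],
    )
    def test_union_rule(self, report, kept):
        out = select_viral([self._votu()], {"v1": report})
        assert bool(out) is kept

    def test_missing_report_means_rejection(self):
        assert select_viral([self._votu()], {}) == []

    def test_phix_removed_even_when_complete(self):
        votu = self._votu(rep="PhiX174")
        report = {"PhiX174": ToolReport("PhiX174", checkv_quality="complete")}
        assert select_viral([votu], report) == []

    def test_phix_removed_by_alignment_when_sequence_given(self, rng):
        seq = _random_seq(rng, 5_386)
        votu = self._votu(rep="NODE_9")
        reports = {"NODE_9": ToolReport("NODE_9", checkv_quality="complete")}
        contigs = {"NODE_9": ContigRecord("NODE_9", seq)}
        out = select_viral(
            [votu], reports, contigs_by_id=contigs,
            phix_sequence=ContigRecord("PhiX174", seq),
        )
        assert out == []

    def test_quality_tier_prefers_checkv(self):
        report = {"v1": ToolReport("v1", vibrant_quality="complete", checkv_quality="medium")}
        (out,) = select_viral([self._votu()], report)
        assert out.quality == "medium"


class TestLifestyleAndHost:
    def test_temperate_flag(self):
        votu = VOTURecord("v1", ["v1"], 5_000)
        out = flag_lifestyle([votu], {"v1": ToolReport("v1", vibrant_lifestyle="temperate")})
        assert out[0].lifestyle == "temperate"
        out = flag_lifestyle([votu], {})
        assert out[0].lifestyle == "virulent_or_unknown"

    def test_dairy_match_overrides_iphop_host(self, rng):
        seq = _random_seq(rng, 6_000)
        db = DairyPhageDB([
            DairyPhageEntry("Montesquieu", seq, "Glutamicibacter", "Montesquieu", "virulent")
        ])
        votu = VOTURecord("v1", ["v1"], 6_000)
        contigs = {"v1": ContigRecord("v1", seq)}
        reports = {"v1": ToolReport("v1", iphop_genus="Arthrobacter")}
        matched = match_dairy_db([votu], contigs, db)
        assert matched[0].dairy_match[0] == "Montesquieu"
        hosted = assign_host(matched, reports, db)
        assert hosted[0].host_genus == "Glutamicibacter"

    def test_iphop_used_without_dairy_match(self):
        db = DairyPhageDB([])
        votu = VOTURecord("v1", ["v1"], 6_000)
        reports = {"v1": ToolReport("v1", iphop_genus="Lactococcus")}
        hosted = assign_host([votu], reports, db)
        assert hosted[0].host_genus == "Lactococcus"

    def test_no_prediction_yields_none(self):
        hosted = assign_host([VOTURecord("v1", ["v1"], 6_000)], {}, DairyPhageDB([]))
        assert hosted[0].host_genus is None


class TestDairyThreshold:
    """Printed worked examples: scores 1.00 and 0.54 match, 0.035 does not."""

    @pytest.mark.parametrize(
        "score,matches", [(1.00, True), (0.54, True), (0.035, False), (0.30, True), (0.29, False)]
    )
    def test_cutoff_classification(self, rng, score, matches):
        seq = _random_seq(rng, 5_000)
        db = DairyPhageDB([DairyPhageEntry("ref", seq, "Brevibacterium", "Rousseau", "virulent")])
        votu = VOTURecord("v1", ["v1"], 5_000)
        out = match_dairy_db(
            [votu], {"v1": ContigRecord("v1", seq)}, db,
            precomputed={("v1", "ref"): score},
        )
        assert (out[0].dairy_match is not None) is matches

    def test_tie_breaks_alphabetically(self, rng):
        seq = _random_seq(rng, 5_000)
        db = DairyPhageDB([
            DairyPhageEntry("Zeta", seq, "X", "Z", "virulent"),
            DairyPhageEntry("Alpha", seq, "Y", "A", "virulent"),
        ])
        votu = VOTURecord("v1", ["v1"], 5_000)
        out = match_dairy_db(
            [votu], {"v1": ContigRecord("v1", seq)}, db,
            precomputed={("v1", "Zeta"): 0.8, ("v1", "Alpha"): 0.8},
        )
        assert out[0].dairy_match[0] == "Alpha"


class TestSummary:
    def test_percentages_round_half_up(self):
        votus = []
        for i in range(331):
            votus.append(
                VOTURecord(
                    representative_id=f"v{i}",
                    member_ids=[f"v{i}"],
                    length=15_000 if i < 79 else 3_000,
                    quality="complete" if i < 25 else "medium",
                    lifestyle="temperate" if i < 27 else "virulent_or_unknown",
                    host_genus="Lactococcus" if i < 272 else None,
                    dairy_match=("db", 0.9) if i < 134 else None,
                )
            )
        s = summarize_catalog(votus)
        assert s["n_votus"] == 331
        # 134/331 = 40.48%: half-up rounding reports 40.5 (one-decimal truncation
        # of the same ratio would print 40.4)
        assert s["pct_dairy_matched"] == 40.5
        assert abs(100 * 134 / 331 - 40.4) < 0.1
        assert s["pct_hosted"] == 82.2
        assert s["pct_temperate"] == 8.2
        assert s["pct_over_10kb"] == 24
        assert s["pct_complete"] == 7.6

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            summarize_catalog([])
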
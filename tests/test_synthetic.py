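"""Ground-truth consistency of the synthetic community generator."""

import numpy as np
import pandas as pd
import pytest

from rindvirome.align import self_alignment_fraction
from rindvirome.io import QUALITY_TIERS
from rindvirome.synthetic import (
    CommunityDesign,
    GuildSpec,
    generate_bacteriome,
    generate_dynamics,
    generate_genomes,
    generate_tool_reports,
    sample_counts,
    simulate_study,
)


class TestGenomes:
    def test_contig_census_matches_design(self, small_design):
        contigs, truth = generate_genomes(small_design)
        assert len(contigs) == len(truth.contigs)
        t = truth.contigs
        assert (t["guild"] == "chimera").sum() == small_design.n_chimeras
        assert (t["guild"] == "fragment").sum() == small_design.n_fragments
        assert (t["guild"] == "nonviral").sum() == small_design.n_nonviral
        assert t["is_phix"].sum() == 1
        # every planted vOTU has a reference contig
        refs = {f"{v}_c0" for v in truth.votus["votu_id"]}
        assert refs <= set(t["contig_id"])

    def test_pairs_map_to_planted_clusters(self):
        design = CommunityDesign(
            guilds=[GuildSpec("g", 10, "stable", 1.0)],
            p_members=1.0, max_members=1, n_outgroups=0, n_chimeras=0,
            n_fragments=0, n_nonviral=0, length_range=(2_000, 6_000), seed=3,
        )
        contigs, truth = generate_genomes(design)
        # 10 refs + 10 members + PhiX decoy
        assert len(contigs) == 21
        members = truth.contigs[~truth.contigs["is_phix"]]
        assert members.groupby("cluster_id").size().eq(2).all()

    def test_chimera_self_alignment_exceeds_threshold(self, small_design):
        contigs, truth = generate_genomes(small_design)
        chim_ids = set(truth.contigs.loc[truth.contigs["is_chimera"], "contig_id"])
        for c in contigs:
            if c.id in chim_ids:
                assert self_alignment_fraction(c) > 1.10

    def test_fragments_below_length_threshold(self, small_design):
        contigs, truth = generate_genomes(small_design)
        frag_ids = set(truth.contigs.loc[truth.contigs["is_fragment"], "contig_id"])
        assert frag_ids
        for c in contigs:
            if c.id in frag_ids:
                assert c.length < 2_000

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            CommunityDesign(guilds=[])


class TestDynamics:
    def test_stable_only_design_is_flat(self):
        design = CommunityDesign(guilds=[GuildSpec("g", 5, "stable", 1.0)], seed=1)
        expected, lfc = generate_dynamics(design)
        assert np.allclose(expected.to_numpy(), expected.to_numpy()[0], atol=1e-12)
        assert (lfc == 0).all()

    def test_declining_sixteen_fold_before_renormalization(self):
        """rate 0.5 over 5 stages: the W5 share falls 0.5^4 = 16-fold."""
        design = CommunityDesign(
            guilds=[
                GuildSpec("down", 1, "declining", 0.5, rate=0.5),
                GuildSpec("flat", 1, "stable", 0.5),
            ],
            seed=1,
        )
        expected, _ = generate_dynamics(design)
        # ratio of declining to stable shares removes the renormalization
        ratio = expected.iloc[:, 0] / expected.iloc[:, 1]
        assert ratio.iloc[4] / ratio.iloc[0] == pytest.approx(0.5 ** 4)

    def test_rising_sixteen_fold_gives_planted_lfc_4(self):
        design = CommunityDesign(
            guilds=[
                GuildSpec("up", 2, "rising", 0.1, rate=16.0),
                GuildSpec("flat", 2, "stable", 0.8),
            ],
            seed=1,
        )
        _, lfc = generate_dynamics(design)
        assert lfc.iloc[:2].to_numpy() == pytest.approx(np.log2(16.0))
        assert lfc.iloc[2:].to_numpy() == pytest.approx(0.0)

    def test_stage_vectors_renormalized(self, small_design):
        expected, _ = generate_dynamics(small_design)
        assert np.allclose(expected.sum(axis=1), 1.0)


class TestCounts:
    def test_determinism(self, small_design):
        expected, _ = generate_dynamics(small_design)
        c1, _ = sample_counts(expected, small_design)
        c2, _ = sample_counts(expected, small_design)
        pd.testing.assert_frame_equal(c1.data, c2.data)

    def test_library_conservation(self, small_design):
        expected, _ = generate_dynamics(small_design)
        counts, meta = sample_counts(expected, small_design)
        assert counts.state == "raw"
        assert (counts.data.sum(axis=1) > 0).all()
        assert set(counts.sample_ids) == set(meta.sample_ids)

    def test_low_overdispersion_splits_evenly(self):
        """theta -> infinity with two equal vOTUs gives ~50/50 multinomial counts."""
        design = CommunityDesign(
            guilds=[GuildSpec("g", 2, "stable", 1.0)],
            theta=1e9, library_log10_sd=0.0, within_guild_level_sd=0.0, seed=5,
        )
        expected, _ = generate_dynamics(design)
        counts, _ = sample_counts(expected, design)
        lib = counts.data.sum(axis=1).to_numpy()
        p = counts.data.iloc[:, 0].to_numpy() / lib
        sigma = np.sqrt(0.25 / lib)
        assert (np.abs(p - 0.5) < 4 * sigma).all()

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            CommunityDesign(theta=-1.0)


class TestBacteriome:
    def test_aerobic_two_log_increase(self, small_design):
        _, plate = generate_bacteriome(small_design)
        w1 = plate[plate["sample_id"].str.startswith("W1")]["aerobic_log10"].mean()
        w5 = plate[plate["sample_id"].str.startswith("W5")]["aerobic_log10"].mean()
        # 2-log designed growth, plate noise sd 0.1 per sample (3 replicates)
        assert w5 - w1 == pytest.approx(2.0, abs=3 * 0.1 * np.sqrt(2.0 / 3.0))

    def test_lab_constant(self, small_design):
        _, plate = generate_bacteriome(small_design)
        assert plate["lab_log10"].to_numpy() == pytest.approx(8.0, abs=0.5)

    def test_zero_noise_is_exact_and_lactococcus_dominance_shifts(self):
        design = CommunityDesign(plate_noise_sd=0.0, seed=2)
        genus, plate = generate_bacteriome(design)
        # noise-free plate counts are exactly the designed log-totals
        w1a = plate[plate["sample_id"] == "W1A"].iloc[0]
        genus_w1a = genus.data.loc["W1A"]
        total = 10 ** w1a["lab_log10"] + 10 ** w1a["aerobic_log10"]
        assert genus_w1a["Lactococcus"] == pytest.approx(10 ** w1a["lab_log10"] / total)
        # LAB dominates the start, aerobes the end
        assert genus.data.loc["W1A", "Lactococcus"] > 0.4
        assert genus.data.loc["W5A", "Lactococcus"] < 0.1


class TestToolReports:
    def test_viral_contigs_receive_qualifying_labels(self, small_design):
        contigs, truth = generate_genomes(small_design)
        reports = generate_tool_reports(truth, small_design)
        assert set(reports) == set(truth.contigs["contig_id"])
        for row in truth.contigs.itertuples(index=False):
            rep = reports[row.contig_id]
            qualifies = (
                rep.vibrant_quality in ("complete", "high", "medium")
                or rep.checkv_quality in ("complete", "high", "medium")
                or rep.virsorter2_label == "full"
            )
            assert qualifies == bool(row.is_viral)
            for tier in (rep.vibrant_quality, rep.checkv_quality):
                assert tier is None or tier in QUALITY_TIERS

    def test_temperate_flag_propagates(self, default_study):
        truth = default_study.truth.contigs.set_index("contig_id")
        for cid, rep in default_study.reports.items():
            if truth.loc[cid, "lifestyle"] == "temperate":
                assert rep.vibrant_lifestyle == "temperate"

    def test_phix_decoy_gets_report(self, default_study):
        assert "PhiX174" in default_study.reports


class TestStudyBundle:
    def test_arms_and_truth_are_complete(self, default_study):
        s = default_study
        assert s.counts_short.shape == (15, 100)
        assert s.counts_long.shape == (9, 100)
        assert set(s.meta_long.groups()) == {"2017", "2019", "2022"}
        assert s.truth.votus["expected_log2fc"].notna().all()
        # sporadic turnover only: non-sporadic vOTUs are present in every year
        non_sporadic = s.truth.votus["dynamic"] != "sporadic"
        assert s.year_presence.loc[:, non_sporadic.to_numpy()].all().all()

    def test_same_seed_reproduces(self):
        a = simulate_study(seed=42)
        b = simulate_study(seed=42)
        pd.testing.assert_frame_equal(a.counts_short.data, b.counts_short.data)
        assert [c.sequence for c in a.contigs[:5]] == [c.sequence for c in b.contigs[:5]]
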
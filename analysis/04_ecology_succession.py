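"""Succession statistics over the ripening stages.

Shannon diversity per sample, Bray-Curtis ordination (PCoA), a PERMANOVA
for the washing-stage effect, the Mantel test linking virome and
bacteriome structure, Spearman correlations between phage groups and
bacterial genera, and complete-linkage clustering of vOTU abundance
trajectories with the within-sum-of-squares cluster-count choice.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rindvirome import io as rio
from rindvirome.abundance import (
    NormalizationConfig,
    aggregate_by_group,
    normalize_chain,
    succession_profiles,
)
from rindvirome.ecology import (
    bray_curtis_matrix,
    hclust_complete,
    kruskal_wallis,
    linkage_to_newick,
    mantel,
    pcoa,
    permanova,
    shannon,
    spearman_matrix,
    wss_cluster_count,
)
from rindvirome.synthetic import SyntheticTruth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--abundancedir", type=Path, default=Path("results/abundance"))
    ap.add_argument("--outdir", type=Path, default=Path("results/ecology"))
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rel = rio.read_counts(args.abundancedir / "relative.tsv", state="relative")
    meta = rio.read_metadata(args.simdir / "metadata_short.tsv")
    rio.check_samples(rel, meta)
    genus = rio.read_counts(args.simdir / "genus_relative.tsv", state="relative")
    truth = SyntheticTruth.from_json(args.simdir / "truth.json")

    # diversity per stage (Kruskal-Wallis across stages)
    h_per_sample = {sid: shannon(rel.data.loc[sid]) for sid in rel.sample_ids}
    stages = meta.groups(rel.sample_ids)
    by_stage = [
        [h_per_sample[s] for s in rel.sample_ids if stages[s] == stage]
        for stage in sorted(stages.unique())
    ]
    h_stat, h_p = kruskal_wallis([pd.Series(g).to_numpy() for g in by_stage])

    # ordination and stage effect
    d = bray_curtis_matrix(rel.data)
    perm = permanova(d, stages, n_perm=999, seed=args.seed)
    coords, explained = pcoa(d)
    coords.to_csv(args.outdir / "pcoa_coordinates.tsv", sep="\t")

    # virome vs bacteriome
    man = mantel(d, bray_curtis_matrix(genus.data), n_perm=999, seed=args.seed)
    labels = truth.votus.set_index("votu_id")["phage_group"].dropna().to_dict()
    groups = aggregate_by_group(rel, labels)
    corr = spearman_matrix(groups.data, genus.data)
    corr.round(4).to_csv(args.outdir / "spearman_groups_vs_genera.tsv", sep="\t")

    # trajectory clustering of the abundant vOTUs
    raw = rio.read_counts(args.simdir / "counts_short.tsv", state="raw")
    lengths = pd.read_csv(args.simdir / "votu_lengths.tsv", sep="\t", index_col=0)["length"]
    profiles = succession_profiles(raw, lengths, NormalizationConfig(seed=args.seed))
    merges, leaf_order = hclust_complete(profiles)
    (args.outdir / "trajectory_dendrogram.nwk").write_text(
        linkage_to_newick(merges, list(profiles.index))
    )
    wss, chosen_k = wss_cluster_count(profiles, k_max=10)

    payload = {
        "shannon_per_sample": {k: round(v, 4) for k, v in h_per_sample.items()},
        "shannon_stage_kruskal_wallis": {"H": round(h_stat, 4), "p": round(h_p, 4)},
        "permanova_stage": {"pseudo_F": round(perm.pseudo_F, 4), "R2": round(perm.R2, 4),
                            "p": perm.p, "n_permutations": perm.n_permutations},
        "mantel_virome_bacteriome": {"r": round(man.r, 4), "p": man.p},
        "pcoa_explained": [round(float(e), 4) for e in explained[:4]],
        "wss_curve": [round(float(w), 2) for w in wss],
        "chosen_cluster_count": chosen_k,
    }
    (args.outdir / "ecology.json").write_text(json.dumps(payload, indent=1))

    hs = pd.Series(h_per_sample)
    print(f"Shannon diversity: {hs.min():.3f}-{hs.max():.3f} nats (median {hs.median():.3f}); "
          f"stage effect on diversity: Kruskal-Wallis p = {h_p:.3f}")
    print(f"washing-stage effect on composition: PERMANOVA R2 = {perm.R2:.3f}, p = {perm.p:.3g}")
    print(f"virome-bacteriome association: Mantel r = {man.r:.3f}, p = {man.p:.3g}")
    print(f"trajectory clustering of {len(profiles)} abundant vOTUs: "
          f"WSS elbow selects k = {chosen_k}")


if __name__ == "__main__":
    main()
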
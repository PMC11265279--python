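"""Simulate the study: a guild-structured cheese-surface phage community.

Generates contigs (with planted species clusters, chimeras, fragments and a
PhiX decoy), tool reports, a dairy-phage reference catalog, raw count
tables for the 5-stage ripening arm and the 3-year persistence arm, the
correlated bacterial genus table and plate counts — plus the full ground
truth. Everything downstream reads the files written here.
"""

import argparse
from pathlib import Path

from rindvirome import io as rio
from rindvirome.synthetic import simulate_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    study = simulate_study(seed=args.seed)
    rio.write_fasta(study.contigs, args.outdir / "contigs.fasta")
    rio.write_tool_reports(study.reports, args.outdir / "tool_reports.tsv")
    rio.write_dairy_db(study.dairy_db, args.outdir / "dairy_db.fasta", args.outdir / "dairy_db.tsv")
    rio.write_counts(study.counts_short, args.outdir / "counts_short.tsv")
    rio.write_metadata(study.meta_short, args.outdir / "metadata_short.tsv")
    rio.write_counts(study.counts_long, args.outdir / "counts_long.tsv")
    rio.write_metadata(study.meta_long, args.outdir / "metadata_long.tsv")
    rio.write_counts(study.genus_rel, args.outdir / "genus_relative.tsv")
    study.plate_counts.to_csv(args.outdir / "plate_counts.tsv", sep="\t", index=False)
    study.truth.to_json(args.outdir / "truth.json")
    study.votu_lengths.rename("length").rename_axis("feature_id").to_csv(
        args.outdir / "votu_lengths.tsv", sep="\t"
    )

    t = study.truth
    print(f"simulated {len(study.contigs)} contigs for {len(t.votus)} planted vOTUs "
          f"({t.contigs['is_chimera'].sum()} chimeras, {t.contigs['is_fragment'].sum()} fragments, "
          f"{(~t.contigs['is_viral']).sum()} non-viral, 1 PhiX decoy)")
    print(f"short-term arm: {study.counts_short.shape[0]} samples; "
          f"long-term arm: {study.counts_long.shape[0]} samples; outputs in {args.outdir}")


if __name__ == "__main__":
    main()
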
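"""Across-year persistence: Venn partition and the core virome.

Presence/absence of each vOTU per production year (detection = any nonzero
count), exact membership-subset counts, the shared-in-all and
shared-in-at-least-two percentages, and the core virome (abundant vOTUs
detected in every year).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rindvirome import io as rio
from rindvirome.abundance import NormalizationConfig, normalize_chain
from rindvirome.persistence import core_virome, presence_absence, venn_partition
from rindvirome.synthetic import SyntheticTruth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/persistence"))
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    raw = rio.read_counts(args.simdir / "counts_long.tsv", state="raw")
    meta = rio.read_metadata(args.simdir / "metadata_long.tsv")
    lengths = pd.read_csv(args.simdir / "votu_lengths.tsv", sep="\t", index_col=0)["length"]
    truth = SyntheticTruth.from_json(args.simdir / "truth.json")

    binary = presence_absence(raw, meta)
    venn = venn_partition(binary)
    tables = normalize_chain(raw, lengths, NormalizationConfig(seed=args.seed))
    core = core_virome(tables["relative"], binary)

    payload = {
        "total_detected": venn.total,
        "pct_all_years": venn.pct_all,
        "pct_at_least_two_years": venn.pct_at_least_two,
        "subset_counts": {"&".join(sorted(k)): v for k, v in venn.counts.items()},
        "core_virome": core,
    }
    (args.outdir / "persistence.json").write_text(json.dumps(payload, indent=1))

    stable = set(truth.votus.loc[
        truth.votus["guild"].isin(["stable_936", "stable_949"]), "votu_id"
    ])
    print(f"{venn.total} vOTUs detected across the three production years; "
          f"{venn.pct_all}% in all years, {venn.pct_at_least_two}% in at least two")
    print(f"core virome (abundant and present every year): {len(core)} vOTUs; "
          f"contains all {len(stable)} planted stable vOTUs -> {stable <= set(core)}")


if __name__ == "__main__":
    main()
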
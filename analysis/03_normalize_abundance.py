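"""Normalize the raw short-term count table.

Rarefaction to the arm's minimum per-sample depth, division by vOTU length
(mean coverage), total-sum scaling, and the 0.005% mean-relative-abundance
filter selecting the abundant fraction of the community.
"""

import argparse
from pathlib import Path

import pandas as pd

from rindvirome import io as rio
from rindvirome.abundance import NormalizationConfig, normalize_chain, sparsity


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/abundance"))
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    raw = rio.read_counts(args.simdir / "counts_short.tsv", state="raw")
    lengths = pd.read_csv(args.simdir / "votu_lengths.tsv", sep="\t", index_col=0)["length"]
    cfg = NormalizationConfig(seed=args.seed)
    tables = normalize_chain(raw, lengths, cfg)
    for name, table in tables.items():
        rio.write_counts(table, args.outdir / f"{name}.tsv")

    depth = int(tables["rarefied"].data.sum(axis=1).iloc[0])
    print(f"rarefied {raw.shape[0]} samples to {depth} reads each")
    print(f"sparsity of the raw table: {100 * sparsity(raw):.1f}% zero cells")
    print(f"abundance filter (> {cfg.abundance_filter:g} mean relative abundance): "
          f"kept {tables['filtered'].shape[1]} of {raw.shape[1]} vOTUs")


if __name__ == "__main__":
    main()
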
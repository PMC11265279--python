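"""Differential abundance between early (W1-2) and late (W4-5) communities.

Negative-binomial Wald test on raw counts (median-of-ratios normalization,
moment dispersions shrunk to a trend), Benjamini-Hochberg correction, and
the three-way significance call (adjusted p < 0.01, |log2FC| > 3, mean raw
count > 1,500). Recovery is measured against the planted fold changes.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rindvirome import io as rio
from rindvirome.diffabund import DAConfig, run_differential_abundance
from rindvirome.synthetic import SyntheticTruth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/differential_abundance.tsv"))
    ap.add_argument("--padj-cutoff", type=float, default=0.01)
    args = ap.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    raw = rio.read_counts(args.simdir / "counts_short.tsv", state="raw")
    meta = rio.read_metadata(args.simdir / "metadata_short.tsv")
    truth = SyntheticTruth.from_json(args.simdir / "truth.json")
    cfg = DAConfig(padj_cutoff=args.padj_cutoff)
    res = run_differential_abundance(raw, meta, ("W1", "W2"), ("W4", "W5"), cfg)
    res = res.join(truth.votus.set_index("votu_id")[["expected_log2fc", "guild"]])
    res.to_csv(args.out, sep="\t")

    called = res[res["significant"]]
    planted = res[np.isclose(res["expected_log2fc"].abs(), 4.0)]
    nulls = res[np.isclose(res["expected_log2fc"], 0.0)]
    risers = planted[planted["expected_log2fc"] > 0]
    print(f"{len(called)} of {len(res)} vOTUs differentially abundant "
          f"(padj < {cfg.padj_cutoff:g}, |log2FC| > {cfg.lfc_cutoff:g}, "
          f"mean raw counts > {cfg.min_mean_raw_count:g})")
    print(f"power on planted |log2FC| = 4 guilds: "
          f"{planted['significant'].mean():.2f} ({int(planted['significant'].sum())}/{len(planted)})")
    print(f"rising-guild median estimate: {risers['log2fc'].median():.2f} (planted +4); "
          f"false positives among stable guilds: {int(nulls['significant'].sum())}/{len(nulls)}")
    print("sign convention check: declining guilds negative, rising positive ->",
          bool(((planted['log2fc'] * planted['expected_log2fc']) > 0).all()))


if __name__ == "__main__":
    main()
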
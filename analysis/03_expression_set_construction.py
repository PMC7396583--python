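#!/usr/bin/env python
"""Differential-expression set construction on the simulated time course.

Runs the expressed-gene filter, per-timepoint DE calls, CDEG detection,
genotype partition, cross-genotype enhancement and the putative-set union on
results/inputs/expression.tsv, then scores recovery of the planted truth.
Writes DE calls, set listings and a summary under results/degsets/.
"""

from pathlib import Path

import pandas as pd

from coldomics.pipeline import PipelineConfig, run_all

IN = Path("results/inputs")
OUT = Path("results/degsets")


def main() -> None:
    cfg = PipelineConfig(
        out_dir=str(OUT),
        expression=str(IN / "expression.tsv"),
        expression_meta=str(IN / "expression_meta.tsv"),
    )
    report = run_all(cfg)
    sizes = report["stages"]["transcriptome_sets"]
    print("derived gene-set sizes:")
    for name in ("cdeg_tolerant", "cdeg_sensitive", "tolerant_only", "sensitive_only",
                 "common", "enhanced_common", "putative"):
        print(f"  {name}: {sizes[name]}")

    truth = pd.read_csv(IN / "truth_genes.tsv", sep="\t", index_col=0)["category"]
    listings = pd.read_csv(OUT / "gene_set_listings.tsv", sep="\t")
    putative = set(listings.loc[listings["set"] == "putative", "gene_id"])
    truly = set(truth.index[truth.isin(
        ["tolerant_only_up", "tolerant_only_down", "enhanced_common_up", "enhanced_common_down"]
    )])
    tp = len(putative & truly)
    print(f"planted putative genes: {len(truly)}; recovered: {len(putative)}; "
          f"overlap: {tp} (sensitivity {tp / len(truly):.3f}, "
          f"precision {tp / max(len(putative), 1):.3f})")
    print("Under replicate noise the recovered sets differ from the planted "
          "counts only through test power, not through the set algebra "
          "(zero-noise recovery is exact; see tests).")


if __name__ == "__main__":
    main()
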
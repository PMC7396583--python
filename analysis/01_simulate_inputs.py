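#!/usr/bin/env python
"""Generate every pipeline input with known ground truth.

Writes, under results/inputs/:
  - a two-genotype x {0,12,24} h x control/cold x 3-replicate FPKM matrix
    planting the published CDEG composition (569 tolerant-exclusive, 2358
    common with 190 enhanced, 1344 sensitive-exclusive) plus nulls;
  - a 168-species / 20-class lipidome with the published grand totals
    (219.27 and 237.16 nmol mg^-1 DW) and cold changes (-7.32% / -22.14%);
  - the 22-component free-fatty-acid panel at its published group means;
  - raw physiology readings that invert to known EL/MDA/chlorophyll values;
  - a demo lipid-metabolism gene panel over the planted genes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from coldomics import io, simulate

SEED = 20260924
OUT = Path("results/inputs")

PATHWAYS = [
    ("pw01", "alpha-linolenic acid metabolism"),
    ("pw02", "linoleic acid metabolism"),
    ("pw03", "glycerolipid metabolism"),
    ("pw04", "glycerophospholipid metabolism"),
    ("pw05", "fatty acid elongation"),
    ("pw06", "fatty acid degradation"),
    ("pw07", "fatty acid biosynthesis"),
    ("pw08", "sphingolipid metabolism"),
    ("pw09", "galactolipid synthesis"),
    ("pw10", "jasmonic acid biosynthesis"),
    ("pw11", "wax and cutin biosynthesis"),
    ("pw12", "phosphatidylinositol signaling"),
    ("pw13", "steroid biosynthesis"),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # expression: mild replicate noise on top of the planted design
    cfg = simulate.study_planted_config(seed=SEED, noise_sd_log=0.15)
    values, meta, truth = simulate.gen_expression(cfg)
    io.write_matrix(values, OUT / "expression.tsv",
                    comment=f"generator: numpy default_rng (PCG64) seed={SEED}")
    meta.to_csv(OUT / "expression_meta.tsv", sep="\t")
    truth.labels.rename_axis("gene_id").to_frame().to_csv(OUT / "truth_genes.tsv", sep="\t")

    # demo lipid gene panel: 651 genes, planted CDEGs enriched, 13 pathways
    planted = truth.labels.index[truth.labels != "null"]
    nulls = truth.labels.index[truth.labels == "null"]
    panel_genes = list(rng.choice(planted, 150, replace=False)) + list(
        rng.choice(nulls, 501, replace=False)
    )
    pw = rng.choice(len(PATHWAYS), size=len(panel_genes))
    panel = pd.DataFrame(
        {
            "gene_id": panel_genes,
            "pathway_id": [PATHWAYS[i][0] for i in pw],
            "pathway_name": [PATHWAYS[i][1] for i in pw],
        }
    )
    # a handful of genes belong to two pathways, as in real panels
    extra = panel.sample(20, random_state=SEED % 2**16).copy()
    extra["pathway_id"] = [PATHWAYS[(i + 1) % len(PATHWAYS)][0] for i in pw[:20]]
    extra["pathway_name"] = [PATHWAYS[(i + 1) % len(PATHWAYS)][1] for i in pw[:20]]
    pd.concat([panel, extra]).drop_duplicates(["gene_id", "pathway_id"]).to_csv(
        OUT / "gene_panel.tsv", sep="\t", index=False
    )

    # lipidome: published totals/changes; MGDG down, DGDG/SQDG up in the tolerant line
    lcfg = simulate.LipidomeSimConfig(
        class_multipliers={"MGDG": 0.7, "DGDG": 1.6, "SQDG": 1.4, "LPC": 1.5,
                           "LPE": 1.4, "TAG": 1.2},
        noise_cv=0.08, replicates=6, seed=SEED,
    )
    lvalues, lmeta, ltruth = simulate.gen_lipidome(lcfg)
    io.write_matrix(lvalues, OUT / "lipidome.tsv",
                    comment=f"generator: numpy default_rng (PCG64) seed={SEED}")
    lmeta.to_csv(OUT / "lipidome_meta.tsv", sep="\t")
    io.write_matrix(ltruth.true_means, OUT / "truth_lipidome.tsv")

    # FFA panel at published means with replicate noise
    fvalues, fmeta = simulate.gen_ffa(io.reference_ffa_table(), noise_cv=0.05,
                                      replicates=6, seed=SEED)
    io.write_matrix(fvalues, OUT / "ffa.tsv")
    fmeta.to_csv(OUT / "ffa_meta.tsv", sep="\t")

    # physiology: indices rising under cold, more steeply in the sensitive line
    rows = []
    for genotype, el_slope, mda_slope in (("tolerant", 0.08, 0.03), ("sensitive", 0.35, 0.12)):
        for tp in (0, 12, 24):
            for rep in range(1, 4):
                rows.append(
                    {
                        "sample_id": f"{genotype}_cold_{tp}h_r{rep}",
                        "genotype": genotype, "timepoint_h": tp,
                        "condition": "cold", "replicate": rep,
                        "el": 12.0 + el_slope * tp + rng.normal(0, 0.8),
                        "mda": 4.0 + mda_slope * tp + rng.normal(0, 0.3),
                        "chl_a": max(0.05, 1.8 - 0.01 * tp + rng.normal(0, 0.05)),
                        "chl_b": max(0.05, 0.7 - 0.002 * tp + rng.normal(0, 0.02)),
                    }
                )
    pmeta = pd.DataFrame(rows).set_index("sample_id")
    readings = simulate.gen_physio(pmeta[["el", "mda", "chl_a", "chl_b"]], seed=SEED)
    io.write_matrix(readings, OUT / "physio_readings.tsv")
    pmeta[["genotype", "timepoint_h", "condition", "replicate"]].to_csv(
        OUT / "physio_meta.tsv", sep="\t"
    )

    print(f"wrote synthetic inputs to {OUT}/")
    print(f"  expression: {values.shape[0]} genes x {values.shape[1]} samples "
          f"(noise sd(log) = {cfg.noise_sd_log})")
    print(f"  lipidome: {lvalues.shape[0]} species x {lvalues.shape[1]} samples")
    print(f"  ffa: {fvalues.shape[0]} components x {fvalues.shape[1]} samples")
    print(f"  physiology: {len(readings)} samples")


if __name__ == "__main__":
    main()
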
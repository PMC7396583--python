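"""Lipid-metabolism gene panel analysis over the CDEG partition.

A gene panel maps gene ids to one or more lipid-pathway labels (compiled by
homology to a model-plant lipid-gene catalog; the panel is an input, not
something this package constructs). Operations: intersect the CDEG union
with the panel, select the cold-tolerance subset (tolerant-exclusive plus
enhanced-common panel genes), tally pathway membership in the X/Y/Z format
(total / tolerant-exclusive / sensitive-exclusive), and group expression
profiles for a heat map by Ward hierarchical clustering of log2
median-centered condition-mean profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from coldomics.degsets import ExpressionMatrix, GeneSetPartition

__all__ = [
    "GenePanel",
    "panel_cdegs",
    "select_cold_tolerance_genes",
    "pathway_tally",
    "heatmap_grouping",
]


class GenePanel:
    """Gene -> lipid-pathway membership table.

    Built from a frame with columns ``gene_id``, ``pathway_id`` and
    optionally ``pathway_name`` and ``symbol``; a gene may carry several
    pathway labels (one row each).
    """

    def __init__(self, table: pd.DataFrame):
        if "gene_id" not in table.columns or "pathway_id" not in table.columns:
            raise ValueError("panel needs gene_id and pathway_id columns")
        if table.empty:
            raise ValueError("empty gene panel")
        self.table = table.copy()

    @property
    def gene_ids(self) -> frozenset:
        return frozenset(self.table["gene_id"])

    def pathways_of(self, gene: str) -> list[str]:
        return self.table.loc[self.table["gene_id"] == gene, "pathway_id"].tolist()

    def pathway_names(self) -> dict[str, str]:
        if "pathway_name" not in self.table.columns:
            return {}
        return dict(zip(self.table["pathway_id"], self.table["pathway_name"]))


def panel_cdegs(partition: GeneSetPartition, panel: GenePanel) -> tuple[frozenset, dict[str, int]]:
    """CDEGs (either genotype) that belong to the panel, with up/down tallies."""
    cdegs = set(partition.cdeg_tolerant.index) | set(partition.cdeg_sensitive.index)
    hit = frozenset(cdegs & panel.gene_ids)
    return hit, partition.counts(hit)


def select_cold_tolerance_genes(
    panel_hit: frozenset, partition: GeneSetPartition
) -> frozenset:
    """Panel CDEGs that are tolerant-exclusive or enhanced-common (disjoint union)."""
    return frozenset(
        (panel_hit & partition.tolerant_only) | (panel_hit & partition.enhanced_common)
    )


def pathway_tally(
    genes: frozenset, panel: GenePanel, partition: GeneSetPartition
) -> pd.DataFrame:
    """Per-pathway X/Y/Z counts for a gene set.

    X = genes of the set in the pathway; Y = of those, tolerant-exclusive
    CDEGs; Z = sensitive-exclusive CDEGs. Genes carrying several pathway
    labels count once in each; genes absent from the panel are excluded with
    a warning.
    """
    rows: dict[str, dict[str, int]] = {}
    names = panel.pathway_names()
    for gene in sorted(genes):
        pathways = panel.pathways_of(gene)
        if not pathways:
            warnings.warn(f"gene {gene} has no pathway label; excluded", stacklevel=2)
            continue
        for pw in pathways:
            rec = rows.setdefault(pw, {"x": 0, "y": 0, "z": 0})
            rec["x"] += 1
            if gene in partition.tolerant_only:
                rec["y"] += 1
            elif gene in partition.sensitive_only:
                rec["z"] += 1
    return pd.DataFrame(
        [
            {"pathway_id": pw, "pathway_name": names.get(pw, ""), **rec}
            for pw, rec in sorted(rows.items())
        ]
    )


def heatmap_grouping(
    m: ExpressionMatrix,
    genes,
    k: int = 5,
    *,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Cluster panel-gene expression profiles into k heat-map groups.

    The per-gene profile is log2(replicate-mean FPKM + eps) over the
    (genotype, timepoint, condition) cells, centered by the gene's median
    across those condition averages. Clustering is agglomerative with
    Euclidean distance and Ward linkage, cut at k groups — the conventional
    heat-map default. Constant profiles cannot be placed meaningfully and
    are flagged into group 0.
    """
    genes = [g for g in genes if g in m.values.index]
    if not genes:
        raise ValueError("no requested genes present in matrix")
    key = m.meta.loc[list(m.values.columns), ["genotype", "timepoint_h", "condition"]]
    cond_means = m.values.loc[genes].T.groupby(
        [key[c] for c in key.columns], sort=True
    ).mean().T
    profiles = np.log2(cond_means + pseudocount)
    profiles = profiles.sub(profiles.median(axis=1), axis=0)

    constant = profiles.std(axis=1) == 0
    assign = pd.Series(0, index=profiles.index, dtype=int, name="group")
    active = profiles.index[~constant]
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant profile(s) assigned to group 0", stacklevel=2)
    if len(active) > 0:
        if k <= 1 or len(active) == 1:
            assign.loc[active] = 1
        else:
            # sort genes so the grouping is invariant to input gene order
            ordered = sorted(active)
            z = linkage(profiles.loc[ordered].to_numpy(), method="ward", metric="euclidean")
            labels = fcluster(z, t=min(k, len(ordered)), criterion="maxclust")
            assign.loc[ordered] = labels
    return assign
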
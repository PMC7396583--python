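"""Differential-expression set construction for a two-genotype cold time course.

The pipeline takes an FPKM matrix (genes x samples) with sample metadata
(genotype in {tolerant, sensitive}, timepoint in hours, condition in
{control, cold}, replicate) and derives, in order:

1. the expressed-gene universe (FPKM >= 1 on group means, by default);
2. per-(genotype, timepoint) differential calls — fold change cold/control
   with a pseudocount, a two-sample test on log2(FPKM+1), and
   Benjamini-Hochberg FDR within the contrast; a gene is "up" when
   FC >= 2 and FDR < 0.01, "down" when FC <= 1/2 and FDR < 0.01;
3. CDEGs — genes differential at one or more stress timepoints ("any" mode)
   or at all of them ("all" mode);
4. the genotype partition: tolerant-only, sensitive-only, common CDEGs;
5. the enhanced-common subset — common CDEGs whose response is at least
   ratio_threshold-fold stronger (in |log2 FC|) in the tolerant genotype,
   with direction agreement;
6. the putative cold-tolerance gene set = tolerant-only U enhanced-common.

The original study engine that produced genome-wide FDR values from raw
reads is deliberately not reproduced; only the set algebra downstream of the
differential labels is the analysis target here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "GeneSetPartition",
    "filter_expressed",
    "call_de",
    "call_de_all",
    "detect_cdeg",
    "partition",
    "enhance_common",
    "putative_set",
    "build_partition",
]

GENOTYPES = ("tolerant", "sensitive")
DIRECTIONS = ("up", "down", "ns")


@dataclass
class ExpressionMatrix:
    """FPKM matrix (genes x samples) with per-sample design metadata.

    ``values``: DataFrame indexed by gene_id, columns sample_id.
    ``meta``: DataFrame indexed by sample_id with columns
    ``genotype``, ``timepoint_h``, ``condition``, ``replicate``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_ids: {dupes[:5]}")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        need = {"genotype", "timepoint_h", "condition", "replicate"}
        lack = need - set(self.meta.columns)
        if lack:
            raise ValueError(f"metadata missing columns: {sorted(lack)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be nonnegative")
        key = self.meta.loc[list(self.values.columns), ["genotype", "timepoint_h", "condition", "replicate"]]
        if key.duplicated().any():
            raise ValueError("duplicate (genotype, timepoint, condition, replicate) design cells")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching all metadata equality conditions, in matrix column order."""
        mask = pd.Series(True, index=self.meta.index)
        for col, val in conditions.items():
            mask &= self.meta[col] == val
        keep = set(self.meta.index[mask])
        return [s for s in self.values.columns if s in keep]

    def stress_timepoints(self) -> list:
        """Timepoints at which both cold and control samples exist, excluding the 0-h baseline."""
        tps = []
        for tp in sorted(self.meta["timepoint_h"].unique()):
            if tp == 0:
                continue
            if self.samples_where(timepoint_h=tp, condition="cold") and self.samples_where(
                timepoint_h=tp, condition="control"
            ):
                tps.append(tp)
        return tps


def filter_expressed(
    m: ExpressionMatrix,
    threshold: float = 1.0,
    scope: str = "any-group-mean",
) -> pd.Index:
    """Genes passing the expressed filter FPKM >= ``threshold``.

    ``scope`` controls where the criterion is evaluated:

    * ``any-group-mean`` (default) — the replicate mean of at least one
      (genotype, timepoint, condition) group passes;
    * ``any-sample`` — at least one individual sample passes;
    * ``all-samples`` — every sample passes.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if len(m.values.columns) == 0 or len(m.values.index) == 0:
        return pd.Index([])
    if scope == "any-sample":
        mask = (m.values >= threshold).any(axis=1)
    elif scope == "all-samples":
        mask = (m.values >= threshold).all(axis=1)
    elif scope == "any-group-mean":
        key = m.meta.loc[list(m.values.columns), ["genotype", "timepoint_h", "condition"]]
        group_means = m.values.T.groupby([key[c] for c in key.columns]).mean().T
        mask = (group_means >= threshold).any(axis=1)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return m.values.index[mask]


def _group_pvalues(log_cold: np.ndarray, log_ctrl: np.ndarray, welch: bool) -> np.ndarray:
    """Row-wise two-sample p-values on log2(FPKM+1), with degenerate-variance handling."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(log_cold, log_ctrl, axis=1, equal_var=not welch).pvalue
    p = np.asarray(p, dtype=float)
    mean_diff = log_cold.mean(axis=1) - log_ctrl.mean(axis=1)
    bad = ~np.isfinite(p)
    # zero variance in both groups: certain difference or certain equality
    p[bad & (np.abs(mean_diff) > 1e-12)] = 0.0
    p[bad & (np.abs(mean_diff) <= 1e-12)] = 1.0
    return p


def call_de(
    m: ExpressionMatrix,
    genotype: str,
    timepoint_h,
    *,
    fc_threshold: float = 2.0,
    fdr_cutoff: float = 0.01,
    pseudocount: float = 0.01,
    genes: pd.Index | None = None,
    welch: bool = True,
) -> pd.DataFrame:
    """Differential calls for one (genotype, timepoint) cold-vs-control contrast.

    Fold change is (mean cold + eps) / (mean control + eps); the test is a
    two-sample t-test on log2(FPKM+1); FDR is Benjamini-Hochberg across all
    genes within this contrast. Direction is 'up' iff FC >= fc_threshold and
    FDR < fdr_cutoff, 'down' iff FC <= 1/fc_threshold and FDR < fdr_cutoff,
    otherwise 'ns'.
    """
    cold = m.samples_where(genotype=genotype, timepoint_h=timepoint_h, condition="cold")
    ctrl = m.samples_where(genotype=genotype, timepoint_h=timepoint_h, condition="control")
    if len(cold) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"contrast ({genotype}, {timepoint_h} h) needs >=2 replicates per group; "
            f"got cold={len(cold)}, control={len(ctrl)}"
        )
    vals = m.values if genes is None else m.values.loc[genes]
    cold_fpkm = vals[cold].to_numpy(float)
    ctrl_fpkm = vals[ctrl].to_numpy(float)

    fc = (cold_fpkm.mean(axis=1) + pseudocount) / (ctrl_fpkm.mean(axis=1) + pseudocount)
    log2fc = np.log2(fc)
    p = _group_pvalues(np.log2(cold_fpkm + 1.0), np.log2(ctrl_fpkm + 1.0), welch)
    fdr = multipletests(p, method="fdr_bh")[1]

    direction = np.full(len(fc), "ns", dtype=object)
    sig = fdr < fdr_cutoff
    direction[sig & (fc >= fc_threshold)] = "up"
    direction[sig & (fc <= 1.0 / fc_threshold)] = "down"

    return pd.DataFrame(
        {
            "gene_id": vals.index,
            "genotype": genotype,
            "timepoint_h": timepoint_h,
            "fc": fc,
            "log2fc": log2fc,
            "pvalue": p,
            "fdr": fdr,
            "direction": direction,
        }
    ).set_index("gene_id", drop=False)


def call_de_all(m: ExpressionMatrix, genes: pd.Index | None = None, **kwargs) -> pd.DataFrame:
    """Differential calls for every genotype at every stress timepoint, concatenated."""
    frames = [
        call_de(m, g, tp, genes=genes, **kwargs)
        for g in sorted(m.meta["genotype"].unique())
        for tp in m.stress_timepoints()
    ]
    return pd.concat(frames, ignore_index=True)


def detect_cdeg(results: pd.DataFrame, mode: str = "any") -> pd.Series:
    """Continuously differentially expressed genes from per-timepoint calls.

    ``mode='any'``: a gene qualifies if its direction is non-'ns' at one or
    more stress timepoints. ``mode='all'``: at every stress timepoint.
    Returns a Series indexed by gene_id with values 'up', 'down' or
    'conflict' (differential in opposite directions at different
    timepoints).
    """
    if mode not in {"any", "all"}:
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    out: dict[str, str] = {}
    for gene, sub in results.groupby("gene_id", sort=False):
        dirs = [d for d in sub["direction"] if d != "ns"]
        if not dirs:
            continue
        if mode == "all" and len(dirs) < len(sub):
            continue
        uniq = set(dirs)
        out[gene] = dirs[0] if len(uniq) == 1 else "conflict"
    return pd.Series(out, dtype=object, name="direction")


@dataclass
class GeneSetPartition:
    """The derived CDEG sets with direction labels.

    ``cdeg_tolerant`` / ``cdeg_sensitive`` are Series (gene -> direction).
    The derived sets are plain frozensets; ``direction_of`` merges the two
    label maps (tolerant label wins for common genes).
    """

    cdeg_tolerant: pd.Series
    cdeg_sensitive: pd.Series
    tolerant_only: frozenset = field(default_factory=frozenset)
    sensitive_only: frozenset = field(default_factory=frozenset)
    common: frozenset = field(default_factory=frozenset)
    enhanced_common: frozenset = field(default_factory=frozenset)
    putative: frozenset = field(default_factory=frozenset)

    def direction_of(self, gene: str) -> str:
        if gene in self.cdeg_tolerant.index:
            return self.cdeg_tolerant[gene]
        return self.cdeg_sensitive[gene]

    def counts(self, genes) -> dict[str, int]:
        """Up/down/conflict tallies for a gene collection."""
        tally = {"up": 0, "down": 0, "conflict": 0}
        for g in genes:
            tally[self.direction_of(g)] += 1
        return tally

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("cdeg_tolerant", "cdeg_sensitive", "tolerant_only", "sensitive_only",
                     "common", "enhanced_common", "putative"):
            obj = getattr(self, name)
            genes = set(obj.index) if isinstance(obj, pd.Series) else set(obj)
            tally = self.counts(genes)
            rows.append({"set": name, "size": len(genes), **tally})
        return pd.DataFrame(rows)


def partition(cdeg_t: pd.Series, cdeg_s: pd.Series) -> GeneSetPartition:
    """Split the two genotype CDEG sets into exclusive and common parts."""
    t, s = set(cdeg_t.index), set(cdeg_s.index)
    return GeneSetPartition(
        cdeg_tolerant=cdeg_t,
        cdeg_sensitive=cdeg_s,
        tolerant_only=frozenset(t - s),
        sensitive_only=frozenset(s - t),
        common=frozenset(t & s),
    )


def enhance_common(
    common: frozenset,
    de_t: pd.DataFrame,
    de_s: pd.DataFrame,
    *,
    ratio_threshold: float = 2.0,
    mode: str = "any",
) -> frozenset:
    """Common CDEGs whose tolerant-genotype response is >= ratio_threshold-fold stronger.

    At a qualifying timepoint the two log2 fold changes must agree in sign
    and satisfy |log2fc_tolerant| - |log2fc_sensitive| >= log2(ratio_threshold)
    (inclusive at equality). ``mode='any'`` requires one such timepoint,
    ``mode='all'`` every shared stress timepoint.
    """
    if mode not in {"any", "all"}:
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    log_ratio = np.log2(ratio_threshold)
    t_piv = de_t.pivot_table(index="gene_id", columns="timepoint_h", values="log2fc")
    s_piv = de_s.pivot_table(index="gene_id", columns="timepoint_h", values="log2fc")
    shared_tps = [tp for tp in t_piv.columns if tp in s_piv.columns]
    out = set()
    for gene in common:
        if gene not in t_piv.index or gene not in s_piv.index:
            warnings.warn(f"gene {gene} lacks paired DE results; skipped", stacklevel=2)
            continue
        quals = []
        for tp in shared_tps:
            lt, ls = t_piv.at[gene, tp], s_piv.at[gene, tp]
            if np.isnan(lt) or np.isnan(ls):
                continue
            agree = np.sign(lt) == np.sign(ls) or ls == 0
            # tolerance absorbs float error in log2 at exact-ratio ties ("≥2" inclusive)
            quals.append(agree and abs(lt) - abs(ls) >= log_ratio - 1e-12)
        if quals and (any(quals) if mode == "any" else all(quals)):
            out.add(gene)
    return frozenset(out)


def putative_set(p: GeneSetPartition) -> frozenset:
    """Putative cold-tolerance gene set: tolerant-only U enhanced-common (disjoint parts)."""
    return frozenset(p.tolerant_only | p.enhanced_common)


def build_partition(
    m: ExpressionMatrix,
    *,
    fpkm_threshold: float = 1.0,
    expressed_scope: str = "any-group-mean",
    fc_threshold: float = 2.0,
    fdr_cutoff: float = 0.01,
    ratio_threshold: float = 2.0,
    cdeg_mode: str = "any",
    pseudocount: float = 0.01,
    welch: bool = True,
) -> tuple[GeneSetPartition, pd.DataFrame]:
    """Run the full set construction; returns the completed partition and the DE table."""
    expressed = filter_expressed(m, fpkm_threshold, expressed_scope)
    de = call_de_all(
        m,
        genes=expressed,
        fc_threshold=fc_threshold,
        fdr_cutoff=fdr_cutoff,
        pseudocount=pseudocount,
        welch=welch,
    )
    de_t = de[de["genotype"] == "tolerant"]
    de_s = de[de["genotype"] == "sensitive"]
    cdeg_t = detect_cdeg(de_t, mode=cdeg_mode)
    cdeg_s = detect_cdeg(de_s, mode=cdeg_mode)
    part = partition(cdeg_t, cdeg_s)
    part.enhanced_common = enhance_common(
        part.common, de_t, de_s, ratio_threshold=ratio_threshold, mode=cdeg_mode
    )
    part.putative = putative_set(part)
    return part, de
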
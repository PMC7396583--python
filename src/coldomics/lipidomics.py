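"""Lipid species nomenclature, class aggregation, unsaturation and FFA summaries.

Species names follow the conventions of targeted plant lipidomics panels and
come in three dialects:

* total-composition glycerolipids — ``C<carbons>:<double bonds>-<CLASS>``,
  e.g. ``C36:6-MGDG`` (36 acyl carbons, 6 double bonds);
* per-chain glycerolipids — ``<c1>:<d1>/<c2>:<d2>[/<c3>:<d3>][-CLASS]``,
  e.g. ``18:2/16:1-DAG``; totals are the chain sums;
* sphingolipids — long-chain base with a ``d`` (dihydroxy) or ``t``
  (trihydroxy) prefix, optionally an ``h``-hydroxylated acyl chain, e.g.
  ``d18:1/24:0-Cer`` or ``t18:1/h22:0-GluCer``. The backbone letters are
  structural flags, not carbons; backbone desaturation does count as double
  bonds (d18:1 contributes one).

The double-bond index (DBI) of a lipid class is the mole-fraction-weighted
double-bond count: DBI_class = sum over species in the class of
(double bonds x mean concentration) / (grand mean concentration of the whole
membrane-lipid panel). Weighting by the panel-wide total rather than within
class makes class DBIs additive — the total membrane DBI is exactly the sum
of the class DBIs — which is how published per-class DBI columns sum to
their printed total.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coldomics.physiology import relative_change, significance_stars
from coldomics.stats import compact_letters

__all__ = [
    "LIPID_CLASSES",
    "MEMBRANE_CLASSES",
    "LipidSpecies",
    "LipidProfile",
    "parse_species",
    "parse_ffa_name",
    "class_totals",
    "dbi",
    "lipid_rc_table",
    "dag_tag_ratio",
    "ffa_summary",
    "saturation_class",
]

LIPID_CLASSES = (
    "MGDG", "DGDG", "SQDG",
    "PA", "PC", "PE", "PG", "PI", "PS", "CL",
    "LPC", "LPE", "LPG",
    "Sph", "Cer", "PhytoCer", "GluCer", "S1P",
    "DAG", "TAG",
)

# Membrane-lipid panel used as the DBI denominator: galactolipids,
# phospholipids and sphingolipids, excluding lyso forms and the
# intermediate/storage classes DAG and TAG.
MEMBRANE_CLASSES = (
    "MGDG", "DGDG", "SQDG", "PA", "PC", "PE", "PG", "PI", "PS", "CL",
    "Sph", "Cer", "PhytoCer", "GluCer", "S1P",
)

_CHAIN_RE = re.compile(r"^(?P<prefix>[dth]?)(?P<carbons>\d+):(?P<db>\d+)$")
_TOTAL_RE = re.compile(r"^C(?P<carbons>\d+):(?P<db>\d+)$")


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid species: class, total acyl carbons, total double bonds, chains."""

    raw: str
    lipid_class: str
    total_carbons: int
    double_bonds: int
    chains: tuple[tuple[int, int, str], ...] | None = None  # (carbons, double_bonds, prefix)


class LipidProfile:
    """Species x sample concentration table (nmol mg^-1 DW) with sample metadata.

    ``values``: DataFrame indexed by raw species name, columns sample ids.
    ``meta``: DataFrame indexed by sample id with ``genotype``, ``condition``,
    ``replicate``. Species names are parsed on construction.
    """

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame):
        if (values.to_numpy() < 0).any():
            raise ValueError("concentrations must be nonnegative")
        missing = set(values.columns) - set(meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        self.values = values
        self.meta = meta
        self.species = {name: parse_species(name) for name in values.index}

    def groups(self) -> list[tuple[str, str]]:
        key = self.meta.loc[list(self.values.columns)]
        return sorted({(g, c) for g, c in zip(key["genotype"], key["condition"])})

    def group_samples(self, genotype: str, condition: str) -> list[str]:
        mask = (self.meta["genotype"] == genotype) & (self.meta["condition"] == condition)
        keep = set(self.meta.index[mask])
        return [s for s in self.values.columns if s in keep]

    def group_means(self) -> pd.DataFrame:
        """Species x group replicate means; columns are '<genotype>-<condition>'."""
        cols = {}
        for g, c in self.groups():
            cols[f"{g}-{c}"] = self.values[self.group_samples(g, c)].mean(axis=1)
        return pd.DataFrame(cols)

    def class_of(self) -> pd.Series:
        return pd.Series({n: sp.lipid_class for n, sp in self.species.items()})

    def double_bonds_of(self) -> pd.Series:
        return pd.Series({n: sp.double_bonds for n, sp in self.species.items()})


def parse_species(name: str) -> LipidSpecies:
    """Parse a lipid species name in any of the three supported dialects."""
    if not name or not name.strip():
        raise ValueError("empty species name")
    token = name.strip()

    # split off the class suffix (last '-' segment that is a known class)
    lipid_class = None
    body = token
    if "-" in token:
        head, _, tail = token.rpartition("-")
        if tail in LIPID_CLASSES:
            lipid_class, body = tail, head

    m = _TOTAL_RE.match(body)
    if m:
        if lipid_class is None:
            raise ValueError(f"species {name!r}: missing or unknown lipid class")
        return LipidSpecies(
            raw=name,
            lipid_class=lipid_class,
            total_carbons=int(m["carbons"]),
            double_bonds=int(m["db"]),
        )

    parts = body.split("/")
    chains = []
    for part in parts:
        cm = _CHAIN_RE.match(part)
        if not cm:
            raise ValueError(f"species {name!r}: unparseable chain token {part!r}")
        chains.append((int(cm["carbons"]), int(cm["db"]), cm["prefix"]))
    if lipid_class is None:
        raise ValueError(f"species {name!r}: missing or unknown lipid class")
    # backbone letters (d/t) and hydroxyl marker (h) are flags only; carbons
    # and double bonds of every chain, including base desaturation, sum to totals
    return LipidSpecies(
        raw=name,
        lipid_class=lipid_class,
        total_carbons=sum(c for c, _, _ in chains),
        double_bonds=sum(d for _, d, _ in chains),
        chains=tuple(chains),
    )


def class_totals(p: LipidProfile) -> pd.DataFrame:
    """Per-class and grand-total concentrations per group: replicate mean and SD.

    The class total of a sample is the sum of its species concentrations in
    that class; the grand total sums all classes. Returns a tidy frame with
    columns class, genotype, condition, mean, sd, n.
    """
    if len(p.values.index) == 0:
        raise ValueError("empty lipid profile")
    cls = p.class_of()
    per_class = p.values.groupby(cls).sum()
    grand = per_class.sum(axis=0).to_frame().T
    grand.index = ["Total"]
    table = pd.concat([per_class, grand])
    rows = []
    for g, c in p.groups():
        samples = p.group_samples(g, c)
        sub = table[samples]
        for klass in table.index:
            v = sub.loc[klass].to_numpy(float)
            rows.append(
                {
                    "class": klass,
                    "genotype": g,
                    "condition": c,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1) if len(v) >= 2 else np.nan,
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)


def dbi(
    p: LipidProfile,
    *,
    panel: tuple[str, ...] = MEMBRANE_CLASSES,
) -> pd.DataFrame:
    """Double-bond index per class and group, plus the panel total row.

    DBI_class = sum_{species in class} double_bonds x mean concentration
    / (grand mean concentration of the panel). Classes outside ``panel``
    (DAG/TAG by default) are excluded from both numerator and denominator.
    The 'Total' row is the exact sum of class rows (additivity).
    """
    cls = p.class_of()
    keep = cls.isin(panel)
    if not keep.any():
        raise ValueError("no panel species in profile")
    means = p.group_means().loc[keep.index[keep]]
    db = p.double_bonds_of().loc[keep.index[keep]]
    grand = means.sum(axis=0)
    if (grand == 0).any():
        raise ValueError("zero grand total concentration in a group; DBI undefined")
    weighted = means.mul(db, axis=0).div(grand, axis=1)
    per_class = weighted.groupby(cls.loc[weighted.index]).sum()
    per_class = per_class.reindex([c for c in panel if c in per_class.index])
    total = per_class.sum(axis=0).to_frame().T
    total.index = ["Total"]
    return pd.concat([per_class, total])


def _stars_per_class(
    p: LipidProfile, table: pd.DataFrame, genotype: str
) -> dict[str, str]:
    """t-test stars for cold vs control per class within one genotype."""
    cls = p.class_of()
    per_class = p.values.groupby(cls).sum()
    ctrl = p.group_samples(genotype, "control")
    cold = p.group_samples(genotype, "cold")
    out = {}
    for klass in table.index:
        if klass == "Total":
            a = p.values[ctrl].sum(axis=0).to_numpy(float)
            b = p.values[cold].sum(axis=0).to_numpy(float)
        elif klass in per_class.index:
            a = per_class.loc[klass, ctrl].to_numpy(float)
            b = per_class.loc[klass, cold].to_numpy(float)
        else:
            continue
        if len(a) < 2 or len(b) < 2 or (np.allclose(a, a[0]) and np.allclose(b, b[0])):
            out[klass] = ""
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pval = stats.ttest_ind(a, b).pvalue
        out[klass] = significance_stars(pval if np.isfinite(pval) else 1.0)
    return out


def lipid_rc_table(
    p: LipidProfile,
    *,
    panel: tuple[str, ...] = MEMBRANE_CLASSES,
    letters_method: str = "tukey",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Class-level unsaturation summary: per-group DBI, concentration, RC, stars, letters.

    One row per class (plus Total) and genotype, with the cold-vs-control
    relative change of the class DBI and of the class concentration, a
    t-test star for the concentration contrast, and compact-letter groups
    from one-way ANOVA + Tukey HSD (or Fisher's LSD) across the four
    genotype x condition groups of class concentration.
    """
    dbi_table = dbi(p, panel=panel)
    cls = p.class_of()
    per_class = p.values.groupby(cls).sum()
    ct = class_totals(p)
    genotypes = sorted(p.meta["genotype"].unique())
    rows = []
    for genotype in genotypes:
        ctrl_col, cold_col = f"{genotype}-control", f"{genotype}-cold"
        if ctrl_col not in dbi_table.columns or cold_col not in dbi_table.columns:
            warnings.warn(f"genotype {genotype}: missing a condition; skipped", stacklevel=2)
            continue
        stars = _stars_per_class(p, dbi_table, genotype)
        for klass in dbi_table.index:
            d_ctrl, d_cold = dbi_table.at[klass, ctrl_col], dbi_table.at[klass, cold_col]
            rc_dbi = relative_change(d_ctrl, d_cold) if d_ctrl != 0 else np.nan
            sub = ct[(ct["class"] == klass) & (ct["genotype"] == genotype)]
            c_ctrl = float(sub.loc[sub["condition"] == "control", "mean"].iloc[0])
            c_cold = float(sub.loc[sub["condition"] == "cold", "mean"].iloc[0])
            rc_conc = relative_change(c_ctrl, c_cold) if c_ctrl != 0 else np.nan
            rows.append(
                {
                    "class": klass,
                    "genotype": genotype,
                    "dbi_control": d_ctrl,
                    "dbi_cold": d_cold,
                    "rc_dbi": rc_dbi,
                    "conc_control": c_ctrl,
                    "conc_cold": c_cold,
                    "rc_concentration": rc_conc,
                    "stars": stars.get(klass, ""),
                }
            )
    out = pd.DataFrame(rows)

    # compact letters across the genotype x condition groups, per class
    letters: dict[tuple[str, str, str], str] = {}
    for klass in dbi_table.index:
        groups = {}
        for g, c in p.groups():
            samples = p.group_samples(g, c)
            if klass == "Total":
                groups[f"{g}-{c}"] = p.values[samples].sum(axis=0).to_numpy(float)
            elif klass in per_class.index:
                groups[f"{g}-{c}"] = per_class.loc[klass, samples].to_numpy(float)
        lets = compact_letters(groups, alpha=alpha, method=letters_method)
        for name, letter in lets.items():
            g, c = name.rsplit("-", 1)
            letters[(klass, g, c)] = letter
    out["letters_control"] = [
        letters.get((r["class"], r["genotype"], "control"), "") for _, r in out.iterrows()
    ]
    out["letters_cold"] = [
        letters.get((r["class"], r["genotype"], "cold"), "") for _, r in out.iterrows()
    ]
    return out


def dag_tag_ratio(p: LipidProfile) -> pd.DataFrame:
    """DAG/TAG class-total ratio per group and its cold-vs-control relative change."""
    cls = p.class_of()
    per_class = p.values.groupby(cls).sum()
    if "DAG" not in per_class.index or "TAG" not in per_class.index:
        raise ValueError("profile lacks DAG or TAG species")
    rows = []
    for genotype in sorted(p.meta["genotype"].unique()):
        ratios = {}
        for condition in ("control", "cold"):
            samples = p.group_samples(genotype, condition)
            if not samples:
                continue
            dag = per_class.loc["DAG", samples].mean()
            tag = per_class.loc["TAG", samples].mean()
            if tag == 0:
                warnings.warn(f"{genotype}-{condition}: zero TAG total; ratio undefined", stacklevel=2)
                ratios[condition] = np.nan
            else:
                ratios[condition] = dag / tag
        rc = (
            relative_change(ratios["control"], ratios["cold"])
            if ratios.get("control") not in (None, 0) and np.isfinite(ratios.get("control", np.nan))
            and np.isfinite(ratios.get("cold", np.nan))
            else np.nan
        )
        rows.append(
            {
                "genotype": genotype,
                "ratio_control": ratios.get("control", np.nan),
                "ratio_cold": ratios.get("cold", np.nan),
                "rc": rc,
            }
        )
    return pd.DataFrame(rows)


# --- free fatty acids -------------------------------------------------------

_FFA_RE = re.compile(r"^C(?P<carbons>\d+):(?P<db>\d+)$")


def parse_ffa_name(name: str) -> tuple[int, int]:
    """Parse 'Cxx:y' into (chain length, double bonds)."""
    m = _FFA_RE.match(name.strip())
    if not m:
        raise ValueError(f"unparseable FFA name {name!r} (expected Cxx:y)")
    return int(m["carbons"]), int(m["db"])


def saturation_class(double_bonds: int) -> str:
    """SFA (0 double bonds), MUFA (1) or PUFA (>=2)."""
    if double_bonds == 0:
        return "SFA"
    if double_bonds == 1:
        return "MUFA"
    return "PUFA"


def ffa_summary(values: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Saturation-class summary of a free-fatty-acid panel.

    ``values`` is an FFA x sample table (ng mg^-1) indexed by Cxx:y names;
    ``meta`` maps sample id to genotype and condition. Returns one row per
    genotype with Total / SFA / MUFA / PUFA group means (control and cold),
    the PUFA/SFA ratio, and the cold-vs-control relative change of each.
    """
    if values.index.duplicated().any():
        raise ValueError("duplicate FFA names")
    sat = pd.Series({n: saturation_class(parse_ffa_name(n)[1]) for n in values.index})
    rows = []
    for genotype in sorted(meta["genotype"].unique()):
        row: dict[str, float | str] = {"genotype": genotype}
        sums: dict[str, dict[str, float]] = {}
        for condition in ("control", "cold"):
            mask = (meta["genotype"] == genotype) & (meta["condition"] == condition)
            samples = [s for s in values.columns if s in set(meta.index[mask])]
            if not samples:
                continue
            means = values[samples].mean(axis=1)
            by_sat = means.groupby(sat).sum()
            sfa = float(by_sat.get("SFA", 0.0))
            mufa = float(by_sat.get("MUFA", 0.0))
            pufa = float(by_sat.get("PUFA", 0.0))
            sums[condition] = {
                "total": float(means.sum()),
                "sfa": sfa,
                "mufa": mufa,
                "pufa": pufa,
                "pufa_sfa_ratio": pufa / sfa if sfa > 0 else 0.0,
            }
            for key, val in sums[condition].items():
                row[f"{key}_{condition}"] = val
        for key in ("total", "sfa", "mufa", "pufa", "pufa_sfa_ratio"):
            if "control" in sums and "cold" in sums and sums["control"][key] != 0:
                row[f"rc_{key}"] = relative_change(sums["control"][key], sums["cold"][key])
        rows.append(row)
    return pd.DataFrame(rows)
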
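"""Physiological stress indices from raw assay readings.

Implements the standard spectrophotometric / conductometric formulas used to
score cold damage in seedlings:

* electrolyte leakage (EL), the conductivity ratio of a leaf-disc wash before
  and after boiling — a membrane-permeability index in percent;
* malondialdehyde (MDA) content by the thiobarbituric-acid assay, a
  lipid-peroxidation index in nmol g^-1 fresh weight;
* chlorophyll a/b by two-wavelength acetone-ethanol extraction, in
  mg g^-1 fresh weight;
* relative change (treated - control) / control, the dimensionless effect
  measure used throughout the lipidomics tables;
* a genotype-contrast time-course summary with t-test significance stars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConductivityReading",
    "MdaAssay",
    "ChlAssay",
    "electrolyte_leakage",
    "mda_content",
    "chlorophyll",
    "relative_change",
    "significance_stars",
    "timecourse_summary",
]


@dataclass(frozen=True)
class ConductivityReading:
    """Paired conductivities of a leaf-disc wash: initial (ec1) and after boiling (ec2)."""

    ec1: float
    ec2: float

    def __post_init__(self) -> None:
        if self.ec1 < 0:
            raise ValueError(f"ec1 must be >= 0, got {self.ec1}")
        if self.ec2 <= 0:
            raise ValueError(f"ec2 must be > 0, got {self.ec2}")


@dataclass(frozen=True)
class MdaAssay:
    """TBA-assay absorbances plus extraction volumes (ml) and fresh mass (g)."""

    a450: float
    a532: float
    a600: float
    vt: float
    vs: float
    m: float

    def __post_init__(self) -> None:
        if self.vs <= 0 or self.m <= 0:
            raise ValueError("vs and m must be positive")
        if self.vt < self.vs:
            raise ValueError(f"vt ({self.vt}) must be >= vs ({self.vs})")


@dataclass(frozen=True)
class ChlAssay:
    """Two-wavelength pigment-extract absorbances, extract volume (ml), fresh weight (g)."""

    a663: float
    a646: float
    v: float
    fw: float

    def __post_init__(self) -> None:
        if self.v <= 0 or self.fw <= 0:
            raise ValueError("v and fw must be positive")


def electrolyte_leakage(r: ConductivityReading) -> float:
    """EL (%) = EC1 / EC2 x 100.

    Scale-invariant in the instrument units. EC1 > EC2 is physically
    implausible (the boiled wash should leak everything) and triggers a
    warning, but the ratio is still returned.
    """
    if r.ec1 > r.ec2:
        warnings.warn(
            f"EC1 ({r.ec1}) exceeds EC2 ({r.ec2}); EL > 100% is physically implausible",
            stacklevel=2,
        )
    return r.ec1 / r.ec2 * 100.0


def mda_content(a: MdaAssay) -> float:
    """MDA (nmol g^-1 FW) = [6.45 x (A532 - A600) - 0.56 x A450] x Vt / (Vs x m).

    The 532/600 nm difference removes turbidity; the 450 nm term corrects for
    interfering soluble sugars. A negative result indicates an assay problem
    and is returned as computed, with a warning, rather than clamped.
    """
    value = (6.45 * (a.a532 - a.a600) - 0.56 * a.a450) * a.vt / (a.vs * a.m)
    if value < 0:
        warnings.warn(f"negative MDA content ({value:.4g}); check assay readings", stacklevel=2)
    return value


def chlorophyll(a: ChlAssay) -> dict[str, float]:
    """Chlorophyll a and b (mg g^-1 FW) from 663/646 nm absorbances.

    Chl a = (12.21 A663 - 2.81 A646) V / FW
    Chl b = (20.13 A646 - 5.03 A663) V / FW

    Returns a dict with ``chl_a``, ``chl_b``, ``chl_ab`` (their sum) and
    ``chl_ratio`` (a/b; NaN when Chl b is 0, with a warning).
    """
    scale = a.v / a.fw
    chl_a = (12.21 * a.a663 - 2.81 * a.a646) * scale
    chl_b = (20.13 * a.a646 - 5.03 * a.a663) * scale
    if chl_a < 0 or chl_b < 0:
        warnings.warn("negative chlorophyll content; check absorbances", stacklevel=2)
    if chl_b == 0:
        warnings.warn("Chl b is zero; a/b ratio undefined", stacklevel=2)
        ratio = float("nan")
    else:
        ratio = chl_a / chl_b
    return {"chl_a": chl_a, "chl_b": chl_b, "chl_ab": chl_a + chl_b, "chl_ratio": ratio}


def relative_change(control: float, treated: float) -> float:
    """RC = (treated - control) / control, on group means."""
    if control == 0:
        raise ZeroDivisionError("relative change undefined for control = 0")
    return (treated - control) / control


def significance_stars(p: float) -> str:
    """'**' for p < 0.01, '*' for p < 0.05, '' otherwise (NaN -> '')."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def timecourse_summary(
    values: pd.DataFrame,
    *,
    index_col: str = "value",
    welch: bool = True,
) -> pd.DataFrame:
    """Summarize replicate index values per genotype x timepoint and test the genotype contrast.

    Parameters
    ----------
    values
        Long-format frame with columns ``genotype``, ``timepoint_h``,
        ``index`` (the name of the physiological index) and ``index_col``
        holding replicate values.
    welch
        Use Welch's unequal-variance t-test (default); ``False`` selects the
        classic pooled-variance Student's test.

    Returns
    -------
    Tidy frame, one row per index x genotype x timepoint with ``mean``,
    ``sd``, ``n`` and, on the first genotype row of each pair, the two-sided
    p-value for the two-genotype contrast at that timepoint and its stars.
    Cells with fewer than two replicates are flagged (``flag='n<2'``) and
    excluded from testing.
    """
    required = {"genotype", "timepoint_h", "index", index_col}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    rows = []
    for (idx, tp), sub in values.groupby(["index", "timepoint_h"], sort=True):
        genos = sorted(sub["genotype"].unique())
        groups = {g: sub.loc[sub["genotype"] == g, index_col].to_numpy(float) for g in genos}
        p = np.nan
        if len(genos) == 2 and all(len(v) >= 2 for v in groups.values()):
            g1, g2 = (groups[g] for g in genos)
            if np.allclose(g1, g1[0]) and np.allclose(g2, g2[0]) and np.isclose(g1[0], g2[0]):
                p = 1.0  # identical constant groups: no evidence of difference
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = stats.ttest_ind(g1, g2, equal_var=not welch).pvalue
                if not np.isfinite(p):
                    # zero variance in both groups but different means
                    p = 0.0 if not np.isclose(g1.mean(), g2.mean()) else 1.0
        for i, g in enumerate(genos):
            v = groups[g]
            rows.append(
                {
                    "index": idx,
                    "genotype": g,
                    "timepoint_h": tp,
                    "mean": v.mean() if len(v) else np.nan,
                    "sd": v.std(ddof=1) if len(v) >= 2 else np.nan,
                    "n": len(v),
                    "p": p if i == 0 else np.nan,
                    "stars": significance_stars(p) if i == 0 else "",
                    "flag": "n<2" if len(v) < 2 else "",
                }
            )
    return pd.DataFrame(rows)
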
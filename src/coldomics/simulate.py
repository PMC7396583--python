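"""Synthetic multi-omics inputs with known ground truth.

Every pipeline input — the two-genotype time-course FPKM matrix, the
lipidome, the free-fatty-acid panel and the raw physiology readings — can be
generated here with planted effects, so each downstream stage is testable
end-to-end without any external data. All randomness flows from a single
NumPy PCG64 generator seeded by the config (the generator algorithm is
recorded in output headers by the I/O layer so fixtures are reproducible).

Noise models: replicate variation on FPKM is multiplicative log-normal
(positivity by construction); on concentrations it is Gaussian with a fixed
coefficient of variation, truncated at zero. Neither form is inferred from
data — they are the simplest conventions matching the positivity
constraints of the measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coldomics.lipidomics import LIPID_CLASSES, parse_ffa_name, parse_species

__all__ = [
    "ExpressionSimConfig",
    "LipidomeSimConfig",
    "SimTruth",
    "PLANT_CATEGORIES",
    "default_species_panel",
    "gen_expression",
    "gen_lipidome",
    "gen_ffa",
    "gen_physio",
]

PLANT_CATEGORIES = (
    "tolerant_only_up",
    "tolerant_only_down",
    "sensitive_only_up",
    "sensitive_only_down",
    "common_up",
    "common_down",
    "enhanced_common_up",
    "enhanced_common_down",
    "null",
)


@dataclass
class SimTruth:
    """Ground truth of a simulation: per-entity labels, true means, sample design."""

    labels: pd.Series
    true_means: pd.DataFrame
    meta: pd.DataFrame


@dataclass
class ExpressionSimConfig:
    """Design of a planted two-genotype, three-timepoint FPKM simulation.

    Planted categories modify the cold-condition group mean at every stress
    timepoint (non-zero hour): "up" categories multiply it by
    2**effect_log2fc, "down" divide; "enhanced_common" genes additionally
    multiply the tolerant-genotype response by enhancement_ratio so they
    exceed the cross-genotype FC >= 2 criterion. effect_log2fc >= 1
    guarantees every planted gene clears the FC >= 2 call at zero noise.
    """

    n_genes: int = 1000
    tolerant_only_up: int = 0
    tolerant_only_down: int = 0
    sensitive_only_up: int = 0
    sensitive_only_down: int = 0
    common_up: int = 0
    common_down: int = 0
    enhanced_common_up: int = 0
    enhanced_common_down: int = 0
    base_fpkm: float = 20.0
    effect_log2fc: float = 2.0
    enhancement_ratio: float = 4.0
    noise_sd_log: float = 0.0
    timepoints: tuple = (0, 12, 24)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = self.planted_counts()
        if any(v < 0 for v in counts.values()):
            raise ValueError("planted counts must be nonnegative")
        if sum(counts.values()) > self.n_genes:
            raise ValueError(
                f"planted counts sum to {sum(counts.values())} > n_genes {self.n_genes}"
            )
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be >= 0")
        if self.effect_log2fc < 1:
            raise ValueError("effect_log2fc must be >= 1 to clear the FC >= 2 threshold")
        if self.enhancement_ratio < 2:
            raise ValueError("enhancement_ratio must be >= 2")
        if self.base_fpkm <= 0:
            raise ValueError("base_fpkm must be positive")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates for testing")

    def planted_counts(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in PLANT_CATEGORIES if c != "null"}

    @property
    def null_genes(self) -> int:
        return self.n_genes - sum(self.planted_counts().values())


def study_planted_config(
    n_genes: int = 8000, seed: int = 0, noise_sd_log: float = 0.0
) -> ExpressionSimConfig:
    """Planted design matching the published CDEG composition of the NH5/FH18
    comparison: 569 tolerant-exclusive (277 up / 292 down), 1344
    sensitive-exclusive (536 up / 808 down), 2358 common of which 190 are
    enhanced in the tolerant genotype (158 up / 32 down), nulls to n_genes.
    The putative cold-tolerance set of this design is 569 + 190 = 759 genes."""
    return ExpressionSimConfig(
        n_genes=n_genes,
        tolerant_only_up=277,
        tolerant_only_down=292,
        sensitive_only_up=536,
        sensitive_only_down=808,
        common_up=1376,
        common_down=792,
        enhanced_common_up=158,
        enhanced_common_down=32,
        noise_sd_log=noise_sd_log,
        seed=seed,
    )


def _sample_meta(genotypes, timepoints, replicates) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        for tp in timepoints:
            for cond in ("control", "cold"):
                for r in range(1, replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{g}_{cond}_{tp}h_r{r}",
                            "genotype": g,
                            "timepoint_h": tp,
                            "condition": cond,
                            "replicate": r,
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def gen_expression(config: ExpressionSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (values, meta, truth) for a planted expression design.

    Returns the FPKM matrix (genes x samples), the sample metadata, and the
    ground truth (per-gene category, true group-mean matrix, metadata). At
    noise_sd_log = 0 the matrix equals the true means exactly.
    """
    rng = np.random.default_rng(config.seed)
    meta = _sample_meta(("tolerant", "sensitive"), config.timepoints, config.replicates)

    labels = []
    for cat in PLANT_CATEGORIES[:-1]:
        labels += [cat] * getattr(config, cat)
    labels += ["null"] * config.null_genes
    gene_ids = [f"G{i:06d}" for i in range(1, config.n_genes + 1)]
    label_s = pd.Series(labels, index=gene_ids, name="category")

    up = 2.0**config.effect_log2fc
    means = pd.DataFrame(config.base_fpkm, index=gene_ids, columns=meta.index, dtype=float)
    stress = [tp for tp in config.timepoints if tp != 0]
    for cat in PLANT_CATEGORIES[:-1]:
        genes = label_s.index[label_s == cat]
        if len(genes) == 0:
            continue
        direction = 1.0 if cat.endswith("_up") else -1.0
        for genotype in ("tolerant", "sensitive"):
            if cat.startswith("tolerant_only") and genotype != "tolerant":
                continue
            if cat.startswith("sensitive_only") and genotype != "sensitive":
                continue
            factor = up
            if cat.startswith("enhanced_common") and genotype == "tolerant":
                factor = up * config.enhancement_ratio
            factor = factor if direction > 0 else 1.0 / factor
            cols = meta.index[
                (meta["genotype"] == genotype)
                & (meta["condition"] == "cold")
                & meta["timepoint_h"].isin(stress)
            ]
            means.loc[genes, cols] = config.base_fpkm * factor

    if config.noise_sd_log > 0:
        noise = rng.normal(0.0, config.noise_sd_log, size=means.shape)
        values = means * np.exp(noise)
    else:
        values = means.copy()
    return values, meta, SimTruth(labels=label_s, true_means=means, meta=meta)


# --- lipidome ---------------------------------------------------------------

# Default species panel: 168 species spread over the 20 classes roughly
# proportionally to their prevalence in targeted plant-leaf lipidomics
# panels (19 DAG species, TAG-rich storage fraction, 15 membrane classes).
_PANEL_COUNTS = {
    "MGDG": 8, "DGDG": 8, "SQDG": 5,
    "PA": 10, "PC": 15, "PE": 15, "PG": 10, "PI": 8, "PS": 6, "CL": 6,
    "LPC": 5, "LPE": 5, "LPG": 3,
    "Sph": 4, "Cer": 6, "PhytoCer": 6, "GluCer": 6, "S1P": 1,
    "DAG": 19, "TAG": 22,
}


def default_species_panel() -> list[str]:
    """168 parseable species names over the 20 lipid classes."""
    names: list[str] = []
    glycero_templates = [(32, 0), (34, 1), (34, 2), (34, 3), (34, 4), (34, 6),
                         (36, 2), (36, 3), (36, 4), (36, 5), (36, 6), (38, 2),
                         (38, 4), (38, 6), (40, 2)]
    lyso_templates = [(16, 0), (16, 1), (18, 1), (18, 2), (18, 3)]
    dag_chains = [(18, 2, 16, 1), (18, 2, 16, 0), (18, 3, 18, 3), (18, 3, 18, 0)]
    sph_bases = [("d", 18, 0), ("d", 18, 1), ("t", 18, 0), ("t", 18, 1)]
    cer_acyls = [("", 16, 0), ("", 22, 0), ("", 24, 0), ("h", 16, 0), ("h", 22, 0), ("h", 24, 0)]
    for klass in ("MGDG", "DGDG", "SQDG", "PA", "PC", "PE", "PG", "PI", "PS", "CL"):
        for c, d in glycero_templates[: _PANEL_COUNTS[klass]]:
            names.append(f"C{c}:{d}-{klass}")
    for klass in ("LPC", "LPE", "LPG"):
        for c, d in lyso_templates[: _PANEL_COUNTS[klass]]:
            names.append(f"C{c}:{d}-{klass}")
    for p, c, d in sph_bases[: _PANEL_COUNTS["Sph"]]:
        names.append(f"{p}{c}:{d}-Sph")
    for klass in ("Cer", "PhytoCer", "GluCer"):
        base = "d18:1" if klass != "PhytoCer" else "t18:0"
        for p, c, d in cer_acyls[: _PANEL_COUNTS[klass]]:
            names.append(f"{base}/{p}{c}:{d}-{klass}")
    names.append("d18:1-S1P")
    for i, (c1, d1, c2, d2) in enumerate(dag_chains):
        names.append(f"{c1}:{d1}/{c2}:{d2}-DAG")
    extra_dag = [(16, 0, 16, 0), (16, 0, 18, 1), (16, 0, 18, 2), (16, 0, 18, 3),
                 (16, 1, 18, 2), (16, 1, 18, 3), (18, 0, 18, 1), (18, 0, 18, 2),
                 (18, 1, 18, 1), (18, 1, 18, 2), (18, 1, 18, 3), (18, 2, 18, 2),
                 (18, 2, 18, 3), (18, 3, 16, 1), (20, 0, 18, 2)]
    for c1, d1, c2, d2 in extra_dag[: _PANEL_COUNTS["DAG"] - len(dag_chains)]:
        names.append(f"{c1}:{d1}/{c2}:{d2}-DAG")
    tag_templates = [(50, d) for d in range(0, 8)] + [(52, d) for d in range(0, 8)] + [
        (54, d) for d in range(0, 6)
    ]
    for c, d in tag_templates[: _PANEL_COUNTS["TAG"]]:
        names.append(f"C{c}:{d}-TAG")
    assert len(names) == 168 and len(set(names)) == 168
    return names


@dataclass
class LipidomeSimConfig:
    """Planted lipidome: class-structured control totals and cold effects.

    ``control_totals`` maps genotype -> grand total (nmol mg^-1 DW) under
    control conditions; ``total_change`` maps genotype -> the fractional
    change of the grand total under cold (e.g. -0.0732); per-class cold
    multipliers shape which classes move, then all cold means are rescaled
    so the grand total matches the configured fraction exactly. Species
    weights within the panel are drawn once (Dirichlet) from the seed.
    """

    species: tuple = field(default_factory=lambda: tuple(default_species_panel()))
    control_totals: dict = field(default_factory=lambda: {"tolerant": 219.27, "sensitive": 237.16})
    total_change: dict = field(default_factory=lambda: {"tolerant": -0.0732, "sensitive": -0.2214})
    class_multipliers: dict = field(default_factory=dict)
    noise_cv: float = 0.0
    replicates: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in self.species:
            parse_species(name)  # raises on an unparseable template
        for k in self.class_multipliers:
            if k not in LIPID_CLASSES:
                raise ValueError(f"unknown lipid class in multipliers: {k!r}")


def gen_lipidome(config: LipidomeSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (values, meta, truth) for a planted lipidome.

    True control means split each genotype's configured grand total across
    the species panel; true cold means apply the per-class multipliers and a
    genotype-wide rescale that pins the grand-total relative change to the
    configured fraction. Replicate noise is Gaussian at noise_cv, truncated
    at zero. Multipliers that would produce negative concentrations are
    clamped at zero with a warning.
    """
    rng = np.random.default_rng(config.seed)
    species = list(config.species)
    classes = [parse_species(s).lipid_class for s in species]
    genotypes = sorted(config.control_totals)

    weights = rng.dirichlet(np.full(len(species), 2.0))
    truth_cols = {}
    for g in genotypes:
        ctrl = weights * config.control_totals[g]
        mult = np.array([config.class_multipliers.get(k, 1.0) for k in classes])
        if (mult < 0).any():
            warnings.warn("negative class multiplier; clamped at 0", stacklevel=2)
            mult = np.clip(mult, 0.0, None)
        cold = ctrl * mult
        frac = config.total_change.get(g)
        if frac is not None and cold.sum() > 0:
            cold = cold * (config.control_totals[g] * (1.0 + frac)) / cold.sum()
        truth_cols[f"{g}-control"] = ctrl
        truth_cols[f"{g}-cold"] = cold
    true_means = pd.DataFrame(truth_cols, index=species)

    rows = []
    for g in genotypes:
        for cond in ("control", "cold"):
            for r in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{g}_{cond}_r{r}",
                        "genotype": g,
                        "condition": cond,
                        "replicate": r,
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample_id")

    values = pd.DataFrame(index=species, columns=meta.index, dtype=float)
    for sample_id, row in meta.iterrows():
        mu = true_means[f"{row['genotype']}-{row['condition']}"].to_numpy()
        if config.noise_cv > 0:
            draw = rng.normal(mu, config.noise_cv * mu)
            values[sample_id] = np.clip(draw, 0.0, None)
        else:
            values[sample_id] = mu
    labels = pd.Series(classes, index=species, name="class")
    return values, meta, SimTruth(labels=labels, true_means=true_means, meta=meta)


def gen_ffa(
    group_means: pd.DataFrame,
    *,
    noise_cv: float = 0.0,
    replicates: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an FFA x sample table from group means.

    ``group_means`` is indexed by Cxx:y names with columns
    '<genotype>-<condition>'. Returns (values, meta) with ``replicates``
    samples per group and Gaussian noise at ``noise_cv`` truncated at zero.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    for name in group_means.index:
        parse_ffa_name(name)  # raises on a malformed panel entry
    rng = np.random.default_rng(seed)
    rows, cols = [], {}
    for col in group_means.columns:
        genotype, condition = col.rsplit("-", 1)
        mu = group_means[col].to_numpy(float)
        for r in range(1, replicates + 1):
            sid = f"{genotype}_{condition}_r{r}"
            rows.append(
                {"sample_id": sid, "genotype": genotype, "condition": condition, "replicate": r}
            )
            if noise_cv > 0:
                cols[sid] = np.clip(rng.normal(mu, noise_cv * mu), 0.0, None)
            else:
                cols[sid] = mu.copy()
    meta = pd.DataFrame(rows).set_index("sample_id")
    values = pd.DataFrame(cols, index=group_means.index)
    return values, meta


def gen_physio(
    true_indices: pd.DataFrame,
    *,
    ec2: float = 100.0,
    vt: float = 5.0,
    vs: float = 2.0,
    m: float = 0.5,
    a600: float = 0.05,
    v: float = 10.0,
    fw: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Invert the physiology formulas: raw readings that reproduce given indices.

    ``true_indices`` has one row per sample with any of the columns ``el``
    (percent, in [0, 100]), ``mda`` (nmol g^-1 FW, >= 0), ``chl_a`` and
    ``chl_b`` (mg g^-1 FW). In noise-free mode, applying the physiology
    formulas to the returned readings recovers the indices exactly.
    Gaussian noise of ``noise_sd`` (relative) perturbs readings otherwise.
    """
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=true_indices.index)
    if "el" in true_indices:
        el = true_indices["el"].to_numpy(float)
        if ((el < 0) | (el > 100)).any():
            raise ValueError("true EL must lie in [0, 100]")
        out["ec2"] = ec2
        out["ec1"] = el / 100.0 * ec2
    if "mda" in true_indices:
        mda = true_indices["mda"].to_numpy(float)
        if (mda < 0).any():
            raise ValueError("true MDA must be >= 0")
        out["vt"], out["vs"], out["m"] = vt, vs, m
        out["a450"] = 0.0
        out["a600"] = np.where(mda == 0, a600, a600)
        out["a532"] = out["a600"] + mda * vs * m / (6.45 * vt)
    if "chl_a" in true_indices and "chl_b" in true_indices:
        scale = v / fw
        coeff = np.array([[12.21, -2.81], [-5.03, 20.13]])
        inv = np.linalg.inv(coeff)
        target = np.vstack(
            [true_indices["chl_a"].to_numpy(float), true_indices["chl_b"].to_numpy(float)]
        ) / scale
        absorb = inv @ target
        out["v"], out["fw"] = v, fw
        out["a663"], out["a646"] = absorb[0], absorb[1]
    if noise_sd > 0:
        for col in out.columns:
            if col in {"vt", "vs", "m", "v", "fw"}:
                continue
            out[col] = out[col] * (1.0 + rng.normal(0.0, noise_sd, size=len(out)))
    return out
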
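"""End-to-end orchestration: configuration, validation, staged run, report.

``run_all`` executes physiology -> DEG set construction -> lipid gene panel
-> lipidomics/FFA over TSV inputs named in a :class:`PipelineConfig`,
writing every stage's tables under the output directory together with a
run report (parameters, counts, output files). Runs are deterministic
given the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from coldomics import degsets, io, lipid_panel, lipidomics, physiology

__all__ = ["PipelineConfig", "ValidationError", "validate_inputs", "run_all"]

log = logging.getLogger("coldomics")

EXIT_VALIDATION = 2
EXIT_STAGE = 3


class ValidationError(RuntimeError):
    """Fatal input-validation failure."""


@dataclass
class PipelineConfig:
    """All file paths, thresholds and mode switches for a pipeline run."""

    out_dir: str = "coldomics_out"
    expression: str | None = None
    expression_meta: str | None = None
    lipid_profile: str | None = None
    lipid_meta: str | None = None
    ffa_table: str | None = None
    ffa_meta: str | None = None
    physio_readings: str | None = None
    physio_meta: str | None = None
    panel: str | None = None

    fpkm_threshold: float = 1.0
    fc_threshold: float = 2.0
    fdr_cutoff: float = 0.01
    ratio_threshold: float = 2.0
    k_groups: int = 5
    alpha: float = 0.05
    pseudocount: float = 0.01

    cdeg_mode: str = "any"
    expressed_scope: str = "any-group-mean"
    welch: bool = True
    letters_method: str = "tukey"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fpkm_threshold", "fc_threshold", "fdr_cutoff", "ratio_threshold",
                     "k_groups", "alpha"):
            if getattr(self, name) <= 0 and name != "fpkm_threshold":
                raise ValueError(f"{name} must be positive")
        if self.cdeg_mode not in {"any", "all"}:
            raise ValueError("cdeg_mode must be 'any' or 'all'")
        if self.expressed_scope not in {"any-group-mean", "all-samples", "any-sample"}:
            raise ValueError(f"unknown expressed_scope {self.expressed_scope!r}")
        if self.letters_method not in {"tukey", "lsd"}:
            raise ValueError("letters_method must be 'tukey' or 'lsd'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Schema checks on every configured input. Returns warnings; raises
    :class:`ValidationError` on fatal problems (missing files, incomplete
    metadata, negative values, unparseable species names)."""
    notes: list[str] = []

    def must_exist(path, what):
        if path is None:
            return False
        if not Path(path).is_file():
            raise ValidationError(f"{what}: file not found: {path}")
        return True

    if must_exist(config.expression, "expression") and must_exist(
        config.expression_meta, "expression metadata"
    ):
        values = io.read_matrix(config.expression)
        meta = io.read_metadata(config.expression_meta)
        missing = set(values.columns) - set(meta.index)
        if missing:
            raise ValidationError(f"expression samples missing metadata: {sorted(missing)[:5]}")
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative FPKM values")
    if must_exist(config.lipid_profile, "lipid profile") and must_exist(
        config.lipid_meta, "lipid metadata"
    ):
        values = io.read_matrix(config.lipid_profile)
        meta = io.read_metadata(config.lipid_meta)
        missing = set(values.columns) - set(meta.index)
        if missing:
            raise ValidationError(f"lipid samples missing metadata: {sorted(missing)[:5]}")
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative lipid concentrations")
        for name in values.index:
            try:
                lipidomics.parse_species(name)
            except ValueError as exc:
                raise ValidationError(str(exc)) from exc
    if must_exist(config.ffa_table, "FFA table") and must_exist(config.ffa_meta, "FFA metadata"):
        values = io.read_matrix(config.ffa_table)
        for name in values.index:
            try:
                lipidomics.parse_ffa_name(name)
            except ValueError as exc:
                raise ValidationError(str(exc)) from exc
    if config.panel is not None:
        must_exist(config.panel, "gene panel")
    return notes


def run_all(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the run report (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": [],
    }

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=index)
        report["outputs"].append(str(path))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")

        if config.physio_readings and config.physio_meta:
            log.info("stage: physiology")
            readings = io.read_matrix(config.physio_readings).join(
                io.read_metadata(config.physio_meta)
            )
            long_rows = []
            for sample_id, row in readings.iterrows():
                idx = {}
                if {"ec1", "ec2"} <= set(readings.columns):
                    idx["el"] = physiology.electrolyte_leakage(
                        physiology.ConductivityReading(row["ec1"], row["ec2"])
                    )
                if {"a450", "a532", "a600", "vt", "vs", "m"} <= set(readings.columns):
                    idx["mda"] = physiology.mda_content(
                        physiology.MdaAssay(row["a450"], row["a532"], row["a600"],
                                            row["vt"], row["vs"], row["m"])
                    )
                if {"a663", "a646", "v", "fw"} <= set(readings.columns):
                    idx.update(physiology.chlorophyll(
                        physiology.ChlAssay(row["a663"], row["a646"], row["v"], row["fw"])
                    ))
                for name, value in idx.items():
                    long_rows.append(
                        {"index": name, "genotype": row["genotype"],
                         "timepoint_h": row["timepoint_h"], "value": value}
                    )
            summary = physiology.timecourse_summary(
                pd.DataFrame(long_rows), welch=config.welch
            )
            emit(summary, "physio_summary.tsv")
            report["stages"]["physiology"] = {"n_rows": len(summary)}

        part = None
        matrix = None
        if config.expression and config.expression_meta:
            log.info("stage: transcriptome sets")
            matrix = io.read_expression(config.expression, config.expression_meta)
            part, de = degsets.build_partition(
                matrix,
                fpkm_threshold=config.fpkm_threshold,
                expressed_scope=config.expressed_scope,
                fc_threshold=config.fc_threshold,
                fdr_cutoff=config.fdr_cutoff,
                ratio_threshold=config.ratio_threshold,
                cdeg_mode=config.cdeg_mode,
                pseudocount=config.pseudocount,
                welch=config.welch,
            )
            emit(de, "de_calls.tsv")
            emit(part.summary(), "gene_sets_summary.tsv")
            listings = []
            for set_name in ("tolerant_only", "sensitive_only", "common",
                             "enhanced_common", "putative"):
                for g in sorted(getattr(part, set_name)):
                    listings.append({"gene_id": g, "set": set_name,
                                     "direction": part.direction_of(g)})
            emit(pd.DataFrame(listings, columns=["gene_id", "set", "direction"]),
                 "gene_set_listings.tsv")
            report["stages"]["transcriptome_sets"] = {
                row["set"]: int(row["size"]) for _, row in part.summary().iterrows()
            }

        if config.panel and part is not None and matrix is not None:
            log.info("stage: lipid gene panel")
            panel = lipid_panel.GenePanel(pd.read_csv(config.panel, sep="\t", comment="#"))
            hit, tallies = lipid_panel.panel_cdegs(part, panel)
            selected = lipid_panel.select_cold_tolerance_genes(hit, part)
            tally = lipid_panel.pathway_tally(hit, panel, part)
            emit(tally, "pathway_tally.tsv")
            present = [g for g in sorted(panel.gene_ids) if g in matrix.values.index]
            if present:
                groups = lipid_panel.heatmap_grouping(matrix, present, k=config.k_groups)
                emit(groups.rename("group").rename_axis("gene_id").reset_index(),
                     "heatmap_groups.tsv")
            report["stages"]["lipid_gene_panel"] = {
                "panel_cdegs": len(hit),
                "up": tallies["up"],
                "down": tallies["down"],
                "selected_cold_tolerance": len(selected),
            }

        if config.lipid_profile and config.lipid_meta:
            log.info("stage: lipidomics")
            profile = io.read_lipid_profile(config.lipid_profile, config.lipid_meta)
            emit(lipidomics.class_totals(profile), "class_totals.tsv")
            emit(lipidomics.dbi(profile).rename_axis("class").reset_index(), "dbi.tsv")
            emit(
                lipidomics.lipid_rc_table(
                    profile, letters_method=config.letters_method, alpha=config.alpha
                ),
                "lipid_rc_table.tsv",
            )
            emit(lipidomics.dag_tag_ratio(profile), "dag_tag_ratio.tsv")
            report["stages"]["lipidomics"] = {"n_species": len(profile.values.index)}

        if config.ffa_table and config.ffa_meta:
            log.info("stage: free fatty acids")
            values, meta = io.read_ffa(config.ffa_table, config.ffa_meta)
            emit(lipidomics.ffa_summary(values, meta), "ffa_summary.tsv")
            report["stages"]["ffa"] = {"n_components": len(values.index)}

    report_path = out_dir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    report["outputs"].append(str(report_path))
    missing = [p for p in report["outputs"] if not Path(p).exists()]
    if missing:
        raise RuntimeError(f"declared outputs missing: {missing}")
    return report
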
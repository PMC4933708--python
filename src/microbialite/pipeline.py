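"""Orchestration of the geochemistry, ecology and differential stages.

``run_pipeline`` consumes a :class:`RunConfig` pointing at the TSV inputs,
runs whichever stages have inputs, and writes a reproducible report bundle:
biosignature offsets and summary, PCoA coordinates and variance fractions,
a UPGMA newick tree, a PERMANOVA table, differential-abundance tables, and
a run log recording parameters and seed.  Stages without inputs are skipped
with a logged notice — never silently fabricated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__, diffabund, ecology, geochem, io

logger = logging.getLogger("microbialite")

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str | Path = "results"
    water_tsv: str | Path | None = None
    carbonate_tsv: str | Path | None = None
    counts_tsv: str | Path | None = None
    metadata_tsv: str | Path | None = None
    # geochemistry
    t_range: tuple[float, float] = (10.0, 40.0)
    constants_variant: str = "freshwater"
    classification_tolerance: float = 0.1
    # ecology
    depth: int = ecology.DEFAULT_NORMALIZATION_DEPTH
    n_perm: int = 999
    # differential abundance
    focal_group: str = "thrombolite"
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    min_base_mean: float = 2000.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("water_tsv", "carbonate_tsv", "counts_tsv", "metadata_tsv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if (self.counts_tsv is None) != (self.metadata_tsv is None):
            raise ValueError("counts_tsv and metadata_tsv must be provided together")


def _run_geochem(cfg: RunConfig, out: Path) -> dict:
    water = io.read_water_samples(cfg.water_tsv)
    prediction = geochem.max_equilibrium_prediction(
        water, cfg.t_range, constants_variant=cfg.constants_variant
    )
    summary = {
        "max_delta13c_hco3_permil": prediction.delta13c_hco3,
        "max_equilibrium_delta13c_arag_permil": prediction.delta13c_arag_eq,
        "prediction_temperature_c": prediction.temperature,
        "prediction_source_sample": prediction.source_sample_id,
    }
    for s in water:
        if s.conductance is not None:
            summary[f"salinity_g_per_l.{s.id}"] = geochem.salinity_from_conductance(
                s.conductance
            )
    if cfg.carbonate_tsv is not None:
        carbonates = io.read_carbonate_samples(cfg.carbonate_tsv)
        result = geochem.biosignature_offsets(
            carbonates, prediction, cfg.classification_tolerance
        )
        io.write_biosignature_report(result, out / "biosignature_offsets.tsv")
        summary.update(
            {
                "offset_min_permil": result.min_offset,
                "offset_max_permil": result.max_offset,
                "offset_mean_permil": result.mean_offset,
                "offset_sd_permil": result.sd_offset,
            }
        )
    io.write_summary(summary, out / "geochem_summary.tsv")
    return summary


def _run_ecology(cfg: RunConfig, table: ecology.CountTable, out: Path) -> dict:
    normalized = ecology.normalize_depth(table, cfg.depth)
    dist = ecology.bray_curtis_matrix(normalized)
    dist.to_csv(out / "bray_curtis.tsv", sep="\t")

    ordination = ecology.pcoa(dist)
    ordination.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    pd.Series(
        ordination.proportion_explained,
        index=ordination.coordinates.columns,
        name="proportion_explained",
    ).to_csv(out / "pcoa_variance.tsv", sep="\t")

    tree = ecology.upgma(dist)
    (out / "upgma.nwk").write_text(ecology.tree_to_newick(tree) + "\n")

    perm = ecology.permanova(dist, table.groups, n_perm=cfg.n_perm, seed=cfg.seed)
    io.write_summary(
        {
            "pseudo_F": perm.pseudo_f,
            "R2": perm.r_squared,
            "p_value": perm.p_value,
            "n_permutations": perm.n_permutations,
            "seed": perm.seed,
        },
        out / "permanova.tsv",
    )
    return {
        "permanova_p": perm.p_value,
        "permanova_r2": perm.r_squared,
        "pc1_fraction": float(ordination.proportion_explained[0]),
    }


def _run_diffabund(cfg: RunConfig, table: ecology.CountTable, out: Path) -> dict:
    records, filtered = diffabund.differential_abundance(
        table,
        focal_group=cfg.focal_group,
        alpha=cfg.alpha,
        min_abs_log2fc=cfg.min_abs_log2fc,
        min_base_mean=cfg.min_base_mean,
    )
    records.rename_axis("feature").to_csv(out / "differential_abundance.tsv", sep="\t")
    filtered.rename_axis("feature").to_csv(
        out / "differential_abundance_filtered.tsv", sep="\t"
    )
    return {
        "n_tested": len(records),
        "n_significant": int((records["padj"] < cfg.alpha).sum()),
        "n_filtered": len(filtered),
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage that has inputs; return the combined summary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    if cfg.water_tsv is not None:
        try:
            report["geochem"] = _run_geochem(cfg, out)
            report["stages"].append("geochem")
        except Exception as e:  # noqa: BLE001 - stage name must be attached
            raise StageError("geochem", e) from e
    else:
        logger.info("geochem stage skipped: no water-sample input")

    if cfg.counts_tsv is not None:
        table = io.read_count_table(cfg.counts_tsv, cfg.metadata_tsv)
        try:
            report["ecology"] = _run_ecology(cfg, table, out)
            report["stages"].append("ecology")
        except Exception as e:
            raise StageError("ecology", e) from e
        try:
            report["diffabund"] = _run_diffabund(cfg, table, out)
            report["stages"].append("diffabund")
        except Exception as e:
            raise StageError("diffabund", e) from e
    else:
        logger.info("ecology/diffabund stages skipped: no count-table input")

    log = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(cfg).items()
        },
        "stages_run": report["stages"],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
    return report
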
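"""End-to-end pipeline: simulate → derive → associate → harmonize → estimate.

A scenario file (YAML) fixes the synthetic cohort (regions, truth, sample
sizes) and the analysis thresholds; a single master seed makes every
stage reproducible, and each stage's input/output counts are logged to a
provenance JSON echoing the instrument-derivation funnel.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ParameterError, PipelineStageError
from .harmonization import harmonize_all
from .instruments import (FunnelLog, InstrumentSet, derive_instruments,
                          load_gene_regions)
from .io import read_tsv, write_tsv
from .mr import estimate_all, forest_report
from .synthetic_cohort import (OutcomePanel, OutcomeTruth, RegionSpec,
                               TrioGenotypes, TruthRecord,
                               simulate_exposure_gwas, simulate_haplotype_panel,
                               simulate_outcomes, simulate_trios)
from .trio_association import association_table

__all__ = ["PipelineConfig", "run_pipeline", "bundled_scenario_path",
           "bundled_gene_regions_path"]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "p_threshold": 5e-8,
    "r2_threshold": 0.01,
    "maf_threshold": 0.42,
    "f_threshold": 10.0,
}
DEFAULT_N_FOUNDERS = 2000


def bundled_scenario_path() -> Path:
    return Path(resources.files("triomr") / "data" / "demo_scenario.yaml")


def bundled_gene_regions_path() -> Path:
    return Path(resources.files("triomr") / "data" / "gene_regions_synthetic.tsv")


@dataclass
class PipelineConfig:
    """Fully resolved pipeline configuration.

    ``truth.beta_snp_exposure`` is keyed by rsid; scenario files may
    instead give per-region ``causal`` maps from SNV index to per-allele
    mm-Hg effect, resolved here once region SNV ids are known.
    """

    regions: list[RegionSpec]
    truth: TruthRecord
    n_trios: int
    n_gwas: int
    n_founders: int = DEFAULT_N_FOUNDERS
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    regions_file: Path | None = None  # None -> bundled synthetic mapping

    def __post_init__(self):
        thr = self.thresholds
        if not (0 < thr["p_threshold"] <= 1):
            raise ParameterError("p_threshold must be in (0, 1]")
        if not (0 < thr["r2_threshold"] <= 1):
            raise ParameterError("r2_threshold must be in (0, 1]")
        if not (0 < thr["maf_threshold"] <= 0.5):
            raise ParameterError("maf_threshold must be in (0, 0.5]")
        if self.n_trios < 2 or self.n_gwas < 10:
            raise ParameterError("n_trios/n_gwas too small")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        regions = [RegionSpec.from_config(r) for r in raw["regions"]]

        beta_snp = {}
        for reg_cfg, reg in zip(raw["regions"], regions):
            for idx, beta in (reg_cfg.get("causal") or {}).items():
                beta_snp[reg.snv_ids[int(idx)]] = float(beta)

        outcomes = [OutcomeTruth(**o) for o in raw["outcomes"]]
        truth = TruthRecord(
            beta_snp_exposure=beta_snp,
            outcomes=outcomes,
            gwas_noise_sd=float(raw.get("gwas_noise_sd", 19.0)),
            gwas_intercept=float(raw.get("gwas_intercept", 135.0)),
        )
        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(raw.get("thresholds") or {})
        return cls(
            regions=regions,
            truth=truth,
            n_trios=int(raw["n_trios"]),
            n_gwas=int(raw["n_gwas"]),
            n_founders=int(raw.get("n_founders", DEFAULT_N_FOUNDERS)),
            thresholds=thresholds,
            regions_file=Path(raw["regions_file"]) if raw.get("regions_file") else None,
        )


def _instrument_table(sets: list[InstrumentSet]) -> pd.DataFrame:
    rows = []
    for s in sets:
        block = s.snvs.copy()
        block.insert(0, "drug_subclass", s.drug_subclass)
        block.insert(1, "mechanism_group", s.mechanism_group)
        block.insert(2, "genes", ";".join(s.genes))
        block["rationale"] = s.rationale
        rows.append(block)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def instrument_sets_from_table(table: pd.DataFrame) -> list[InstrumentSet]:
    """Rebuild :class:`InstrumentSet`s from a written instruments TSV."""
    sets = []
    stat_cols = [c for c in table.columns
                 if c not in ("drug_subclass", "mechanism_group", "genes", "rationale")]
    for (subclass, mech, genes), grp in table.groupby(
            ["drug_subclass", "mechanism_group", "genes"], sort=True):
        sets.append(InstrumentSet(
            drug_subclass=subclass,
            mechanism_group=mech,
            genes=tuple(genes.split(";")),
            snvs=grp[stat_cols].reset_index(drop=True),
            rationale=str(grp["rationale"].iloc[0]) if "rationale" in grp else "",
        ))
    return sets


def _pooled_parent_dosages(trios: TrioGenotypes) -> pd.DataFrame:
    """LD reference: mothers and fathers stacked as one population sample."""
    import numpy as np
    pooled = np.vstack([trios.dosage_m, trios.dosage_f])
    return pd.DataFrame(pooled, columns=trios.snv_ids)


def run_pipeline(config: PipelineConfig, seed: int, out_dir) -> Path:
    """Execute all stages, writing intermediates and results under ``out_dir``.

    Identical config and seed give byte-identical outputs. Any stage
    failure aborts with a :class:`PipelineStageError` naming the stage and
    carrying a machine-readable code (the underlying exception class).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("triomr")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)

    def _stage(name, fn):
        try:
            logger.info("stage %s: start", name)
            result = fn()
            logger.info("stage %s: done", name)
            return result
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineStageError(name, type(exc).__name__, exc) from exc

    try:
        # -- simulate ------------------------------------------------------
        def do_simulate():
            panels = [simulate_haplotype_panel(r, config.n_founders, seed)
                      for r in config.regions]
            trios = simulate_trios(panels, config.n_trios, seed)
            stats, excluded = simulate_exposure_gwas(
                panels, config.truth, config.n_gwas, seed)
            outcomes = simulate_outcomes(trios, config.truth, seed)
            if excluded:
                logger.warning("monomorphic SNVs excluded from GWAS: %s", excluded)
            write_tsv(stats, out / "summary_stats.tsv", seed=seed)
            for role, mat in (("maternal", trios.dosage_m),
                              ("paternal", trios.dosage_f),
                              ("offspring", trios.dosage_o)):
                write_tsv(pd.DataFrame(mat, columns=trios.snv_ids),
                          out / f"dosage_{role}.tsv", seed=seed)
            write_tsv(trios.snv_meta, out / "snv_meta.tsv", seed=seed)
            write_tsv(outcomes.data, out / "outcomes.tsv", seed=seed)
            (out / "truth.yaml").write_text(config.truth.to_yaml())
            return panels, trios, stats, outcomes

        panels, trios, stats, outcomes = _stage("simulate", do_simulate)

        # -- derive --------------------------------------------------------
        def do_derive():
            regions_path = config.regions_file or bundled_gene_regions_path()
            regions = load_gene_regions(regions_path)
            reference = _pooled_parent_dosages(trios)
            sets, funnel = derive_instruments(
                stats, regions, trios.snv_ids, reference,
                p_threshold=config.thresholds["p_threshold"],
                r2_threshold=config.thresholds["r2_threshold"],
            )
            write_tsv(_instrument_table(sets), out / "instruments.tsv", seed=seed)
            (out / "provenance.json").write_text(
                funnel.to_json(seed=seed, n_targets=len(sets)))
            return sets, funnel

        sets, funnel = _stage("derive", do_derive)

        # -- associate -----------------------------------------------------
        def do_associate():
            table = association_table(sets, trios, outcomes)
            write_tsv(table, out / "associations.tsv", seed=seed)
            return table

        associations = _stage("associate", do_associate)

        # -- harmonize -----------------------------------------------------
        def do_harmonize():
            exposure = pd.concat([s.snvs for s in sets], ignore_index=True)
            exposure = exposure.drop_duplicates(subset="rsid")
            maf_thr = config.thresholds["maf_threshold"]
            per_role = {}
            for role in ("maternal", "paternal", "offspring"):
                sub = associations[
                    (associations["role"] == role) & associations["converged"]
                ]
                drops = []
                for outcome in outcomes.outcome_names:
                    h, dlog = harmonize_all(
                        exposure, sub[sub["outcome"] == outcome], maf_thr)
                    h.insert(1, "outcome", outcome)
                    drops.append((outcome, h, dlog))
                harmonized = pd.concat([h for _, h, _ in drops], ignore_index=True)
                write_tsv(harmonized, out / f"harmonized_{role}.tsv", seed=seed)
                per_role[role] = harmonized
            drop_all = pd.concat(
                [h[h["dropped"]][["rsid", "outcome", "reason"]]
                 for h in per_role.values()], ignore_index=True)
            write_tsv(drop_all.drop_duplicates(), out / "drop_log.tsv", seed=seed)
            return per_role

        _stage("harmonize", do_harmonize)

        # -- estimate ------------------------------------------------------
        def do_estimate():
            results = estimate_all(
                sets, associations, outcomes.kinds,
                maf_threshold=config.thresholds["maf_threshold"])
            write_tsv(results, out / "results.tsv", seed=seed)
            (out / "forest_report.txt").write_text(forest_report(results))
            return results

        _stage("estimate", do_estimate)
        return out
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def results_checksum(run_dir) -> str:
    """SHA-256 of the results table (determinism check helper)."""
    data = (Path(run_dir) / "results.tsv").read_bytes()
    return hashlib.sha256(data).hexdigest()
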
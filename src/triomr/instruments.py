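"""Instrument derivation for drug-target MR.

Reproduces the funnel that turns a drug-subclass → gene → genomic-region
mapping plus exposure GWAS summary statistics into per-target instrument
sets:

1. extract all SNVs inside the mapped gene regions,
2. keep those present in both the exposure and outcome datasets,
3. keep those below the genome-wide significance threshold (P < 5e-8,
   strict),
4. LD-clump greedily at r² < 0.01 against a reference dosage panel,
5. group by drug subclass, splitting subclasses whose genes carry
   conflicting mechanism-of-action tags.

Every step logs input/output counts to a provenance funnel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

__all__ = [
    "GENE_REGION_COLUMNS",
    "FunnelLog",
    "InstrumentSet",
    "load_gene_regions",
    "extract_region_snvs",
    "intersect_datasets",
    "filter_genomewide",
    "ld_clump",
    "group_by_mechanism",
    "derive_instruments",
]

logger = logging.getLogger(__name__)

GENE_REGION_COLUMNS = [
    "drug_subclass", "bnf_code", "gene", "chrom", "start", "end", "mechanism",
]

GENOMEWIDE_P = 5e-8
CLUMP_R2 = 0.01
CLUMP_WINDOW_BP = 10_000_000  # cross-window pairs are assumed unlinked


class FunnelLog:
    """Ordered record of filter-step counts (the derivation funnel)."""

    def __init__(self):
        self.steps: list[dict] = []

    def record(self, stage: str, n_in: int, n_out: int, **detail):
        self.steps.append({"stage": stage, "n_in": int(n_in),
                           "n_out": int(n_out), **detail})

    def to_json(self, **extra) -> str:
        return json.dumps({"funnel": self.steps, **extra}, indent=2)

    def __repr__(self):
        inner = " -> ".join(f"{s['stage']}:{s['n_out']}" for s in self.steps)
        return f"FunnelLog({inner})"


@dataclass
class InstrumentSet:
    """Instruments for one drug target (subclass × mechanism group)."""

    drug_subclass: str
    mechanism_group: str
    genes: tuple[str, ...]
    snvs: pd.DataFrame  # exposure summary-stat rows, one per instrument SNV
    rationale: str = ""
    provenance: FunnelLog | None = field(default=None, repr=False)

    @property
    def label(self) -> str:
        return f"{self.drug_subclass} [{self.mechanism_group}]"

    @property
    def snv_ids(self) -> list[str]:
        return self.snvs["rsid"].tolist()

    @property
    def n_snps(self) -> int:
        return len(self.snvs)


def _normalize_rsid(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip().str.lower()


def load_gene_regions(mapping_file) -> pd.DataFrame:
    """Load and validate the drug-subclass → gene → region mapping TSV.

    Coordinates are 1-based inclusive. Rows with start > end are rejected
    by (1-based) row number; duplicated (gene, chrom, start, end) rows are
    rejected listing the offending genes. An empty file yields an empty
    frame with a logged warning.
    """
    regions = pd.read_csv(mapping_file, sep="\t", dtype={"chrom": str, "bnf_code": str})
    missing = [c for c in GENE_REGION_COLUMNS if c not in regions.columns]
    if missing:
        raise ValidationError(f"mapping file missing columns: {missing}")
    if regions.empty:
        logger.warning("gene-region mapping %s is empty", mapping_file)
        return regions

    bad = regions[regions["start"] > regions["end"]]
    if not bad.empty:
        rows = ", ".join(str(i + 1) for i in bad.index)
        raise ValidationError(f"start > end in mapping rows: {rows}")
    if (regions[["start", "end"]] <= 0).any().any():
        raise ValidationError("region coordinates must be positive (1-based)")

    dup = regions.duplicated(subset=["gene", "chrom", "start", "end"], keep=False)
    if dup.any():
        offenders = sorted(regions.loc[dup, "gene"].unique())
        raise ValidationError(f"duplicate region rows for genes: {offenders}")
    if regions["mechanism"].isna().any() or (regions["mechanism"].astype(str).str.strip() == "").any():
        raise ValidationError("every region row needs a mechanism tag")
    return regions


def extract_region_snvs(stats: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Keep SNVs lying inside any mapped region (1-based inclusive ends).

    Returns one row per (SNV, containing region): a SNV inside overlapping
    regions is annotated with each. Region columns (drug_subclass, gene,
    mechanism, ...) are appended to the summary-stat columns.
    """
    if stats.empty or regions.empty:
        return stats.iloc[0:0].assign(**{c: pd.Series(dtype=object)
                                         for c in GENE_REGION_COLUMNS})
    pieces = []
    for _, reg in regions.iterrows():
        hit = stats[
            (stats["chrom"].astype(str) == str(reg["chrom"]))
            & (stats["pos"] >= reg["start"])
            & (stats["pos"] <= reg["end"])
        ]
        if hit.empty:
            continue
        hit = hit.copy()
        for col in GENE_REGION_COLUMNS:
            hit[col] = reg[col]
        pieces.append(hit)
    if not pieces:
        return stats.iloc[0:0].assign(**{c: pd.Series(dtype=object)
                                         for c in GENE_REGION_COLUMNS})
    return pd.concat(pieces, ignore_index=True)


def intersect_datasets(
    exposure_snvs: pd.DataFrame, outcome_snv_ids: Iterable[str]
) -> pd.DataFrame:
    """Keep exposure SNVs whose rsid is also present in the outcome data.

    Matching is case-insensitive and whitespace-stripped; input order is
    preserved.
    """
    available = set(_normalize_rsid(pd.Series(list(outcome_snv_ids), dtype=object)))
    keep = _normalize_rsid(exposure_snvs["rsid"]).isin(available)
    return exposure_snvs.loc[keep].reset_index(drop=True)


def filter_genomewide(snvs: pd.DataFrame, threshold: float = GENOMEWIDE_P) -> pd.DataFrame:
    """Keep SNVs with p-value strictly below the significance threshold."""
    if not (0 < threshold <= 1):
        raise InputError("significance threshold must be in (0, 1]")
    return snvs.loc[snvs["pval"] < threshold].reset_index(drop=True)


def _reference_r2(
    x: np.ndarray, y: np.ndarray
) -> float:
    """Squared Pearson correlation of two dosage vectors (0 if degenerate)."""
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if den == 0.0:
        return 0.0
    return float(((xc * yc).sum() / den) ** 2)


def ld_clump(
    snvs: pd.DataFrame,
    reference_dosages: pd.DataFrame,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> pd.DataFrame:
    """Greedy LD clumping against a reference dosage panel.

    Repeatedly takes the remaining SNV with the lowest p-value (ties broken
    by ascending chromosome then position) as an index variant and removes
    every remaining SNV with reference r² >= ``r2_threshold`` against it.
    Pairs on different chromosomes, or further apart than ``window_bp``,
    are treated as unlinked. The retained set therefore has all pairwise
    r² below the threshold.
    """
    if snvs.empty:
        return snvs.reset_index(drop=True)
    missing = [rs for rs in snvs["rsid"].unique() if rs not in reference_dosages.columns]
    if missing:
        raise InputError(f"SNVs absent from LD reference: {missing}")

    work = snvs.drop_duplicates(subset="rsid").copy()
    chrom_sort = work["chrom"].astype(str)
    order = np.lexsort((work["pos"].to_numpy(), chrom_sort.to_numpy(),
                        work["pval"].to_numpy()))
    queue = work.iloc[order].reset_index(drop=True)

    kept_ids: list[str] = []
    remaining = queue
    while not remaining.empty:
        index_row = remaining.iloc[0]
        kept_ids.append(index_row["rsid"])
        rest = remaining.iloc[1:]
        if rest.empty:
            break
        x = reference_dosages[index_row["rsid"]].to_numpy(dtype=float)
        drop = []
        for _, row in rest.iterrows():
            linked = (
                str(row["chrom"]) == str(index_row["chrom"])
                and abs(int(row["pos"]) - int(index_row["pos"])) <= window_bp
            )
            if linked:
                y = reference_dosages[row["rsid"]].to_numpy(dtype=float)
                if _reference_r2(x, y) >= r2_threshold:
                    drop.append(row["rsid"])
        remaining = rest.loc[~rest["rsid"].isin(drop)].reset_index(drop=True)

    keep_mask = snvs["rsid"].isin(kept_ids)
    return snvs.loc[keep_mask].reset_index(drop=True)


def group_by_mechanism(
    snvs: pd.DataFrame, regions: pd.DataFrame | None = None
) -> list[InstrumentSet]:
    """Group instruments into drug targets by subclass and mechanism.

    ``snvs`` must carry region annotation (one row per SNV × region, as
    produced by :func:`extract_region_snvs`). Within a drug subclass, if
    every annotated gene shares one mechanism tag the SNVs form a single
    set (eligible for IVW); conflicting tags split the subclass into one
    set per mechanism, each carrying its rationale.
    """
    required = {"drug_subclass", "gene", "mechanism", "rsid"}
    if not required.issubset(snvs.columns):
        raise InputError(
            f"grouping needs region-annotated SNVs with columns {sorted(required)}"
        )
    if snvs["mechanism"].isna().any():
        bad = snvs.loc[snvs["mechanism"].isna(), "rsid"].tolist()
        raise InputError(f"SNVs with no mechanism tag: {bad}")

    stat_cols = [c for c in snvs.columns if c not in GENE_REGION_COLUMNS]
    sets: list[InstrumentSet] = []
    for subclass, sub in snvs.groupby("drug_subclass", sort=True):
        mechanisms = sorted(sub["mechanism"].unique())
        if len(mechanisms) == 1:
            rationale = f"single mechanism '{mechanisms[0]}' across genes"
            groups = [(mechanisms[0], sub)]
        else:
            rationale = (
                "conflicting mechanisms "
                + ", ".join(mechanisms)
                + " — subclass split per mechanism"
            )
            groups = [(mech, sub[sub["mechanism"] == mech]) for mech in mechanisms]
        for mech, grp in groups:
            uniq = grp.drop_duplicates(subset="rsid").sort_values(
                ["chrom", "pos"]).reset_index(drop=True)
            sets.append(InstrumentSet(
                drug_subclass=subclass,
                mechanism_group=mech,
                genes=tuple(sorted(grp["gene"].unique())),
                snvs=uniq[stat_cols],
                rationale=rationale,
            ))
    return sets


def derive_instruments(
    stats: pd.DataFrame,
    regions: pd.DataFrame,
    outcome_snv_ids: Sequence[str],
    reference_dosages: pd.DataFrame,
    p_threshold: float = GENOMEWIDE_P,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> tuple[list[InstrumentSet], FunnelLog]:
    """Run the whole derivation funnel and return targets with provenance."""
    log = FunnelLog()

    annotated = extract_region_snvs(stats, regions)
    log.record("extract_region_snvs", len(stats), annotated["rsid"].nunique(),
               n_regions=int(len(regions)))

    shared = intersect_datasets(annotated, outcome_snv_ids)
    log.record("intersect_datasets", annotated["rsid"].nunique(),
               shared["rsid"].nunique())

    significant = filter_genomewide(shared, p_threshold)
    log.record("filter_genomewide", shared["rsid"].nunique(),
               significant["rsid"].nunique(), p_threshold=p_threshold)

    clumped = ld_clump(significant, reference_dosages, r2_threshold, window_bp)
    log.record("ld_clump", significant["rsid"].nunique(),
               clumped["rsid"].nunique(), r2_threshold=r2_threshold)

    sets = group_by_mechanism(clumped)
    log.record("group_by_mechanism", clumped["rsid"].nunique(), len(sets))
    for s in sets:
        s.provenance = log
    return sets, log
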
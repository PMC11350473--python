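"""Synthetic trio cohort and exposure-GWAS generator.

This module produces the two samples a two-sample intergenerational MR
analysis needs, with known ground truth:

* a *trio sample* — mother/father/offspring genotype dosages over gene-scale
  SNV panels with tunable linkage disequilibrium, plus offspring outcomes
  generated from a causal structure in which maternal, paternal and
  offspring allele scores (in mm Hg of systolic blood pressure) can each
  have their own effect on the outcome; and
* an independent *exposure sample* — per-SNV marginal summary statistics
  from a simulated SBP GWAS of unrelated individuals drawn from the same
  haplotype frequencies.

Mendelian transmission is exact (no mutation, no within-region
recombination): each offspring inherits one whole regional haplotype from
each parent. The true causal effects are expressed per 10-mm-Hg *decrease*
in SBP so that downstream causal estimates can be compared to the truth
without unit conversion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ._rng import component_rng
from .errors import InputError, ParameterError

__all__ = [
    "RegionSpec",
    "HaplotypePanel",
    "TrioGenotypes",
    "OutcomeTruth",
    "TruthRecord",
    "OutcomePanel",
    "simulate_haplotype_panel",
    "simulate_trios",
    "simulate_exposure_gwas",
    "simulate_outcomes",
    "mendelian_consistency",
    "SUMMARY_COLUMNS",
]

#: Column contract for exposure summary-statistic tables.
SUMMARY_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

# Default non-palindromic allele pairs cycled over SNVs within a region.
_DEFAULT_ALLELES = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
_PALINDROMIC_ALLELES = ("A", "T")

#: Proportion of female offspring in the emulated cohort.
FEMALE_FRACTION = 0.489
#: Parental age distributions (years): means from the emulated cohort.
MATERNAL_AGE_MEAN, PATERNAL_AGE_MEAN, PARENTAL_AGE_SD = 30.2, 32.8, 5.0
#: Number of genotyping batches and ancestry principal components.
N_BATCHES, N_PCS = 3, 20


# ---------------------------------------------------------------------------
# region specification


@dataclass(frozen=True)
class RegionSpec:
    """Specification of one gene-scale SNV region to simulate."""

    region_id: str
    chrom: str
    positions: tuple[int, ...]
    maf: tuple[float, ...]
    ld_r: float
    snv_ids: tuple[str, ...] = ()
    effect_alleles: tuple[str, ...] = ()
    other_alleles: tuple[str, ...] = ()

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        if pos.size == 0:
            raise ParameterError(f"region {self.region_id}: no positions")
        if np.any(np.diff(pos) <= 0):
            raise ParameterError(
                f"region {self.region_id}: positions must be strictly increasing"
            )
        maf = np.asarray(self.maf, dtype=float)
        if maf.shape != pos.shape:
            raise ParameterError(
                f"region {self.region_id}: maf and positions length mismatch"
            )
        if np.any(maf <= 0.01) or np.any(maf > 0.5):
            raise ParameterError(
                f"region {self.region_id}: maf must lie in (0.01, 0.5]"
            )
        if not (0.0 <= self.ld_r < 1.0):
            raise ParameterError(
                f"region {self.region_id}: ld_r must lie in [0, 1)"
            )
        if not self.snv_ids:
            ids = tuple(f"rs{self.chrom}{p:08d}" for p in pos)
            object.__setattr__(self, "snv_ids", ids)
        if len(set(self.snv_ids)) != len(self.snv_ids):
            raise ParameterError(f"region {self.region_id}: duplicate snv_ids")
        if not self.effect_alleles:
            pairs = [_DEFAULT_ALLELES[i % 4] for i in range(len(pos))]
            object.__setattr__(self, "effect_alleles", tuple(p[0] for p in pairs))
            object.__setattr__(self, "other_alleles", tuple(p[1] for p in pairs))

    @property
    def n_snvs(self) -> int:
        return len(self.positions)

    @classmethod
    def from_config(cls, cfg: Mapping) -> "RegionSpec":
        """Build a spec from a scenario-file mapping.

        Positions may be explicit (``positions``) or arithmetic
        (``n_snvs`` + ``start`` + ``spacing``); ``maf`` may be a scalar or a
        list; ``palindromic`` lists SNV indices given strand-ambiguous A/T
        alleles (for exercising harmonization).
        """
        if "positions" in cfg:
            positions = tuple(int(p) for p in cfg["positions"])
        else:
            n, start, step = int(cfg["n_snvs"]), int(cfg["start"]), int(cfg["spacing"])
            positions = tuple(start + i * step for i in range(n))
        maf = cfg["maf"]
        maf = tuple(float(m) for m in maf) if isinstance(maf, (list, tuple)) \
            else (float(maf),) * len(positions)
        m = len(positions)
        pairs = [_DEFAULT_ALLELES[i % 4] for i in range(m)]
        for idx in cfg.get("palindromic", []):
            pairs[int(idx)] = _PALINDROMIC_ALLELES
        return cls(
            region_id=str(cfg["region_id"]),
            chrom=str(cfg["chrom"]),
            positions=positions,
            maf=maf,
            ld_r=float(cfg.get("ld_r", 0.0)),
            effect_alleles=tuple(p[0] for p in pairs),
            other_alleles=tuple(p[1] for p in pairs),
        )


# ---------------------------------------------------------------------------
# haplotype panel


@dataclass
class HaplotypePanel:
    """Founder haplotypes for one region (two per founder).

    ``haplotypes`` is a (2 * n_founders, n_snvs) binary matrix of
    effect-allele indicators. Adjacent-SNV LD follows a Gaussian-copula
    AR(1) construction: a latent standard-normal process with lag-one
    correlation ``ld_r`` is thresholded at the per-SNV allele-frequency
    quantile, so one parameter gives monotonically tunable adjacent r².
    """

    region_id: str
    chrom: str
    snv_ids: list[str]
    positions: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]
    maf: np.ndarray
    ld_r: float
    haplotypes: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0] // 2

    def allele_freqs(self) -> np.ndarray:
        """Empirical effect-allele frequency per SNV."""
        return self.haplotypes.mean(axis=0)

    def ld_matrix(self) -> np.ndarray:
        """Pairwise haplotype r² computed from first principles.

        Uses explicit centred cross-products (not a library correlation
        routine) so tests can cross-check it independently. Monomorphic
        columns yield NaN rows/columns.
        """
        h = self.haplotypes.astype(float)
        hc = h - h.mean(axis=0)
        cov = hc.T @ hc / h.shape[0]
        sd = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cov / np.outer(sd, sd)
        return r ** 2

    def snv_meta(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rsid": self.snv_ids,
            "chrom": self.chrom,
            "pos": self.positions,
            "effect_allele": self.effect_alleles,
            "other_allele": self.other_alleles,
            "region_id": self.region_id,
        })


def simulate_haplotype_panel(
    region_spec: RegionSpec, n_founders: int, seed: int
) -> HaplotypePanel:
    """Simulate founder haplotypes for one region.

    Parameters
    ----------
    region_spec
        Region layout: positions, per-SNV allele frequencies, adjacent
        latent LD ``ld_r``.
    n_founders
        Number of founders; twice as many haplotypes are drawn.
    seed
        Master seed; the panel uses the ``panel:<region_id>`` substream.
    """
    if n_founders < 2:
        raise ParameterError("n_founders must be >= 2")
    rng = component_rng(seed, f"panel:{region_spec.region_id}")
    m = region_spec.n_snvs
    n_hap = 2 * n_founders
    rho = region_spec.ld_r

    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    scale = np.sqrt(1.0 - rho ** 2)
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + scale * rng.standard_normal(n_hap)
    thresholds = stats.norm.ppf(np.asarray(region_spec.maf))
    haplotypes = (z < thresholds).astype(np.uint8)

    return HaplotypePanel(
        region_id=region_spec.region_id,
        chrom=region_spec.chrom,
        snv_ids=list(region_spec.snv_ids),
        positions=np.asarray(region_spec.positions, dtype=np.int64),
        effect_alleles=list(region_spec.effect_alleles),
        other_alleles=list(region_spec.other_alleles),
        maf=np.asarray(region_spec.maf, dtype=float),
        ld_r=rho,
        haplotypes=haplotypes,
    )


# ---------------------------------------------------------------------------
# trios


@dataclass
class TrioGenotypes:
    """Effect-allele dosage matrices for mothers, fathers and offspring.

    Rows index trios; columns index SNVs (concatenated across regions, in
    ``snv_ids`` order). ``snv_meta`` carries per-SNV chromosome, position,
    alleles and source region.
    """

    n_trios: int
    snv_ids: list[str]
    dosage_m: np.ndarray
    dosage_f: np.ndarray
    dosage_o: np.ndarray
    snv_meta: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        shapes = {self.dosage_m.shape, self.dosage_f.shape, self.dosage_o.shape}
        if len(shapes) != 1:
            raise InputError("dosage matrices have mismatched shapes")
        if self.dosage_m.shape != (self.n_trios, len(self.snv_ids)):
            raise InputError("dosage shape does not match n_trios x n_snvs")

    def dosage(self, role: str) -> np.ndarray:
        return {"maternal": self.dosage_m,
                "paternal": self.dosage_f,
                "offspring": self.dosage_o}[role]

    def column(self, rsid: str, role: str) -> np.ndarray:
        try:
            j = self.snv_ids.index(rsid)
        except ValueError:
            raise InputError(f"SNV {rsid!r} not present in trio dosages") from None
        return self.dosage(role)[:, j]


def _sample_genotypes(
    panel: HaplotypePanel, n: int, rng: np.random.Generator, resample: bool,
    offset: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n individuals' haplotype pairs from the founder pool.

    Returns the two haplotype matrices (each n x m). With ``resample``
    haplotypes are drawn with replacement; otherwise founders ``offset`` to
    ``offset + n - 1`` contribute their own pairs.
    """
    if resample:
        idx = rng.integers(0, panel.n_haplotypes, size=(n, 2))
        return panel.haplotypes[idx[:, 0]], panel.haplotypes[idx[:, 1]]
    if panel.n_founders < offset + n:
        raise InputError(
            f"panel {panel.region_id} has {panel.n_founders} founders; "
            f"{offset + n} required without resampling"
        )
    rows = np.arange(offset, offset + n)
    return panel.haplotypes[2 * rows], panel.haplotypes[2 * rows + 1]


def simulate_trios(
    panels: HaplotypePanel | Sequence[HaplotypePanel],
    n_trios: int,
    seed: int,
    resample: bool = True,
) -> TrioGenotypes:
    """Simulate mother-father-offspring trios from founder haplotypes.

    Each parent is two haplotypes sampled from the founder pool; the
    offspring inherits exactly one whole haplotype per parent per region
    (no within-region recombination, no mutation), so Mendelian
    consistency holds for every trio-SNV cell by construction.

    With ``resample=False`` the panel must hold at least ``2 * n_trios``
    founder pairs; mothers take the first block and fathers the second,
    guaranteeing distinct founders.
    """
    if isinstance(panels, HaplotypePanel):
        panels = [panels]
    if not panels:
        raise InputError("no haplotype panels supplied")
    if n_trios < 1:
        raise ParameterError("n_trios must be >= 1")

    rng = component_rng(seed, "trios")
    dm, df_, do, metas, snv_ids = [], [], [], [], []
    for panel in panels:
        m1, m2 = _sample_genotypes(panel, n_trios, rng, resample, offset=0)
        f1, f2 = _sample_genotypes(panel, n_trios, rng, resample, offset=n_trios)
        # transmitted haplotype choice: one fair coin per parent per region
        tm = rng.integers(0, 2, size=n_trios)[:, None]
        tf = rng.integers(0, 2, size=n_trios)[:, None]
        child_m = np.where(tm == 0, m1, m2)
        child_f = np.where(tf == 0, f1, f2)
        dm.append((m1 + m2).astype(np.int8))
        df_.append((f1 + f2).astype(np.int8))
        do.append((child_m + child_f).astype(np.int8))
        metas.append(panel.snv_meta())
        snv_ids.extend(panel.snv_ids)

    return TrioGenotypes(
        n_trios=n_trios,
        snv_ids=snv_ids,
        dosage_m=np.hstack(dm),
        dosage_f=np.hstack(df_),
        dosage_o=np.hstack(do),
        snv_meta=pd.concat(metas, ignore_index=True),
    )


def mendelian_consistency(trios: TrioGenotypes) -> float:
    """Fraction of trio-SNV cells consistent with Mendelian transmission.

    Checked independently of how the offspring dosages were produced: a
    parent with dosage 0/1/2 can transmit {0}/{0,1}/{1} effect alleles, so
    the offspring dosage must lie between the summed minima and maxima.
    Under the no-mutation generator this is exactly 1.0.
    """
    gm, gf, go = trios.dosage_m, trios.dosage_f, trios.dosage_o
    lo = (gm == 2).astype(np.int8) + (gf == 2).astype(np.int8)
    hi = (gm > 0).astype(np.int8) + (gf > 0).astype(np.int8)
    ok = (go >= lo) & (go <= hi)
    return float(ok.mean())


# ---------------------------------------------------------------------------
# truth record


@dataclass
class OutcomeTruth:
    """True generative parameters for one offspring outcome.

    Causal effects are per 10-mm-Hg *decrease* in the relevant allele
    score: ``beta_m10`` (maternal, the MR estimand), ``beta_p10``
    (paternal, the negative-control path) and ``beta_o10`` (offspring
    direct genetic effect). For binary outcomes they are log odds ratios
    and ``intercept`` is the logistic intercept; for continuous outcomes
    ``noise_sd`` is the residual SD.
    """

    name: str
    kind: str  # "continuous" | "binary"
    beta_m10: float = 0.0
    beta_p10: float = 0.0
    beta_o10: float = 0.0
    covariate_effects: dict = field(default_factory=dict)
    noise_sd: float | None = 1.0
    intercept: float = 0.0

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ParameterError(f"unknown outcome kind {self.kind!r}")


@dataclass
class TruthRecord:
    """Exact generator parameters, serializable for round-trip checks."""

    beta_snp_exposure: dict  # rsid -> per-allele SBP effect (mm Hg)
    outcomes: list[OutcomeTruth]
    gwas_noise_sd: float = 19.0
    gwas_intercept: float = 135.0

    def outcome(self, name: str) -> OutcomeTruth:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise InputError(f"no outcome named {name!r} in truth record")

    def to_yaml(self) -> str:
        payload = dataclasses.asdict(self)
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TruthRecord":
        payload = yaml.safe_load(text)
        outcomes = [OutcomeTruth(**o) for o in payload.pop("outcomes")]
        return cls(outcomes=outcomes, **payload)


# ---------------------------------------------------------------------------
# exposure GWAS


def simulate_exposure_gwas(
    panels: HaplotypePanel | Sequence[HaplotypePanel],
    truth: TruthRecord,
    n_gwas: int,
    seed: int,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate marginal SBP GWAS summary statistics from unrelated individuals.

    Individuals are drawn afresh from the founder haplotype frequencies
    under the ``gwas`` substream, so the exposure sample shares no
    individual with the trio sample (two-sample design). SBP is the
    per-allele truth effects applied to the dosages plus Normal noise, and
    each SNV gets an *unadjusted* least-squares regression of SBP on
    dosage: beta, SE, normal-reference p-value, effect-allele frequency
    and sample size.

    Returns the summary table and the rsids of SNVs monomorphic in the
    sample (flagged and excluded from the table).
    """
    if isinstance(panels, HaplotypePanel):
        panels = [panels]
    if n_gwas < 10:
        raise ParameterError("n_gwas must be >= 10")
    rng = component_rng(seed, "gwas")

    dosage_blocks, metas = [], []
    for panel in panels:
        h1, h2 = _sample_genotypes(panel, n_gwas, rng, resample=True)
        dosage_blocks.append((h1 + h2).astype(np.int8))
        metas.append(panel.snv_meta())
    X = np.hstack(dosage_blocks).astype(float)
    meta = pd.concat(metas, ignore_index=True)

    beta_true = np.array(
        [truth.beta_snp_exposure.get(rs, 0.0) for rs in meta["rsid"]]
    )
    sbp = (
        truth.gwas_intercept
        + X @ beta_true
        + rng.normal(0.0, truth.gwas_noise_sd, size=n_gwas)
    )

    xm = X.mean(axis=0)
    xc = X - xm
    yc = sbp - sbp.mean()
    sxx = (xc ** 2).sum(axis=0)
    monomorphic = sxx == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xc.T @ yc / sxx
        rss = (yc ** 2).sum() - beta * (xc.T @ yc)
        sigma2 = rss / (n_gwas - 2)
        se = np.sqrt(sigma2 / sxx)
        zval = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))

    out = meta[["rsid", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out["eaf"] = xm / 2.0
    out["beta"] = beta
    out["se"] = se
    out["pval"] = np.clip(pval, np.nextafter(0, 1), 1.0)
    out["n"] = n_gwas
    excluded = out.loc[monomorphic, "rsid"].tolist()
    return out.loc[~monomorphic].reset_index(drop=True), excluded


# ---------------------------------------------------------------------------
# outcomes


@dataclass
class OutcomePanel:
    """Per-trio outcomes and covariates (complete cases by construction).

    ``data`` holds one row per trio with covariate columns (``sex``,
    ``age_m``, ``age_f``, ``batch``, ``pc1``..``pc20``) and one column per
    outcome; ``kinds`` maps outcome name to ``continuous``/``binary``.
    """

    data: pd.DataFrame
    kinds: dict

    @property
    def outcome_names(self) -> list[str]:
        return list(self.kinds)

    @property
    def covariate_columns(self) -> list[str]:
        pcs = [c for c in self.data.columns if c.startswith("pc")]
        return ["sex", "age_m", "age_f", "batch"] + pcs


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cov = pd.DataFrame({
        "sex": rng.binomial(1, FEMALE_FRACTION, size=n),
        "age_m": rng.normal(MATERNAL_AGE_MEAN, PARENTAL_AGE_SD, size=n),
        "age_f": rng.normal(PATERNAL_AGE_MEAN, PARENTAL_AGE_SD, size=n),
        "batch": rng.integers(1, N_BATCHES + 1, size=n),
    })
    cov["batch"] = "b" + cov["batch"].astype(str)
    for k in range(1, N_PCS + 1):
        cov[f"pc{k}"] = rng.standard_normal(n)
    return cov


def _covariate_design(cov: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    """Linear contribution of covariates given named effect sizes.

    Batch effects are keyed ``batch_b2``/``batch_b3`` relative to the
    reference level ``b1``; unrecognized keys raise to catch typos.
    """
    eta = np.zeros(len(cov))
    for key, val in effects.items():
        if key.startswith("batch_"):
            eta += (cov["batch"] == key.removeprefix("batch_")).to_numpy() * val
        elif key in cov.columns:
            eta += cov[key].to_numpy(dtype=float) * val
        else:
            raise ParameterError(f"unknown covariate effect {key!r}")
    return eta


def allele_scores(trios: TrioGenotypes, truth: TruthRecord) -> dict[str, np.ndarray]:
    """Per-role allele scores in mm Hg: dosage times per-allele SBP effect."""
    beta = np.array(
        [truth.beta_snp_exposure.get(rs, 0.0) for rs in trios.snv_ids]
    )
    return {
        "m": trios.dosage_m @ beta,
        "f": trios.dosage_f @ beta,
        "o": trios.dosage_o @ beta,
    }


def simulate_outcomes(
    trios: TrioGenotypes, truth: TruthRecord, seed: int
) -> OutcomePanel:
    """Generate offspring outcomes from the causal truth structure.

    The linear predictor injects each role's mm-Hg allele score with slope
    ``-beta_x10 / 10``, so the causal effect of a 10-mm-Hg *decrease* in
    the score equals ``beta_x10`` exactly — the quantity the MR pipeline
    estimates. Continuous outcomes add Normal(0, noise_sd) residuals;
    binary outcomes pass the predictor through a logistic link.
    """
    rng = component_rng(seed, "outcomes")
    scores = allele_scores(trios, truth)
    cov = _simulate_covariates(trios.n_trios, rng)

    data = cov.copy()
    kinds = {}
    for spec in truth.outcomes:
        eta = (
            spec.intercept
            + (-spec.beta_m10 / 10.0) * scores["m"]
            + (-spec.beta_p10 / 10.0) * scores["f"]
            + (-spec.beta_o10 / 10.0) * scores["o"]
            + _covariate_design(cov, spec.covariate_effects)
        )
        if spec.kind == "continuous":
            y = eta + rng.normal(0.0, spec.noise_sd, size=trios.n_trios)
        else:
            p = 1.0 / (1.0 + np.exp(-eta))
            y = rng.binomial(1, p).astype(float)
        data[spec.name] = y
        kinds[spec.name] = spec.kind
    return OutcomePanel(data=data, kinds=kinds)
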
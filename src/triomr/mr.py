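"""Causal-effect estimation: Wald ratio, fixed-effect IVW, diagnostics.

Per-SNV causal estimates are Wald ratios — the harmonized SNV-outcome
beta divided by the SNV-exposure beta — with the first-order delta-method
standard error that treats the exposure beta as known (standard in
two-sample summary-data MR, where the exposure GWAS is far larger than
the outcome sample). Multi-SNV targets combine ratios with fixed-effect
inverse-variance weights; a single SNV reduces exactly to the Wald ratio.

Estimates are computed per 1-mm-Hg *increase* in systolic blood pressure
and rescaled to a 10-mm-Hg *decrease* (multiplying by -10), the magnitude
of blood-pressure lowering typical of antihypertensive treatment, so the
reported effect reads as "what a treatment-sized reduction would do".
Binary-outcome estimates are exponentiated to odds ratios. Instrument
strength is screened with per-SNV and mean F statistics (F = (beta/se)²,
weak below 10), and the paternal estimate serves as a negative control:
paternal alleles share the familial confounding structure but cannot act
through the intrauterine environment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .instruments import InstrumentSet

__all__ = [
    "Z_95",
    "F_WEAK_THRESHOLD",
    "MRResult",
    "FStatReport",
    "wald_ratio",
    "ivw",
    "scale_per_10mmhg_decrease",
    "to_odds_ratio",
    "f_statistics",
    "negative_control_contrast",
    "estimate_target",
    "estimate_all",
    "forest_report",
    "RESULT_COLUMNS",
]

Z_95 = 1.959964  # normal 97.5% quantile, summary-data MR convention
F_WEAK_THRESHOLD = 10.0

RESULT_COLUMNS = [
    "drug_subclass", "mechanism_group", "genes", "outcome", "role", "method",
    "n_snps", "estimate_10", "se_10", "ci_low_10", "ci_high_10",
    "or_10", "or_ci_low_10", "or_ci_high_10", "mean_f", "weak_flag", "snv_ids",
]


@dataclass
class MRResult:
    """One drug-target causal estimate per 10-mm-Hg decrease in SBP."""

    drug_subclass: str
    mechanism_group: str
    genes: tuple[str, ...]
    outcome: str
    role: str
    method: str  # "wald" | "ivw"
    n_snps: int
    estimate_10: float
    se_10: float
    ci_low_10: float
    ci_high_10: float
    snv_ids: tuple[str, ...]
    or_scale: tuple[float, float, float] | None = None  # (OR, low, high)
    mean_f: float = float("nan")
    weak_flag: bool = False


@dataclass
class FStatReport:
    """Per-SNV instrument-strength F statistics for one target."""

    snv_ids: tuple[str, ...]
    f_values: tuple[float, ...]
    mean_f: float
    weak_flag: bool  # any F <= 10


def wald_ratio(beta_exp: float, beta_out: float, se_out: float) -> tuple[float, float]:
    """Single-SNV causal estimate per 1-mm-Hg increase in the exposure.

    estimate = beta_out / beta_exp; se = se_out / |beta_exp| (first-order
    delta method, exposure beta treated as fixed).
    """
    if beta_exp == 0:
        raise InputError("Wald ratio undefined: exposure beta is zero")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def ivw(pairs: pd.DataFrame) -> tuple[float, float]:
    """Fixed-effect inverse-variance-weighted estimate over harmonized pairs.

    ``pairs`` needs columns beta_exp, beta_out, se_out. Each SNV's Wald
    ratio r_i is weighted by w_i = (beta_exp_i / se_out_i)^2 — the inverse
    of its delta-method variance — giving estimate sum(w r)/sum(w) and
    se = sum(w)^{-1/2}. With one pair this is exactly the Wald ratio.
    """
    if len(pairs) == 0:
        raise InputError("IVW requires at least one harmonized pair")
    be = pairs["beta_exp"].to_numpy(dtype=float)
    bo = pairs["beta_out"].to_numpy(dtype=float)
    so = pairs["se_out"].to_numpy(dtype=float)
    if np.any(be == 0):
        raise InputError("IVW requires all exposure betas nonzero")
    if len(be) == 1:  # exact reduction, bit-identical to the Wald ratio
        return wald_ratio(float(be[0]), float(bo[0]), float(so[0]))
    w = (be / so) ** 2
    r = bo / be
    estimate = float(np.sum(w * r) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return estimate, se


def scale_per_10mmhg_decrease(estimate: float, se: float) -> tuple[float, float, float, float]:
    """Rescale a per-1-mm-Hg-increase estimate to per 10-mm-Hg decrease.

    Returns (estimate_10, se_10, ci_low_10, ci_high_10) with a 95% normal
    interval. The sign flips because the reporting direction is a
    *decrease*.
    """
    est10 = -10.0 * estimate
    se10 = 10.0 * se
    return est10, se10, est10 - Z_95 * se10, est10 + Z_95 * se10


def to_odds_ratio(estimate_10: float, ci_low_10: float, ci_high_10: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds triple to the odds-ratio scale (order kept)."""
    return math.exp(estimate_10), math.exp(ci_low_10), math.exp(ci_high_10)


def f_statistics(exp_records: pd.DataFrame) -> FStatReport:
    """Instrument-strength report: per-SNV F = (beta/se)², group mean.

    ``weak_flag`` is set when any individual F is at or below 10, the
    conventional weak-instrument threshold.
    """
    if (exp_records["se"] <= 0).any():
        raise InputError("F statistic requires positive exposure SEs")
    f = (exp_records["beta"].to_numpy(dtype=float)
         / exp_records["se"].to_numpy(dtype=float)) ** 2
    return FStatReport(
        snv_ids=tuple(exp_records["rsid"]),
        f_values=tuple(float(v) for v in f),
        mean_f=float(f.mean()),
        weak_flag=bool((f <= F_WEAK_THRESHOLD).any()),
    )


def negative_control_contrast(maternal: MRResult, paternal: MRResult) -> dict:
    """Contrast the maternal estimate against the paternal negative control.

    If instrument effects reach the offspring through the intrauterine
    environment, the maternal estimate should differ from the paternal
    one; a shared familial path moves both alike. Returns the difference
    (maternal minus paternal), its SE (independent-samples), z and a
    two-sided p — interpretation is left to the reader, as point estimates
    this imprecise are compared qualitatively.
    """
    same = (
        maternal.drug_subclass == paternal.drug_subclass
        and maternal.mechanism_group == paternal.mechanism_group
        and maternal.outcome == paternal.outcome
        and maternal.method == paternal.method
    )
    if not same or maternal.role != "maternal" or paternal.role != "paternal":
        raise InputError("contrast requires maternal vs paternal results "
                         "for the same target, outcome and method")
    diff = maternal.estimate_10 - paternal.estimate_10
    se = math.hypot(maternal.se_10, paternal.se_10)
    z = diff / se if se > 0 else float("nan")
    p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else float("nan")
    return {
        "drug_subclass": maternal.drug_subclass,
        "mechanism_group": maternal.mechanism_group,
        "outcome": maternal.outcome,
        "difference": diff,
        "se_diff": se,
        "z": z,
        "pval": p,
    }


# ---------------------------------------------------------------------------
# drivers


def estimate_target(
    target: InstrumentSet,
    harmonized: pd.DataFrame,
    outcome: str,
    role: str,
    binary: bool,
) -> MRResult:
    """Estimate one target × outcome × role from harmonized pairs.

    ``harmonized`` is the retained output of harmonization for this
    outcome and role; only rows for the target's SNVs are used. Drops any
    pair flagged dropped upstream.
    """
    pairs = harmonized[
        harmonized["rsid"].isin(target.snv_ids) & ~harmonized["dropped"]
    ]
    if pairs.empty:
        raise InputError(
            f"no usable harmonized pairs for {target.label} / {outcome}"
        )
    if len(pairs) == 1:
        row = pairs.iloc[0]
        est, se = wald_ratio(row["beta_exp"], row["beta_out"], row["se_out"])
        method = "wald"
    else:
        est, se = ivw(pairs)
        method = "ivw"
    est10, se10, lo, hi = scale_per_10mmhg_decrease(est, se)

    fstat = f_statistics(
        pairs.rename(columns={"beta_exp": "beta", "se_exp": "se"})
    )
    return MRResult(
        drug_subclass=target.drug_subclass,
        mechanism_group=target.mechanism_group,
        genes=target.genes,
        outcome=outcome,
        role=role,
        method=method,
        n_snps=len(pairs),
        estimate_10=est10,
        se_10=se10,
        ci_low_10=lo,
        ci_high_10=hi,
        snv_ids=tuple(pairs["rsid"]),
        or_scale=to_odds_ratio(est10, lo, hi) if binary else None,
        mean_f=fstat.mean_f,
        weak_flag=fstat.weak_flag,
    )


def estimate_all(
    targets: list[InstrumentSet],
    associations: pd.DataFrame,
    outcome_kinds: dict,
    maf_threshold: float = 0.42,
) -> pd.DataFrame:
    """Estimate every target × outcome × role; returns a tidy results table.

    ``associations`` is the trio association table (one row per SNV ×
    outcome × role with both alleles and eaf). Harmonization is applied
    per outcome × role against each target's exposure records.
    Non-converged association rows are excluded with the pair.
    """
    from .harmonization import harmonize_all  # local import avoids cycle

    rows = []
    for target in targets:
        exp = target.snvs
        for outcome, kind in outcome_kinds.items():
            for role in ("maternal", "paternal", "offspring"):
                sub = associations[
                    (associations["outcome"] == outcome)
                    & (associations["role"] == role)
                    & associations["converged"]
                    & associations["rsid"].isin(target.snv_ids)
                ]
                if sub.empty:
                    continue
                harmonized, _ = harmonize_all(exp, sub, maf_threshold)
                usable = harmonized[~harmonized["dropped"]]
                if usable.empty:
                    continue
                res = estimate_target(target, harmonized, outcome, role,
                                      binary=(kind == "binary"))
                d = {
                    "drug_subclass": res.drug_subclass,
                    "mechanism_group": res.mechanism_group,
                    "genes": ";".join(res.genes),
                    "outcome": res.outcome,
                    "role": res.role,
                    "method": res.method,
                    "n_snps": res.n_snps,
                    "estimate_10": res.estimate_10,
                    "se_10": res.se_10,
                    "ci_low_10": res.ci_low_10,
                    "ci_high_10": res.ci_high_10,
                    "or_10": res.or_scale[0] if res.or_scale else float("nan"),
                    "or_ci_low_10": res.or_scale[1] if res.or_scale else float("nan"),
                    "or_ci_high_10": res.or_scale[2] if res.or_scale else float("nan"),
                    "mean_f": res.mean_f,
                    "weak_flag": res.weak_flag,
                    "snv_ids": ";".join(res.snv_ids),
                }
                rows.append(d)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def forest_report(results: pd.DataFrame) -> str:
    """Plain-text forest-style report, one block per outcome.

    Binary outcomes print odds ratios, continuous outcomes mean
    differences, both per 10-mm-Hg decrease in SBP.
    """
    lines = []
    for outcome, block in results.groupby("outcome", sort=True):
        lines.append(f"Outcome: {outcome}")
        lines.append("-" * (9 + len(outcome)))
        for role, sub in block.groupby("role", sort=True):
            lines.append(f"  [{role}]")
            for _, r in sub.iterrows():
                binary = not math.isnan(r["or_10"])
                if binary:
                    est = (f"OR {r['or_10']:.2f} "
                           f"({r['or_ci_low_10']:.2f} to {r['or_ci_high_10']:.2f})")
                else:
                    est = (f"{r['estimate_10']:+.2f} "
                           f"({r['ci_low_10']:+.2f} to {r['ci_high_10']:+.2f})")
                weak = " WEAK" if r["weak_flag"] else ""
                lines.append(
                    f"    {r['drug_subclass']} [{r['mechanism_group']}] "
                    f"({r['genes']}): {est} per 10-mm-Hg decrease, "
                    f"{r['method']} n_snps={r['n_snps']} "
                    f"mean F={r['mean_f']:.1f}{weak}"
                )
        lines.append("")
    return "\n".join(lines)
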
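"""Trio-conditional SNV-outcome association.

One joint regression per (SNV, outcome) of the offspring outcome on the
maternal, paternal and offspring dosage of that SNV — plus offspring sex,
parental ages (linear), genotyping batch (dummy-coded, first level as
reference) and the top ancestry principal components — yields the three
role-specific coefficients from a single fit. Conditioning the maternal
coefficient on the paternal and offspring genotypes blocks the
direct-inheritance path, which is what makes the maternal estimate usable
as an instrument for the intrauterine exposure and the paternal estimate a
negative control.

Continuous outcomes use ordinary least squares with classical standard
errors; binary outcomes use logistic regression fitted by iteratively
reweighted least squares with Wald standard errors. Non-convergence (or
perfect separation) is surfaced via ``converged=False`` rather than
silently patched.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .errors import InputError, RankDeficiencyError
from .instruments import InstrumentSet
from .synthetic_cohort import OutcomePanel, TrioGenotypes

__all__ = ["AssociationRecord", "fit_trio_model", "association_table",
           "ASSOCIATION_COLUMNS"]

ROLES = ("maternal", "paternal", "offspring")

ASSOCIATION_COLUMNS = [
    "rsid", "outcome", "role", "beta", "se", "pval", "n",
    "effect_allele", "other_allele", "eaf", "converged",
]

_IRLS_MAXITER = 100
_IRLS_TOL = 1e-8


@dataclass
class AssociationRecord:
    """One genotype coefficient (role) from a joint trio regression."""

    rsid: str
    outcome: str
    role: str
    beta: float
    se: float
    pval: float
    n: int
    effect_allele: str
    other_allele: str
    eaf: float
    converged: bool


def _check_rank(X: pd.DataFrame) -> None:
    """Raise :class:`RankDeficiencyError` naming collinear columns.

    Pivoted QR: columns pivoted past the numerical rank are the ones that
    add no independent information.
    """
    A = X.to_numpy(dtype=float)
    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < A.shape[1]:
        offenders = [X.columns[j] for j in piv[rank:]]
        raise RankDeficiencyError(offenders)


def _design(
    trios: TrioGenotypes,
    outcomes: OutcomePanel,
    rsid: str,
    outcome_name: str,
    include_family: bool,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Complete-case response, design matrix and maternal/paternal/offspring dosages."""
    if outcome_name not in outcomes.kinds:
        raise InputError(f"unknown outcome {outcome_name!r}")
    gm = trios.column(rsid, "maternal").astype(float)
    gf = trios.column(rsid, "paternal").astype(float)
    go = trios.column(rsid, "offspring").astype(float)

    df = outcomes.data
    cols = [outcome_name] + outcomes.covariate_columns
    keep = df[cols].notna().all(axis=1).to_numpy()

    X = pd.DataFrame({"const": 1.0, "g_maternal": gm}, index=df.index)
    if include_family:
        X["g_paternal"] = gf
        X["g_offspring"] = go
    X["sex"] = df["sex"].astype(float)
    X["age_m"] = df["age_m"].astype(float)
    X["age_f"] = df["age_f"].astype(float)
    batch = pd.get_dummies(df["batch"].astype(str), prefix="batch", drop_first=True)
    for c in batch.columns:
        X[c] = batch[c].astype(float)
    for c in outcomes.covariate_columns:
        if c.startswith("pc"):
            X[c] = df[c].astype(float)

    y = df[outcome_name].to_numpy(dtype=float)[keep]
    X = X.loc[keep]
    dosages = np.column_stack([gm, gf, go])[keep]
    return y, X, dosages


def fit_trio_model(
    rsid: str,
    trios: TrioGenotypes,
    outcomes: OutcomePanel,
    outcome_name: str,
    include_family: bool = True,
) -> list[AssociationRecord]:
    """Fit the joint trio regression for one SNV and one outcome.

    Returns maternal, paternal and offspring :class:`AssociationRecord`s
    sharing a single complete-case sample size. ``include_family=False``
    fits a deliberately unadjusted maternal-only model (used to
    demonstrate direct-inheritance bias); it returns only the maternal
    record.
    """
    y, X, dosages = _design(trios, outcomes, rsid, outcome_name, include_family)
    _check_rank(X)
    kind = outcomes.kinds[outcome_name]

    if kind == "continuous":
        res = sm.OLS(y, X).fit()
        converged = True
    elif kind == "binary":
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=_IRLS_MAXITER, tol=_IRLS_TOL)
            converged = bool(res.converged)
        except Exception:  # perfect separation or IRLS breakdown
            res = None
            converged = False
    else:
        raise InputError(f"unknown outcome kind {kind!r}")

    meta = trios.snv_meta.set_index("rsid").loc[rsid]
    n = len(y)
    role_cols = {"maternal": "g_maternal", "paternal": "g_paternal",
                 "offspring": "g_offspring"}
    roles = ROLES if include_family else ("maternal",)

    records = []
    for i, role in enumerate(roles):
        col = role_cols[role]
        if res is not None:
            beta = float(res.params[col])
            se = float(res.bse[col])
            pval = float(res.pvalues[col])
        else:
            beta = se = pval = float("nan")
        records.append(AssociationRecord(
            rsid=rsid,
            outcome=outcome_name,
            role=role,
            beta=beta,
            se=se,
            pval=pval,
            n=n,
            effect_allele=str(meta["effect_allele"]),
            other_allele=str(meta["other_allele"]),
            eaf=float(dosages[:, i].mean() / 2.0),
            converged=converged,
        ))
    return records


def association_table(
    instrument_sets: list[InstrumentSet] | list[str],
    trios: TrioGenotypes,
    outcomes: OutcomePanel,
) -> pd.DataFrame:
    """Fit every instrument SNV against every outcome.

    Accepts instrument sets or a plain list of rsids. SNVs are fitted in
    (chrom, pos) order and outcomes in panel order, so reruns on identical
    inputs produce bit-identical tables. A SNV missing from the trio
    dosages aborts before any fitting.
    """
    if instrument_sets and isinstance(instrument_sets[0], InstrumentSet):
        rsids = []
        for s in instrument_sets:
            rsids.extend(s.snv_ids)
    else:
        rsids = list(instrument_sets)
    rsids = list(dict.fromkeys(rsids))  # dedupe, keep first occurrence

    missing = [rs for rs in rsids if rs not in trios.snv_ids]
    if missing:
        raise InputError(f"instrument SNVs missing from trio dosages: {missing}")

    meta = trios.snv_meta.set_index("rsid")
    rsids.sort(key=lambda rs: (str(meta.loc[rs, "chrom"]), int(meta.loc[rs, "pos"])))

    rows = []
    for rs in rsids:
        for outcome_name in outcomes.outcome_names:
            for rec in fit_trio_model(rs, trios, outcomes, outcome_name):
                rows.append(asdict(rec))
    table = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    return table
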
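"""Exposure/outcome summary-statistic harmonization.

Two-sample MR requires the exposure and outcome associations for each SNV
to refer to the same effect allele. Records may disagree by a simple
allele swap, by strand (reported on opposite DNA strands, so alleles are
complements), or both; harmonization resolves these and negates the
outcome beta (and reflects its allele frequency) whenever the effect
allele flips.

Palindromic SNVs (A/T or C/G) are strand-ambiguous: allele labels cannot
distinguish a swap from a strand flip. They are aligned by allele-frequency
concordance instead — both effect-allele frequencies on the same side of
0.5 means the alleles already agree, opposite sides means a flip — and
discarded as non-inferable when the minor allele frequency exceeds 0.42 in
either dataset (frequencies that close to 0.5 cannot resolve the
ambiguity).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import pandas as pd

from .errors import InputError

__all__ = [
    "PALINDROME_MAF_THRESHOLD",
    "HarmonizedPair",
    "is_palindromic",
    "harmonize_pair",
    "harmonize_all",
]

PALINDROME_MAF_THRESHOLD = 0.42

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NUCLEOTIDES = frozenset(_COMPLEMENT)

# action -> whether the outcome beta is negated (swap of effect allele)
_ACTIONS = ("match", "swap", "strand_flip", "strand_flip_swap",
            "palindrome_inferred")


@dataclass
class HarmonizedPair:
    """One SNV's exposure/outcome associations on a common effect allele.

    ``action`` records how the outcome record was aligned; ``flipped``
    states whether its beta was negated (and eaf reflected). Dropped pairs
    carry a reason code and NaN outcome fields are left as supplied.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    eaf_exp: float
    beta_out: float
    se_out: float
    eaf_out: float
    action: str
    flipped: bool
    dropped: bool = False
    reason: str = ""


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-complementary (A/T or C/G)."""
    a1, a2 = str(a1).upper(), str(a2).upper()
    if a1 not in _NUCLEOTIDES or a2 not in _NUCLEOTIDES:
        raise InputError(f"non-nucleotide allele codes: {a1!r}/{a2!r}")
    if a1 == a2:
        raise InputError("alleles of a SNV must differ")
    return a2 == _COMPLEMENT[a1]


def _simple_alleles(rec: Mapping) -> tuple[str, str] | None:
    """Upper-cased single-nucleotide alleles, or None for indels/multi-allelics."""
    a1 = str(rec["effect_allele"]).upper()
    a2 = str(rec["other_allele"]).upper()
    if a1 in _NUCLEOTIDES and a2 in _NUCLEOTIDES and a1 != a2:
        return a1, a2
    return None


def harmonize_pair(
    exp_rec: Mapping,
    out_rec: Mapping,
    maf_threshold: float = PALINDROME_MAF_THRESHOLD,
) -> HarmonizedPair:
    """Align one outcome record to the exposure record's effect allele.

    Both records need keys rsid, effect_allele, other_allele, beta, se,
    eaf. The exposure representation is kept; the outcome beta is negated
    and its eaf reflected whenever the effect allele flips. Palindromic
    SNVs are aligned by frequency concordance and dropped when the minor
    allele frequency exceeds ``maf_threshold`` in either dataset
    (strictly: MAF exactly at the threshold is retained).
    """
    if str(exp_rec["rsid"]).strip().lower() != str(out_rec["rsid"]).strip().lower():
        raise InputError(
            f"rsid mismatch: {exp_rec['rsid']!r} vs {out_rec['rsid']!r}"
        )

    base = dict(
        rsid=exp_rec["rsid"],
        effect_allele=str(exp_rec["effect_allele"]).upper(),
        other_allele=str(exp_rec["other_allele"]).upper(),
        beta_exp=float(exp_rec["beta"]),
        se_exp=float(exp_rec["se"]),
        eaf_exp=float(exp_rec["eaf"]),
        beta_out=float(out_rec["beta"]),
        se_out=float(out_rec["se"]),
        eaf_out=float(out_rec["eaf"]),
    )

    exp_alleles = _simple_alleles(exp_rec)
    out_alleles = _simple_alleles(out_rec)
    if exp_alleles is None or out_alleles is None:
        return HarmonizedPair(**base, action="match", flipped=False,
                              dropped=True, reason="incompatible_alleles")
    e1, e2 = exp_alleles
    o1, o2 = out_alleles

    if is_palindromic(e1, e2):
        if not is_palindromic(o1, o2) or {o1, o2} != {e1, e2}:
            return HarmonizedPair(**base, action="match", flipped=False,
                                  dropped=True, reason="incompatible_alleles")
        maf_exp = min(base["eaf_exp"], 1.0 - base["eaf_exp"])
        maf_out = min(base["eaf_out"], 1.0 - base["eaf_out"])
        if maf_exp > maf_threshold or maf_out > maf_threshold:
            return HarmonizedPair(**base, action="palindrome_inferred",
                                  flipped=False, dropped=True,
                                  reason="palindrome_maf_gt_threshold")
        # allele labels are uninformative: align by frequency concordance
        same_side = (base["eaf_exp"] < 0.5) == (base["eaf_out"] < 0.5)
        flipped = not same_side
        if flipped:
            base["beta_out"] = -base["beta_out"]
            base["eaf_out"] = 1.0 - base["eaf_out"]
        return HarmonizedPair(**base, action="palindrome_inferred",
                              flipped=flipped)

    if {o1, o2} == {e1, e2}:
        action = "match" if o1 == e1 else "swap"
    else:
        c1, c2 = _COMPLEMENT[o1], _COMPLEMENT[o2]
        if {c1, c2} == {e1, e2}:
            action = "strand_flip" if c1 == e1 else "strand_flip_swap"
        else:
            return HarmonizedPair(**base, action="match", flipped=False,
                                  dropped=True, reason="incompatible_alleles")

    flipped = action in ("swap", "strand_flip_swap")
    if flipped:
        base["beta_out"] = -base["beta_out"]
        base["eaf_out"] = 1.0 - base["eaf_out"]
    return HarmonizedPair(**base, action=action, flipped=flipped)


def harmonize_all(
    exp_set: pd.DataFrame,
    out_set: pd.DataFrame,
    maf_threshold: float = PALINDROME_MAF_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonize all SNVs shared between an exposure and an outcome table.

    Both tables need columns rsid, effect_allele, other_allele, beta, se,
    eaf (extra columns are ignored). Returns the harmonized table (one row
    per shared rsid, retained and dropped alike, in exposure order) and a
    drop log with one row per drop reason and its count.
    """
    out_by_rsid = {
        str(r["rsid"]).strip().lower(): r for _, r in out_set.iterrows()
    }
    rows = []
    for _, exp_rec in exp_set.iterrows():
        key = str(exp_rec["rsid"]).strip().lower()
        out_rec = out_by_rsid.get(key)
        if out_rec is None:
            continue
        rows.append(asdict(harmonize_pair(exp_rec, out_rec, maf_threshold)))
    harmonized = pd.DataFrame(
        rows, columns=[f.name for f in HarmonizedPair.__dataclass_fields__.values()]
    ) if rows else pd.DataFrame(
        columns=[f.name for f in HarmonizedPair.__dataclass_fields__.values()]
    )
    if len(harmonized):
        counts = harmonized.loc[harmonized["dropped"], "reason"].value_counts()
    else:
        counts = pd.Series(dtype=int)
    drop_log = pd.DataFrame({
        "reason": counts.index,
        "n_dropped": counts.to_numpy(dtype=int),
    })
    return harmonized, drop_log
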
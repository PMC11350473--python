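"""Shared construction helpers for the test suite."""

import pandas as pd

from triomr.synthetic_cohort import OutcomeTruth, TruthRecord


def make_truth(region, beta_snp=1.0, **outcome_kwargs):
    """Truth record with one continuous outcome over all region SNVs."""
    defaults = dict(name="outcome", kind="continuous", noise_sd=1.0)
    defaults.update(outcome_kwargs)
    return TruthRecord(
        beta_snp_exposure={rs: beta_snp for rs in region.snv_ids},
        outcomes=[OutcomeTruth(**defaults)],
    )


def summary_frame(rows):
    """Exposure-style summary-stat frame from (rsid, ea, oa, beta, se, eaf)."""
    return pd.DataFrame(rows, columns=["rsid", "effect_allele", "other_allele",
                                       "beta", "se", "eaf"])
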
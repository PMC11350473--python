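"""TSV serialization helpers.

All pipeline outputs are tab-separated with explicit headers and floats at
12 significant digits, so reruns with identical seeds produce
checksum-identical files. A leading ``# key=value`` comment block records
the master seed (and any other provenance) in every written table.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["write_tsv", "read_tsv"]

FLOAT_FORMAT = "%.12g"


def write_tsv(df: pd.DataFrame, path, seed: int | None = None, **header) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for key, value in header.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("comment", "#")
    kwargs.setdefault("dtype", {"chrom": str})
    return pd.read_csv(path, sep="\t", **kwargs)
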
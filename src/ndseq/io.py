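"""Tab-separated I/O for the pipeline's tables.

All tables are plain TSV with a header row; counts have gene ids in the
first column and sample ids as the remaining headers. Floats are written
with 10 significant digits so repeated runs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate gene or sample ids")
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return counts


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col=0)
    samples.index.name = "sample_id"
    if "condition" not in samples.columns:
        raise ValueError(f"{path}: sample table needs a 'condition' column")
    return samples


def read_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", index_col=0)
    annot.index.name = "gene_id"
    if "biotype" not in annot.columns:
        raise ValueError(f"{path}: annotation needs a 'biotype' column")
    return annot


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
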
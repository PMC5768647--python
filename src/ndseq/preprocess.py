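"""Count-matrix preprocessing: biotype filter, low-count filter,
median-of-ratios normalization, and robust outlier winsorization.

Count matrices are pandas DataFrames (genes x samples, gene ids on the
index); sample metadata is a DataFrame indexed by sample id with at least a
``condition`` column; gene annotation is a DataFrame indexed by gene id
with ``symbol`` and ``biotype`` columns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Biotypes of polyadenylated transcripts retained by default. Both the
#: historical misspelling "sense_overlaping" and Ensembl's
#: "sense_overlapping" are accepted.
POLYA_BIOTYPES = frozenset(
    {
        "protein_coding",
        "lincRNA",
        "processed_transcript",
        "sense_intronic",
        "sense_overlaping",
        "sense_overlapping",
        "IG_V_gene",
        "IG_D_gene",
        "IG_J_gene",
        "IG_C_gene",
        "TR_V_gene",
        "TR_D_gene",
        "TR_J_gene",
        "TR_C_gene",
    }
)

#: Conditions pooled as the neurodegenerative-disease case group.
ND_CONDITIONS = frozenset({"HD", "PD"})


def filter_biotypes(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    allowed: frozenset[str] | set[str] = POLYA_BIOTYPES,
) -> pd.DataFrame:
    """Keep only genes whose annotated biotype is in ``allowed``.

    Gene order is preserved. Genes missing from the annotation raise a
    ``KeyError`` naming the offending ids. An empty ``allowed`` set yields
    an empty matrix, not an error.
    """
    missing = counts.index.difference(annotation.index)
    if len(missing) > 0:
        raise KeyError(
            f"{len(missing)} genes missing from annotation: "
            f"{sorted(missing)[:10]}{'...' if len(missing) > 10 else ''}"
        )
    biotypes = annotation.loc[counts.index, "biotype"]
    keep = biotypes.isin(allowed).to_numpy()
    logger.info(
        "biotype filter removed %d of %d genes", (~keep).sum(), len(counts)
    )
    return counts.loc[keep]


def filter_low_counts(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    case_conditions: frozenset[str] | set[str] = ND_CONDITIONS,
    control_conditions: frozenset[str] | set[str] = frozenset({"C"}),
) -> pd.DataFrame:
    """Drop genes with zeros in more than half the case OR control samples.

    "More than half" is strict: a gene with zeros in exactly half of a
    group survives that group's test.
    """
    cond = samples.loc[counts.columns, "condition"]
    case_ids = cond.index[cond.isin(case_conditions)]
    ctrl_ids = cond.index[cond.isin(control_conditions)]
    if len(case_ids) == 0 or len(ctrl_ids) == 0:
        raise ValueError(
            f"empty condition group: {len(case_ids)} case / {len(ctrl_ids)} "
            "control samples"
        )
    zeros_case = (counts[case_ids] == 0).sum(axis=1)
    zeros_ctrl = (counts[ctrl_ids] == 0).sum(axis=1)
    drop = (zeros_case > len(case_ids) / 2) | (zeros_ctrl > len(ctrl_ids) / 2)
    logger.info(
        "low-count filter removed %d of %d genes", int(drop.sum()), len(counts)
    )
    return counts.loc[~drop]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each sample, the factor is the median over reference genes of
    count / geometric-mean-across-samples, where the reference set is the
    genes with strictly positive counts in every sample (geometric means
    are computed in log space).
    """
    mat = counts.to_numpy(dtype=float)
    ref = (mat > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has all-positive counts; apply count filtering first"
        )
    log_ref = np.log(mat[ref])
    log_geomean = log_ref.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_ref - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if set(sf.index) != set(counts.columns):
        raise ValueError("size factor ids do not match count matrix samples")
    return counts / sf.reindex(counts.columns)


def trim_outliers(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    z_max: float = 3.0,
) -> pd.DataFrame:
    """Winsorize extreme values per gene within each condition group.

    A value whose robust z-score |x - median| / (1.4826 * MAD) exceeds
    ``z_max`` is replaced by the boundary median +/- z_max * 1.4826 * MAD.
    Groups with fewer than three samples, and genes with zero MAD in a
    group, are left untouched (the former with a logged warning). The
    group median and range are never increased.
    """
    if z_max <= 0:
        raise ValueError("z_max must be > 0")
    out = norm.to_numpy(dtype=float).copy()
    cond = samples.loc[norm.columns, "condition"]
    for group in cond.unique():
        cols = np.flatnonzero((cond == group).to_numpy())
        if len(cols) < 3:
            logger.warning(
                "condition group %r has %d samples; outlier trimming skipped",
                group,
                len(cols),
            )
            continue
        block = out[:, cols]
        med = np.median(block, axis=1, keepdims=True)
        mad = np.median(np.abs(block - med), axis=1, keepdims=True)
        scale = 1.4826 * mad
        lo = med - z_max * scale
        hi = med + z_max * scale
        # zero-MAD genes are degenerate in this group: leave them alone
        ok = mad > 0
        out[:, cols] = np.where(ok, np.clip(block, lo, hi), block)
    return pd.DataFrame(out, index=norm.index, columns=norm.columns)


def preprocess(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    annotation: pd.DataFrame,
    allowed_biotypes: frozenset[str] | set[str] = POLYA_BIOTYPES,
    case_conditions: frozenset[str] | set[str] = ND_CONDITIONS,
    z_max: float | None = 3.0,
) -> pd.DataFrame:
    """Full preprocessing chain: biotype filter, zero-count filter,
    median-of-ratios normalization, then (optionally) outlier trimming.

    Pass ``z_max=None`` to disable trimming.
    """
    filtered = filter_biotypes(counts, annotation, allowed_biotypes)
    filtered = filter_low_counts(filtered, samples, case_conditions)
    sf = size_factors(filtered)
    norm = normalize(filtered, sf)
    if z_max is not None:
        norm = trim_outliers(norm, samples, z_max)
    return norm
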
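"""Firth logistic differential expression for the three contrasts.

Fits per-gene Firth penalized logistic regressions of disease status on
standardized normalized counts for HD vs C, PD vs C and the pooled
ND vs C contrast, reports DE counts at q < 0.01 and recovery of the
planted truth, and runs the batch-concordance diagnostic.
"""

import logging

import numpy as np
import pandas as pd

from common import parse_args, study_config
from ndseq.firth import DEFAULT_CONTRASTS, batch_concordance
from ndseq.io import read_samples
from ndseq.pipeline import stage_de


def main() -> None:
    args = parse_args(__doc__)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    config = study_config(args.outdir, args.seed)
    stage_de(config)
    truth = pd.read_csv(f"{config.outdir}/truth.tsv", sep="\t", index_col=0)
    for contrast in DEFAULT_CONTRASTS:
        de = pd.read_csv(
            f"{config.outdir}/de_{contrast.name}.tsv", sep="\t", index_col=0
        )
        t = truth.loc[de.index]
        shared = (t["label"] == "shared").to_numpy()
        recall = de.loc[shared, "de"].mean()
        calls = de["de"].to_numpy()
        fdr = ((t["label"] == "null").to_numpy() & calls).sum() / max(calls.sum(), 1)
        print(
            f"{contrast.name}: {int(calls.sum())} DE genes at q<{config.de_q}; "
            f"shared-gene recall {recall:.2f}; null fraction among calls {fdr:.3f}"
        )

    norm = pd.read_csv(f"{config.outdir}/normalized.tsv", sep="\t", index_col=0)
    samples = read_samples(f"{config.outdir}/samples.tsv")
    for contrast in DEFAULT_CONTRASTS:
        bc = batch_concordance(norm, samples, contrast)
        print(f"{contrast.name}: batch concordance Spearman rho = {bc.rho:.3f}")


if __name__ == "__main__":
    main()
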
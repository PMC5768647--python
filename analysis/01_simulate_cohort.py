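"""Simulate the synthetic two-disease cohort with planted truth.

Writes counts, sample metadata, annotation, the per-gene truth table and
the simulated gene-set collection (with per-set truth) to the results
directory, then reports the planted composition.
"""

import logging

import pandas as pd

from common import parse_args, study_config
from ndseq.pipeline import stage_simulate


def main() -> None:
    args = parse_args(__doc__)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    config = study_config(args.outdir, args.seed)
    stage_simulate(config)
    truth = pd.read_csv(f"{config.outdir}/truth.tsv", sep="\t", index_col=0)
    set_truth = pd.read_csv(f"{config.outdir}/set_truth.tsv", sep="\t", index_col=0)
    print("gene labels:", truth["label"].value_counts().to_dict())
    print(
        "planted enriched sets:",
        set_truth[set_truth["enriched"]]
        .groupby("target_label")
        .size()
        .to_dict(),
    )


if __name__ == "__main__":
    main()
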
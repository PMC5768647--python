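"""Robust rank aggregation across the three contrast gene lists.

Orders each contrast's genes by significance, computes the per-gene RRA
rho score from binomial order statistics of the normalized ranks, and
reports the consensus genes below the 0.01 score threshold together with
their planted labels.
"""

import logging

import pandas as pd

from common import parse_args, study_config
from ndseq.pipeline import stage_rra


def main() -> None:
    args = parse_args(__doc__)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    config = study_config(args.outdir, args.seed)
    stage_rra(config)
    rra = pd.read_csv(f"{config.outdir}/rra.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(f"{config.outdir}/truth.tsv", sep="\t", index_col=0)
    sig = rra[rra["significant"]]
    labels = truth.loc[sig.index, "label"].value_counts().to_dict()
    print(
        f"RRA: {len(sig)} genes below score {config.rra_threshold}; "
        f"their planted labels: {labels}"
    )
    top = rra.head(10).join(truth["label"])
    print("top 10 consensus genes:")
    print(top[["score", "rra_rank", "label"]].to_string())


if __name__ == "__main__":
    main()
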
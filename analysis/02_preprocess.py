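"""Filter, normalize and trim the simulated count matrix.

Applies the polyadenylated-biotype filter, the zero-count filter (a gene
is dropped when more than half the pooled-disease or control samples have
zero counts), median-of-ratios normalization, and per-gene per-condition
robust-z winsorization, then reports what survived.
"""

import logging

import pandas as pd

from common import parse_args, study_config
from ndseq.pipeline import stage_preprocess


def main() -> None:
    args = parse_args(__doc__)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    config = study_config(args.outdir, args.seed)
    stage_preprocess(config)
    norm = pd.read_csv(f"{config.outdir}/normalized.tsv", sep="\t", index_col=0)
    sf = pd.read_csv(f"{config.outdir}/size_factors.tsv", sep="\t", index_col=0)
    print(f"normalized matrix: {norm.shape[0]} genes x {norm.shape[1]} samples")
    print(
        "size factors: min %.3f median %.3f max %.3f"
        % (sf["size_factor"].min(), sf["size_factor"].median(), sf["size_factor"].max())
    )


if __name__ == "__main__":
    main()
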
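"""Partition and compare the two disease DE gene lists.

Intersects the HD and PD DE lists into disease-unique and common
partitions, tests each partition for gene-set over-representation,
groups enriched sets that share more than 20% of their DE genes, and
checks that every set significant in more than one GSEA contrast is
enriched in the same direction.
"""

import logging

import pandas as pd

from common import parse_args, study_config
from ndseq.pipeline import stage_compare


def main() -> None:
    args = parse_args(__doc__)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    config = study_config(args.outdir, args.seed)
    stage_compare(config)
    parts = pd.read_csv(f"{config.outdir}/partitions.tsv", sep="\t")
    print("partition sizes:", parts.groupby("partition").size().to_dict())
    enr = pd.read_csv(f"{config.outdir}/partition_enrichment.tsv", sep="\t")
    sig = enr[enr["q"] < config.gsea_q]
    print(
        f"partition enrichment at q<{config.gsea_q}:",
        sig.groupby("partition").size().to_dict(),
    )
    groups = pd.read_csv(f"{config.outdir}/set_groups.tsv", sep="\t")
    if len(groups):
        print(
            "gene-set groups (shared-DE-gene components):",
            groups.groupby(["partition", "group"]).size().to_dict(),
        )
    conc = pd.read_csv(f"{config.outdir}/concordance.tsv", sep="\t", index_col=0)
    multi = conc[conc["n_significant"] >= 2]
    print(
        f"{len(multi)} sets significant in >=2 contrasts; "
        f"all direction-concordant: {bool(multi['concordant'].all())}"
    )
    print(pd.read_csv(f"{config.outdir}/venn_counts.tsv", sep="\t", index_col=0))


if __name__ == "__main__":
    main()
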
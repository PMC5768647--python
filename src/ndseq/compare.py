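"""Cross-disease comparison of DE results.

The two disease DE gene lists are partitioned into disease-unique and
common sets; each partition is tested for gene-set over-representation;
enriched sets are grouped when they share a large fraction of their DE
genes; and per-contrast GSEA results are checked for direction
concordance among sets significant in more than one contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from ndseq.enrich import GeneSetCollection, hypergeom_enrich

PARTITION_LABELS = ("HD_only", "common", "PD_only")


def partition_de(
    hd: Iterable[str], pd_genes: Iterable[str]
) -> dict[str, set[str]]:
    """Split two DE gene lists into disease-unique and common sets.

    The three sets are disjoint and their union is the union of the
    inputs; empty inputs are fine.
    """
    hd, pd_genes = set(hd), set(pd_genes)
    return {
        "HD_only": hd - pd_genes,
        "common": hd & pd_genes,
        "PD_only": pd_genes - hd,
    }


def enrich_partitions(
    partitions: Mapping[str, set[str]],
    universe: Iterable[str],
    collections: Mapping[str, GeneSetCollection],
) -> pd.DataFrame:
    """Hypergeometric enrichment of each partition against each
    collection, BH-adjusted within each partition x collection block.
    Empty partitions contribute no rows."""
    universe = set(universe)
    frames = []
    for part_name, genes in partitions.items():
        if not genes:
            continue
        for coll_name, coll in collections.items():
            res = hypergeom_enrich(genes, universe, coll).reset_index()
            res.insert(0, "partition", part_name)
            res.insert(1, "collection", coll_name)
            frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=[
                "partition",
                "collection",
                "set",
                "overlap",
                "query_size",
                "set_size",
                "universe_size",
                "p",
                "q",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def group_gene_sets(
    de_members: Mapping[str, set[str]],
    threshold: float = 0.2,
    method: str = "overlap",
) -> list[list[str]]:
    """Group gene sets that share DE genes.

    ``de_members`` maps each enriched set name to its DE genes (set
    intersected with the query). Two sets are linked when their sharing
    fraction strictly exceeds ``threshold``; the fraction is the overlap
    coefficient |A & B| / min(|A|, |B|) by default, or Jaccard with
    ``method="jaccard"``. Groups are the connected components of the
    resulting graph (so chains group transitively); singletons are kept.
    Returned groups and their members are sorted for determinism.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if method not in ("overlap", "jaccard"):
        raise ValueError(f"unknown sharing method {method!r}")
    graph = nx.Graph()
    graph.add_nodes_from(de_members)
    for a, b in combinations(sorted(de_members), 2):
        ga, gb = de_members[a], de_members[b]
        inter = len(ga & gb)
        if method == "overlap":
            denom = min(len(ga), len(gb))
        else:
            denom = len(ga | gb)
        if denom and inter / denom > threshold:
            graph.add_edge(a, b)
    groups = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(groups)


@dataclass
class ConcordanceResult:
    """Direction agreement of gene sets enriched in multiple contrasts."""

    table: pd.DataFrame  # per set: significance flag & direction per contrast
    venn_counts: pd.Series  # sets significant in exactly each contrast subset

    @property
    def all_concordant(self) -> bool:
        shared = self.table["n_significant"] >= 2
        return bool(self.table.loc[shared, "concordant"].all())


def direction_concordance(
    gsea_by_contrast: Mapping[str, pd.DataFrame],
    q_threshold: float = 0.05,
) -> ConcordanceResult:
    """Check whether sets significant in several contrasts agree in sign.

    For every set significant (q < ``q_threshold``) in at least two
    contrasts, ``concordant`` records whether all significant NES signs
    are equal. ``venn_counts`` gives, for every non-empty contrast subset,
    the number of sets significant in exactly those contrasts.
    """
    contrasts = list(gsea_by_contrast)
    all_sets = sorted(set().union(*(df.index for df in gsea_by_contrast.values())))
    rows = []
    for name in all_sets:
        sig_dirs = []
        row: dict[str, object] = {"set": name}
        for c in contrasts:
            df = gsea_by_contrast[c]
            if name in df.index and df.loc[name, "q"] < q_threshold:
                row[f"sig_{c}"] = True
                d = int(df.loc[name, "direction"])
                row[f"dir_{c}"] = d
                sig_dirs.append(d)
            else:
                row[f"sig_{c}"] = False
                row[f"dir_{c}"] = 0
        row["n_significant"] = len(sig_dirs)
        row["concordant"] = (
            len(set(sig_dirs)) == 1 if len(sig_dirs) >= 2 else pd.NA
        )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("set")

    counts = {}
    for r in range(1, len(contrasts) + 1):
        for subset in combinations(contrasts, r):
            mask = pd.Series(True, index=table.index)
            for c in contrasts:
                mask &= table[f"sig_{c}"] == (c in subset)
            counts["&".join(subset)] = int(mask.sum())
    return ConcordanceResult(table=table, venn_counts=pd.Series(counts, name="n_sets"))
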
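"""Robust rank aggregation (RRA) across per-contrast gene lists.

Each input list ranks the same gene universe; a gene's normalized rank in
list i is position_i / N. Under the null of uncorrelated lists the
normalized ranks are independent Uniform(0, 1]. For a gene with sorted
normalized ranks r_(1) <= ... <= r_(n), the binomial order-statistic
probability beta_k = P(Bin(n, r_(k)) >= k) asks how surprising it is that
at least k of n uniform draws fall at or below r_(k); the rho score is
min_k beta_k, Bonferroni-corrected over the n choices of k:
score = min(1, n * rho). Small scores flag genes ranked consistently
better than chance across lists.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from ndseq.enrich import RankedList


def significance_ranking(results: pd.DataFrame, name: str | None = None) -> RankedList:
    """Order genes by ascending raw p, ties broken by descending |LOR|
    then ascending gene id — the per-contrast ordering fed into RRA."""
    if results.index.has_duplicates:
        raise ValueError("duplicate genes in DE results")
    order = sorted(
        range(len(results)),
        key=lambda i: (
            results["p"].iloc[i] if np.isfinite(results["p"].iloc[i]) else np.inf,
            -abs(results["lor"].iloc[i]),
            results.index[i],
        ),
    )
    if name is None:
        name = str(results["contrast"].iloc[0]) if "contrast" in results else ""
    return RankedList(
        genes=results.index.to_numpy()[order],
        scores=-results["p"].to_numpy()[order],
        name=name,
    )


def _orderings(lists: Sequence[RankedList | Sequence[str]]) -> list[np.ndarray]:
    return [
        np.asarray(l.genes if isinstance(l, RankedList) else l, dtype=object)
        for l in lists
    ]


def normalized_ranks(lists: Sequence[RankedList | Sequence[str]]) -> pd.DataFrame:
    """Per-gene normalized ranks (rank / N, best = 1/N) for each list.

    All lists must cover the same gene universe; a mismatch raises with
    the symmetric difference.
    """
    orders = _orderings(lists)
    if not orders:
        raise ValueError("need at least one ranked list")
    universe = set(orders[0])
    for i, order in enumerate(orders[1:], start=2):
        diff = universe ^ set(order)
        if diff:
            raise ValueError(
                f"list 1 and list {i} differ in {len(diff)} genes: "
                f"{sorted(diff)[:10]}"
            )
    n_genes = len(universe)
    names = [
        (l.name if isinstance(l, RankedList) and l.name else f"list_{i+1}")
        for i, l in enumerate(lists)
    ]
    genes = sorted(universe)
    data = {}
    for name, order in zip(names, orders):
        pos = {g: (i + 1) / n_genes for i, g in enumerate(order)}
        data[name] = [pos[g] for g in genes]
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


def rho_score(r: np.ndarray | Sequence[float]) -> tuple[float, float]:
    """RRA rho and Bonferroni-corrected score for one gene.

    ``r`` holds the gene's normalized ranks across lists (any order);
    values must lie in (0, 1]. Returns ``(rho, min(1, n * rho))``.
    """
    r = np.sort(np.asarray(r, dtype=float))
    if r.size == 0:
        raise ValueError("empty rank vector")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("normalized ranks must lie in (0, 1]")
    n = len(r)
    k = np.arange(1, n + 1)
    beta = binom.sf(k - 1, n, r)
    rho = float(beta.min())
    return rho, min(1.0, n * rho)


def aggregate(
    lists: Sequence[RankedList | Sequence[str]],
    score_threshold: float = 0.01,
) -> pd.DataFrame:
    """Aggregate gene lists into a consensus ranking by RRA score.

    Returns a DataFrame indexed by gene id with the integer rank in each
    input list, ``rho``, the corrected ``score``, the consensus
    ``rra_rank`` (ascending score, ties broken by gene id) and a
    ``significant`` flag at ``score < score_threshold``.
    """
    ranks = normalized_ranks(lists)
    n_genes = len(ranks)
    out = (ranks * n_genes).round().astype(int)
    out.columns = [f"rank_{c}" for c in ranks.columns]
    scored = ranks.apply(lambda row: rho_score(row.to_numpy()), axis=1)
    out["rho"] = [s[0] for s in scored]
    out["score"] = [s[1] for s in scored]
    out = out.sort_index().sort_values("score", kind="mergesort")
    out["rra_rank"] = np.arange(1, n_genes + 1)
    out["significant"] = out["score"] < score_threshold
    return out
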
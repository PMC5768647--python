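"""Gene-set enrichment: preranked GSEA and hypergeometric tests.

Preranked GSEA scores a gene set against a single ranked gene list with
the weighted Kolmogorov-Smirnov-like running sum: walking down the list,
the sum rises by |score|^p / sum_set |score|^p at each set member ("hit")
and falls by 1/(N - m) at each non-member ("miss"); the enrichment score
(ES) is the signed maximum deviation from zero. Because the list is fixed,
the null is gene sampling: random same-size sets drawn from the universe,
from which a normalized ES (NES) and a permutation p-value are derived.

Discrete gene lists (e.g. DE-gene partitions) are tested for
over-representation with the upper-tail hypergeometric test instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions.

    Set names are unique (dict keys); duplicate members within a set are
    removed with a warning, preserving first-occurrence order; empty sets
    are rejected.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} has no members")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "gene set %r: %d duplicate members removed",
                    name,
                    len(members) - len(unique),
                )
            cleaned[name] = unique
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneSetCollection)
            and self.sets == other.sets
            and self.descriptions == other.descriptions
        )


@dataclass
class RankedList:
    """Genes in strictly descending score order with a deterministic
    (ascending gene id) tie-break."""

    genes: np.ndarray
    scores: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(results: pd.DataFrame, score_column: str = "lor", name: str | None = None) -> RankedList:
    """Order genes by descending score (standardized LOR), ties broken by
    ascending gene id."""
    if results.index.has_duplicates:
        dups = results.index[results.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate genes in DE results: {dups[:10]}")
    order = sorted(
        range(len(results)),
        key=lambda i: (-results[score_column].iloc[i], results.index[i]),
    )
    if name is None:
        name = str(results["contrast"].iloc[0]) if "contrast" in results else ""
    return RankedList(
        genes=results.index.to_numpy()[order],
        scores=results[score_column].to_numpy()[order],
        name=name,
    )


def _es_core(
    abs_weights: np.ndarray, positions: np.ndarray, n_total: int
) -> np.ndarray:
    """Signed maximum running-sum deviation for one or many hit-position
    vectors.

    ``positions`` is (m,) or (B, m), 0-based and sorted ascending within
    each row; ``abs_weights`` is |score|^p over the full ranked list. The
    running sum is piecewise linear between hits, so only the value just
    after each hit (candidate maximum) and just before it (candidate
    minimum) need be evaluated. Ties between the positive and negative
    extreme (to within float noise) resolve to the positive one.
    """
    pos = np.atleast_2d(positions)
    m = pos.shape[1]
    w = abs_weights[pos]
    tot = w.sum(axis=1, keepdims=True)
    uniform = tot == 0  # all-zero scores inside the set: unweighted hits
    w = np.where(uniform, 1.0, w)
    tot = np.where(uniform, float(m), tot)
    cumw = np.cumsum(w, axis=1) / tot
    miss = 1.0 / (n_total - m)
    idx = np.arange(1, m + 1)
    after = cumw - (pos + 1 - idx) * miss
    before = np.concatenate(
        [np.zeros((pos.shape[0], 1)), cumw[:, :-1]], axis=1
    ) - (pos - (idx - 1)) * miss
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    # ties between the extremes (up to float noise) resolve positive
    es = np.where(hi >= -lo - 1e-9, hi, lo)
    return es if positions.ndim == 2 else float(es[0])


def gsea_es(
    ranked: RankedList, gene_set: Iterable[str], weight: float = 1.0
) -> float:
    """Enrichment score of ``gene_set`` in ``ranked`` (weight p=1 default,
    p=0 for the unweighted statistic)."""
    index = {g: i for i, g in enumerate(ranked.genes)}
    positions = np.sort([index[g] for g in set(gene_set) if g in index])
    n = len(ranked)
    if len(positions) == 0 or len(positions) >= n:
        raise ValueError(
            "gene set must overlap the ranked universe without covering it"
        )
    abs_w = np.abs(ranked.scores) ** weight
    return _es_core(abs_w, positions, n)


def _null_es(
    abs_w: np.ndarray,
    set_size: int,
    n_total: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES distribution from random same-size gene draws."""
    keys = rng.random((n_perm, n_total))
    pos = np.sort(np.argpartition(keys, set_size, axis=1)[:, :set_size], axis=1)
    return _es_core(abs_w, pos, n_total)


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Preranked GSEA of every set in ``collection`` against ``ranked``.

    Per set: ES; a gene-sampling null of ``n_perm`` random same-size
    draws (shared across sets of equal size); NES = ES divided by the mean
    |null ES| of matching sign; nominal p = fraction of same-sign null ES
    at least as extreme, with a +1 pseudocount so p is in (0, 1];
    q = BH across the collection. Sets overlapping the universe in fewer
    than ``min_size`` genes are skipped with a log entry.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    from ndseq.firth import bh_adjust

    n = len(ranked)
    index = {g: i for i, g in enumerate(ranked.genes)}
    abs_w = np.abs(ranked.scores) ** weight
    rng = np.random.default_rng(seed)

    effective: dict[str, np.ndarray] = {}
    for name, members in collection:
        positions = np.sort([index[g] for g in members if g in index])
        if len(positions) < min_size or len(positions) >= n:
            logger.info(
                "gene set %r skipped (%d genes in universe)", name, len(positions)
            )
            continue
        effective[name] = positions

    # null distributions are drawn once per distinct set size, in sorted
    # size order so results do not depend on collection ordering
    null_cache: dict[int, np.ndarray] = {}
    for size in sorted({len(p) for p in effective.values()}):
        null_cache[size] = _null_es(abs_w, size, n, n_perm, rng)

    rows = []
    for name, positions in effective.items():
        es = _es_core(abs_w, positions, n)
        null = null_cache[len(positions)]
        if es >= 0:
            same = null[null >= 0]
            n_extreme = int((same >= es).sum())
        else:
            same = null[null < 0]
            n_extreme = int((same <= es).sum())
        p = (1 + n_extreme) / (1 + len(same)) if len(same) else 1.0
        denom = np.abs(same).mean() if len(same) else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        rows.append((name, len(positions), es, nes, p))

    out = pd.DataFrame(
        rows, columns=["set", "size", "es", "nes", "p"]
    ).set_index("set")
    out["q"] = bh_adjust(out["p"])
    out["direction"] = np.sign(out["es"]).astype(int)
    out["significant"] = out["q"] < q_threshold
    return out


def hypergeom_enrich(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each
    set of ``collection``, BH-adjusted across the collection.

    Sets are intersected with the universe before testing; the query must
    be a subset of the universe.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        extra = sorted(query - universe)
        raise ValueError(
            f"{len(extra)} query genes outside the universe: {extra[:10]}"
        )
    from ndseq.firth import bh_adjust

    m_univ = len(universe)
    n_query = len(query)
    rows = []
    for name, members in collection:
        in_univ = set(members) & universe
        overlap = len(in_univ & query)
        p = float(hypergeom.sf(overlap - 1, m_univ, len(in_univ), n_query))
        rows.append((name, overlap, n_query, len(in_univ), m_univ, p))
    out = pd.DataFrame(
        rows,
        columns=["set", "overlap", "query_size", "set_size", "universe_size", "p"],
    ).set_index("set")
    out["q"] = bh_adjust(out["p"])
    return out


def read_gmt(path: str) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":  # trailing tabs
                fields.pop()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            name, description, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    """Write a collection in GMT format (round-trips with :func:`read_gmt`)."""
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
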
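"""End-to-end orchestration of the analysis.

Stages communicate through TSV/GMT files in the output directory so each
can be run on its own (via the CLI subcommands) or chained by
:func:`run_pipeline`; either route produces byte-identical tables for the
same configuration and seed. A machine-readable manifest records the
seed, thresholds and outputs of each run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import ndseq
from ndseq import io
from ndseq.compare import (
    direction_concordance,
    enrich_partitions,
    group_gene_sets,
    partition_de,
)
from ndseq.enrich import gsea_preranked, rank_genes, read_gmt, write_gmt
from ndseq.firth import DEFAULT_CONTRASTS, de_contrast
from ndseq.preprocess import POLYA_BIOTYPES, preprocess, size_factors
from ndseq.rra import aggregate, significance_ranking
from ndseq.simulate import SimConfig, simulate_dataset, simulate_genesets

logger = logging.getLogger(__name__)

_STAGE_IDS = {"simulate": 0, "genesets": 1, "gsea": 2}


def _subseed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2^31) from the global seed."""
    state = np.random.SeedSequence((seed, _STAGE_IDS[stage])).generate_state(1)
    return int(state[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    """Run configuration.

    Either ``simulate`` holds a :class:`SimConfig` (synthetic mode, where
    a gene-set collection is simulated alongside the cohort), or the
    ``counts`` / ``samples`` / ``annotation`` / ``gmt_paths`` inputs point
    at files (ingest mode). Thresholds default to the conventions used
    throughout: DE at q < 0.01, enrichment at q < 0.05, RRA at
    score < 0.01.
    """

    outdir: str = "results"
    seed: int = 0
    # ingest-mode inputs
    counts: str | None = None
    samples: str | None = None
    annotation: str | None = None
    gmt_paths: dict[str, str] = field(default_factory=dict)
    # synthetic mode
    simulate: SimConfig | None = None
    n_sets: int = 60
    set_size_range: tuple[int, int] = (10, 50)
    n_enriched_sets: int = 9
    set_purity: float = 0.9
    # analysis parameters
    covariates: tuple[str, ...] = ()
    de_q: float = 0.01
    gsea_q: float = 0.05
    rra_threshold: float = 0.01
    n_perm: int = 1000
    gsea_weight: float = 1.0
    min_set_size: int = 5
    trim_z: float | None = 3.0
    group_share_threshold: float = 0.2

    def __post_init__(self) -> None:
        for name in ("de_q", "gsea_q", "rra_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.simulate is None:
            for name in ("counts", "samples", "annotation"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(
                        f"ingest mode needs {name!r} (or set 'simulate')"
                    )
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")
            for cname, path in self.gmt_paths.items():
                if not Path(path).exists():
                    raise FileNotFoundError(
                        f"gene-set file for {cname!r} not found: {path}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if isinstance(raw.get("simulate"), dict):
            raw["simulate"] = SimConfig(**raw["simulate"])
        elif raw.get("simulate") is True:
            raw["simulate"] = SimConfig()
        for key in ("set_size_range", "covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _input_paths(config: PipelineConfig) -> dict[str, Path]:
    out = Path(config.outdir)
    if config.simulate is not None:
        return {
            "counts": out / "counts.tsv",
            "samples": out / "samples.tsv",
            "annotation": out / "annotation.tsv",
        }
    return {
        "counts": Path(config.counts),
        "samples": Path(config.samples),
        "annotation": Path(config.annotation),
    }


def _collections(config: PipelineConfig) -> dict[str, Path]:
    if config.simulate is not None:
        return {"synthetic": Path(config.outdir) / "gene_sets.gmt"}
    return {name: Path(p) for name, p in config.gmt_paths.items()}


def stage_simulate(config: PipelineConfig) -> None:
    """Generate the synthetic cohort and gene-set collection."""
    if config.simulate is None:
        logger.info("ingest mode: nothing to simulate")
        return
    out = Path(config.outdir)
    sim = dataclasses.replace(config.simulate, seed=_subseed(config.seed, "simulate"))
    counts, samples, annotation, truth = simulate_dataset(sim)
    collection, set_truth = simulate_genesets(
        truth,
        n_sets=config.n_sets,
        size_range=config.set_size_range,
        n_enriched=config.n_enriched_sets,
        seed=_subseed(config.seed, "genesets"),
        purity=config.set_purity,
    )
    io.write_table(counts, out / "counts.tsv")
    io.write_table(samples, out / "samples.tsv")
    io.write_table(annotation, out / "annotation.tsv")
    io.write_table(truth, out / "truth.tsv")
    io.write_table(set_truth, out / "set_truth.tsv")
    write_gmt(collection, str(out / "gene_sets.gmt"))
    logger.info(
        "simulated %d genes x %d samples, %d gene sets",
        len(counts),
        counts.shape[1],
        len(collection),
    )


def stage_preprocess(config: PipelineConfig) -> None:
    """Filter, normalize and trim the count matrix."""
    paths = _input_paths(config)
    counts = io.read_counts(paths["counts"])
    samples = io.read_samples(paths["samples"])
    annotation = io.read_annotation(paths["annotation"])
    out = Path(config.outdir)
    from ndseq.preprocess import filter_biotypes, filter_low_counts

    filtered = filter_biotypes(counts, annotation, POLYA_BIOTYPES)
    filtered = filter_low_counts(filtered, samples)
    sf = size_factors(filtered)
    norm = filtered / sf.reindex(filtered.columns)
    if config.trim_z is not None:
        from ndseq.preprocess import trim_outliers

        norm = trim_outliers(norm, samples, config.trim_z)
    io.write_table(sf.to_frame(), out / "size_factors.tsv")
    io.write_table(norm, out / "normalized.tsv")
    logger.info("normalized matrix: %d genes retained", len(norm))


def stage_de(config: PipelineConfig) -> None:
    """Firth DE for the three contrasts."""
    out = Path(config.outdir)
    norm = pd.read_csv(out / "normalized.tsv", sep="\t", index_col=0)
    samples = io.read_samples(_input_paths(config)["samples"])
    annotation = io.read_annotation(_input_paths(config)["annotation"])
    for contrast in DEFAULT_CONTRASTS:
        res = de_contrast(
            norm, samples, contrast, config.covariates, config.de_q
        )
        res.insert(0, "symbol", annotation["symbol"].reindex(res.index))
        io.write_table(res, out / f"de_{contrast.name}.tsv")
        logger.info(
            "%s: %d DE genes at q < %g",
            contrast.name,
            int(res["de"].sum()),
            config.de_q,
        )


def _read_de(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    out = Path(config.outdir)
    return {
        c.name: pd.read_csv(out / f"de_{c.name}.tsv", sep="\t", index_col=0)
        for c in DEFAULT_CONTRASTS
    }


def stage_gsea(config: PipelineConfig) -> None:
    """Preranked GSEA of each contrast's full gene list."""
    out = Path(config.outdir)
    de = _read_de(config)
    collections = _collections(config)
    primary = next(iter(collections))  # GSEA runs on the primary collection
    collection = read_gmt(str(collections[primary]))
    seed = _subseed(config.seed, "gsea")
    for name, res in de.items():
        ranked = rank_genes(res, name=name)
        gsea = gsea_preranked(
            ranked,
            collection,
            n_perm=config.n_perm,
            seed=seed,
            weight=config.gsea_weight,
            min_size=config.min_set_size,
            q_threshold=config.gsea_q,
        )
        io.write_table(gsea, out / f"gsea_{name}.tsv")
        logger.info(
            "%s: %d gene sets enriched at q < %g",
            name,
            int(gsea["significant"].sum()),
            config.gsea_q,
        )


def stage_rra(config: PipelineConfig) -> None:
    """Robust rank aggregation across the three contrast lists."""
    out = Path(config.outdir)
    de = _read_de(config)
    lists = [significance_ranking(res, name=name) for name, res in de.items()]
    rra = aggregate(lists, score_threshold=config.rra_threshold)
    io.write_table(rra, out / "rra.tsv")
    logger.info(
        "RRA: %d genes below score %g",
        int(rra["significant"].sum()),
        config.rra_threshold,
    )


def stage_compare(config: PipelineConfig) -> None:
    """Partition the disease DE lists, enrich and group the partitions,
    and tabulate GSEA direction concordance."""
    out = Path(config.outdir)
    de = _read_de(config)
    norm = pd.read_csv(out / "normalized.tsv", sep="\t", index_col=0)
    universe = set(norm.index)

    hd = set(de["HD_vs_C"].index[de["HD_vs_C"]["de"]])
    pd_set = set(de["PD_vs_C"].index[de["PD_vs_C"]["de"]])
    partitions = partition_de(hd, pd_set)
    part_rows = [
        {"partition": label, "gene_id": g}
        for label, genes in partitions.items()
        for g in sorted(genes)
    ]
    io.write_table(pd.DataFrame(part_rows), out / "partitions.tsv", index=False)

    collections = {
        name: read_gmt(str(path)) for name, path in _collections(config).items()
    }
    enrichment = enrich_partitions(partitions, universe, collections)
    io.write_table(enrichment, out / "partition_enrichment.tsv", index=False)

    group_rows = []
    for label, genes in partitions.items():
        block = enrichment[
            (enrichment["partition"] == label) & (enrichment["q"] < config.gsea_q)
        ]
        members = {}
        for _, row in block.iterrows():
            members[row["set"]] = (
                set(collections[row["collection"]][row["set"]]) & genes
            )
        for gid, group in enumerate(
            group_gene_sets(members, config.group_share_threshold), start=1
        ):
            for set_name in group:
                group_rows.append(
                    {"partition": label, "group": gid, "set": set_name}
                )
    io.write_table(
        pd.DataFrame(group_rows, columns=["partition", "group", "set"]),
        out / "set_groups.tsv",
        index=False,
    )

    gsea = {
        c.name: pd.read_csv(out / f"gsea_{c.name}.tsv", sep="\t", index_col=0)
        for c in DEFAULT_CONTRASTS
    }
    conc = direction_concordance(gsea, config.gsea_q)
    io.write_table(conc.table, out / "concordance.tsv")
    io.write_table(conc.venn_counts.to_frame(), out / "venn_counts.tsv")
    logger.info(
        "partitions: HD_only=%d common=%d PD_only=%d; multi-contrast sets all "
        "concordant: %s",
        len(partitions["HD_only"]),
        len(partitions["common"]),
        len(partitions["PD_only"]),
        conc.all_concordant,
    )


_STAGES = (
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("de", stage_de),
    ("gsea", stage_gsea),
    ("rra", stage_rra),
    ("compare", stage_compare),
)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order and write a run manifest.

    Returns the output directory. Any stage error aborts the run with the
    failing stage named.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, stage in _STAGES:
        try:
            stage(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest = {
        "ndseq_version": ndseq.__version__,
        "seed": config.seed,
        "mode": "synthetic" if config.simulate is not None else "ingest",
        "thresholds": {
            "de_q": config.de_q,
            "gsea_q": config.gsea_q,
            "rra_score": config.rra_threshold,
        },
        "n_perm": config.n_perm,
        "covariates": list(config.covariates),
        "contrasts": [c.name for c in DEFAULT_CONTRASTS],
        "stages": [name for name, _ in _STAGES],
        "outputs": sorted(
            p.name
            for p in out.iterdir()
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
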
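"""Synthetic case/case/control RNA-seq cohorts with planted ground truth.

Counts are negative-binomial (variance = mu + dispersion * mu^2) around a
per-gene baseline mean, scaled by a per-sample size factor, with planted
log2 fold changes for three kinds of non-null genes: effects shared by both
disease groups, and effects unique to either disease. Sample metadata
carries condition labels (two diseases plus control), sequencing batch, and
covariates (age at death, post-mortem interval, RNA integrity number) drawn
from cohort-like Gaussians but with no influence on counts, so the design
matrix path is exercised while the planted truth stays clean.

Gene-set collections are simulated on top of a cohort's truth table:
enriched sets oversample genes of a single truth label with a consistent
effect sign, background sets sample the universe uniformly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ndseq.enrich import GeneSetCollection

CONDITIONS = ("HD", "PD", "C")

# per-condition (mean, sd) of the no-effect covariates, cohort-like values
_COVARIATE_PARAMS = {
    "age_at_death": {"HD": (60.5, 11.4), "PD": (77.5, 8.9), "C": (68.6, 15.8)},
    "pmi": {"HD": (16.4, 7.8), "PD": (11.1, 9.7), "C": (14.6, 9.5)},
    "rin": {"HD": (7.1, 1.2), "PD": (7.0, 0.7), "C": (7.8, 0.7)},
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated cohort.

    Defaults mirror the two-disease post-mortem brain design the pipeline
    targets: 29 + 29 disease samples against 49 shared controls, sequenced
    in five batches, with a tenth of genes carrying a shared disease effect
    and a twentieth each carrying a disease-unique effect at |log2FC| = 1.
    """

    n_disease1: int = 29
    n_disease2: int = 29
    n_control: int = 49
    n_genes: int = 1000
    frac_shared_de: float = 0.10
    frac_d1_only_de: float = 0.05
    frac_d2_only_de: float = 0.05
    lfc_magnitude: float = 1.0
    dispersion: float = 0.1
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    baseline_mean_range: tuple[float, float] = (20.0, 2000.0)
    n_batches: int = 5
    batch_lfc: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_disease1", "n_disease2", "n_control", "n_genes", "n_batches"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        fracs = (self.frac_shared_de, self.frac_d1_only_de, self.frac_d2_only_de)
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise ValueError(
                "DE fractions must be non-negative and sum to at most 1, "
                f"got {fracs}"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must be a positive interval")
        blo, bhi = self.baseline_mean_range
        if not (0 < blo <= bhi):
            raise ValueError("baseline_mean_range must be a positive interval")

    @property
    def n_samples(self) -> int:
        return self.n_disease1 + self.n_disease2 + self.n_control


def nb_counts(
    means: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws with variance = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    p = shape / (shape + np.asarray(means, dtype=float))
    return rng.negative_binomial(shape, p)


def _assign_labels(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random label per gene plus signed log2 effects per disease."""
    n = config.n_genes
    n_shared = round(config.frac_shared_de * n)
    n_d1 = round(config.frac_d1_only_de * n)
    n_d2 = round(config.frac_d2_only_de * n)
    labels = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_shared]] = "shared"
    labels[order[n_shared : n_shared + n_d1]] = "d1_only"
    labels[order[n_shared + n_d1 : n_shared + n_d1 + n_d2]] = "d2_only"

    signs = rng.choice([-1.0, 1.0], size=n)
    mag = config.lfc_magnitude
    lfc_d1 = np.where(np.isin(labels, ["shared", "d1_only"]), signs * mag, 0.0)
    lfc_d2 = np.where(np.isin(labels, ["shared", "d2_only"]), signs * mag, 0.0)
    return labels, lfc_d1, lfc_d2


def simulate_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Returns
    -------
    counts : DataFrame, genes x samples, non-negative integers.
    samples : DataFrame indexed by sample id with columns
        ``condition, age_at_death, pmi, rin, batch``.
    annotation : DataFrame indexed by gene id with columns
        ``symbol, biotype`` (all ``protein_coding`` so the biotype filter
        is an identity unless the caller edits it).
    truth : DataFrame indexed by gene id with columns
        ``label`` in {null, shared, d1_only, d2_only} and signed planted
        ``lfc_hd``/``lfc_pd`` log2 effects.

    The same config (including seed) reproduces the output bit-for-bit;
    independent RNG streams are spawned for cohort structure, counts, and
    covariates so each part is individually reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_counts, rng_cov = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    gene_ids = [f"gene_{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"sample_{i:03d}" for i in range(config.n_samples)]
    condition = np.repeat(
        ["HD", "PD", "C"], [config.n_disease1, config.n_disease2, config.n_control]
    )

    labels, lfc_d1, lfc_d2 = _assign_labels(config, rng_struct)

    log_lo, log_hi = (math.log(b) for b in config.baseline_mean_range)
    base_mean = np.exp(rng_struct.uniform(log_lo, log_hi, size=config.n_genes))
    sf = rng_struct.uniform(*config.size_factor_range, size=config.n_samples)

    # every batch is represented: cyclic assignment, then shuffled
    batch = np.arange(config.n_samples) % config.n_batches
    rng_struct.shuffle(batch)

    lfc = np.zeros((config.n_genes, config.n_samples))
    lfc[:, condition == "HD"] = lfc_d1[:, None]
    lfc[:, condition == "PD"] = lfc_d2[:, None]
    if config.batch_lfc != 0.0:
        batch_sign = rng_struct.choice(
            [-1.0, 1.0], size=(config.n_genes, config.n_batches)
        )
        lfc = lfc + config.batch_lfc * batch_sign[:, batch]

    means = base_mean[:, None] * sf[None, :] * np.exp2(lfc)
    counts = pd.DataFrame(
        nb_counts(means, config.dispersion, rng_counts),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )

    cov = {}
    for name, params in _COVARIATE_PARAMS.items():
        vals = np.empty(config.n_samples)
        for cond in CONDITIONS:
            mask = condition == cond
            mu, sd = params[cond]
            vals[mask] = rng_cov.normal(mu, sd, size=mask.sum())
        cov[name] = vals
    cov["pmi"] = np.clip(cov["pmi"], 0.5, None)
    cov["rin"] = np.clip(cov["rin"], 1.0, 10.0)

    samples = pd.DataFrame(
        {
            "condition": condition,
            "age_at_death": cov["age_at_death"],
            "pmi": cov["pmi"],
            "rin": cov["rin"],
            "batch": [f"batch_{b}" for b in batch],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    annotation = pd.DataFrame(
        {
            "symbol": [f"SYM{i:05d}" for i in range(config.n_genes)],
            "biotype": "protein_coding",
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    truth = pd.DataFrame(
        {"label": labels, "lfc_hd": lfc_d1, "lfc_pd": lfc_d2},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return counts, samples, annotation, truth


_LABEL_LFC_COLUMN = {"shared": "lfc_hd", "d1_only": "lfc_hd", "d2_only": "lfc_pd"}


def simulate_genesets(
    truth: pd.DataFrame,
    n_sets: int,
    size_range: tuple[int, int],
    n_enriched: int,
    seed: int,
    purity: float = 0.9,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Simulate a gene-set collection over a cohort's gene universe.

    The first ``n_enriched`` sets are enriched: a target truth label
    (cycling through shared / d1_only / d2_only, skipping empty pools) and
    an effect sign are chosen, and ``purity`` of the members are drawn from
    genes carrying that label with that sign; the remainder, and all
    background sets, are drawn uniformly from the universe.

    Returns the collection and a per-set truth table with columns
    ``enriched`` (bool), ``direction`` (+1/-1 planted sign, 0 for
    background) and ``target_label``.
    """
    if n_enriched > n_sets:
        raise ValueError("n_enriched must be <= n_sets")
    lo, hi = size_range
    universe = np.asarray(truth.index)
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError(
            f"size_range {size_range} outside gene universe of {len(universe)}"
        )
    if not (0.0 <= purity <= 1.0):
        raise ValueError("purity must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    target_labels = [
        lab
        for lab in ("shared", "d1_only", "d2_only")
        if (truth["label"] == lab).any()
    ]
    if n_enriched > 0 and not target_labels:
        raise ValueError("cannot plant enriched sets: no non-null genes in truth")

    sets: dict[str, list[str]] = {}
    rows = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"set_{i:03d}"
        if i < n_enriched:
            label = target_labels[i % len(target_labels)]
            direction = int(rng.choice([-1, 1]))
            col = _LABEL_LFC_COLUMN[label]
            pool = universe[
                (truth["label"] == label).to_numpy()
                & (np.sign(truth[col].to_numpy()) == direction)
            ]
            n_core = min(round(purity * size), len(pool))
            core = rng.choice(pool, size=n_core, replace=False)
            rest_pool = np.setdiff1d(universe, core)
            rest = rng.choice(rest_pool, size=size - n_core, replace=False)
            members = np.concatenate([core, rest])
            rows.append((name, True, direction, label))
        else:
            members = rng.choice(universe, size=size, replace=False)
            rows.append((name, False, 0, ""))
        sets[name] = sorted(members.tolist())

    collection = GeneSetCollection(
        sets, descriptions={n: "synthetic" for n in sets}
    )
    set_truth = pd.DataFrame(
        rows, columns=["set", "enriched", "direction", "target_label"]
    ).set_index("set")
    return collection, set_truth
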
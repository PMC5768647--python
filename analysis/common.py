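"""Shared run configuration for the numbered analysis scripts.

The analysis runs the full synthetic-cohort study at its default
conditions: a 29 + 29 + 49 cohort (two disease groups, shared controls),
1000 genes with 10% shared and 5% + 5% disease-unique planted effects at
|log2FC| = 1, and 60 gene sets of which 9 are enriched. Every script
takes --outdir and --seed and reads/writes the same results directory so
the steps chain.
"""

import argparse

from ndseq.pipeline import PipelineConfig
from ndseq.simulate import SimConfig


def study_config(outdir: str, seed: int) -> PipelineConfig:
    return PipelineConfig(outdir=outdir, seed=seed, simulate=SimConfig())


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--outdir", default="results/study")
    parser.add_argument("--seed", type=int, default=7)
    return parser.parse_args()
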
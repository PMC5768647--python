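import numpy as np
import pandas as pd
import pytest

from ndseq.pipeline import PipelineConfig, run_pipeline
from ndseq.preprocess import preprocess
from ndseq.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A modest 29/29/49 cohort with planted effects, preprocessed."""
    config = SimConfig(n_genes=300, seed=3)
    counts, samples, annotation, truth = simulate_dataset(config)
    norm = preprocess(counts, samples, annotation)
    return {
        "config": config,
        "counts": counts,
        "samples": samples,
        "annotation": annotation,
        "truth": truth,
        "norm": norm,
    }


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full synthetic pipeline run at the default study conditions."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = PipelineConfig(outdir=str(outdir), seed=7, simulate=SimConfig(seed=0))
    run_pipeline(config)
    return config


def read_result(config: PipelineConfig, name: str) -> pd.DataFrame:
    return pd.read_csv(f"{config.outdir}/{name}", sep="\t", index_col=0)
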
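import numpy as np
import pytest

from tdploc import design, synthdata
from tdploc.config import PipelineConfig, SimConfig
from tdploc.structure import BasePairBackend


@pytest.fixture(scope="session")
def backend():
    """One backend for the whole session (numba kernel compiles once)."""
    be = BasePairBackend()
    be.pair_probabilities("GGGAAAACCC")  # warm the JIT
    return be


@pytest.fixture(scope="session")
def small_utr_set():
    cfg = SimConfig(seed=7, n_target_utrs=4, n_background_utrs=4)
    return cfg, synthdata.gen_utr_set(cfg)


@pytest.fixture(scope="session")
def small_pool(small_utr_set):
    cfg, utrs = small_utr_set
    kept, _ = design.filter_utrs(utrs.records)
    metas = [design.merge_meta_utr([r]) for r in kept]
    pool = design.assemble_pool(metas)
    truth = synthdata.annotate_pool_truth(pool, utrs.truth, cfg)
    return cfg, pool, truth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-scale pipeline run shared by the end-to-end tests."""
    from tdploc import pipeline

    outdir = tmp_path_factory.mktemp("run_all")
    summary = pipeline.run_all(PipelineConfig(seed=1), str(outdir))
    return summary, outdir
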
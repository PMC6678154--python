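import pytest

from proteoannot.pipeline import PipelineConfig, run_all
from proteoannot.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_bundle():
    """A small simulated study shared across read-only tests."""
    return simulate(SimConfig(seed=1, n_genes=60, n_lncrnas=30))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One end-to-end pipeline run on a small study."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(seed=1, out_dir=str(out), n_genes=60, n_lncrnas=30)
    manifest = run_all(cfg)
    return {"out": out, "config": cfg, "manifest": manifest}
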
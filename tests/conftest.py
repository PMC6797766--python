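from types import SimpleNamespace

import pytest

from srnamir.cli import make_demo, run_pipeline

DEMO_SEED = 42


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """One zero-noise synthetic study, run through the full pipeline once and
    shared by every test that checks planted-truth recovery."""
    work = tmp_path_factory.mktemp("demo")
    config, truth = make_demo(DEMO_SEED, work)
    manifest = run_pipeline(config)
    return SimpleNamespace(
        config=config, truth=truth, manifest=manifest, outdir=config.output_dir, workdir=work
    )
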
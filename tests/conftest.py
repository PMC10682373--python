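import pathlib

import pytest
import yaml

from afa.cli import RunConfig, run_build
from afa.fixtures import FixtureSpec, generate


def build_from_fixture(result, outdir):
    """Run the full pipeline on a generated fixture dataset."""
    cfg = {
        "reference": str(result.reference_path),
        "states": {s: str(p) for s, p in result.state_paths.items()},
        "register": [str(p) for p in result.register_paths],
        "output_dir": str(outdir),
    }
    cfg_path = pathlib.Path(outdir).parent / "run.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    return run_build(RunConfig.from_file(cfg_path)), cfg_path


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """One generated dataset at the default study conditions."""
    root = tmp_path_factory.mktemp("fixture")
    return generate(FixtureSpec(n_taxa=120, seed=11), root / "data")


@pytest.fixture(scope="session")
def built_pipeline(default_fixture, tmp_path_factory):
    """Artifacts of a full pipeline run over the default fixture."""
    outdir = tmp_path_factory.mktemp("build") / "out"
    artifacts, _ = build_from_fixture(default_fixture, outdir)
    return artifacts
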
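import pytest

from rbpes import fixtures
from rbpes.formulary import Formulary, load_formulary


@pytest.fixture()
def fixture_cfg() -> fixtures.FixtureConfig:
    return fixtures.FixtureConfig(seed=7, n_ais=3, n_evidence_per_ai=2)


@pytest.fixture()
def formulary_dir(tmp_path, fixture_cfg):
    out = tmp_path / "formulary"
    out.mkdir()
    fixtures.generate_formulary(fixture_cfg, out)
    return out


@pytest.fixture()
def formulary(formulary_dir) -> Formulary:
    return load_formulary(formulary_dir)


@pytest.fixture()
def paclitaxel_spec():
    return fixtures.paclitaxel_worked_example()


@pytest.fixture()
def site_yaml(tmp_path, fixture_cfg):
    path = tmp_path / "site.yaml"
    fixtures.generate_site_config(fixture_cfg, path)
    return path
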
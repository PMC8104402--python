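import pytest
from hypothesis import settings

from landghg.fixtures import FixtureSpec, generate_params, generate_scenarios
from landghg.params_io import load_parameters

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def fixture_dirs(tmp_path_factory, fixture_spec):
    root = tmp_path_factory.mktemp("fixture")
    params_dir = generate_params(fixture_spec, root / "params")
    scenario_files = generate_scenarios(fixture_spec, root / "scenarios")
    return params_dir, scenario_files


@pytest.fixture(scope="session")
def params_dir(fixture_dirs):
    return fixture_dirs[0]


@pytest.fixture(scope="session")
def scenario_files(fixture_dirs):
    return fixture_dirs[1]


@pytest.fixture(scope="session")
def params(params_dir):
    return load_parameters(params_dir)
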
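import warnings

import pytest

import tposcreen as tp

# The MLP does not always fully converge inside its iteration budget on the
# small desk-scale datasets used here; that is expected and harmless.
warnings.filterwarnings("ignore", message=".*Maximum iterations.*")


@pytest.fixture(scope="session")
def chemotypes() -> tp.SmartsLibrary:
    return tp.SmartsLibrary.default()


@pytest.fixture(scope="session")
def small_library():
    """A 150-compound synthetic library with default planted signal."""
    spec = tp.SyntheticSpec(n_compounds=150, seed=3)
    activity, truth = tp.generate_library(spec)
    return spec, activity, truth


@pytest.fixture(scope="session")
def small_activity_csv(tmp_path_factory, small_library):
    _, activity, _ = small_library
    path = tmp_path_factory.mktemp("data") / "activity.csv"
    activity.to_csv(path, index=False)
    return path
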
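import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230531)


# small fixture trees (newick, n_tips); mix of shapes and branch lengths
FIXTURE_TREES = [
    ("(A:1,B:1);", 2),
    ("((A:1,B:1):0.5,C:1.5);", 3),
    ("((A:0.3,B:0.9):0.5,C:1.5);", 3),
    ("(((A:1,B:1):0.5,C:1.5):0.5,D:2);", 4),
    ("((A:0.2,B:0.7):1.1,(C:0.4,D:1.3):0.6);", 4),
    ("(((A:1,B:2):0.5,(C:0.5,D:0.5):1.5):1,E:3);", 5),
    ("((((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5):0.5,F:3.5);", 6),
]


@pytest.fixture(params=FIXTURE_TREES, ids=lambda p: f"{p[1]}tips")
def fixture_tree(request):
    return request.param
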
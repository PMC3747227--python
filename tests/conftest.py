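import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_cq_csv(tmp_path):
    """4 rows x 2 genes, factors condition/timepoint, one ND and one empty cell."""
    path = tmp_path / "cq.csv"
    path.write_text(
        "sample,tech_rep,condition,timepoint,geneA,geneB\n"
        "s1,1,control,one,25.0,30.1\n"
        "s1,2,control,one,25.2,ND\n"
        "s2,1,heat,one,24.1,29.0\n"
        "s2,2,heat,one,24.3,\n"
    )
    return path


@pytest.fixture()
def toy_eff_csv(tmp_path):
    path = tmp_path / "eff.csv"
    path.write_text("gene,efficiency,cq1\ngeneA,2.0,37\ngeneB,1.9,38\n")
    return path
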
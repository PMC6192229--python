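import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-size labeled cohort shared by read-only tests."""
    from wrkyevol.synthetic_data import SimConfig, gen_cohort

    return gen_cohort(SimConfig(seed=42))


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(entries, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write
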
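import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kicscan import KicConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def config() -> KicConfig:
    return KicConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def fasta_file(tmp_path):
    """Write a small multi-FASTA and return its path."""

    def _write(entries: dict[str, str], name: str = "test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries.items():
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write
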
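import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from protacable.aa_tables import CANONICAL_AA
from protacable.seq_io import ProteinRecord
from protacable.synthetic import SimulationConfig


def random_sequence(rng, length):
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Scaled-down simulation for fast unit tests."""
    return SimulationConfig(
        n_positive=30, n_negative=35, length_range=(80, 140),
        embed_dim=32, signal_dims=(1, 2, 3, 4), seed=7,
    )


@pytest.fixture
def tiny_fasta(tmp_path):
    p = tmp_path / "tiny.fa"
    p.write_text(">p1 first protein\nMKV\n>p2\nACD\n")
    return p


@pytest.fixture
def records():
    return [
        ProteinRecord("p1", "MKVACDEFGH"),
        ProteinRecord("p2", "ACDEFGHIKL"),
        ProteinRecord("p3", "GHIKLMNPQR"),
    ]
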
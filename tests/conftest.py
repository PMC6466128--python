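import numpy as np
import pytest

from bivirome import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def edited_pileup():
    """A 10 kb reference tiled at 100x with error-free injected A-to-G edits."""
    ref = sim.random_sequence(10000, seed=11)
    cfg = sim.SimulationConfig(seed=12, coverage=100.0, edit_rate=0.05,
                               error_rate=0.0)
    sam, truth = sim.gen_edited_pileup(ref, cfg)
    return ref, sam, truth


@pytest.fixture
def sam_path(tmp_path):
    def _write(text, name="aln.sam"):
        p = tmp_path / name
        p.write_text(text)
        return p
    return _write
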
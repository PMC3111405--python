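import numpy as np
import pytest

from nucperiod import IndicatorSequence, SymbolicFragment


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def write_fasta(tmp_path):
    """Write records [(seq_id, sequence), ...] to a temp FASTA and return its path."""

    def _write(records, name="input.fasta"):
        path = tmp_path / name
        with open(path, "wt") as fh:
            for seq_id, seq in records:
                fh.write(f">{seq_id}\n{seq}\n")
        return path

    return _write


def random_indicator(rng, N, density=0.2):
    return IndicatorSequence((rng.random(N) < density).astype(np.uint8))


def random_dna(rng, N):
    return SymbolicFragment("rand", "".join(rng.choice(list("ACGT"), size=N)))
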
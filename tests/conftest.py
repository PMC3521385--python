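import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mitocount import ReferenceMito, SimSpec, simulate_dataset


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def toy_circle() -> str:
    """A 2,000 bp random circular sequence."""
    rng = np.random.default_rng(20)
    return random_dna(rng, 2000)


@pytest.fixture(scope="session")
def toy_reference(toy_circle) -> ReferenceMito:
    return ReferenceMito(id="toy", sequence=toy_circle)


def tile_reads(circle: str, read_length: int = 100, step: int = 50) -> list[str]:
    """Noiseless forward reads tiling a circular sequence."""
    doubled = circle * 2
    return [doubled[s : s + read_length] for s in range(0, len(circle), step)]


@pytest.fixture(scope="session")
def toy_tiling(toy_circle) -> list[str]:
    return tile_reads(toy_circle)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """Simulated dataset reused by classifier tests: 2 kb circle, 1% error."""
    spec = SimSpec(
        nuclear_length=50_000,
        mito_length=2000,
        true_k=50,
        n_pairs=2000,
        error_rate=0.01,
        mito_divergence=5,
        seed=11,
    )
    genome, reads = simulate_dataset(spec)
    return spec, genome, reads
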
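import numpy as np
import pytest

from satcen.simulate import MonomerSpec, SimConfig, build_panel, simulate_genome


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A scaled-down study design for fast unit tests."""
    return SimConfig(
        seed=7,
        array_copies={"cen_sat": [6, 5], "peri_satA": [8], "peri_satB": [8]},
        interspersed_copies={"ere_like": 3},
        background_length=30_000,
        n_reads_ip=4_000,
        n_reads_input=4_000,
        n_reads_rna=2_000,
        fibre_counts=(4, 3, 2),
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return build_panel(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def mutate_seq(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for b in seq:
        if rng.random() < rate:
            out.append("ACGT"[(("ACGT".index(b)) + int(rng.integers(1, 4))) % 4])
        else:
            out.append(b)
    return "".join(out)
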
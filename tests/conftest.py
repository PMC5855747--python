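from __future__ import annotations

import numpy as np
import pytest

from plastomekit import GenePlan
from plastomekit.simulate import PlastomeSpec, generate_plastome


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), length))


@pytest.fixture(scope="session")
def full_genome():
    """Default full-size synthetic plastome (Table-1-scale layout)."""
    record, truth = generate_plastome(PlastomeSpec(seed=1))
    return record, truth


@pytest.fixture(scope="session")
def small_genome():
    """A fast 16 kb quadripartite genome without genes."""
    record, truth = generate_plastome(PlastomeSpec.minimal(seed=3))
    return record, truth


@pytest.fixture(scope="session")
def layout_genome():
    """A mid-size genome exercising the junction layout and a few genes."""
    spec = PlastomeSpec(
        lsc_len=16000,
        ssc_len=9000,
        ir_len=5000,
        gene_inventory=[
            GenePlan("psbA", "protein", "LSC", (1062,), "-"),
            GenePlan("rps16", "protein", "LSC", (40, 860, 227), "+"),
            GenePlan("rps19", "protein", "LSC", (279,), "-"),
            GenePlan("rrn16", "rRNA", "IR", (1491,), "+"),
            GenePlan("ndhF", "protein", "SSC", (800,), "-"),
        ],
        seed=17,
    )
    record, truth = generate_plastome(spec)
    return record, truth
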
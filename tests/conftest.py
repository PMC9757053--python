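import logging

import numpy as np
import pytest

from cisnet.networks import build_mirna_network
from cisnet.pipeline import CohortData
from cisnet.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_cohort,
    simulate_mirna_targets,
    simulate_network,
)

logging.getLogger("cisnet").setLevel(logging.ERROR)


def build_cohort(seed: int, **overrides):
    """Simulate a full cohort and wrap it as pipeline-ready CohortData."""
    cfg = SimulationConfig(seed=seed, **overrides)
    ann = simulate_annotation(cfg)
    net = simulate_network(cfg, ann.genes)
    targets = simulate_mirna_targets(cfg, ann.arms, ann.genes)
    cohort = simulate_cohort(cfg, ann, net, targets)
    data = CohortData(
        genome=ann.genome,
        tfbs=ann.tfbs,
        exons=ann.exons,
        tss=ann.tss,
        elements=ann.elements,
        network=net,
        mirna_network=build_mirna_network(targets),
        arms=ann.arms,
        mutations=cohort["mutations"],
        counts=cohort["counts"],
        mirna_counts=cohort["mirna_counts"],
        cna=cohort["cna"],
    )
    return data, cohort, ann


@pytest.fixture(scope="session")
def planted_cohort():
    """One default-condition cohort with planted drivers, shared across tests."""
    return build_cohort(seed=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
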
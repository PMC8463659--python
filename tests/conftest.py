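import numpy as np
import pytest

from csfmir.qpcr_io import ProbePanel
from csfmir.synthetic_data import (
    DetectionEffect,
    LevelEffect,
    SimConfig,
    SynergyEffect,
    mirna_names,
    simulate,
    worked_example_fixture,
)


@pytest.fixture(scope="session")
def worked_example():
    """Tiny deterministic dataset with hand-computable expectations."""
    records, phenos, expectations = worked_example_fixture()
    return records, phenos, expectations


@pytest.fixture(scope="session")
def fixture_panel(worked_example):
    records, _, _ = worked_example
    return ProbePanel(mirna_ids=tuple(sorted({r.mirna_id for r in records})))


#: Reduced-scale simulation: keeps every structural feature of the default
#: configuration (3 groups, ECs, censoring, failures) at unit-test cost.
SMALL_SIM = SimConfig(
    group_sizes=(20, 10, 16),
    n_mirnas=50,
    seed=7,
)


@pytest.fixture(scope="session")
def small_sim():
    records, phenos, manifest = simulate(SMALL_SIM)
    return records, phenos, manifest


@pytest.fixture(scope="session")
def planted_sim():
    """Mid-scale simulation with one planted effect of each kind."""
    base = SimConfig(group_sizes=(30, 12, 24), n_mirnas=80, seed=11)
    _, targets = mirna_names(base)
    cfg = SimConfig(
        group_sizes=base.group_sizes,
        n_mirnas=base.n_mirnas,
        seed=base.seed,
        level_effects=(LevelEffect(targets[0], "DepTBI", -1.0),),
        detection_effects=(DetectionEffect(targets[1], "DepTBI", 0.85, 0.25),),
        synergy_effects=(SynergyEffect(targets[2], 2.5),),
    )
    records, phenos, manifest = simulate(cfg)
    return records, phenos, manifest, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(42)
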
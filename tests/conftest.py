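from __future__ import annotations

import numpy as np
import pytest

from parthenotrace import fixtures as fx
from parthenotrace.genotypes_io import LocusGenotype, MultilocusGenotype, Panel
from parthenotrace.synthetic_data import default_locus_models, panel_of


@pytest.fixture(scope="session")
def panel() -> Panel:
    return fx.load_panel()


@pytest.fixture(scope="session")
def offspring15(panel):
    return {g.individual_id: g for g in fx.load_parthenote_offspring()}


@pytest.fixture(scope="session")
def habitat_parthenotes():
    return fx.load_habitat_parthenotes()


@pytest.fixture(scope="session")
def known_dams():
    return fx.load_known_dams()


@pytest.fixture(scope="session")
def published_reconstructions():
    return fx.load_published_reconstructions()


@pytest.fixture(scope="session")
def trials():
    return fx.load_trials()


@pytest.fixture(scope="session")
def trial_events(trials):
    return fx.build_trial_events(trials)


@pytest.fixture(scope="session")
def locus_models():
    return default_locus_models()


@pytest.fixture(scope="session")
def synthetic_panel(locus_models):
    return panel_of(locus_models)


@pytest.fixture
def rng():
    return np.random.default_rng(20210513)


def mlg(ind_id: str, cells: dict[str, tuple], role: str = "unknown") -> MultilocusGenotype:
    """Terse multilocus-genotype builder for tests."""
    return MultilocusGenotype(
        ind_id, {locus: LocusGenotype(*pair) for locus, pair in cells.items()}, role
    )
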
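"""Shared fixtures: one default-scale simulated study reused across the
suite (session-scoped, so the expensive pieces are computed once)."""

import pytest

from barleynam import ModelB, MultiEnvTrial, simulate_heb25

#: master seed for the shared study
SEED = 11


@pytest.fixture(scope="session")
def heb():
    """Default-scale simulated study: 1,420 lines, 25 families, 2,000 markers."""
    return simulate_heb25(seed=SEED)


@pytest.fixture(scope="session")
def trial(heb):
    return MultiEnvTrial(heb.phenotypes).fit()


@pytest.fixture(scope="session")
def modelb(heb, trial):
    return ModelB(trial.blues, heb.genotypes, heb.families, heb.gmap)


@pytest.fixture(scope="session")
def gwas_fit(modelb):
    return modelb.fit(family_effects=False)


@pytest.fixture(scope="session")
def small():
    """Smaller genome for cheap structural tests."""
    return simulate_heb25(seed=5, n_markers=400)


def make_chip_fixture(n_lines=60, n_informative=5709, n_mono=1027,
                      n_highmiss=1128, seed=0):
    """Chip-scale raw call table built programmatically: informative markers
    with both homozygote classes, fully monomorphic markers, and markers
    with >10% no-calls, in shuffled column order."""
    import numpy as np
    import pandas as pd
    rng = np.random.default_rng(seed)
    cols = {}
    states = np.array(["AA", "AB", "BB"], dtype=object)
    for j in range(n_informative):
        calls = states[rng.choice(3, n_lines, p=[0.72, 0.06, 0.22])]
        calls[:2] = ["AA", "BB"]          # guarantee polymorphism
        cols[f"inf{j}"] = calls
    for j in range(n_mono):
        cols[f"mono{j}"] = np.repeat("AA", n_lines)
    n_missing = int(np.floor(0.10 * n_lines)) + 1   # strictly > 10%
    for j in range(n_highmiss):
        calls = states[rng.choice(3, n_lines, p=[0.72, 0.06, 0.22])].astype(object)
        calls[:2] = ["AA", "BB"]
        calls[rng.choice(n_lines, n_missing, replace=False)] = pd.NA
        cols[f"miss{j}"] = calls
    df = pd.DataFrame(cols, index=[f"L{i}" for i in range(n_lines)])
    return df[rng.permutation(df.columns)]


@pytest.fixture(scope="session")
def chip_raw():
    return make_chip_fixture()
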
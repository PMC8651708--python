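import numpy as np
import pytest

import polytrainsel as pts


@pytest.fixture(scope="session")
def small_panel():
    """Complete 30 x 80 tetraploid panel, 3 strata."""
    return pts.simulate_panel(pts.SimConfig(n_individuals=30, n_markers=80, seed=11))


@pytest.fixture(scope="session")
def mid_panel():
    """60 x 300 panel used by sampler/model tests."""
    return pts.simulate_panel(pts.SimConfig(n_individuals=60, n_markers=300, seed=7))


@pytest.fixture(scope="session")
def default_panel():
    """The full-scale study panel: 190 individuals x 3,262 markers, 3 strata."""
    return pts.simulate_panel(pts.SimConfig(seed=33))


@pytest.fixture(scope="session")
def tv_records_default(default_panel):
    """Desk-scale training-validation run on the full panel.

    4 sampling methods x 5 training sizes x 20 replicates, GBLUP and
    BayesC-pi (1,000 iterations / 500 burn-in) on one simulated trait.
    Shared by the qualitative-reproduction checks and the size-trend check.
    """
    trait = pts.simulate_trait(
        default_panel, n_qtl=20, h2=0.85, seed=5, name="fructose_like"
    )
    return pts.run_tv_scheme(
        default_panel,
        [trait],
        models=("GBLUP", "BAYESC"),
        sizes=(50, 75, 100, 125, 150),
        reps=20,
        seed=17,
    )


def make_panel(dosages, ploidy=4, missing=None, **kw):
    dosages = np.asarray(dosages)
    return pts.DosagePanel(
        genotype_ids=[f"g{i}" for i in range(dosages.shape[0])],
        dosages=dosages,
        ploidy=ploidy,
        missing=missing,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
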
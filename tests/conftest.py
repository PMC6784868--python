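import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_world():
    """The default small synthetic world used across modules."""
    from rubmi.synthetic_world import generate_world

    return generate_world(seed=1)


@pytest.fixture(scope="session")
def recovery_fit(default_world):
    """One full fit of the trend model (women) on the default world.

    Shared across parameter-recovery, gap-recovery and postprocessing
    consistency tests so the expensive MCMC runs once per session.
    """
    from rubmi.trend_model import fit_world

    return fit_world(default_world, "female", n_draws=800, burn=400, seed=3)


@pytest.fixture(scope="session")
def crosswalk_setup():
    """World with prevalence-only rows plus a crosswalk trained on the rest."""
    from rubmi.crosswalk import fit_crosswalk, make_training_pairs
    from rubmi.synthetic_world import generate_world, make_prevalence_only_subset

    world = generate_world(seed=4)
    keep, prev = make_prevalence_only_subset(world.observations, world.config)
    model = fit_crosswalk(make_training_pairs(keep))
    return keep, prev, model


@pytest.fixture(scope="session")
def make_population():
    """Factory for hand-built population tables in small targeted tests."""
    import xarray as xr

    from rubmi.synthetic_world import PopulationTable

    def _make(countries, years, sexes, ages, share=0.5, population=1000.0):
        dims = ("country", "year", "sex", "age")
        coords = {"country": countries, "year": years, "sex": sexes, "age": ages}
        shape = tuple(len(coords[d]) for d in dims)
        pop = xr.DataArray(np.full(shape, float(population)), dims=dims, coords=coords)
        sh = xr.DataArray(np.full(shape, float(share)), dims=dims, coords=coords)
        return PopulationTable(population=pop, share_urban=sh)

    return _make
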
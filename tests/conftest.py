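import datetime as dt

import pytest

from windgain.simulate import (
    ColonyScenario,
    SeasonWindow,
    WindScenario,
    simulate_colony,
)


def small_windows(days: int = 20, guard_days: int = 6) -> tuple[SeasonWindow, ...]:
    """One short season starting mid-December."""
    start = dt.date(2009, 12, 11)
    return (
        SeasonWindow(
            label="2009/10",
            start=start,
            guard_end=start + dt.timedelta(days=guard_days - 1),
            end=start + dt.timedelta(days=days - 1),
        ),
    )


def creche_windows(days: int = 20) -> tuple[SeasonWindow, ...]:
    """A season that is crèche throughout (guard window empty)."""
    start = dt.date(2010, 1, 1)
    return (
        SeasonWindow(
            label="2009/10",
            start=start,
            guard_end=start - dt.timedelta(days=1),
            end=start + dt.timedelta(days=days - 1),
        ),
    )


def small_colony(seed: int, days: int = 20, n_birds: int = 24, **kw) -> ColonyScenario:
    return ColonyScenario(
        n_birds=n_birds,
        season_windows=small_windows(days),
        rng_seed=seed,
        **kw,
    )


def small_wind(seed: int, days: int = 20, **kw) -> WindScenario:
    return WindScenario(n_days=days, rng_seed=seed, **kw)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario simulation shared across tests (read-only)."""
    colony = ColonyScenario(rng_seed=101)
    wind = WindScenario(n_days=60, rng_seed=202)
    return simulate_colony(colony, wind)
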
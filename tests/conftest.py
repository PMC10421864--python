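import numpy as np
import pytest

import lucflux as lf


@pytest.fixture(scope="session")
def params():
    return lf.default_parameters()


@pytest.fixture(scope="session")
def central(params):
    return lf.select_scenario(params, "central")


def random_scene(seed, width=10, height=10, n_years=5, central=None,
                 max_fires=4, max_transitions=3):
    """A randomised but fully scripted toy world for property tests."""
    rng = np.random.default_rng(seed)
    n = width * height
    base = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.5, 0.2, 0.15, 0.1, 0.05])
    year0 = 2000
    years = list(range(year0, year0 + n_years))
    transitions = []
    for _ in range(rng.integers(0, max_transitions + 1)):
        cells = tuple(rng.choice(n, size=rng.integers(1, 6), replace=False).tolist())
        transitions.append(
            lf.Transition(cells=cells, year=int(rng.choice(years[1:])),
                          to=lf.Category(int(rng.integers(1, 6))))
        )
    fires = []
    for _ in range(rng.integers(0, max_fires + 1)):
        days = tuple(sorted(rng.choice(np.arange(1, 366),
                                       size=rng.integers(1, 5), replace=False).tolist()))
        fires.append(
            lf.FireEvent(cell=int(rng.integers(0, n)), year=int(rng.choice(years[1:])),
                         days=days,
                         confidence=str(rng.choice(["low", "nominal", "high"])))
        )
    peat = rng.choice(n, size=max(1, n // 5), replace=False).tolist()
    region = (np.arange(n) >= n // 2).astype(int)
    cfg = lf.SceneConfig(
        width=width, height=height, year_start=year0, year_end=years[-1],
        base=base, transitions=transitions, fires=fires, peat_cells=peat,
        region_id=region, agb0_jitter_sd=5.0,
    )
    return lf.build_scene(cfg, seed=seed, params=central)


@pytest.fixture(scope="session")
def quiet_forest_scene(central):
    """All-forest, no fires, no transitions, no peat."""
    cfg = lf.SceneConfig(width=6, height=6, year_start=2000, year_end=2004)
    return lf.build_scene(cfg, seed=0, params=central)
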
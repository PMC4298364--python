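from dataclasses import replace

import numpy as np
import pytest

import hscsoma as h


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_config():
    """Tiny, fast configuration: 50 cells, 200 weeks, 200-cell capacity."""
    cfg = h.get_preset("mutations_only")
    return replace(
        cfg,
        lifespan_weeks=200,
        initial_cells=50,
        schedules=replace(cfg.schedules, initial_size=50, adult_size=200),
        seed=7,
    )


def desk_scale(preset: str, seed: int = 0, **over):
    """A full-lifespan run scaled to a 2,000-cell adult pool."""
    cfg = h.get_preset(preset)
    cfg = replace(
        cfg,
        schedules=replace(cfg.schedules, adult_size=2000),
        record_cadence=26,
        seed=seed,
    )
    return replace(cfg, **over) if over else cfg
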
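"""Deterministic fixture generation for demos, audits and smoke tests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import AML_TIER3_SLOPE, WEEKS_PER_YEAR
from .metrics import default_incidence_curve


def generate_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the standard plain-text fixtures into ``out_dir``.

    Produces, deterministically (byte-identical across runs):

    * ``incidence_reference.csv`` — the synthetic age-vs-incidence curve;
    * ``tier3_linear_fixture.csv`` — a noiseless trajectory whose pool-mean
      Tier-3 count rises at exactly the reference AML slope
      (0.09162 mutations/year), for validating the slope estimator;
    * ``smoke_config.yaml`` — a tiny configuration (50 cells, 200 weeks)
      that runs in seconds.

    Returns the list of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    incidence_path = out / "incidence_reference.csv"
    default_incidence_curve().to_csv(incidence_path)
    written.append(incidence_path)

    weeks = np.arange(0, 4421, 52, dtype=np.int64)
    ages = weeks / WEEKS_PER_YEAR
    fixture = pd.DataFrame(
        {
            "week": weeks,
            "pool_size": np.full(len(weeks), 11_000, dtype=np.int64),
            "mean_fitness": np.ones(len(weeks)),
            "mean_tier3": AML_TIER3_SLOPE * ages,
            "top_clone_share": np.full(len(weeks), 1.0 / 300.0),
            "n_clones": np.full(len(weeks), 300, dtype=np.int64),
        }
    )
    fixture_path = out / "tier3_linear_fixture.csv"
    fixture.to_csv(fixture_path, index=False)
    written.append(fixture_path)

    smoke = {
        "preset": "mutations_only",
        "lifespan_weeks": 200,
        "initial_cells": 50,
        "seed": 0,
        "demography": {"initial_size": 50, "adult_size": 200},
    }
    smoke_path = out / "smoke_config.yaml"
    with open(smoke_path, "w") as handle:
        yaml.safe_dump(smoke, handle, sort_keys=True)
    written.append(smoke_path)
    return written
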
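import math

import numpy as np
import pandas as pd
import pytest

from mangovol.data import RECORD_COLUMNS, Dataset, dataset_from_scenes
from mangovol.synth import make_fruit_population, render_views


def analytic_dataset(fruits) -> Dataset:
    """Exact modeling table from fruit specs, bypassing rasterization.

    Projected areas and dimensions follow from the generating ellipsoid in
    closed form, so V_e equals the true volume exactly.  Used where a test
    needs the modeling table's structure rather than rendering noise.
    """
    rows = []
    for f in fruits:
        a_s = math.pi * f.semi_axis_h * f.semi_axis_d
        a_b = math.pi * f.semi_axis_w * f.semi_axis_d
        rows.append(
            {
                "id": f.id,
                "A_s": a_s,
                "A_b": a_b,
                "A_s15": a_s**1.5,
                "A_b15": a_b**1.5,
                "h": 2 * f.semi_axis_h,
                "w": 2 * f.semi_axis_w,
                "d1": 2 * f.semi_axis_d,
                "d2": 2 * f.semi_axis_d,
                "V_e": f.volume,
                "mass_g": f.mass,
                "v_true": f.volume,
                "origin": "real",
            }
        )
    return Dataset(pd.DataFrame(rows, columns=RECORD_COLUMNS), provenance="analytic")


def render_dataset(n, seed, mm_per_px=0.5, exclude_calyx=True, **population_kwargs):
    fruits = make_fruit_population(n, seed=seed, **population_kwargs)
    rng = np.random.default_rng(seed + 1000)
    pairs = [render_views(f, mm_per_px, rng=rng) for f in fruits]
    return dataset_from_scenes(pairs, exclude_calyx=exclude_calyx)


@pytest.fixture(scope="session")
def fleet_pairs():
    """200 rendered fruits at 0.5 mm/px, reused across modules (read-only)."""
    fruits = make_fruit_population(200, seed=1)
    rng = np.random.default_rng(2)
    return [render_views(fruit, 0.5, rng=rng) for fruit in fruits]


@pytest.fixture(scope="session")
def fleet_dataset(fleet_pairs):
    return dataset_from_scenes(fleet_pairs)
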
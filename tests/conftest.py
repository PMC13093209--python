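import numpy as np
import pytest

import sdmshift as s


@pytest.fixture(scope="session")
def small_stack():
    """60x60 stack: trending temperature, two noise layers, one categorical."""
    cfg = s.LandscapeConfig(
        n_rows=60,
        n_cols=60,
        origin_lon=100.0,
        origin_lat=35.0,
        layer_specs=[
            s.LayerSpec("temp", trend_slope=-1.0, std=0.5),
            s.LayerSpec("precip"),
            s.LayerSpec("elev"),
            s.LayerSpec("landcov", kind="categorical", n_classes=3),
        ],
        seed=11,
    )
    return s.generate_env_stack(cfg)


@pytest.fixture(scope="session")
def strong_species(small_stack):
    """Sharp single-driver niche on temperature: near-binary suitability."""
    return s.make_virtual_species(small_stack, [("temp", 0.0, 0.5, 30.0)], 0.05)


@pytest.fixture(scope="session")
def fitted_ensemble(small_stack, strong_species):
    """A small fitted committee (GLM + GAM, 4 folds) with its training data."""
    occ = s.sample_presences(strong_species, small_stack, 120, seed=21)
    pa = s.sample_pseudo_absences(small_stack, occ, n=600, seed=22)
    cont = small_stack.continuous_names()
    levels = {
        n: sorted(
            np.unique(small_stack.layers[n].values[small_stack.mask]).tolist()
        )
        for n in small_stack.categorical_names()
    }
    pres = s.extract_values(small_stack, occ)
    pres = pres[~pres["masked"]].drop(columns=["masked"])
    ab = s.extract_values(small_stack, pa)
    ab = ab[~ab["masked"]].drop(columns=["masked"])
    data = s.make_folds(
        s.encode_predictors(pres, levels), s.encode_predictors(ab, levels), k=4, seed=23
    )
    evals = s.evaluate_algorithms(
        ["GLM", "GAM"], data, continuous=cont, seed=24, categorical_levels=levels
    )
    committee = s.select_members(evals, tss_min=0.5)
    import pandas as pd

    raw = pd.concat([pres, ab], ignore_index=True)[
        cont + small_stack.categorical_names()
    ]
    return {
        "stack": small_stack,
        "committee": committee,
        "data": data,
        "evals": evals,
        "raw_rows": raw,
        "levels": levels,
    }
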
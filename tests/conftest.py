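import numpy as np
import pandas as pd
import pytest

from grazefd import synth
from grazefd.traits import DEFAULT_SCHEMES, RawTraitEntry, build_trait_table


@pytest.fixture(scope="session")
def small_trait_table():
    """Four species with hand-set LDMC/SLA and minimal coded traits."""
    entries = []
    specs = {
        "spA": {"ldmc_mg_per_g": 200.0, "sla_mm2_per_mg": 25.0, "canopy_height_m": 0.2,
                "leaf_size_mm2": 400.0, "flowering_start_month": 5, "life_form": "Hemicryptophyte",
                "canopy_structure": "Rosette", "leafing_period": "Evergreen",
                "life_span": "Perennial", "veg_spread_rhizome": "Rhizomatous",
                "veg_spread_stolon": "Not stoloniferous"},
        "spB": {"ldmc_mg_per_g": 300.0, "sla_mm2_per_mg": 15.0, "canopy_height_m": 0.5,
                "leaf_size_mm2": 900.0, "flowering_start_month": 6, "life_form": "Chamaephyte",
                "canopy_structure": "Erosulate", "leafing_period": "Summer green",
                "life_span": "Perennial", "veg_spread_rhizome": "Not rhizomatous",
                "veg_spread_stolon": "Stoloniferous"},
        "spC": {"ldmc_mg_per_g": 250.0, "sla_mm2_per_mg": 20.0, "canopy_height_m": 0.35,
                "leaf_size_mm2": 600.0, "flowering_start_month": 7, "life_form": "Geophyte",
                "canopy_structure": "Hemirosette", "leafing_period": "Evergreen",
                "life_span": "Annual", "veg_spread_rhizome": "Not rhizomatous",
                "veg_spread_stolon": "Not stoloniferous"},
        "spD": {"ldmc_mg_per_g": 350.0, "sla_mm2_per_mg": 10.0, "canopy_height_m": 0.8,
                "leaf_size_mm2": 1500.0, "flowering_start_month": 4, "life_form": "Therophyte",
                "canopy_structure": "Rosette", "leafing_period": "Summer green",
                "life_span": "Biennial", "veg_spread_rhizome": "Rhizomatous",
                "veg_spread_stolon": "Stoloniferous"},
    }
    for sp, traits in specs.items():
        for trait, value in traits.items():
            entries.append(RawTraitEntry(sp, trait, value))
    return build_trait_table(entries, DEFAULT_SCHEMES)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded synthetic dataset at the default design."""
    return synth.generate_dataset(synth.GeneratorConfig(seed=12345))


@pytest.fixture(scope="session")
def fast_dataset():
    """Seeded dataset without the MST-based metrics, for model tests."""
    return synth.generate_dataset(synth.GeneratorConfig(seed=2024, compute_feve=False))


def random_community(rng, n_rows, species):
    p = rng.dirichlet(np.ones(len(species)) * 0.7, size=n_rows)
    idx = pd.MultiIndex.from_tuples(
        [("E01", "B1", f"P{i}", 2000) for i in range(n_rows)],
        names=["experiment", "block", "plot", "year"],
    )
    return pd.DataFrame(p, index=idx, columns=species)
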
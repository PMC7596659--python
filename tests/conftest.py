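import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from chipbiome import array_quant as aq
from chipbiome import synthetic_data as sd
from chipbiome.containers import ArrayManifest, SpotTable

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> sd.SimulationConfig:
    """Compact cohort: 24 samples, 40-probe array, 4 planted species at 4x."""
    return sd.SimulationConfig(
        n_all=14, n_nc=10, n_species=40, n_differential=4,
        fold_min=4.0, fold_max=4.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> sd.SimulatedCohort:
    return sd.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return aq.quantify_cohort(small_cohort.spot_tables, small_cohort.manifest)


def make_instance(rng: np.random.Generator, n_species: int | None = None, allow_ties: bool = True):
    """Random small array instance: (SpotTable, ArrayManifest)."""
    if n_species is None:
        n_species = int(rng.integers(4, 13))
    rows = []
    manifest_rows = []
    for i in range(n_species):
        probe = f"p{i:02d}"
        manifest_rows.append(
            {"probe_id": probe, "species": f"sp{i:02d}", "genus": f"g{i // 2}",
             "family": f"f{i // 4}", "order": f"o{i // 8}"}
        )
        n_spots = int(rng.integers(1, 4))
        for _ in range(n_spots):
            if allow_ties and rng.random() < 0.3:
                cy5 = float(rng.integers(1, 20) * 50)
                cy3 = float(rng.integers(1, 8) * 100)
            else:
                cy5 = float(rng.uniform(10, 5000))
                cy3 = float(rng.uniform(50, 800))
            rows.append({"probe_id": probe, "cy5": cy5, "cy3": cy3})
    spots = SpotTable(sample_id="s1", data=pd.DataFrame(rows))
    manifest = ArrayManifest(pd.DataFrame(manifest_rows).set_index("probe_id"))
    return spots, manifest
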
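import pandas as pd
import pytest
from hypothesis import settings

from settlecarbon import cleaning, reconcile, synth

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic landscape (mixed biomes, urban patches, clouds)."""
    return synth.generate(synth.SyntheticConfig(seed=3))


@pytest.fixture(scope="session")
def cleaned(dataset):
    out, _ = cleaning.clean_settlements(
        dataset.settlements, dataset.registry, dataset.region_boundary
    )
    return out


@pytest.fixture(scope="session")
def fragments(dataset, cleaned) -> pd.DataFrame:
    return reconcile.reconcile(
        cleaned, dataset.prodes, dataset.pmdbbs, dataset.carbon,
        hydro_class_id=synth.HYDRO_CLASS, urban_class_id=synth.URBAN_CLASS,
    )
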
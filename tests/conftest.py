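import pytest

from ahisplex.catalog import load_catalog, load_chrom_lengths
from ahisplex.classify import load_rules
from ahisplex.model import load_model
from ahisplex.simulate import panel_from_catalog, sample_individuals
from ahisplex.workflow import default_model_path, default_rules_path


@pytest.fixture(scope="session")
def catalog38():
    return load_catalog(build="GRCh38")


@pytest.fixture(scope="session")
def lengths38():
    return load_chrom_lengths(build="GRCh38")


@pytest.fixture(scope="session")
def demo_model(catalog38):
    return load_model(default_model_path(), catalog38)


@pytest.fixture(scope="session")
def rules():
    return load_rules(default_rules_path())


@pytest.fixture(scope="session")
def small_panel(catalog38):
    """Catalog-embedded panel small enough for per-test imputation runs."""
    return panel_from_catalog(catalog38, n_hap=60, fillers_per_marker=10, seed=11)


@pytest.fixture(scope="session")
def small_individuals(small_panel):
    return sample_individuals(small_panel, n=6, seed=12)
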
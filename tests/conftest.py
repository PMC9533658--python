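import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from potholeveg.survey import (
    HydroClass,
    Observation,
    WetlandSite,
    WetlandSurvey,
    Zone,
)
from potholeveg.traits import (
    GrowthForm,
    Lifespan,
    Nativity,
    SpeciesTrait,
    TraitTable,
)


@pytest.fixture
def four_species_traits() -> TraitTable:
    """Trait table for the four-species worked example."""
    tt = TraitTable(provenance="worked example")
    tt.add(SpeciesTrait("Andropogon gerardii", "Andropogon",
                        Nativity.NATIVE, Lifespan.PERENNIAL, GrowthForm.GRASS, 8))
    tt.add(SpeciesTrait("Balsamorhiza sagittata", "Balsamorhiza",
                        Nativity.NATIVE, Lifespan.PERENNIAL, GrowthForm.FORB, 5))
    tt.add(SpeciesTrait("Bromus inermis", "Bromus",
                        Nativity.INTRODUCED, Lifespan.PERENNIAL, GrowthForm.GRASS))
    tt.add(SpeciesTrait("Dalea candida", "Dalea",
                        Nativity.NATIVE, Lifespan.ANNUAL, GrowthForm.FORB, 1))
    return tt


@pytest.fixture
def four_species_survey() -> WetlandSurvey:
    """Seasonal survey: two wet-meadow natives, two low-prairie species."""
    site = WetlandSite("wl-01", HydroClass.SEASONALLY_PONDED, "native", 2020)
    obs = [
        Observation("Andropogon gerardii", Zone.WET_MEADOW, 9),
        Observation("Balsamorhiza sagittata", Zone.LOW_PRAIRIE, 1),
        Observation("Bromus inermis", Zone.LOW_PRAIRIE, 1),
        Observation("Dalea candida", Zone.WET_MEADOW, 10),
    ]
    return WetlandSurvey(site=site, observations=obs)
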
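"""Shared fixtures: printed worked-example compositions and a session-scoped
default synthetic dataset with its fitted classifier (expensive, reused)."""

from __future__ import annotations

import numpy as np
import pytest

from crancoda import (
    CvConfig,
    GeneratorConfig,
    ObservationRecord,
    TissueComposition,
    close_composition,
    confusion_partition,
    generate_dataset,
    train_classifier,
)
from crancoda.simulate import (
    DENSITY_FIELDS,
    FERTILIZER_ELEMENTS,
    MONTHS,
    SOIL_TEST_FIELDS,
    TEXTURE_FIELDS,
)

# Worked diagnostic cases: printed tissue rows (g/kg) of the defective and
# closest successful specimens for the two cultivars, plus the regional
# true-negative average and the next-year reference composition.
DEFECTIVE_QC_STEVENS = (12.1, 1.1, 4.0, 1.5, 8.2, 0.030, 0.005, 0.030, 0.220, 0.090)
SUCCESSFUL_QC_STEVENS = (10.1, 1.0, 4.7, 1.9, 9.0, 0.029, 0.006, 0.018, 0.222, 0.097)
DEFECTIVE_WI_CRIMSON = (10.2, 1.4, 6.9, 2.0, 9.3, 0.024, 0.004, 0.017, 1.198, 0.060)
SUCCESSFUL_WI_CRIMSON = (12.3, 1.5, 6.2, 2.8, 14.7, 0.053, 0.003, 0.020, 0.339, 0.074)
TN_AVERAGE = (10.6, 1.1, 5.4, 2.0, 8.9, 0.052, 0.004, 0.021, 0.355, 0.117)
NEXT_YEAR_REFERENCE = (11.4, 0.7, 4.8, 1.5, 5.7, 0.043, 0.003, 0.048, 0.197, 0.077)

YIELD_DEFECTIVE_QC = 26.7
YIELD_SUCCESSFUL_QC = 57.6
YIELD_DEFECTIVE_WI = 11.7
YIELD_SUCCESSFUL_WI = 62.8
YIELD_NEXT_YEAR_REF = 57.1


def make_record(
    nutrients,
    yield_t: float,
    cultivar: str = "Stevens",
    region: str = "Quebec",
    site: str = "S01",
    bed: str = "S01-B01",
    year: int = 2016,
) -> ObservationRecord:
    """A schema-complete record around a given tissue row (dummy covariates)."""
    comp = (nutrients if isinstance(nutrients, TissueComposition)
            else close_composition(nutrients))
    texture = dict(zip(TEXTURE_FIELDS, (2.0, 5.0, 3.0, 20.0, 40.0, 25.0, 5.0)))
    return ObservationRecord(
        region=region, site=site, bed=bed, year=year,
        cultivar=cultivar, farming_system="conventional",
        fertilization={e: 10.0 for e in FERTILIZER_ELEMENTS},
        composition=comp,
        soil={s: (4.8 if s == "pH" else 10.0) for s in SOIL_TEST_FIELDS},
        texture=texture,
        bulk_density={d: 1.3 for d in DENSITY_FIELDS},
        soil_series="St-Judes",
        temperature={m: 15.0 for m in MONTHS},
        precipitation={m: 100.0 for m in MONTHS},
        yield_t=yield_t,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic survey: 10 sites × 20 beds × 5 years."""
    return generate_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_classifier(default_dataset):
    """Full-feature classifier on the default survey, 10-fold CV."""
    return train_classifier(default_dataset, cv=CvConfig(folds=10, seed=0))


@pytest.fixture(scope="session")
def default_quadrants(default_classifier):
    return confusion_partition(default_classifier)


@pytest.fixture(scope="session")
def small_dataset():
    """A small survey for cheap unit tests: 4 sites × 6 beds × 3 years."""
    return generate_dataset(
        GeneratorConfig(seed=3, n_sites=4, n_beds_per_site=6, years=(2015, 2016, 2017))
    )
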
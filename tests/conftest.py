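"""Shared fixtures: one fully simulated cohort (seed 1) and its processed
tables, reused across test modules to keep the suite fast."""

from __future__ import annotations

import pytest

from osteomet import build_default_library, process_cells, process_media
from osteomet.simulate import CohortConfig, simulate_cohort

DEMO_SEED = 1


@pytest.fixture(scope="session")
def library():
    return build_default_library()


@pytest.fixture(scope="session")
def cohort(library):
    """Default-condition cohort: study design, planted effects, seed 1."""
    return simulate_cohort(library, CohortConfig(seed=DEMO_SEED))


@pytest.fixture(scope="session")
def endo_table(library, cohort):
    cells, _, _, _ = cohort
    return process_cells(cells, library)


@pytest.fixture(scope="session")
def exo_tables(library, cohort):
    _, media, blanks, _ = cohort
    return process_media(media, blanks, library)


@pytest.fixture(scope="session")
def noise_free_cohort(library):
    cfg = CohortConfig(seed=DEMO_SEED, noise_sd=0.0, shift_jitter_sd=0.0,
                       global_shift_sd=0.0, bio_cv=0.0, blank_cv=0.0,
                       missing_pattern=[])
    return simulate_cohort(library, cfg), cfg


def small_grid_config(**kw) -> CohortConfig:
    """A light config for tests that only need structural behavior."""
    defaults = dict(n_points=2048, seed=DEMO_SEED)
    defaults.update(kw)
    return CohortConfig(**defaults)
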
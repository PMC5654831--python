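import logging

import numpy as np
import pytest

from shotgunlipids.nomenclature import build_species_database
from shotgunlipids.pipeline import analyze, quantify_cohort, simulate
from shotgunlipids.synthetic import CohortConfig, SpectrumNoiseModel

logging.getLogger("shotgunlipids").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def db():
    return build_species_database()


@pytest.fixture(scope="session")
def zero_noise_run(db):
    """Noise-free cohort (cv=0, additive noise off, envelope on) with its
    recovered concentration table; the generator truth is the oracle."""
    config = CohortConfig(seed=1, cv=0.0)
    noise = SpectrumNoiseModel(baseline=0.0, noise_sd=0.0, envelope=True)
    truth, spectra, _ = simulate(config, noise=noise, db=db)
    conc = quantify_cohort(truth.samples, truth.internal_standards, spectra,
                           db=db)
    return truth, conc


@pytest.fixture(scope="session")
def default_cohort_run(db):
    """The default study conditions (CohortConfig(): 5 strains x 2 diets x
    4 replicates, cv 0.2, full noise model) quantified and analyzed end to
    end."""
    config = CohortConfig()
    truth, spectra, _ = simulate(config, db=db)
    conc = quantify_cohort(truth.samples, truth.internal_standards, spectra,
                           db=db)
    return truth, conc, analyze(conc)


def truth_matrix_relative_error(truth, conc):
    merged = conc.merge(
        truth.concentrations.rename(columns={"true_nmol_per_mg": "truth"}),
        on=["sample_id", "species"], how="outer")
    rel = np.abs(merged["concentration"] - merged["truth"]) / merged["truth"]
    return merged, rel
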
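"""Shotgun-lipidomics quantification and muscle lipidome diet-response
analysis.

The package takes per-sample precursor/neutral-loss scan peak lists (real
or simulated) through isotope-corrected internal-standard quantification,
isobaric molecular-species resolution, derived membrane-composition
metrics (PC/PE ratio, PUFA category sums, diet deltas) and a screened
ANOVA + protected Fisher's LSD significance pipeline.
"""

from importlib import resources

import pandas as pd

from .chem import ElementalComposition
from .nomenclature import (
    AcylClassification,
    ChainSpace,
    FattyAcyl,
    LipidSpecies,
    SpeciesDatabase,
    build_species_database,
    classify_acyl,
    count_pufa_chains,
    elemental_composition,
    format_shorthand,
    parse_shorthand,
)
from .pipeline import ProcessingParams, analyze, quantify_cohort, simulate
from .synthetic import (
    CohortConfig,
    EffectModel,
    SpectrumNoiseModel,
    ZERO_NOISE,
    generate_cohort_truth,
    synthesize_spectra,
)

__version__ = "0.1.0"


def load_reference_class_totals() -> pd.DataFrame:
    """Published muscle class-total table (mean +/- SEM, nmol/mg, n = 4).

    A packaged fixture of per-class totals for five inbred mouse strains on
    chow and high-fat diets, with per-class species counts and directional
    significance counts; used for downstream arithmetic (ratios, deltas)
    and as a magnitude reference for the synthetic cohort defaults.
    """
    with resources.files("shotgunlipids.data").joinpath(
            "reference_class_totals.csv").open() as fh:
        return pd.read_csv(fh)


__all__ = [
    "AcylClassification", "ChainSpace", "CohortConfig", "EffectModel",
    "ElementalComposition", "FattyAcyl", "LipidSpecies", "ProcessingParams",
    "SpeciesDatabase", "SpectrumNoiseModel", "ZERO_NOISE", "analyze",
    "build_species_database", "classify_acyl", "count_pufa_chains",
    "elemental_composition", "format_shorthand", "generate_cohort_truth",
    "load_reference_class_totals", "parse_shorthand", "quantify_cohort",
    "simulate", "synthesize_spectra",
]
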
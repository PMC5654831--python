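"""Run configuration: one flat YAML file covering simulation, processing
and statistics.

Every study constant lives here exactly once — the s/n inclusion threshold
(10), the ether-PE response factor (3.45), the omnibus screen (0.05), the
LSD threshold (0.01) and the group size (4 replicates) — and every field
can be overridden from the file or from CLI flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .pipeline import ProcessingParams
from .synthetic import CohortConfig, EffectModel, SpectrumNoiseModel


@dataclass
class RunConfig:
    """Flat key-value run configuration with documented defaults."""

    # cohort design
    seed: int = 0
    replicates_per_group: int = 4
    cv: float = 0.2
    tissue_mass_mg: float = 25.0
    tag_hfd_factor: float = 2.0
    double_pufa_hfd_factor: float = 0.6
    protected_strain: str = "BALB/c"
    # instrument model
    response: float = 1.0e5
    baseline: float = 30.0
    noise_sd: float = 30.0
    envelope: bool = True
    envelope_model: str = "binomial"
    ether_pe_suppression: float = 3.45
    # processing
    snr_threshold: float = 10.0
    smooth_window: int = 1
    mz_tolerance: float = 0.3
    isotope_correction: bool = True
    ether_pe_factor: float = 3.45
    pair_evidence: str = "sum"
    # statistics
    screen_alpha: float = 0.05
    lsd_alpha: float = 0.01
    anova_mode: str = "cells"

    def __post_init__(self) -> None:
        for name in ("snr_threshold", "mz_tolerance", "screen_alpha",
                     "lsd_alpha", "ether_pe_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- assembled sub-configs ----------------------------------------------

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            replicates_per_group=self.replicates_per_group, seed=self.seed,
            cv=self.cv, tissue_mass_mg=self.tissue_mass_mg,
            effect_model=EffectModel(
                tag_hfd_factor=self.tag_hfd_factor,
                double_pufa_hfd_factor=self.double_pufa_hfd_factor,
                protected_strain=self.protected_strain))

    def noise_model(self) -> SpectrumNoiseModel:
        return SpectrumNoiseModel(
            response=self.response, baseline=self.baseline,
            noise_sd=self.noise_sd, envelope=self.envelope,
            envelope_model=self.envelope_model,
            ether_pe_suppression=self.ether_pe_suppression)

    def processing_params(self) -> ProcessingParams:
        return ProcessingParams(
            snr_threshold=self.snr_threshold,
            smooth_window=self.smooth_window,
            mz_tolerance=self.mz_tolerance,
            isotope_correction=self.isotope_correction,
            envelope_model=self.envelope_model,
            ether_pe_factor=self.ether_pe_factor,
            pair_evidence=self.pair_evidence,
            screen_alpha=self.screen_alpha, lsd_alpha=self.lsd_alpha,
            anova_mode=self.anova_mode)

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
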
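"""Synthetic cohorts and scan spectra with the study's statistical structure.

The generator emulates a 5-strain x 2-diet mouse muscle cohort (n = 4 per
group, 25 mg tissue per sample) profiled by direct-infusion (shotgun)
lipidomics: per-sample peak lists for the positive-mode 184.1 phosphocholine
precursor scan (PC/PC-O, and SM in a separately hydrolyzed extract), the 141
neutral-loss PE scan (PE/PE-O, ether species suppressed 3.45-fold), class
scans for TAG/DAG/CE/PS/CER, and negative-mode fatty-acyl precursor channels
used to resolve isobaric molecular species.

The default effect model encodes the diet response the analysis is meant to
detect: high-fat feeding doubles TAG species, leaves DAG/CER/SM unchanged,
shifts phospholipid acyl composition toward n-6 at the expense of n-3, and
reduces double-PUFA phospholipids in four strains but not in the protected
strain (BALB/c).  Double-PUFA species are seeded at ~1.6% of the
phospholipid pool, inside the 1.0-2.6% band such species occupy in muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import NEUTRON_SPACING, envelope_for
from .nomenclature import (
    DEFAULT_OMEGA_TABLE,
    LipidSpecies,
    ScanChannel,
    SpeciesDatabase,
    classify_acyl,
    count_pufa_chains,
    fa_channel,
    parse_shorthand,
)
from .spectra import ScanSpectrum

DEFAULT_STRAINS = ("C57BL/6", "129X1", "BALB/c", "DBA/2", "FVB/N")
DIETS = ("CHOW", "HFD")

#: per-species CHOW baseline means, nmol/mg tissue.  Class totals are scaled
#: to the magnitudes typical of mouse skeletal muscle (TAG ~8, PC ~11,
#: PE ~3, sphingolipids ~0.1-0.3 nmol/mg).
DEFAULT_BASE_MEANS: dict[str, float] = {
    # PC molecular species (most abundant: 16:0/18:1, 16:0/18:2, 16:0/20:4,
    # 16:0/22:6)
    "PC 16:0/18:1": 3.0, "PC 16:0/18:2": 2.2, "PC 16:0/20:4": 1.6,
    "PC 16:0/22:6": 1.5, "PC 18:0/20:4": 1.0, "PC 18:0/22:6": 0.7,
    "PC 16:1/22:6": 0.25, "PC 18:1/22:6": 0.3, "PC 16:0/22:5": 0.2,
    "PC 18:0/22:5": 0.15, "PC 18:1/18:2": 0.4,
    "PC 18:2/20:4": 0.13, "PC 18:2/22:6": 0.10,     # double-PUFA
    # PE molecular species
    "PE 18:0/20:4": 1.0, "PE 16:0/22:6": 0.7, "PE 18:0/22:6": 0.6,
    "PE 16:0/18:2": 0.35, "PE 18:1/18:2": 0.25,
    "PE 20:4/22:6": 0.09,                            # double-PUFA
    # ether phospholipids (first chain alkyl)
    "PE-O 16:0/20:4": 0.3, "PE-O 18:0/22:6": 0.2,
    "PC-O 16:0/18:1": 0.2, "PC-O 16:0/18:2": 0.1,
    # PS
    "PS 18:0/18:1": 0.18, "PS 18:0/22:6": 0.15,
    # TAG sum species (the nine most diet-responsive)
    "TAG 50:1": 0.7, "TAG 50:2": 0.8, "TAG 50:3": 0.6,
    "TAG 52:2": 1.2, "TAG 52:3": 1.3, "TAG 52:4": 0.9,
    "TAG 54:3": 0.9, "TAG 54:4": 0.8, "TAG 54:5": 0.6,
    # DAG sum species
    "DAG 34:1": 0.25, "DAG 34:2": 0.3, "DAG 36:2": 0.3, "DAG 36:3": 0.25,
    "DAG 36:4": 0.3, "DAG 38:4": 0.15,
    # ceramides (d18:1 backbone, N-acyl named; 18:0 dominates in muscle)
    "CER 18:0": 0.045, "CER 16:0": 0.008, "CER 18:1": 0.002,
    "CER 20:0": 0.003, "CER 22:0": 0.004, "CER 24:0": 0.004,
    "CER 24:1": 0.003, "CER 14:0": 0.0005, "CER 26:0": 0.0005,
    # sphingomyelins
    "SM 18:0": 0.12, "SM 16:0": 0.07, "SM 24:1": 0.05, "SM 18:1": 0.02,
    "SM 20:0": 0.01, "SM 22:0": 0.01, "SM 24:0": 0.02,
    # cholesterol esters
    "CE 18:1": 0.02, "CE 18:2": 0.025, "CE 20:4": 0.015,
}

#: mild between-strain baseline scaling
DEFAULT_STRAIN_FACTORS: dict[str, float] = {
    "C57BL/6": 1.0, "129X1": 0.95, "BALB/c": 1.05, "DBA/2": 1.10,
    "FVB/N": 0.90,
}

#: class-specific internal standards: non-endogenous species, one physical
#: standard per acquisition channel (the ether classes are referenced to
#: their diacyl class standard, as is standard practice).
DEFAULT_INTERNAL_STANDARDS: dict[str, tuple[str, float]] = {
    "PC": ("PC 14:0/14:0", 0.5),
    "PC-O": ("PC 14:0/14:0", 0.5),
    "PE": ("PE 14:0/14:0", 0.5),
    "PE-O": ("PE 14:0/14:0", 0.5),
    "PS": ("PS 14:0/14:0", 0.5),
    "TAG": ("TAG 42:0", 0.5),
    "DAG": ("DAG 28:0", 0.5),
    "CE": ("CE 14:0", 0.5),
    "CER": ("CER 12:0", 0.5),
    "SM": ("SM 12:0", 0.5),
}


class ConfigError(ValueError):
    """Invalid cohort or noise configuration."""


@dataclass(frozen=True)
class EffectModel:
    """Maps (species, strain, diet) to a mean concentration in nmol/mg."""

    base_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_MEANS))
    strain_factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRAIN_FACTORS))
    tag_hfd_factor: float = 2.0
    double_pufa_hfd_factor: float = 0.6
    n6_hfd_factor: float = 1.3
    n3_hfd_factor: float = 0.8
    protected_strain: str = "BALB/c"

    def _hfd_factor(self, species: LipidSpecies, strain: str) -> float:
        cls = species.lipid_class.name
        if cls == "TAG":
            return self.tag_hfd_factor
        if cls in ("DAG", "CER", "SM", "CE"):
            return 1.0
        if species.level != "molecular":
            return 1.0
        if count_pufa_chains(species) == 2:
            return (1.0 if strain == self.protected_strain
                    else self.double_pufa_hfd_factor)
        families = {classify_acyl(c, DEFAULT_OMEGA_TABLE).omega_family
                    for c in species.chains}
        if "n-3" in families:
            return self.n3_hfd_factor
        if "n-6" in families:
            return self.n6_hfd_factor
        return 1.0

    def mean(self, species: LipidSpecies, strain: str, diet: str) -> float:
        base = self.base_means[species.name]
        if base <= 0:
            raise ConfigError(f"non-positive mean for {species.name}")
        out = base * self.strain_factors.get(strain, 1.0)
        if diet == "HFD":
            out *= self._hfd_factor(species, strain)
        return out


@dataclass(frozen=True)
class CohortConfig:
    """Study design and replicate-noise parameters.

    ``cv`` is the lognormal coefficient of variation of biological
    replicates around their group mean (0.2 by default, comparable to the
    SEM/mean ratios of published muscle class totals at n = 4).
    """

    strains: tuple[str, ...] = DEFAULT_STRAINS
    diets: tuple[str, ...] = DIETS
    replicates_per_group: int = 4
    seed: int = 0
    cv: float = 0.2
    tissue_mass_mg: float = 25.0
    effect_model: EffectModel = field(default_factory=EffectModel)
    internal_standards: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTERNAL_STANDARDS))

    def __post_init__(self) -> None:
        if self.replicates_per_group < 2:
            raise ConfigError("statistics need >= 2 replicates per group")
        if self.cv < 0:
            raise ConfigError("cv must be >= 0")


@dataclass(frozen=True)
class SpectrumNoiseModel:
    """Instrument response and additive-noise parameters.

    ``response`` converts nmol in the infused sample to counts; the ether-PE
    suppression models the inefficient 141 neutral loss of PE-O species
    (peaks emitted at 1/3.45 of the diacyl response).
    """

    response: float = 1.0e5         # counts per nmol
    baseline: float = 30.0          # baseline level, counts
    noise_sd: float = 30.0          # additive noise sd, counts
    envelope: bool = True
    envelope_model: str = "binomial"
    p13: float = 0.0107
    ether_pe_suppression: float = 3.45
    baseline_step: float = 1.0      # Th between baseline points

    def __post_init__(self) -> None:
        if self.response <= 0:
            raise ConfigError("response factor must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise sd must be >= 0")


ZERO_NOISE = SpectrumNoiseModel(baseline=0.0, noise_sd=0.0, envelope=False)


@dataclass
class GroundTruth:
    """Per-sample true concentrations plus the spiked standards."""

    samples: pd.DataFrame         # sample_id, strain, diet, replicate, tissue_mass_mg
    concentrations: pd.DataFrame  # sample_id, species, class, level, true_nmol_per_mg
    internal_standards: dict[str, tuple[str, float]]

    def truth_matrix(self) -> pd.DataFrame:
        """species x sample matrix of true concentrations."""
        return self.concentrations.pivot(index="species", columns="sample_id",
                                         values="true_nmol_per_mg")


def generate_cohort_truth(config: CohortConfig | None = None) -> GroundTruth:
    """Draw per-sample true concentrations under the effect model.

    Replicates are mean-preserving lognormal draws:
    ``x = m * exp(sigma*z - sigma^2/2)`` with ``sigma^2 = ln(1 + cv^2)``, so
    ``cv = 0`` reproduces the group mean exactly and E[x] = m for every cv.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    model = config.effect_model
    species = [parse_shorthand(name) for name in model.base_means]

    sigma = float(np.sqrt(np.log1p(config.cv ** 2)))
    sample_rows, conc_rows = [], []
    for strain in config.strains:
        for diet in config.diets:
            for rep in range(1, config.replicates_per_group + 1):
                sid = f"{strain.replace('/', '')}_{diet}_{rep}"
                sample_rows.append({
                    "sample_id": sid, "strain": strain, "diet": diet,
                    "replicate": rep,
                    "tissue_mass_mg": config.tissue_mass_mg,
                })
                for sp in species:
                    m = model.mean(sp, strain, diet)
                    if sigma > 0:
                        z = rng.standard_normal()
                        value = m * float(np.exp(sigma * z - sigma ** 2 / 2))
                    else:
                        value = m
                    conc_rows.append({
                        "sample_id": sid, "species": sp.name,
                        "class": sp.lipid_class.name, "level": sp.level,
                        "true_nmol_per_mg": value,
                    })
    return GroundTruth(pd.DataFrame(sample_rows), pd.DataFrame(conc_rows),
                       dict(config.internal_standards))


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------

def _merge_peaks(mz: np.ndarray, intensity: np.ndarray,
                 resolution: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Merge peaks closer than the instrument can separate.

    Intensities sum; m/z becomes the intensity-weighted mean, mirroring how
    a unit-resolution analyzer reports coincident isotopologues of
    neighbouring species as one peak.
    """
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    out_mz, out_int = [], []
    for m, i in zip(mz, intensity):
        if out_mz and m - out_mz[-1] <= resolution:
            tot = out_int[-1] + i
            if tot > 0:
                out_mz[-1] = (out_mz[-1] * out_int[-1] + m * i) / tot
            out_int[-1] = tot
        else:
            out_mz.append(m)
            out_int.append(i)
    return np.array(out_mz), np.array(out_int)


def synthesize_sample_spectra(sample_conc: pd.DataFrame, tissue_mass_mg: float,
                              internal_standards: dict[str, tuple[str, float]],
                              db: SpeciesDatabase,
                              noise: SpectrumNoiseModel,
                              rng: np.random.Generator,
                              ) -> dict[str, ScanSpectrum]:
    """Emit one :class:`ScanSpectrum` per channel for a single sample.

    Quant channels carry each sum species (endogenous amounts pooled over
    isobaric molecular species, plus the class standard) at
    ``response * nmol`` with the isotope envelope distributed over M0..M+4.
    Fatty-acyl channels carry one peak per molecular species per acyl chain
    at the parent sum species' [M-H]- m/z, envelope off: isobaric partners
    share an elemental composition, so envelopes cancel in the fractional
    split these channels exist to provide.
    """
    # nmol per species name in the infused sample
    amounts: dict[str, float] = {}
    classes_present: set[str] = set()
    for species_name, cls, nmol_per_mg in zip(
            sample_conc["species"], sample_conc["class"],
            sample_conc["true_nmol_per_mg"]):
        amounts[species_name] = amounts.get(species_name, 0.0) + \
            nmol_per_mg * tissue_mass_mg
        classes_present.add(cls)
    is_amounts: dict[str, float] = {}
    for cls, (is_name, nmol) in internal_standards.items():
        if cls in classes_present:
            is_amounts[is_name] = nmol

    # --- positive quant channels: pool by (channel, sum species) ----------
    by_channel: dict[ScanChannel, dict[str, float]] = {}
    def _add(channel: ScanChannel, sum_name: str, counts: float) -> None:
        by_channel.setdefault(channel, {}).setdefault(sum_name, 0.0)
        by_channel[channel][sum_name] += counts

    for name, nmol in amounts.items():
        if name not in db:
            sp = parse_shorthand(name)
            if sp.sum_name not in db:
                raise ConfigError(f"species {name} missing from database")
        sp = parse_shorthand(name)
        lc = sp.lipid_class
        counts = noise.response * nmol
        if lc.name == "PE-O":
            counts /= noise.ether_pe_suppression
        _add(lc.quant_channel, sp.sum_name, counts)
    for is_name, nmol in is_amounts.items():
        sp = parse_shorthand(is_name)
        lc = sp.lipid_class
        counts = noise.response * nmol
        if lc.name == "PE-O":
            counts /= noise.ether_pe_suppression
        _add(lc.quant_channel, sp.sum_name, counts)

    spectra: dict[str, ScanSpectrum] = {}
    for channel in sorted(by_channel, key=lambda c: c.id):
        mzs, ints = [], []
        for sum_name, counts in sorted(by_channel[channel].items()):
            sp = db.get(sum_name)
            center = sp.mz()
            if noise.envelope:
                frac = envelope_for(sp.composition, noise.envelope_model,
                                    p13=noise.p13)
                for k, f in enumerate(frac):
                    mzs.append(center + k * NEUTRON_SPACING)
                    ints.append(counts * f)
            else:
                mzs.append(center)
                ints.append(counts)
        spectra[channel.id] = _finish_spectrum(
            channel, np.array(mzs), np.array(ints), noise, rng)

    # --- negative fatty-acyl channels --------------------------------------
    fa_peaks: dict[ScanChannel, dict[float, float]] = {}
    for name, nmol in amounts.items():
        sp = parse_shorthand(name)
        if sp.level != "molecular" or not sp.lipid_class.is_phospholipid:
            continue
        precursor = db.get(sp.sum_name).negative_mz
        for chain in sp.chains:
            if chain.ether:
                continue  # alkyl chains yield no carboxylate
            ch = fa_channel(chain.carbons, chain.double_bonds)
            fa_peaks.setdefault(ch, {}).setdefault(precursor, 0.0)
            fa_peaks[ch][precursor] += noise.response * nmol
    for channel in sorted(fa_peaks, key=lambda c: c.id):
        items = sorted(fa_peaks[channel].items())
        mzs = np.array([m for m, _ in items])
        ints = np.array([i for _, i in items])
        spectra[channel.id] = _finish_spectrum(channel, mzs, ints, noise, rng)

    return spectra


def _finish_spectrum(channel: ScanChannel, mz: np.ndarray,
                     intensity: np.ndarray, noise: SpectrumNoiseModel,
                     rng: np.random.Generator) -> ScanSpectrum:
    if mz.size:
        mz, intensity = _merge_peaks(mz, intensity)
    if noise.noise_sd > 0:
        intensity = np.clip(
            intensity + rng.normal(0.0, noise.noise_sd, intensity.size), 0, None)
    if noise.noise_sd > 0 or noise.baseline > 0:
        lo = (mz.min() if mz.size else 600.0) - 5.0
        hi = (mz.max() if mz.size else 900.0) + 5.0
        grid = np.arange(lo, hi, noise.baseline_step) + 0.37
        base = np.abs(rng.normal(noise.baseline, max(noise.noise_sd, 1e-12),
                                 grid.size))
        mz = np.concatenate([mz, grid])
        intensity = np.concatenate([intensity, base])
        order = np.argsort(mz)
        mz, intensity = mz[order], intensity[order]
    # the simulator knows its own noise floor, so it reports true s/n the
    # way an instrument does; the baseline estimate in spectral processing
    # is the fallback for peak lists that lack the column
    if noise.noise_sd > 0:
        snr = intensity / noise.noise_sd
    else:
        snr = np.full(intensity.size, np.inf)
    return ScanSpectrum(polarity=channel.polarity, scan_type=channel.scan_type,
                        extract=channel.extract, mz=mz, intensity=intensity,
                        snr=snr)


def synthesize_spectra(truth: GroundTruth, db: SpeciesDatabase,
                       noise: SpectrumNoiseModel | None = None,
                       seed: int = 0,
                       ) -> dict[str, dict[str, ScanSpectrum]]:
    """Spectra for every sample in the cohort: sample_id -> channel id -> spectrum."""
    noise = noise or SpectrumNoiseModel()
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, ScanSpectrum]] = {}
    for row in truth.samples.itertuples():
        sample_conc = truth.concentrations[
            truth.concentrations["sample_id"] == row.sample_id]
        out[row.sample_id] = synthesize_sample_spectra(
            sample_conc, row.tissue_mass_mg, truth.internal_standards, db,
            noise, rng)
    return out


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------

def write_cohort(outdir: str | Path, truth: GroundTruth,
                 spectra: dict[str, dict[str, ScanSpectrum]]) -> Path:
    """Write peak lists (TSV), manifest, truth sidecar and IS table."""
    outdir = Path(outdir)
    peakdir = outdir / "peaklists"
    peakdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    sample_meta = truth.samples.set_index("sample_id")
    for sample_id in sorted(spectra):
        meta = sample_meta.loc[sample_id]
        for channel_id in sorted(spectra[sample_id]):
            spec = spectra[sample_id][channel_id]
            fname = f"{sample_id}__{channel_id.replace(':', '_')}.tsv"
            path = peakdir / fname
            snr = spec.snr if spec.snr is not None else \
                np.full(len(spec), np.inf)
            with open(path, "w") as fh:
                fh.write("mz\tintensity\tsnr\n")
                for m, i, s in zip(spec.mz, spec.intensity, snr):
                    fh.write(f"{m:.6f}\t{i:.4f}\t{s:.4f}\n")
            manifest_rows.append({
                "sample_id": sample_id, "strain": meta["strain"],
                "diet": meta["diet"],
                "tissue_mass_mg": meta["tissue_mass_mg"],
                "channel_id": channel_id, "extract": spec.extract,
                "path": str(path.relative_to(outdir)),
            })
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    truth.concentrations.to_csv(outdir / "truth.csv", index=False)
    is_rows = [{"class": cls, "species": name, "amount_nmol": nmol}
               for cls, (name, nmol) in sorted(truth.internal_standards.items())]
    pd.DataFrame(is_rows).to_csv(outdir / "internal_standards.csv", index=False)
    return outdir


def read_peaklist(path: str | Path, channel_id: str, extract: str
                  ) -> ScanSpectrum:
    """Read one tab-delimited peak list back into a :class:`ScanSpectrum`."""
    mzs, ints, snrs = [], [], []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        has_snr = len(header) > 2
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            try:
                mzs.append(float(parts[0]))
                ints.append(float(parts[1]))
                if has_snr:
                    snrs.append(float(parts[2]))
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: corrupt peak-list line {line!r}"
                ) from exc
    pol = "-" if channel_id.startswith("neg") else "+"
    scan_type = channel_id.split("_", 1)[1].rsplit(".", 1)[0]
    return ScanSpectrum(polarity=pol, scan_type=scan_type, extract=extract,
                        mz=np.array(mzs), intensity=np.array(ints),
                        snr=np.array(snrs) if has_snr else None)


def read_cohort(outdir: str | Path
                ) -> tuple[pd.DataFrame, dict[str, tuple[str, float]],
                           dict[str, dict[str, ScanSpectrum]]]:
    """Load manifest, IS table and all peak lists from a cohort directory."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    is_frame = pd.read_csv(outdir / "internal_standards.csv")
    standards = {row["class"]: (row["species"], float(row["amount_nmol"]))
                 for _, row in is_frame.iterrows()}
    spectra: dict[str, dict[str, ScanSpectrum]] = {}
    for row in manifest.itertuples():
        spec = read_peaklist(outdir / row.path, row.channel_id, row.extract)
        spectra.setdefault(row.sample_id, {})[row.channel_id] = spec
    return manifest, standards, spectra


def generate_null_matrix(n_species: int, design: pd.DataFrame, cv: float,
                         seed: int, mean: float = 1.0) -> pd.DataFrame:
    """Complete-null concentration matrix: every cell shares one mean.

    Used for type-I-error calibration of the significance pipeline; returns
    a species x sample DataFrame of lognormal draws with the given CV.
    """
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    z = rng.standard_normal((n_species, len(design)))
    values = mean * np.exp(sigma * z - sigma ** 2 / 2)
    return pd.DataFrame(values,
                        index=[f"species_{i:04d}" for i in range(n_species)],
                        columns=design["sample_id"].tolist())
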
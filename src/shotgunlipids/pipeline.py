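"""End-to-end orchestration: simulate -> quantify -> analyze.

These functions are the programmatic API behind the command-line interface;
each stage consumes and produces the package's canonical tables (the long
concentration table, the per-species statistics, the class x strain
significance grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import profiles as prof
from . import stats as st
from .nomenclature import SpeciesDatabase, build_species_database
from .quant import (
    InternalStandard,
    QuantifiedSpecies,
    quantify_class,
    resolve_molecular_species,
)
from .spectra import (
    ScanSpectrum,
    detect_and_filter,
    isotope_correct,
    match_to_database,
    smooth,
)
from .synthetic import (
    CohortConfig,
    SpectrumNoiseModel,
    generate_cohort_truth,
    read_cohort,
    synthesize_spectra,
    write_cohort,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProcessingParams:
    """Spectral-processing and statistics thresholds for one run."""

    snr_threshold: float = 10.0
    smooth_window: int = 1
    mz_tolerance: float = 0.3
    isotope_correction: bool = True
    envelope_model: str = "binomial"
    ether_pe_factor: float = 3.45
    pair_evidence: str = "sum"
    screen_alpha: float = 0.05
    lsd_alpha: float = 0.01
    anova_mode: str = "cells"


def simulate(config: CohortConfig | None = None,
             noise: SpectrumNoiseModel | None = None,
             db: SpeciesDatabase | None = None,
             outdir: str | Path | None = None,
             ):
    """Generate a cohort (truth + spectra), optionally writing it to disk."""
    config = config or CohortConfig()
    db = db or build_species_database()
    truth = generate_cohort_truth(config)
    spectra = synthesize_spectra(truth, db, noise=noise, seed=config.seed)
    if outdir is not None:
        write_cohort(outdir, truth, spectra)
    return truth, spectra, db


def quantify_sample(sample_id: str,
                    channels: dict[str, ScanSpectrum],
                    standards: dict[str, tuple[str, float]],
                    tissue_mass_mg: float,
                    db: SpeciesDatabase,
                    params: ProcessingParams,
                    ) -> list[QuantifiedSpecies]:
    """Peak lists of one sample -> quantified (and resolved) species."""
    identified_by_class: dict[str, list] = {}
    fa_identified: dict[str, dict[str, float]] = {}
    qc = {"peaks_in": 0, "peaks_kept": 0, "peaks_matched": 0}

    for channel_id in sorted(channels):
        spectrum = channels[channel_id]
        spectrum = smooth(spectrum, params.smooth_window)
        peaks = detect_and_filter(spectrum, params.snr_threshold)
        qc["peaks_in"] += len(spectrum)
        qc["peaks_kept"] += len(peaks)
        identified = match_to_database(peaks, db, spectrum.channel,
                                       tol=params.mz_tolerance)
        qc["peaks_matched"] += len(identified)
        if spectrum.scan_type.startswith("fa-"):
            fa_identified[channel_id] = {
                rec.species.name: rec.raw_intensity for rec in identified}
            continue
        identified = isotope_correct(identified,
                                     enabled=params.isotope_correction,
                                     envelope_model=params.envelope_model,
                                     post_snr_threshold=params.snr_threshold)
        for rec in identified:
            identified_by_class.setdefault(
                rec.species.lipid_class.name, []).append(rec)

    log.info("sample %s QC: %s", sample_id, qc)
    quantified: list[QuantifiedSpecies] = []
    for cls, (is_name, amount) in sorted(standards.items()):
        records = identified_by_class.get(cls)
        if not records:
            continue
        is_record = InternalStandard(cls, is_name, amount)
        # standards are shared across channel classes; pass everything the
        # channel saw so the IS is found even when it sits in another class
        channel_id = records[0].channel_id
        channel_records = [r for recs in identified_by_class.values()
                           for r in recs if r.channel_id == channel_id]
        quantified.extend(quantify_class(
            channel_records, is_record, tissue_mass_mg, sample_id=sample_id,
            ether_pe_factor=params.ether_pe_factor))

    return resolve_molecular_species(quantified, fa_identified, db,
                                     combiner=params.pair_evidence)


def quantify_cohort(manifest: pd.DataFrame,
                    standards: dict[str, tuple[str, float]],
                    spectra: dict[str, dict[str, ScanSpectrum]],
                    db: SpeciesDatabase | None = None,
                    params: ProcessingParams | None = None,
                    ) -> pd.DataFrame:
    """All samples -> the canonical long concentration table."""
    db = db or build_species_database()
    params = params or ProcessingParams()
    meta = manifest[["sample_id", "strain", "diet", "tissue_mass_mg"]] \
        .drop_duplicates().set_index("sample_id")
    rows = []
    for sample_id in sorted(spectra):
        quantified = quantify_sample(
            sample_id, spectra[sample_id], standards,
            float(meta.loc[sample_id, "tissue_mass_mg"]), db, params)
        for q in quantified:
            if q.concentration <= 0:
                continue  # not detected; absent from the table
            rows.append({
                "sample_id": sample_id,
                "strain": meta.loc[sample_id, "strain"],
                "diet": meta.loc[sample_id, "diet"],
                "species": q.name,
                "class": q.species.lipid_class.name,
                "level": q.species.level,
                "concentration": q.concentration,
                "resolved": q.resolved,
                "source": q.source,
            })
    if not rows:
        log.warning("no species quantified; empty concentration table")
        return pd.DataFrame(columns=[
            "sample_id", "strain", "diet", "species", "class", "level",
            "concentration", "resolved", "source"])
    return pd.DataFrame(rows)


@dataclass
class AnalysisResult:
    profiles: pd.DataFrame            # per-sample metrics
    group_summary: pd.DataFrame       # class x strain x diet mean/SEM grid
    anova: pd.DataFrame               # per-species omnibus results
    posthoc: pd.DataFrame             # protected LSD records
    significance_counts: pd.DataFrame  # class x strain up/down counts
    class_total_posthoc: pd.DataFrame  # protected LSD on class totals
    summary_table: pd.DataFrame       # class x strain mean/SEM/count grid
    rank_diagnostic: pd.DataFrame     # ranked p values vs uniform quantiles
    deltas: pd.DataFrame              # per-strain HFD - CHOW for key metrics

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(outdir / "sample_profiles.csv", index=False)
        self.group_summary.to_csv(outdir / "class_totals_summary.csv",
                                  index=False)
        self.anova.to_csv(outdir / "anova.csv", index=False)
        self.posthoc.to_csv(outdir / "posthoc_lsd.csv", index=False)
        self.significance_counts.to_csv(
            outdir / "significance_counts.csv", index=False)
        self.class_total_posthoc.to_csv(
            outdir / "class_total_significance.csv", index=False)
        self.summary_table.to_csv(outdir / "class_summary_table.csv",
                                  index=False)
        self.rank_diagnostic.to_csv(outdir / "pvalue_ranks.csv", index=False)
        self.deltas.to_csv(outdir / "diet_deltas.csv", index=False)


def analyze(conc: pd.DataFrame, params: ProcessingParams | None = None
            ) -> AnalysisResult:
    """Concentration table -> profile metrics + significance tables."""
    params = params or ProcessingParams()
    profile = prof.sample_profiles(conc)
    summary = prof.group_summary(conc)

    values = conc.pivot_table(index="species", columns="sample_id",
                              values="concentration", aggfunc="sum")
    design = st.GroupDesign(conc[["sample_id", "strain", "diet"]]
                            .drop_duplicates())
    transformed = st.log_transform(values)
    raw = values.loc[transformed.index]
    anovas, posthocs = st.run_significance(
        transformed, design, raw_values=raw,
        screen_alpha=params.screen_alpha, lsd_alpha=params.lsd_alpha,
        mode=params.anova_mode)
    species_class = dict(conc[["species", "class"]]
                         .drop_duplicates().itertuples(index=False))
    counts = st.count_directional_changes(posthocs, species_class)
    ranks = (st.rank_pvalue_diagnostic(anovas) if len(anovas) >= 2
             else pd.DataFrame())

    # the same screened-LSD procedure on per-sample class totals — the
    # machine form of a class-total table's significance highlighting
    totals = prof.class_totals(conc)
    totals_matrix = totals.T  # class x sample
    _, total_posthocs = st.run_significance(
        st.log_transform(totals_matrix), design, raw_values=totals_matrix,
        screen_alpha=params.screen_alpha, lsd_alpha=params.lsd_alpha,
        mode=params.anova_mode)
    total_posthoc_frame = st.posthoc_frame(total_posthocs)
    if not total_posthoc_frame.empty:
        total_posthoc_frame = total_posthoc_frame.rename(
            columns={"species": "class"})

    delta_rows = []
    metric_cols = ["pc_pe_ratio", "n6_pl", "n3_pl", "ge1_pufa_pl",
                   "double_pufa_pl", "PL_total"]
    for metric in metric_cols + [c for c in profile.columns
                                 if c in ("TAG", "DAG", "CER", "SM")]:
        if metric not in profile.columns:
            continue
        d = prof.diet_delta(
            profile.rename(columns={metric: "value"}), "value")
        d.insert(0, "metric", metric)
        delta_rows.append(d)
    deltas = pd.concat(delta_rows, ignore_index=True) if delta_rows \
        else pd.DataFrame(columns=["metric", "strain", "delta"])

    return AnalysisResult(
        profiles=profile, group_summary=summary,
        anova=st.anova_frame(anovas), posthoc=st.posthoc_frame(posthocs),
        significance_counts=counts, class_total_posthoc=total_posthoc_frame,
        summary_table=prof.summary_table(conc, counts),
        rank_diagnostic=ranks, deltas=deltas)


def run_from_directory(cohort_dir: str | Path,
                       db: SpeciesDatabase | None = None,
                       params: ProcessingParams | None = None,
                       ) -> tuple[pd.DataFrame, AnalysisResult]:
    """Load a written cohort, quantify and analyze it."""
    manifest, standards, spectra = read_cohort(cohort_dir)
    conc = quantify_cohort(manifest, standards, spectra, db=db, params=params)
    return conc, analyze(conc, params=params)
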
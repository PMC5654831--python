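"""Absolute quantification against class internal standards and resolution
of isobaric phospholipid molecular species.

Concentrations come from the ratio of a species' isotope-corrected
intensity to its class standard, scaled by the spiked amount and tissue
mass.  Ether-PE species lose the 141 head-group fragment ~3.45x less
efficiently than diacyl PE, so their head-group-scan intensities are
multiplied by that factor.  Molecular species of PC/PE/PS (and the ether
classes) are resolved by distributing each sum species' concentration over
candidate chain pairs in proportion to the fatty-acyl fragment evidence
observed at the sum species' negative-mode precursor m/z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .spectra import IdentifiedIntensity
from .nomenclature import (
    FattyAcyl,
    LipidSpecies,
    SpeciesDatabase,
    fa_channel,
    parse_shorthand,
)


log = logging.getLogger(__name__)

ETHER_PE_FACTOR = 3.45


class QuantificationError(RuntimeError):
    """Internal standard missing or unusable for a class/sample."""


@dataclass(frozen=True)
class InternalStandard:
    lipid_class: str
    species: str
    amount_nmol: float

    def __post_init__(self) -> None:
        if self.amount_nmol <= 0:
            raise ValueError("IS amount must be > 0")


@dataclass
class QuantifiedSpecies:
    """Species amount in nmol/mg tissue for one sample, with provenance."""

    sample_id: str
    species: LipidSpecies
    concentration: float          # nmol per mg tissue
    isotope_corrected: bool = True
    ether_pe_factor_applied: bool = False
    source: str = "headgroup"     # "headgroup" | "fractional"
    resolved: bool = True         # False: sum species kept unresolved

    @property
    def name(self) -> str:
        return self.species.name


def quantify_class(identified: list[IdentifiedIntensity],
                   is_record: InternalStandard,
                   tissue_mass_mg: float,
                   sample_id: str = "",
                   ether_pe_factor: float = ETHER_PE_FACTOR,
                   ) -> list[QuantifiedSpecies]:
    """Concentrations for one class in one sample.

    ``conc(i) = intensity(i) / intensity(IS) * amount(IS) / tissue_mass``,
    with the ether-PE factor applied multiplicatively for class PE-O.  The
    IS itself is not reported.  A missing or zero-intensity standard raises
    :class:`QuantificationError` so the sample is flagged rather than
    silently dropped.
    """
    if tissue_mass_mg <= 0:
        raise ValueError("tissue mass must be > 0")
    class_records = [r for r in identified
                     if r.species.lipid_class.name == is_record.lipid_class]
    # the standard is detected as its sum composition in the head-group scan
    is_names = {is_record.species, parse_shorthand(is_record.species).sum_name}
    is_intensity = None
    for rec in identified:
        if rec.species.name in is_names:
            is_intensity = rec.intensity
            break
    if is_intensity is None or is_intensity <= 0:
        raise QuantificationError(
            f"internal standard {is_record.species} absent or zero in "
            f"class {is_record.lipid_class}, sample {sample_id!r}")

    out = []
    apply_factor = is_record.lipid_class == "PE-O"
    floor = 1e-6 * is_record.amount_nmol / tissue_mass_mg
    for rec in class_records:
        if rec.species.name in is_names:
            continue
        conc = (rec.intensity / is_intensity) * is_record.amount_nmol \
            / tissue_mass_mg
        if apply_factor:
            conc *= ether_pe_factor
        if conc < floor:
            # numerical dust left by the clamped isotope subtraction of a
            # peak that was pure contamination
            conc = 0.0
        out.append(QuantifiedSpecies(
            sample_id=sample_id, species=rec.species, concentration=conc,
            isotope_corrected=rec.corrected_intensity is not None,
            ether_pe_factor_applied=apply_factor, source="headgroup",
            resolved=rec.species.level == "molecular"))
    return out


def _fragment_intensity(fa_identified: dict[str, dict[str, float]],
                        chain: FattyAcyl, sum_name: str) -> float:
    channel_id = fa_channel(chain.carbons, chain.double_bonds).id
    return fa_identified.get(channel_id, {}).get(sum_name, 0.0)


def resolve_molecular_species(sum_quants: list[QuantifiedSpecies],
                              fa_identified: dict[str, dict[str, float]],
                              db: SpeciesDatabase,
                              combiner: str = "sum",
                              ) -> list[QuantifiedSpecies]:
    """Split sum-species concentrations over detected chain pairs.

    ``fa_identified`` maps fatty-acyl channel id -> {sum species name ->
    fragment intensity at that sum species' precursor m/z}.  Evidence for a
    candidate pair is the combined intensity of its distinct acyl chains
    (``sum`` by default, ``min`` as a conservative alternative); fractions
    are evidence over total evidence, so molecular concentrations conserve
    the sum-species total exactly.  Sum species without any fragment
    evidence pass through unresolved and flagged.
    """
    if combiner not in ("sum", "min"):
        raise ValueError("combiner must be 'sum' or 'min'")
    out: list[QuantifiedSpecies] = []
    for q in sum_quants:
        if (q.species.level == "molecular"
                or not q.species.lipid_class.is_phospholipid):
            out.append(q)
            continue
        candidates = db.molecular_candidates.get(q.species.name, [])
        evidence: list[tuple[LipidSpecies, float]] = []
        for mol in candidates:
            acyl_chains = {FattyAcyl(c.carbons, c.double_bonds)
                           for c in mol.chains if not c.ether}
            values = [_fragment_intensity(fa_identified, ch, q.species.name)
                      for ch in acyl_chains]
            if not values:
                continue
            ev = sum(values) if combiner == "sum" else min(values)
            if ev > 0:
                evidence.append((mol, ev))
        if not evidence:
            log.info("no fatty-acyl evidence for %s; kept unresolved",
                     q.species.name)
            out.append(QuantifiedSpecies(
                sample_id=q.sample_id, species=q.species,
                concentration=q.concentration,
                isotope_corrected=q.isotope_corrected,
                ether_pe_factor_applied=q.ether_pe_factor_applied,
                source="headgroup", resolved=False))
            continue
        total = sum(ev for _, ev in evidence)
        for mol, ev in evidence:
            out.append(QuantifiedSpecies(
                sample_id=q.sample_id, species=mol,
                concentration=q.concentration * ev / total,
                isotope_corrected=q.isotope_corrected,
                ether_pe_factor_applied=q.ether_pe_factor_applied,
                source="fractional", resolved=True))
    return out


def assign_ether_or_odd(candidate_mz: float, db: SpeciesDatabase,
                        tol: float = 0.3,
                        head_group: str | None = None,
                        ) -> LipidSpecies | None:
    """Resolve the ether vs odd-chain mass ambiguity.

    At unit resolution an ether species and the odd-chain diacyl species
    one CH2 short are isobaric; masses matching both readings are assigned
    to the ether-linked species (the rule used for these spectra), and the
    decision is logged.  A mass matching only one reading gets that
    reading; a mass matching neither returns ``None``.  ``head_group``
    ("PC", "PE", ...) restricts the search to one head-group scan's
    classes, since a bare mass is also ambiguous across scan channels.
    """
    def in_scope(species: LipidSpecies) -> bool:
        if head_group is None:
            return True
        return species.lipid_class.name.split("-")[0] == head_group

    ether_hit = odd_hit = None
    for name, odd_species in db.odd_chain_interpretations.items():
        ether_species = db.get(name)
        if not in_scope(ether_species):
            continue
        if (ether_hit is None
                and abs(ether_species.mz() - candidate_mz) <= tol):
            ether_hit = ether_species
        if odd_hit is None and abs(odd_species.mz() - candidate_mz) <= tol:
            odd_hit = odd_species
    if ether_hit is not None:
        if odd_hit is not None:
            log.info("m/z %.4f matches both %s and %s; assigned ether",
                     candidate_mz, ether_hit.name, odd_hit.name)
        return ether_hit
    if odd_hit is not None:
        return odd_hit
    for species in db.species:
        if in_scope(species) and abs(species.mz() - candidate_mz) <= tol:
            return species
    return None


def assign_sm_backbone(n_acyl: FattyAcyl) -> LipidSpecies:
    """Name an SM detection from the 184.1 channel by its N-linked acyl.

    The 184.1 precursor scan cannot distinguish isobaric dihydro-SM from SM;
    detections are assumed to carry the major d18:1 sphingoid backbone and
    are reported as ``SM <C>:<D>`` of the N-acyl.
    """
    return parse_shorthand(f"SM {n_acyl.carbons}:{n_acyl.double_bonds}")
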
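"""Peak-list processing: smoothing, s/n filtering, identification and the
two-stage isotope correction.

The correction mirrors vendor-style processing of unit-resolution shotgun
spectra.  Stage 1 removes the isotope contribution of lower-mass species:
within one class and channel, the M+2 (and M+4) isotopologues of a species
with one (two) more double bond(s) fall on the monoisotopic peak of its
2-Th (4-Th) neighbour and are subtracted recursively in ascending m/z.
Stage 2 corrects for the isotope distribution of the species itself by
dividing by its monoisotopic envelope fraction, so corrected intensities
represent total species abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np


from .chem import envelope_for
from .nomenclature import LipidSpecies, ScanChannel, SpeciesDatabase

log = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


@dataclass
class ScanSpectrum:
    """One acquisition channel's peak list.

    ``mz`` ascending; ``snr`` is optional — when absent it is estimated
    from the non-peak baseline at filtering time.
    """

    polarity: str
    scan_type: str
    extract: str
    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz)
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if self.snr is not None:
                self.snr = np.asarray(self.snr)[order]

    @property
    def channel(self) -> ScanChannel:
        return ScanChannel(self.scan_type, self.extract, self.polarity)

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class IdentifiedIntensity:
    """A database species with its raw and isotope-corrected intensity.

    ``noise_scale`` is the channel's noise level implied by the peak's
    reported s/n, carried so the detection rule can be re-applied after
    isotope correction.
    """

    species: LipidSpecies
    raw_intensity: float
    corrected_intensity: float | None = None
    channel_id: str = ""
    noise_scale: float | None = None

    @property
    def intensity(self) -> float:
        return (self.corrected_intensity if self.corrected_intensity is not None
                else self.raw_intensity)


def smooth(spectrum: ScanSpectrum, window: int) -> ScanSpectrum:
    """Centered moving average over intensity with edge truncation.

    ``window`` must be odd; m/z values are unchanged.  Window 1 is the
    identity (the default for already-centroided peak lists).
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError("smoothing window must be odd and >= 1")
    if window == 1 or len(spectrum) == 0:
        return replace(spectrum, intensity=spectrum.intensity.copy())
    half = window // 2
    n = len(spectrum)
    csum = np.concatenate([[0.0], np.cumsum(spectrum.intensity)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(spectrum, intensity=smoothed)


def estimate_snr(spectrum: ScanSpectrum,
                 isolation: float = 1.5) -> np.ndarray:
    """Estimate per-point s/n from the non-peak baseline.

    Candidate peaks are local maxima, plus isolated points with no
    neighbour within ``isolation`` Th (a sparse centroid list carries no
    baseline around such points).  The noise scale is 1.4826 x the median
    absolute intensity of the remaining non-peak points — the MAD-based
    robust sigma of the baseline.  A spectrum with no baseline points
    (e.g. a noise-free simulation) gets infinite s/n.
    """
    intensity = spectrum.intensity
    mz = spectrum.mz
    n = intensity.size
    if n == 0:
        return np.empty(0)
    is_peak = np.zeros(n, dtype=bool)
    if n == 1:
        is_peak[0] = True
    else:
        gap_left = np.concatenate([[np.inf], np.diff(mz)])
        gap_right = np.concatenate([np.diff(mz), [np.inf]])
        higher_left = np.concatenate([[True], intensity[1:] > intensity[:-1]])
        higher_right = np.concatenate([intensity[:-1] > intensity[1:], [True]])
        local_max = higher_left & higher_right
        isolated = (gap_left > isolation) & (gap_right > isolation)
        is_peak = local_max | isolated
    baseline = intensity[~is_peak]
    if baseline.size == 0:
        return np.full(n, np.inf)
    scale = 1.4826 * float(np.median(np.abs(baseline)))
    if scale <= 0:
        return np.full(n, np.inf)
    return intensity / scale


def detect_and_filter(spectrum: ScanSpectrum,
                      snr_threshold: float = 10.0) -> list[Peak]:
    """Retain peaks with s/n strictly greater than the threshold.

    Uses the spectrum's own s/n values when present, otherwise the baseline
    estimate of :func:`estimate_snr`.  The strict inequality reads the
    stated inclusion rule "s/n over 10" literally; the threshold is
    configurable.
    """
    if snr_threshold <= 0:
        raise ParameterError("s/n threshold must be > 0")
    if len(spectrum) == 0:
        return []
    snr = spectrum.snr if spectrum.snr is not None else estimate_snr(spectrum)
    snr = np.asarray(snr, dtype=float)
    keep = snr > snr_threshold
    return [Peak(float(m), float(i), float(s))
            for m, i, s in zip(spectrum.mz[keep], spectrum.intensity[keep],
                               snr[keep])]


def match_to_database(peaks: list[Peak], db: SpeciesDatabase,
                      channel: ScanChannel, tol: float = 0.3,
                      ) -> list[IdentifiedIntensity]:
    """Assign each peak to the nearest database target within tolerance.

    Unassigned peaks are dropped; a peak maps to at most one species
    (nearest target wins, ties broken toward lower m/z and logged).
    Several peaks assigned to one target — e.g. a monoisotopic peak and the
    coincident M+2 isotopologue of a 2-Th neighbour reported separately —
    sum into one raw intensity.
    """
    if tol <= 0:
        raise ParameterError("matching tolerance must be > 0")
    targets = db.channel_targets(channel)
    if not targets or not peaks:
        return []
    target_mz = np.array([t[0] for t in targets])
    totals: dict[int, float] = {}
    scales: dict[int, float] = {}
    for peak in peaks:
        dist = np.abs(target_mz - peak.mz)
        j = int(np.argmin(dist))
        # np.argmin already prefers the lower index == lower m/z on ties,
        # but make the tie explicit for the log.
        if dist[j] > tol:
            continue
        ties = np.flatnonzero(np.isclose(dist, dist[j]))
        if ties.size > 1:
            log.info("m/z %.4f equidistant from %d targets; keeping %.4f",
                     peak.mz, ties.size, target_mz[ties[0]])
            j = int(ties[0])
        totals[j] = totals.get(j, 0.0) + peak.intensity
        if (peak.snr is not None and np.isfinite(peak.snr)
                and peak.snr > 0):
            scales[j] = peak.intensity / peak.snr
    return [IdentifiedIntensity(species=targets[j][1], raw_intensity=raw,
                                channel_id=channel.id,
                                noise_scale=scales.get(j))
            for j, raw in sorted(totals.items())]


def isotope_correct(identified: list[IdentifiedIntensity],
                    enabled: bool = True,
                    envelope_model: str = "binomial",
                    p13: float = 0.0107,
                    spacing_tol: float = 0.2,
                    post_snr_threshold: float | None = None,
                    ) -> list[IdentifiedIntensity]:
    """Two-stage isotope correction within one acquisition channel.

    Stage 1 (type-II, ascending target m/z): subtract from each species
    the M+k isotopologue contributions (k = 1..4) of already-corrected
    lower-mass species in the same channel whose target m/z sits
    ``k x 1.00336`` (within ``spacing_tol`` Th) below it.  The dominant
    case is the M+2 of the same-class species one double bond up, two Th
    lower; the m/z criterion also catches the unit-resolution collisions
    between ether-class targets and diacyl isotopologues.  Negative
    results clamp to zero with a warning.  Stage 2 (type-I): divide by the
    species' monoisotopic envelope fraction so intensities represent total
    species abundance.  Disabled, the operation is the identity.

    ``post_snr_threshold`` re-applies the detection rule after stage 1: a
    species whose remaining (contamination-free) signal no longer clears
    the s/n threshold is dropped — its peak was an isotopologue of a
    neighbour, not a detection.  Its stage-1 residual still participates
    in the subtraction ladder.
    """
    out = []
    if not enabled:
        for rec in identified:
            out.append(replace(rec, corrected_intensity=rec.raw_intensity))
        return out

    by_channel: dict[str, list[IdentifiedIntensity]] = {}
    for rec in identified:
        by_channel.setdefault(rec.channel_id, []).append(rec)

    from .chem import NEUTRON_SPACING

    for _, group in sorted(by_channel.items()):
        group = sorted(group, key=lambda r: r.species.mz())
        mzs = [r.species.mz() for r in group]
        stage1: list[float] = []
        envs: list[np.ndarray] = []
        for i, rec in enumerate(group):
            sp = rec.species
            envs.append(envelope_for(sp.composition, envelope_model, p13=p13))
            value = rec.raw_intensity
            for j in range(i - 1, -1, -1):
                delta = mzs[i] - mzs[j]
                if delta > 4 * NEUTRON_SPACING + spacing_tol:
                    break
                k = int(round(delta / NEUTRON_SPACING))
                if (1 <= k <= 4
                        and abs(delta - k * NEUTRON_SPACING) <= spacing_tol):
                    e = envs[j]
                    value -= (e[k] / e[0]) * stage1[j]
            if value < 0:
                if value < -1e-6 * max(rec.raw_intensity, 1.0):
                    log.warning("isotope correction drove %s below zero "
                                "(%.3g); clamped", sp.name, value)
                value = 0.0
            stage1.append(value)
            if (post_snr_threshold is not None
                    and rec.noise_scale is not None
                    and value <= post_snr_threshold * rec.noise_scale):
                log.debug("%s below s/n after isotope correction; dropped",
                          sp.name)
                continue
            out.append(replace(rec, corrected_intensity=value / float(envs[i][0])))
    return out
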
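"""Smoothing, s/n filtering, identification and isotope correction."""

import numpy as np
import pytest

from oracles import carbon_binomial_envelope, full_convolution_envelope

from shotgunlipids.nomenclature import CLASSES, parse_shorthand
from shotgunlipids.spectra import (
    IdentifiedIntensity,
    ParameterError,
    Peak,
    ScanSpectrum,
    detect_and_filter,
    isotope_correct,
    match_to_database,
    smooth,
)


def _spectrum(mz, intensity, snr=None, scan_type="hg184", extract="total"):
    return ScanSpectrum(polarity="+", scan_type=scan_type, extract=extract,
                        mz=np.asarray(mz, dtype=float),
                        intensity=np.asarray(intensity, dtype=float),
                        snr=None if snr is None else np.asarray(snr, float))


class TestSmooth:
    def test_window_one_is_identity(self):
        spec = _spectrum([1, 2, 3], [5.0, 7.0, 9.0])
        out = smooth(spec, 1)
        np.testing.assert_array_equal(out.intensity, spec.intensity)

    def test_constant_spectrum_unchanged(self):
        spec = _spectrum(range(10), [4.0] * 10)
        out = smooth(spec, 5)
        np.testing.assert_allclose(out.intensity, 4.0)

    def test_impulse_hand_computed(self):
        spec = _spectrum(range(5), [0, 0, 3, 0, 0])
        out = smooth(spec, 3)
        np.testing.assert_allclose(out.intensity, [0, 1, 1, 1, 0])

    def test_mz_unchanged(self):
        spec = _spectrum([1.5, 2.5, 3.5], [1, 2, 3])
        np.testing.assert_array_equal(smooth(spec, 3).mz, spec.mz)

    @pytest.mark.parametrize("window", [0, 2, 4, -1])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ParameterError):
            smooth(_spectrum([1], [1]), window)


class TestDetectAndFilter:
    def test_boundary_is_strict(self):
        spec = _spectrum([100, 200, 300], [1, 1, 1], snr=[5, 10, 10.01])
        kept = detect_and_filter(spec, 10)
        assert [p.snr for p in kept] == [10.01]

    def test_snr_one_to_hundred_retains_strictly_over_ten(self):
        snrs = list(range(1, 101))
        spec = _spectrum([100 + i for i in snrs], [1] * 100, snr=snrs)
        kept = sorted(p.snr for p in detect_and_filter(spec, 10))
        assert kept == [s for s in snrs if s > 10]
        assert min(kept) == 11

    def test_permissive_threshold_keeps_everything(self):
        spec = _spectrum([1, 2, 3], [1, 2, 3], snr=[1, 2, 3])
        assert len(detect_and_filter(spec, 1e-4)) == 3

    def test_empty_spectrum_gives_empty_result(self):
        assert detect_and_filter(_spectrum([], []), 10) == []

    def test_baseline_estimate_keeps_strong_peaks_only(self):
        rng = np.random.default_rng(0)
        grid = np.arange(700.0, 800.0, 1.0)
        baseline = np.abs(rng.normal(30, 30, grid.size))
        mz = np.concatenate([grid, [750.5, 760.5]])
        intensity = np.concatenate([baseline, [5000.0, 90.0]])
        kept = detect_and_filter(_spectrum(mz, intensity), 10)
        assert [p.mz for p in kept] == [750.5]

    def test_all_baseline_spectrum_empty(self):
        rng = np.random.default_rng(1)
        grid = np.arange(700.0, 760.0, 1.0)
        spec = _spectrum(grid, np.abs(rng.normal(30, 30, grid.size)))
        assert detect_and_filter(spec, 10) == []

    def test_noise_free_sparse_spectrum_all_retained(self):
        spec = _spectrum([700.0, 702.0, 704.0], [10.0, 500.0, 20.0])
        assert len(detect_and_filter(spec, 10)) == 3


class TestMatchToDatabase:
    def test_peak_assigned_within_tolerance(self, db):
        target = db.get("PC 34:1").mz()
        peaks = [Peak(target + 0.2, 1000.0)]
        out = match_to_database(peaks, db, CLASSES["PC"].quant_channel,
                                tol=0.3)
        assert len(out) == 1 and out[0].species.name == "PC 34:1"

    def test_far_peak_dropped(self, db):
        mzs = np.array([mz for mz, _ in
                        db.channel_targets(CLASSES["PC"].quant_channel)])
        lonely = mzs.max() + 5.0
        out = match_to_database([Peak(lonely, 10.0)], db,
                                CLASSES["PC"].quant_channel, tol=0.5)
        assert out == []

    def test_equidistant_tie_goes_to_lower_mz(self, db):
        a = db.get("TAG 50:1")
        b = db.get("TAG 50:0")  # exactly one double bond apart, 2 Th up
        midpoint = (a.mz() + b.mz()) / 2
        out = match_to_database([Peak(midpoint, 10.0)], db,
                                CLASSES["TAG"].quant_channel, tol=1.5)
        assert out[0].species.name == "TAG 50:1"  # lower m/z of the pair

    def test_coincident_peaks_sum_into_one_species(self, db):
        target = db.get("PC 34:1").mz()
        peaks = [Peak(target, 100.0), Peak(target + 0.01, 11.0)]
        out = match_to_database(peaks, db, CLASSES["PC"].quant_channel)
        assert out[0].raw_intensity == pytest.approx(111.0)


def _identified(name, raw, channel="pos_hg184.total"):
    return IdentifiedIntensity(species=parse_shorthand(name),
                               raw_intensity=raw, channel_id=channel)


class TestIsotopeCorrect:
    def test_lone_species_divided_by_m0_fraction(self):
        out = isotope_correct([_identified("PC 34:1", 1000.0)])
        f0 = carbon_binomial_envelope(42)[0]
        assert out[0].corrected_intensity == pytest.approx(1000.0 / f0)
        assert out[0].corrected_intensity == pytest.approx(1571, abs=1.0)

    def test_pure_contamination_zeroes_out(self):
        """A peak that is entirely the M+2 of the species one double bond
        up corrects to zero."""
        env = carbon_binomial_envelope(46)  # PC 38:x carries 46 carbons
        raw_j = 1000.0
        raw_i = raw_j * env[2] / env[0]  # what stage 1 will subtract
        out = isotope_correct([_identified("PC 38:6", raw_j),
                               _identified("PC 38:5", raw_i)])
        by_name = {r.species.name: r for r in out}
        assert by_name["PC 38:5"].corrected_intensity == pytest.approx(
            0.0, abs=1e-9)
        assert by_name["PC 38:6"].corrected_intensity == pytest.approx(
            raw_j / env[0], rel=1e-9)

    def test_disabled_is_identity(self):
        out = isotope_correct([_identified("PC 38:6", 123.0)], enabled=False)
        assert out[0].corrected_intensity == 123.0

    def test_stage1_noop_without_neighbours(self):
        """With no species 2 Th below, stage 1 leaves the raw value; only
        the stage-2 normalization applies (so reapplying stage 1 would be
        idempotent)."""
        records = [_identified("PC 34:1", 500.0),
                   _identified("PC 40:6", 800.0)]
        out = isotope_correct(records)
        for rec, raw in zip(out, [500.0, 800.0]):
            f0 = carbon_binomial_envelope(rec.species.composition.C)[0]
            assert rec.corrected_intensity == pytest.approx(raw / f0)

    def test_order_independence(self):
        records = [_identified("PC 38:6", 1000.0),
                   _identified("PC 38:5", 300.0),
                   _identified("PC 38:4", 200.0)]
        forward = isotope_correct(list(records))
        backward = isotope_correct(list(reversed(records)))
        key = lambda r: r.species.name
        for a, b in zip(sorted(forward, key=key), sorted(backward, key=key)):
            assert a.corrected_intensity == pytest.approx(
                b.corrected_intensity)

    def test_negative_clamped_to_zero(self):
        env = carbon_binomial_envelope(46)
        out = isotope_correct([_identified("PC 38:6", 1000.0),
                               _identified("PC 38:5", 0.5 * 1000 * env[2]
                                           / env[0])])
        by_name = {r.species.name: r for r in out}
        assert by_name["PC 38:5"].corrected_intensity == 0.0

    @pytest.mark.parametrize("name", [
        "PC 34:1",    # 42 carbons
        "TAG 54:5",   # 57 carbons
        "TAG 56:2",   # 59 carbons
    ])
    def test_composition_mode_matches_full_convolution(self, name):
        """Composition-mode correction agrees with an independently coded
        multi-element convolution to within 1% up to ~60 carbons."""
        species = parse_shorthand(name)
        counts = species.composition.as_dict()
        oracle = full_convolution_envelope(counts)
        true_total = 1000.0
        raw_m0 = true_total * oracle[0]  # M0 peak of a full envelope
        out = isotope_correct(
            [IdentifiedIntensity(species=species, raw_intensity=raw_m0,
                                 channel_id="c")],
            envelope_model="composition")
        assert out[0].corrected_intensity == pytest.approx(
            true_total, rel=0.01)

    def test_composition_mode_pair_recovery(self):
        """Full-envelope spectra with M+2 cross-contamination: the
        composition-mode correction recovers both abundances within 1%."""
        sp_j = parse_shorthand("PC 38:6")
        sp_i = parse_shorthand("PC 38:5")
        env_j = full_convolution_envelope(sp_j.composition.as_dict())
        env_i = full_convolution_envelope(sp_i.composition.as_dict())
        total_j, total_i = 1000.0, 250.0
        raw_j = total_j * env_j[0]
        raw_i = total_i * env_i[0] + total_j * env_j[2]
        out = isotope_correct(
            [IdentifiedIntensity(sp_j, raw_j, channel_id="c"),
             IdentifiedIntensity(sp_i, raw_i, channel_id="c")],
            envelope_model="composition")
        by_name = {r.species.name: r for r in out}
        assert by_name["PC 38:6"].corrected_intensity == pytest.approx(
            total_j, rel=0.01)
        assert by_name["PC 38:5"].corrected_intensity == pytest.approx(
            total_i, rel=0.01)
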
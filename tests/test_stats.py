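"""Log transform, omnibus ANOVA, rank diagnostic and protected LSD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import anova_by_hand, lsd_t_by_hand

from shotgunlipids.stats import (
    AnovaResult,
    GroupDesign,
    count_directional_changes,
    log_transform,
    null_design,
    omnibus_anova,
    protected_lsd,
    protected_null_false_positive_rate,
    rank_pvalue_diagnostic,
    run_significance,
)
from shotgunlipids.synthetic import generate_null_matrix


def _design(groups):
    """groups: {(strain, diet): n_samples} -> GroupDesign."""
    rows = []
    for (strain, diet), n in groups.items():
        for i in range(n):
            rows.append({"sample_id": f"{strain}_{diet}_{i}",
                         "strain": strain, "diet": diet})
    return GroupDesign(pd.DataFrame(rows))


def _series(design, values):
    return pd.Series(values, index=design.frame["sample_id"].tolist())


TWO_CELL = _design({("A", "CHOW"): 4, ("A", "HFD"): 4})


class TestLogTransform:
    def test_e_maps_to_one(self):
        values = pd.DataFrame({"s1": [np.e]}, index=["x"])
        assert log_transform(values).loc["x", "s1"] == pytest.approx(1.0)

    def test_zeros_replaced_by_half_minimum_positive(self):
        values = pd.DataFrame([[0.0, 2.0, 4.0]], index=["x"],
                              columns=["a", "b", "c"])
        out = log_transform(values)
        assert out.loc["x", "a"] == pytest.approx(np.log(1.0))

    def test_all_zero_species_excluded(self):
        values = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["dead", "ok"],
                              columns=["a", "b"])
        out = log_transform(values)
        assert list(out.index) == ["ok"]

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame([[-1.0]], index=["x"], columns=["a"]))


class TestOmnibusAnova:
    def test_identical_cells_with_zero_variance_give_p_one(self):
        design = _design({("A", "CHOW"): 4, ("A", "HFD"): 4,
                          ("B", "CHOW"): 4, ("B", "HFD"): 4})
        res = omnibus_anova(_series(design, [1.0] * 16), design)
        assert res.p_value == 1.0

    def test_zero_variance_different_means_give_p_zero(self):
        res = omnibus_anova(_series(TWO_CELL, [1.0] * 4 + [2.0] * 4),
                            TWO_CELL)
        assert res.p_value == 0.0

    def test_two_cell_textbook_instance(self):
        values = [1, 2, 3, 4, 2, 3, 4, 5]
        res = omnibus_anova(_series(TWO_CELL, values), TWO_CELL)
        f, mse, dfb, dfw = anova_by_hand([[1, 2, 3, 4], [2, 3, 4, 5]])
        assert res.f_statistic == pytest.approx(f, rel=1e-12)
        assert res.mse == pytest.approx(mse, rel=1e-12)
        assert (res.df_between, res.df_within) == (dfb, dfw)
        assert res.f_statistic == pytest.approx(1.2)

    def test_matches_brute_force_on_random_instances(self):
        """Omnibus F and the LSD t agree with plain-Python sum-of-squares
        computations to 1e-10 relative on 25 random small instances."""
        rng = np.random.default_rng(12)
        design = _design({("A", "CHOW"): 3, ("A", "HFD"): 4,
                          ("B", "CHOW"): 5, ("B", "HFD"): 3})
        cells = dict(design.cells())
        for _ in range(25):
            values = _series(design, rng.lognormal(0, 0.4, 15))
            res = omnibus_anova(values, design)
            groups = [values.loc[ids].tolist()
                      for ids in cells.values()]
            f, mse, _, _ = anova_by_hand(groups)
            assert res.f_statistic == pytest.approx(f, rel=1e-10)
            posthocs = protected_lsd(res, values, design, screen_alpha=1.1)
            for ph in posthocs:
                hfd = values.loc[cells[(ph.strain, "HFD")]].tolist()
                chow = values.loc[cells[(ph.strain, "CHOW")]].tolist()
                assert ph.t_statistic == pytest.approx(
                    lsd_t_by_hand(hfd, chow, mse), rel=1e-10)

    def test_two_cell_anova_equals_pooled_t_test(self):
        rng = np.random.default_rng(5)
        values = _series(TWO_CELL, rng.normal(0, 1, 8))
        res = omnibus_anova(values, TWO_CELL)
        t_res = sps.ttest_ind(values.iloc[4:], values.iloc[:4],
                              equal_var=True)
        assert res.p_value == pytest.approx(t_res.pvalue, rel=1e-12)

    def test_null_p_values_uniform(self):
        """Under a complete null the omnibus p values are U(0,1)."""
        design = GroupDesign(null_design())
        values = generate_null_matrix(1000, design.frame, cv=0.2, seed=7)
        pvals = [omnibus_anova(row, design).p_value
                 for _, row in np.log(values).iterrows()]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestRankDiagnostic:
    def test_sorting_and_ranks(self):
        results = [AnovaResult(s, 1.0, p, 9, 30, 1.0)
                   for s, p in [("a", 0.2), ("b", 0.05), ("c", 0.9)]]
        out = rank_pvalue_diagnostic(results)
        assert list(out["p_value"]) == [0.05, 0.2, 0.9]
        assert list(out["rank"]) == [1, 2, 3]

    def test_uniform_p_tracks_expected_quantiles(self):
        rng = np.random.default_rng(0)
        pvals = rng.uniform(size=500)
        results = [AnovaResult(f"s{i}", 1.0, p, 9, 30, 1.0)
                   for i, p in enumerate(pvals)]
        out = rank_pvalue_diagnostic(results)
        corr = np.corrcoef(out["p_value"], out["expected_uniform"])[0, 1]
        assert corr > 0.99

    def test_needs_two_species(self):
        with pytest.raises(ValueError):
            rank_pvalue_diagnostic([AnovaResult("a", 1, 0.5, 1, 6, 1.0)])


class TestProtectedLsd:
    def test_failed_screen_produces_no_records(self):
        design = _design({("A", "CHOW"): 4, ("A", "HFD"): 4})
        values = _series(design, np.arange(8.0))
        anova = AnovaResult("x", 1.0, 0.2, 1, 6, 1.0)
        assert protected_lsd(anova, values, design) == []

    def test_equal_means_strain_not_called(self):
        design = _design({("A", "CHOW"): 4, ("A", "HFD"): 4,
                          ("B", "CHOW"): 4, ("B", "HFD"): 4})
        values = _series(design,
                         [1.0, 1.1, 0.9, 1.0, 1.0, 0.9, 1.1, 1.0,  # A: equal
                          1.0, 1.1, 0.9, 1.0, 5.0, 5.1, 4.9, 5.0])  # B: up
        res = omnibus_anova(values, design)
        posthocs = protected_lsd(res, values, design)
        by_strain = {ph.strain: ph for ph in posthocs}
        assert by_strain["A"].p_value > 0.9
        assert by_strain["A"].direction == "none"
        assert by_strain["B"].significant and by_strain["B"].direction == "up"

    def test_direction_from_raw_mean_difference(self):
        design = _design({("A", "CHOW"): 4, ("A", "HFD"): 4})
        transformed = _series(design, [0, 0, 0, 0, 3, 3, 3, 3.01])
        raw = _series(design, [1, 1, 1, 1, 20, 20, 20, 20.5])
        res = omnibus_anova(transformed, design)
        posthocs = protected_lsd(res, transformed, design, raw_values=raw)
        assert posthocs[0].direction == "up"
        assert posthocs[0].mean_difference == pytest.approx(
            raw.iloc[4:].mean() - raw.iloc[:4].mean())

    def test_tag_effect_detected_in_every_strain(self):
        """Power check: a doubling of TAG species at cv 0.1, n = 4 per
        cell, is called 'up' in all five strains."""
        from shotgunlipids.synthetic import CohortConfig, \
            generate_cohort_truth

        truth = generate_cohort_truth(CohortConfig(seed=8, cv=0.1))
        conc = truth.concentrations
        values = conc.pivot(index="species", columns="sample_id",
                            values="true_nmol_per_mg")
        design = GroupDesign(truth.samples[["sample_id", "strain", "diet"]])
        transformed = log_transform(values)
        anovas, posthocs = run_significance(transformed, design,
                                            raw_values=values)
        tag_up = {(ph.species, ph.strain) for ph in posthocs
                  if ph.species.startswith("TAG") and ph.direction == "up"
                  and ph.significant}
        tag_species = [s for s in values.index if s.startswith("TAG")]
        for species in tag_species:
            for strain in design.strains:
                assert (species, strain) in tag_up


class TestProtection:
    def test_null_false_positive_rate_bounded(self):
        """Complete-null simulation: per-comparison false-positive rate of
        the protected procedure stays at or below the LSD threshold."""
        out = protected_null_false_positive_rate(n_species=1000, cv=0.2,
                                                 seed=42)
        assert out["false_positive_rate"] <= 0.01

    def test_gate_no_posthoc_without_screen(self):
        """No species failing the omnibus screen has any post-hoc record."""
        out = protected_null_false_positive_rate(n_species=300, cv=0.2,
                                                 seed=11)
        screened = {a.species for a in out["anovas"] if a.p_value < 0.05}
        posthoc_species = {ph.species for ph in out["posthocs"]}
        assert posthoc_species <= screened

    def test_monotonic_in_effect_size(self):
        """A larger simulated TAG effect never yields fewer significant TAG
        calls (same seed)."""
        from shotgunlipids.synthetic import CohortConfig, EffectModel, \
            generate_cohort_truth

        counts = []
        for factor in (1.2, 2.0, 3.5):
            config = CohortConfig(
                seed=13, cv=0.2,
                effect_model=EffectModel(tag_hfd_factor=factor))
            truth = generate_cohort_truth(config)
            values = truth.concentrations.pivot(
                index="species", columns="sample_id",
                values="true_nmol_per_mg")
            design = GroupDesign(
                truth.samples[["sample_id", "strain", "diet"]])
            _, posthocs = run_significance(log_transform(values), design,
                                           raw_values=values)
            counts.append(sum(1 for ph in posthocs if ph.significant
                              and ph.species.startswith("TAG")))
        assert counts == sorted(counts)


class TestDirectionalCounts:
    def test_no_significant_species_gives_empty_grid(self):
        out = count_directional_changes([], {})
        assert out.empty

    def test_counts_partition_by_class(self):
        from shotgunlipids.stats import PosthocResult
        posthocs = [
            PosthocResult("TAG 52:3", "A", 5.0, 0.001, "up", True, 1.0),
            PosthocResult("TAG 54:5", "A", 5.0, 0.002, "up", True, 1.0),
            PosthocResult("PC 16:0/22:6", "A", -5.0, 0.002, "down", True,
                          -1.0),
            PosthocResult("PC 16:0/22:6", "B", -1.0, 0.5, "none", False,
                          -0.1),
        ]
        classes = {"TAG 52:3": "TAG", "TAG 54:5": "TAG",
                   "PC 16:0/22:6": "PC"}
        out = count_directional_changes(posthocs, classes)
        grid = out.set_index(["class", "strain"])
        assert grid.loc[("TAG", "A"), "n_up"] == 2
        assert grid.loc[("TAG", "A"), "n_down"] == 0
        assert grid.loc[("PC", "A"), "n_down"] == 1
        assert ("PC", "B") not in grid.index
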
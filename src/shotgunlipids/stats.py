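"""Significance pipeline: log transform, per-species one-way ANOVA,
p-value-rank diagnostic, protected Fisher's LSD and directional counts.

Species tables are log-transformed (concentrations are positive and
right-skewed), screened by a one-way ANOVA across all strain x diet cells,
and only species passing the omnibus screen (P < 0.05) receive per-strain
CHOW-vs-HFD least-significant-difference t tests using the pooled ANOVA
error (p < 0.01, two-sided).  The "protection" is this screen: no omnibus
significance, no post-hoc records.  No additional multiplicity correction
is applied on top of the protected procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

DEFAULT_SCREEN_ALPHA = 0.05
DEFAULT_LSD_ALPHA = 0.01


@dataclass(frozen=True)
class GroupDesign:
    """Sample-to-cell assignment for the strain x diet layout."""

    frame: pd.DataFrame  # sample_id, strain, diet

    def __post_init__(self) -> None:
        counts = self.frame.groupby(["strain", "diet"]).size()
        if (counts >= 2).sum() < 2:
            raise ValueError("need >= 2 cells with >= 2 samples")

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.frame["strain"]))

    def cells(self) -> list[tuple[tuple[str, str], list[str]]]:
        out = []
        for key, group in self.frame.groupby(["strain", "diet"], sort=False):
            out.append((key, group["sample_id"].tolist()))
        return out


@dataclass
class AnovaResult:
    species: str
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    mse: float  # pooled within-cell variance


@dataclass
class PosthocResult:
    species: str
    strain: str
    t_statistic: float
    p_value: float
    direction: str        # "up" | "down" | "none"
    significant: bool
    mean_difference: float  # raw HFD - CHOW


def log_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Natural log of a species x sample matrix.

    Zeros are replaced by half the species' minimum positive value before
    the transform (logged); species that are zero everywhere are excluded
    from the result (logged) since no contrast is estimable for them.
    """
    if (values < 0).any().any():
        raise ValueError("concentrations must be non-negative")
    out = {}
    for name, row in values.iterrows():
        positive = row[row > 0]
        if positive.empty:
            log.info("species %s is zero in all samples; excluded", name)
            continue
        if (row == 0).any():
            floor = positive.min() / 2.0
            log.info("species %s: %d zero(s) replaced by %.3g before log",
                     name, int((row == 0).sum()), floor)
            row = row.replace(0.0, floor)
        out[name] = np.log(row.astype(float))
    return pd.DataFrame(out).T if out else pd.DataFrame(columns=values.columns)


def omnibus_anova(values: pd.Series, design: GroupDesign,
                  species: str = "") -> AnovaResult:
    """One-way ANOVA of one species across all design cells.

    Returns F, p, the between/within degrees of freedom and the pooled
    within-cell variance (MSE) reused by the protected LSD.  With zero
    within-cell variance everywhere, p is 0 when cell means differ and 1
    when they are identical (logged convention for degenerate input).
    """
    groups = [values.loc[ids].to_numpy(dtype=float)
              for _, ids in design.cells()]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n_total - k
    if ss_within <= 0:
        p = 1.0 if np.isclose(ss_between, 0.0) else 0.0
        log.info("species %s: zero within-cell variance; p=%g by convention",
                 species, p)
        f = np.inf if p == 0.0 else 0.0
        return AnovaResult(species, f, p, df_between, df_within, 0.0)
    mse = ss_within / df_within
    f = (ss_between / df_between) / mse
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(species, float(f), p, df_between, df_within,
                       float(mse))


def rank_pvalue_diagnostic(results: list[AnovaResult]) -> pd.DataFrame:
    """Ranked omnibus p values with expected-uniform quantiles.

    Purely a plotting aid (p versus rank should be linear under the global
    null); the operative screen is the omnibus threshold, not this plot.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 species to rank")
    frame = pd.DataFrame(
        {"species": [r.species for r in results],
         "p_value": [r.p_value for r in results]})
    frame = frame.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    m = len(frame)
    frame["rank"] = np.arange(1, m + 1)
    frame["expected_uniform"] = frame["rank"] / (m + 1)
    return frame


def protected_lsd(anova: AnovaResult, values: pd.Series, design: GroupDesign,
                  raw_values: pd.Series | None = None,
                  screen_alpha: float = DEFAULT_SCREEN_ALPHA,
                  lsd_alpha: float = DEFAULT_LSD_ALPHA,
                  ) -> list[PosthocResult]:
    """Per-strain CHOW-vs-HFD LSD t tests, gated by the omnibus screen.

    With omnibus p >= ``screen_alpha`` no post-hoc records exist.  The t
    statistic uses transformed group means and the pooled ANOVA MSE with
    the within-cell degrees of freedom; direction comes from the sign of
    the raw (untransformed) mean difference when raw values are supplied.
    """
    if anova.p_value >= screen_alpha:
        return []
    cell_ids = dict(design.cells())
    out = []
    for strain in design.strains:
        ids_chow = cell_ids.get((strain, "CHOW"))
        ids_hfd = cell_ids.get((strain, "HFD"))
        if not ids_chow or not ids_hfd:
            log.info("strain %s missing a diet group; LSD skipped", strain)
            continue
        m_chow = float(values.loc[ids_chow].mean())
        m_hfd = float(values.loc[ids_hfd].mean())
        n1, n2 = len(ids_hfd), len(ids_chow)
        se = np.sqrt(anova.mse * (1.0 / n1 + 1.0 / n2))
        diff = m_hfd - m_chow
        if se == 0:
            t = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            t = diff / se
            p = float(2.0 * sps.t.sf(abs(t), anova.df_within))
        source = raw_values if raw_values is not None else values
        raw_diff = float(source.loc[ids_hfd].mean()
                         - source.loc[ids_chow].mean())
        significant = p < lsd_alpha
        direction = "none"
        if significant:
            direction = "up" if raw_diff > 0 else "down"
        out.append(PosthocResult(anova.species, strain, float(t), p,
                                 direction, significant, raw_diff))
    return out


def run_significance(values: pd.DataFrame, design: GroupDesign,
                     raw_values: pd.DataFrame | None = None,
                     screen_alpha: float = DEFAULT_SCREEN_ALPHA,
                     lsd_alpha: float = DEFAULT_LSD_ALPHA,
                     mode: str = "cells",
                     ) -> tuple[list[AnovaResult], list[PosthocResult]]:
    """Screen + post-hoc over a transformed species x sample matrix.

    ``mode="cells"`` (default) runs the omnibus across all strain x diet
    cells with a pooled MSE; ``mode="per-strain"`` restricts each species'
    omnibus to one strain's two diet groups at a time, the alternative
    reading of a two-group one-way layout.
    """
    anovas: list[AnovaResult] = []
    posthocs: list[PosthocResult] = []
    for name, row in values.iterrows():
        raw = None if raw_values is None else raw_values.loc[name]
        if mode == "cells":
            res = omnibus_anova(row, design, species=name)
            anovas.append(res)
            posthocs.extend(protected_lsd(res, row, design, raw_values=raw,
                                          screen_alpha=screen_alpha,
                                          lsd_alpha=lsd_alpha))
        elif mode == "per-strain":
            for strain in design.strains:
                sub = GroupDesign(
                    design.frame[design.frame["strain"] == strain])
                res = omnibus_anova(row, sub, species=name)
                anovas.append(res)
                posthocs.extend(protected_lsd(res, row, sub, raw_values=raw,
                                              screen_alpha=screen_alpha,
                                              lsd_alpha=lsd_alpha))
        else:
            raise ValueError("mode must be 'cells' or 'per-strain'")
    return anovas, posthocs


def count_directional_changes(posthocs: list[PosthocResult],
                              species_class: dict[str, str],
                              ) -> pd.DataFrame:
    """Class x strain counts of significantly decreased/increased species.

    The machine-readable form of the arrow columns of a class-total table.
    """
    rows = []
    for ph in posthocs:
        if not ph.significant:
            continue
        rows.append({"class": species_class[ph.species], "strain": ph.strain,
                     "direction": ph.direction})
    if not rows:
        return pd.DataFrame(columns=["class", "strain", "n_down", "n_up"])
    frame = pd.DataFrame(rows)
    counts = (frame.groupby(["class", "strain", "direction"]).size()
              .unstack("direction", fill_value=0))
    for col in ("down", "up"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts.rename(columns={"down": "n_down", "up": "n_up"})
    return counts[["n_down", "n_up"]].reset_index()


def anova_frame(anovas: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in anovas])


def posthoc_frame(posthocs: list[PosthocResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in posthocs])


# ---------------------------------------------------------------------------
# type-I-error calibration
# ---------------------------------------------------------------------------

def null_design(n_strains: int = 5, replicates: int = 4) -> pd.DataFrame:
    """A strain x diet sample layout with no effects attached."""
    rows = []
    for s in range(1, n_strains + 1):
        for diet in ("CHOW", "HFD"):
            for r in range(1, replicates + 1):
                rows.append({"sample_id": f"S{s}_{diet}_{r}",
                             "strain": f"S{s}", "diet": diet})
    return pd.DataFrame(rows)


def protected_null_false_positive_rate(
        n_species: int = 1000, cv: float = 0.2, seed: int = 42,
        n_strains: int = 5, replicates: int = 4,
        screen_alpha: float = DEFAULT_SCREEN_ALPHA,
        lsd_alpha: float = DEFAULT_LSD_ALPHA) -> dict:
    """Empirical per-comparison false-positive rate under a complete null.

    Simulates ``n_species`` independent lognormal species with identical
    means in every strain x diet cell, runs the full omnibus-screen +
    protected-LSD pipeline, and divides the number of significant
    within-strain calls by the number of comparisons the procedure
    evaluates (``n_species x n_strains``; contrasts of species that fail
    the screen are evaluated as not significant).
    """
    from .synthetic import generate_null_matrix

    design = null_design(n_strains=n_strains, replicates=replicates)
    values = generate_null_matrix(n_species, design, cv, seed)
    transformed = log_transform(values)
    anovas, posthocs = run_significance(
        transformed, GroupDesign(design), raw_values=values,
        screen_alpha=screen_alpha, lsd_alpha=lsd_alpha)
    n_significant = sum(1 for ph in posthocs if ph.significant)
    n_comparisons = n_species * n_strains
    screened = {a.species for a in anovas if a.p_value < screen_alpha}
    return {
        "false_positive_rate": n_significant / n_comparisons,
        "n_significant": n_significant,
        "n_comparisons": n_comparisons,
        "n_screened_species": len(screened),
        "anovas": anovas,
        "posthocs": posthocs,
    }
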
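"""Derived lipidome metrics: class totals, PC/PE ratio, PUFA category sums
and diet-response deltas.

All operations act on the pipeline's canonical concentration table — a long
DataFrame with columns ``sample_id, strain, diet, species, class, level,
concentration, resolved`` in nmol/mg tissue.  A species contributes at
molecular level where resolved and at sum level otherwise, never both.

The phospholipid pool is defined explicitly as PC + PC-O + PE + PE-O + PS.
A species with one n-6 and one n-3 chain counts in both family sums (the
shorthand carries no basis to pick one); set ``families="exclusive"`` to
assign by majority chain family instead.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .nomenclature import (
    DEFAULT_OMEGA_TABLE,
    PHOSPHOLIPID_CLASSES,
    classify_acyl,
    count_pufa_chains,
    parse_shorthand,
)

log = logging.getLogger(__name__)


class ConsistencyError(ValueError):
    """A species is counted at both sum and molecular level."""


def _check_single_level(conc: pd.DataFrame) -> None:
    molecular = conc[conc["level"] == "molecular"]
    if molecular.empty:
        return
    parent = molecular["species"].map(lambda n: parse_shorthand(n).sum_name)
    sum_rows = conc[conc["level"] == "sum"]
    clash = set(zip(molecular["sample_id"], parent)) & \
        set(zip(sum_rows["sample_id"], sum_rows["species"]))
    if clash:
        sample, name = next(iter(clash))
        raise ConsistencyError(
            f"{name} appears at both sum and molecular level in {sample}")


def class_totals(conc: pd.DataFrame) -> pd.DataFrame:
    """Per-sample per-class totals (nmol/mg); columns are classes."""
    _check_single_level(conc)
    totals = (conc.groupby(["sample_id", "class"])["concentration"]
              .sum().unstack(fill_value=0.0))
    return totals


def pl_total(totals: pd.DataFrame) -> pd.Series:
    cols = [c for c in PHOSPHOLIPID_CLASSES if c in totals.columns]
    return totals[cols].sum(axis=1)


def pc_pe_ratio(totals: pd.DataFrame, include_ether: bool = False
                ) -> pd.Series:
    """Per-sample PC/PE ratio (diacyl classes by default).

    Raises for zero PE (undefined ratio); zero PC simply gives 0.
    """
    pc = totals.get("PC", pd.Series(0.0, index=totals.index)).copy()
    pe = totals.get("PE", pd.Series(0.0, index=totals.index)).copy()
    if include_ether:
        pc = pc + totals.get("PC-O", 0.0)
        pe = pe + totals.get("PE-O", 0.0)
    if (pe <= 0).any():
        bad = pe.index[pe <= 0][0]
        raise ZeroDivisionError(f"PE total is zero in sample {bad!r}; "
                                "PC/PE ratio undefined")
    return pc / pe


def pufa_category_sums(conc: pd.DataFrame,
                       omega_table: dict | None = None,
                       families: str = "both",
                       ) -> pd.DataFrame:
    """Per-sample sums of PUFA-containing phospholipids, nmol/mg.

    Columns: ``n6_pl``, ``n3_pl`` (any chain in the family), ``ge1_pufa_pl``
    (>= 1 chain with >= 2 double bonds), ``double_pufa_pl`` (both chains),
    plus ``double_pufa_share`` of the total PL pool.  Only molecular-level
    phospholipids enter the categories; unresolved sum species are excluded
    (and logged) but still count toward the PL total in the share.
    """
    if omega_table is None:
        omega_table = DEFAULT_OMEGA_TABLE
    pl = conc[conc["class"].isin(PHOSPHOLIPID_CLASSES)]
    samples = conc["sample_id"].unique()
    out = pd.DataFrame(0.0, index=pd.Index(samples, name="sample_id"),
                       columns=["n6_pl", "n3_pl", "ge1_pufa_pl",
                                "double_pufa_pl"])
    unresolved = pl[pl["level"] != "molecular"]
    if not unresolved.empty:
        log.info("%d unresolved phospholipid rows excluded from PUFA "
                 "categories", len(unresolved))
    molecular = pl[pl["level"] == "molecular"]
    for name, group in molecular.groupby("species"):
        species = parse_shorthand(name)
        n_pufa = count_pufa_chains(species)
        fams = [classify_acyl(c, omega_table).omega_family
                for c in species.chains]
        in_n6, in_n3 = "n-6" in fams, "n-3" in fams
        if families == "exclusive" and in_n6 and in_n3:
            n6_count = fams.count("n-6")
            n3_count = fams.count("n-3")
            in_n6, in_n3 = n6_count >= n3_count, n3_count > n6_count
        per_sample = group.groupby("sample_id")["concentration"].sum()
        if in_n6:
            out.loc[per_sample.index, "n6_pl"] += per_sample
        if in_n3:
            out.loc[per_sample.index, "n3_pl"] += per_sample
        if n_pufa >= 1:
            out.loc[per_sample.index, "ge1_pufa_pl"] += per_sample
        if n_pufa == 2:
            out.loc[per_sample.index, "double_pufa_pl"] += per_sample
    pl_pool = pl.groupby("sample_id")["concentration"].sum()
    out["double_pufa_share"] = (out["double_pufa_pl"]
                                / pl_pool.reindex(out.index)).fillna(0.0)
    return out


def diet_delta(metric: pd.DataFrame, value_column: str = "value"
               ) -> pd.DataFrame:
    """Per-strain mean(HFD) - mean(CHOW) on raw (untransformed) values.

    ``metric`` needs columns ``strain``, ``diet`` and the value column.
    A strain missing either diet group raises with the strain and diet
    named.
    """
    rows = []
    for strain, group in metric.groupby("strain", sort=False):
        means = group.groupby("diet")[value_column].mean()
        for diet in ("CHOW", "HFD"):
            if diet not in means.index:
                raise ValueError(f"strain {strain!r} has no {diet} samples")
        rows.append({"strain": strain,
                     "delta": float(means["HFD"] - means["CHOW"])})
    return pd.DataFrame(rows)


def species_count_summary(conc: pd.DataFrame) -> pd.Series:
    """Detected species per class (nonzero concentration in >= 1 sample)."""
    detected = conc[conc["concentration"] > 0]
    if detected.empty:
        return pd.Series(dtype=int)
    return detected.groupby("class")["species"].nunique()


def sample_profiles(conc: pd.DataFrame, include_ether_in_ratio: bool = False
                    ) -> pd.DataFrame:
    """One row per sample: class totals, PL total, PC/PE ratio and the four
    PUFA category sums."""
    totals = class_totals(conc)
    meta = (conc[["sample_id", "strain", "diet"]]
            .drop_duplicates().set_index("sample_id"))
    profile = totals.copy()
    profile["PL_total"] = pl_total(totals)
    profile["pc_pe_ratio"] = pc_pe_ratio(totals,
                                         include_ether=include_ether_in_ratio)
    cats = pufa_category_sums(conc)
    profile = profile.join(cats, how="left")
    return meta.join(profile, how="right").reset_index()


def group_summary(conc: pd.DataFrame) -> pd.DataFrame:
    """Class x strain grid of group mean +/- SEM per diet (the shape of a
    published class-total table)."""
    totals = class_totals(conc)
    meta = (conc[["sample_id", "strain", "diet"]]
            .drop_duplicates().set_index("sample_id"))
    stacked = totals.join(meta).melt(
        id_vars=["strain", "diet"], var_name="class", value_name="total",
        ignore_index=False)
    grouped = stacked.groupby(["class", "strain", "diet"])["total"]
    summary = grouped.agg(
        mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
    return (summary.unstack("diet").swaplevel(axis=1).sort_index(axis=1)
            .reset_index())


def summary_table(conc: pd.DataFrame,
                  significance_counts: pd.DataFrame | None = None
                  ) -> pd.DataFrame:
    """Class x strain grid of CHOW/HFD mean +/- SEM, species count and
    directional significance counts — one row per class and strain, the
    shape of a published class-total table."""
    grid = group_summary(conc)
    grid.columns = ["class", "strain"] + [
        f"{diet.lower()}_{stat}" for diet, stat in grid.columns[2:]]
    counts = species_count_summary(conc).rename("species_in_class")
    grid = grid.merge(counts, left_on="class", right_index=True, how="left")
    if significance_counts is not None and not significance_counts.empty:
        grid = grid.merge(significance_counts, on=["class", "strain"],
                          how="left")
        grid[["n_down", "n_up"]] = grid[["n_down", "n_up"]] \
            .fillna(0).astype(int)
    else:
        grid["n_down"] = 0
        grid["n_up"] = 0
    return grid
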
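"""Cleaning rules for multiplex cytokine panels.

Bead-based multiplex assays report concentrations interpolated from a
standard curve; samples outside the curve's range are unreliable.  Cleaning
applies two rules:

1. censoring — concentrations below the curve's lower limit are set to
   0 pg/mL, concentrations above the upper limit to the curve maximum;
2. analyte retention — an analyte is kept for modelling if it is non-zero
   (above background) in at least half of the subjects in the stratum, or,
   failing that, if its non-zero values are skewed toward one genotype
   (a one-sided Fisher exact test on the genotype x non-zero table; the
   smaller of the two directional p-values is compared to ``bias_p``).

Every retention decision is recorded in an audit table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = ["CytokinePanel", "censor", "retain_analytes", "panel_to_wide"]

_LONG_COLUMNS = ["subject", "genotype", "age_months", "region", "analyte",
                 "concentration_pg_per_ml", "below_limit", "above_limit"]


@dataclass
class CytokinePanel:
    """Long-format cytokine concentrations plus per-analyte curve limits.

    ``data`` columns: subject, genotype, age_months, region, analyte,
    concentration_pg_per_ml, below_limit, above_limit.  ``limits`` is indexed
    by analyte with columns lower_pg_ml / upper_pg_ml.  ``planted`` optionally
    records ground-truth signal analytes from the synthetic generator.
    """

    data: pd.DataFrame
    limits: pd.DataFrame
    planted: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _LONG_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel missing columns {missing}")
        if (self.data["concentration_pg_per_ml"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        both = (self.data["below_limit"] & self.data["above_limit"]).any()
        if both:
            raise ValueError("below/above-limit flags must be mutually exclusive")
        if not (self.limits["lower_pg_ml"] < self.limits["upper_pg_ml"]).all():
            raise ValueError("curve lower limit must be below upper limit")

    @property
    def analytes(self) -> list[str]:
        return sorted(self.data["analyte"].unique())

    def copy(self) -> "CytokinePanel":
        return CytokinePanel(self.data.copy(), self.limits.copy(),
                             list(self.planted))


def censor(panel: CytokinePanel) -> CytokinePanel:
    """Map out-of-curve concentrations to 0 / curve maximum (idempotent)."""
    missing = set(panel.data["analyte"]) - set(panel.limits.index)
    if missing:
        raise ValueError(f"no curve limits for analytes {sorted(missing)}")
    df = panel.data.copy()
    lower = panel.limits["lower_pg_ml"].reindex(df["analyte"]).to_numpy()
    upper = panel.limits["upper_pg_ml"].reindex(df["analyte"]).to_numpy()
    conc = df["concentration_pg_per_ml"].to_numpy(dtype=float)
    below = conc < lower
    above = conc > upper
    conc = np.where(below, 0.0, conc)
    conc = np.where(above, upper, conc)
    df["concentration_pg_per_ml"] = conc
    df["below_limit"] = below | (conc == 0.0) & df["below_limit"].to_numpy()
    df["above_limit"] = above | np.isclose(conc, upper) & df["above_limit"].to_numpy()
    df["below_limit"] = df["below_limit"] & ~df["above_limit"]
    return CytokinePanel(df, panel.limits.copy(), list(panel.planted))


def _bias_p(nonzero_by_group: dict[str, int], totals: dict[str, int],
            groups: tuple[str, str]) -> float:
    """Smaller one-sided Fisher exact p for genotype-skewed non-zeros."""
    a, b = groups
    table = [[nonzero_by_group.get(a, 0), totals[a] - nonzero_by_group.get(a, 0)],
             [nonzero_by_group.get(b, 0), totals[b] - nonzero_by_group.get(b, 0)]]
    p_hi = fisher_exact(table, alternative="greater")[1]
    p_lo = fisher_exact(table, alternative="less")[1]
    return min(p_hi, p_lo)


def retain_analytes(panel: CytokinePanel,
                    groups: tuple[str, str] = ("5xFAD", "WT"),
                    bias_p: float = 0.10,
                    region: str | None = None):
    """Apply the half-subjects retention rule with the group-bias exception.

    Operates within one stratum: the subjects (optionally restricted to one
    ``region``) entering a model.  Returns the filtered panel and an audit
    table with one row per analyte: counts, the rule that fired
    (``half_rule`` / ``bias_exception`` / ``dropped``), and the Fisher p.
    """
    df = panel.data
    if region is not None:
        df = df[df["region"] == region]
    sub = df.drop_duplicates(["subject", "genotype"])
    totals = sub.groupby("genotype")["subject"].nunique().to_dict()
    for g in groups:
        if totals.get(g, 0) < 2:
            raise ValueError(f"need >= 2 subjects per group; {g} has {totals.get(g, 0)}")
    n_subjects = sum(totals[g] for g in groups)
    audit_rows = []
    retained = []
    for analyte, adf in df.groupby("analyte", sort=True):
        nz = adf[adf["concentration_pg_per_ml"] > 0]
        nz_subjects = nz.drop_duplicates("subject")
        n_nonzero = len(nz_subjects)
        frac = n_nonzero / n_subjects
        by_group = nz_subjects.groupby("genotype")["subject"].nunique().to_dict()
        p = _bias_p(by_group, totals, groups)
        if frac >= 0.5:
            rule = "half_rule"
        elif p < bias_p:
            rule = "bias_exception"
        else:
            rule = "dropped"
        if rule != "dropped":
            retained.append(analyte)
        audit_rows.append({"analyte": analyte, "n_nonzero": n_nonzero,
                           "n_subjects": n_subjects, "fraction_nonzero": frac,
                           "fisher_p": p, "rule": rule,
                           "retained": rule != "dropped"})
    audit = pd.DataFrame(audit_rows)
    out = panel.data[panel.data["analyte"].isin(retained)]
    if region is not None:
        out = out[out["region"] == region]
    cleaned = CytokinePanel(out.reset_index(drop=True), panel.limits.copy(),
                            [a for a in panel.planted if a in retained])
    return cleaned, audit


def panel_to_wide(panel: CytokinePanel, genotype: str | None = None,
                  region: str | None = None):
    """Subjects x analytes concentration matrix plus aligned metadata.

    Returns ``(X, meta)`` where ``meta`` has one row per subject with
    genotype and age_months — the shape the PLS module consumes.
    """
    df = panel.data
    if genotype is not None:
        df = df[df["genotype"] == genotype]
    if region is not None:
        df = df[df["region"] == region]
    wide = df.pivot_table(index="subject", columns="analyte",
                          values="concentration_pg_per_ml", aggfunc="first")
    meta = (df.drop_duplicates("subject")
            .set_index("subject")[["genotype", "age_months"]]
            .loc[wide.index])
    return wide, meta
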
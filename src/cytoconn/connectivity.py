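"""System-level aggregation and group contrasts of ROI connectivity.

Pairwise Pearson correlations between ROI BOLD time courses are the raw
currency of resting-state functional connectivity.  Because correlations are
bounded and skewed, every averaging and differencing operation here happens in
Fisher-z space (``arctanh``), with results transformed back to r space for
reporting.  Group contrasts are fitted edge by edge with a linear mixed-effects
model, ``y = X beta + Z u + eps``, where the response is the z-transformed
correlation of one edge across scans, fixed effects encode genotype (and
optionally age and their interaction), and a per-subject random intercept
absorbs repeated scans of the same animal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConnectivityMatrix",
    "SystemDefinition",
    "EdgeStats",
    "fisher_z",
    "inv_fisher_z",
    "aggregate_system",
    "group_mean_matrix",
    "difference_matrix",
    "matrices_to_edge_table",
    "fit_edgewise_lme",
    "anova_genotype_by_age",
    "fdr_correct",
    "binarize",
]

#: clip |r| to this bound before arctanh so duplicated ROIs (r = 1) stay finite
_R_CLIP = 1.0 - 1e-10

# The seven anatomical systems used for system-level summaries.
SEVEN_SYSTEMS = (
    "Sensorimotor Cortex",
    "Heteromodal Cortex",
    "Olfactory Cortex",
    "Hippocampus",
    "Striatum-Pallidum",
    "Thalamus",
    "Hypothalamus",
)


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI-by-ROI Pearson correlation matrix with metadata.

    ``r`` may contain NaN rows/columns for degenerate (zero-variance) ROIs;
    those entries propagate as missing through aggregation.
    """

    r: np.ndarray
    roi_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if len(self.roi_names) != self.r.shape[0]:
            raise ValueError("roi_names length must match matrix size")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("roi_names must be unique")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.r)) > 1 + 1e-9:
                raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(
            np.nan_to_num(self.r), np.nan_to_num(self.r.T), atol=1e-10
        ):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.roi_names, columns=self.roi_names)


@dataclass
class SystemDefinition:
    """Mapping of anatomical system name -> ordered ROI-name list."""

    systems: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, rois in self.systems.items():
            dup = seen.intersection(rois)
            if dup:
                raise ValueError(f"systems must be disjoint; {sorted(dup)} repeated")
            seen.update(rois)

    def validate_against(self, matrix: ConnectivityMatrix) -> None:
        known = set(matrix.roi_names)
        for name, rois in self.systems.items():
            missing = [r for r in rois if r not in known]
            if missing:
                raise ValueError(f"system {name!r} references unknown ROIs {missing}")

    @property
    def names(self) -> list[str]:
        return list(self.systems)


@dataclass
class EdgeStats:
    """Edgewise mixed-model contrast results.

    ``table`` has one row per edge: roi_i, roi_j, beta, se, tstat, df,
    p, q, sig and an ``ols_fallback`` flag marking edges where the
    mixed-model fit was singular and an OLS fit was used instead.
    """

    table: pd.DataFrame
    alpha: float
    term: str

    def mask(self, roi_names: Sequence[str], alpha: float | None = None) -> np.ndarray:
        """Symmetric binary significance mask over the ROI set."""
        a = self.alpha if alpha is None else alpha
        n = len(roi_names)
        idx = {name: i for i, name in enumerate(roi_names)}
        m = np.zeros((n, n), dtype=bool)
        for row in self.table.itertuples():
            if row.p < a:
                i, j = idx[row.roi_i], idx[row.roi_j]
                m[i, j] = m[j, i] = True
        return m


def fisher_z(r):
    """Fisher z-transform ``arctanh(r)``; ``|r| = 1`` is clipped just inside."""
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmax(np.abs(r), initial=0.0) > 1 + 1e-9:
            raise ValueError("|r| > 1 is not a correlation")
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def inv_fisher_z(z):
    """Inverse Fisher transform ``tanh(z)``."""
    return np.tanh(np.asarray(z, dtype=float))


def _system_pairs(matrix: ConnectivityMatrix, rois_a: list[str], rois_b: list[str],
                  intra: bool) -> np.ndarray:
    idx = {name: i for i, name in enumerate(matrix.roi_names)}
    ia = [idx[r] for r in rois_a]
    ib = [idx[r] for r in rois_b]
    vals = []
    if intra:
        for u in range(len(ia)):
            for v in range(u + 1, len(ia)):
                vals.append(matrix.r[ia[u], ia[v]])
    else:
        for u in ia:
            for v in ib:
                vals.append(matrix.r[u, v])
    return np.asarray(vals, dtype=float)


def aggregate_system(matrix: ConnectivityMatrix,
                     systems: SystemDefinition) -> pd.DataFrame:
    """Average ROI-pair connectivity to a system-by-system matrix.

    Entry (A, B) is ``tanh(mean(arctanh(r)))`` over all ROI pairs with one end
    in A and the other in B; diagonal entries average the within-system pairs
    only (self-pairs excluded).  NaN pair values (degenerate ROIs) are dropped
    from the mean.
    """
    systems.validate_against(matrix)
    names = systems.names
    out = np.full((len(names), len(names)), np.nan)
    for a, na in enumerate(names):
        for b in range(a, len(names)):
            nb = names[b]
            if a == b:
                if len(systems.systems[na]) < 2:
                    raise ValueError(
                        f"system {na!r} has < 2 ROIs; intra-system value undefined")
                vals = _system_pairs(matrix, systems.systems[na], [], intra=True)
            else:
                vals = _system_pairs(matrix, systems.systems[na],
                                     systems.systems[nb], intra=False)
            z = fisher_z(vals)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                m = float(np.tanh(np.nanmean(z))) if vals.size else np.nan
            out[a, b] = out[b, a] = m
    return pd.DataFrame(out, index=names, columns=names)


def group_mean_matrix(matrices: Iterable[ConnectivityMatrix],
                      group: str | None = None) -> ConnectivityMatrix:
    """Entrywise z-space mean of a set of connectivity matrices."""
    mats = list(matrices)
    if not mats:
        raise ValueError("cannot average an empty collection")
    names = mats[0].roi_names
    for m in mats[1:]:
        if m.roi_names != names:
            raise ValueError("matrices must share an identical ROI set")
    zs = np.stack([fisher_z(m.r) for m in mats])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r = inv_fisher_z(np.nanmean(zs, axis=0))
    np.fill_diagonal(mean_r, 1.0)
    return ConnectivityMatrix(mean_r, list(names),
                              metadata={"group": group, "n": len(mats)})


def difference_matrix(group_a: ConnectivityMatrix,
                      group_b: ConnectivityMatrix) -> pd.DataFrame:
    """Signed edgewise difference ``arctanh(A) - arctanh(B)`` in z units."""
    if group_a.roi_names != group_b.roi_names:
        raise ValueError("ROI sets differ between groups")
    d = fisher_z(group_a.r) - fisher_z(group_b.r)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=group_a.roi_names, columns=group_a.roi_names)


def matrices_to_edge_table(matrices: Sequence[ConnectivityMatrix]) -> pd.DataFrame:
    """Long table of z-transformed edges: one row per scan x edge.

    Columns: roi_i, roi_j, y (arctanh r), subject, genotype, age_months,
    scan_id.  Metadata keys absent from a matrix become NaN.
    """
    rows = []
    for m in matrices:
        z = fisher_z(m.r)
        md = m.metadata
        for i in range(m.n_rois):
            for j in range(i + 1, m.n_rois):
                rows.append({
                    "roi_i": m.roi_names[i],
                    "roi_j": m.roi_names[j],
                    "y": z[i, j],
                    "subject": md.get("subject"),
                    "genotype": md.get("genotype"),
                    "age_months": md.get("age_months"),
                    "scan_id": md.get("scan_id"),
                })
    return pd.DataFrame(rows)


def _design(df: pd.DataFrame, longitudinal: bool):
    g = (df["genotype"].astype(str) == "5xFAD").astype(float).to_numpy()
    if longitudinal:
        age = df["age_months"].astype(float).to_numpy()
        X = np.column_stack([np.ones(len(df)), g, age, g * age])
        cols = ["intercept", "genotype", "age", "genotype:age"]
    else:
        X = np.column_stack([np.ones(len(df)), g])
        cols = ["intercept", "genotype"]
    return X, cols


def _fit_one_edge(y, X, cols, groups, term):
    """REML random-intercept fit for one edge; OLS fallback on singular fits."""
    k = cols.index(term)
    fallback = False
    beta = se = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X, groups=groups)
            res = model.fit(reml=True, method="bfgs", maxiter=200)
            beta = res.fe_params[k]
            se = res.bse_fe[k]
        except Exception:
            fallback = True
    if fallback or not np.isfinite(beta) or not np.isfinite(se) or se == 0:
        fallback = True
        res = sm.OLS(y, X).fit()
        beta = res.params[k]
        se = res.bse[k]
    df_t = max(len(y) - X.shape[1], 1)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df_t)
    return beta, se, t, df_t, p, fallback


def fit_edgewise_lme(edge_table: pd.DataFrame, *, longitudinal: bool = False,
                     term: str = "genotype", alpha: float = 0.05) -> EdgeStats:
    """Fit the mixed model per edge and test one fixed-effect coefficient.

    Per-timepoint analyses (``longitudinal=False``) use genotype as the sole
    fixed effect; longitudinal analyses add age and the genotype x age
    interaction.  Subjects are the random effect (random intercept, REML).
    The coefficient named by ``term`` is tested with a two-tailed t statistic
    on residual degrees of freedom (n - p).  Singular mixed fits fall back to
    OLS and are flagged.

    Raises if either genotype has fewer than 2 subjects.
    """
    for g in ("5xFAD", "WT"):
        sub = edge_table.loc[edge_table["genotype"] == g, "subject"].nunique()
        if sub < 2:
            raise ValueError(f"need >= 2 subjects per genotype; {g} has {sub}")
    rows = []
    for (ri, rj), df in edge_table.groupby(["roi_i", "roi_j"], sort=True):
        df = df.dropna(subset=["y"])
        X, cols = _design(df, longitudinal)
        y = df["y"].to_numpy()
        groups = df["subject"].to_numpy()
        beta, se, t, df_t, p, fb = _fit_one_edge(y, X, cols, groups, term)
        rows.append({"roi_i": ri, "roi_j": rj, "beta": beta, "se": se,
                     "tstat": t, "df": df_t, "p": p, "ols_fallback": fb})
    table = pd.DataFrame(rows)
    table["q"] = fdr_correct(table["p"].to_numpy())
    table["sig"] = table["p"] < alpha
    return EdgeStats(table=table, alpha=alpha, term=term)


def anova_genotype_by_age(values: pd.DataFrame, response: str = "value"
                          ) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA: genotype x age on subject-mean values.

    Used for global graph metrics (strength, efficiency, clustering,
    assortativity) where each subject contributes one value per timepoint:
    ``values`` needs columns subject, genotype, age_months and ``response``.
    Repeated scans should be averaged to subject level first.  Returns the
    type-II ANOVA table (sum_sq, df, F, PR(>F)) with rows for genotype,
    age (categorical), and their interaction.
    """
    from statsmodels.formula.api import ols

    df = values.rename(columns={response: "y"}).copy()
    df["genotype"] = df["genotype"].astype(str)
    df["age_c"] = df["age_months"].astype(str)
    model = ols("y ~ C(genotype) * C(age_c)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return table.rename(index={
        "C(genotype)": "genotype",
        "C(age_c)": "age",
        "C(genotype):C(age_c)": "genotype:age",
    })


def fdr_correct(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binarize(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Binary significance mask ``p < alpha``."""
    return np.asarray(p, dtype=float) < alpha
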
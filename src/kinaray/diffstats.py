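"""Per-substrate inference for kinome-array experiments.

Each retained substrate's log2 net intensities are modeled by ordinary
least squares with treatment-coded categorical covariates::

    y ~ 1 + time + cell_type + replicate

with reference levels time = 0 min, cell type = Teff, replicate = 1, so
the cell-type coefficient is the Treg-vs-Teff activity contrast adjusted
for time and replicate.  Per coefficient, two-sided t-tests against zero;
per substrate, a nested-model ANOVA F-test of the full model against a
null lacking the cell-type term (configurable to intercept-only).

Across substrates, Benjamini-Hochberg false discovery rates are computed
separately within each parameter family (time, cell type, replicate), and
the ANOVA p-values are Bonferroni-corrected with m = number of substrates
tested.  Descriptive layers: Welch t-tests between conditions, per-time
log2 fold changes (Treg over Teff), and kinetic profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

CELL_NUMERATOR = "Treg"
CELL_REFERENCE = "Teff"

TERMS = ("time", "cell_type", "replicate")


class DegenerateTTestWarning(UserWarning):
    """Both groups have zero variance but different means."""


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def substrate_ttest(group_a, group_b) -> TTestResult:
    """Two-sided Welch t-test between two sets of log2 intensities.

    Zero-variance degeneracies are resolved explicitly: identical
    constant groups give (t=0, p=1); constant groups at different levels
    are flagged degenerate (p reported as 0 with a warning).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0)
        warnings.warn("zero-variance groups with unequal means: p "
                      "degenerates to 0", DegenerateTTestWarning)
        return TTestResult(np.inf if a.mean() > b.mean() else -np.inf,
                           0.0, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(t), float(p))


# ---------------------------------------------------------------------------
# design matrix and linear model


def design_matrix(samples: pd.DataFrame):
    """Treatment-coded design matrix from sample metadata.

    Reference levels: smallest time point, cell type ``Teff`` (or the
    first sorted level if absent), replicate 1 (smallest).  Returns
    ``(X, names, families)`` where ``families`` maps each model term to
    its column indices in X.
    """
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    families = {}

    times = sorted(samples["time_min"].unique())
    families["time"] = []
    for t in times[1:]:
        families["time"].append(len(names))
        cols.append((samples["time_min"] == t).to_numpy(float))
        names.append(f"time[{t}]")

    cells = sorted(samples["cell_type"].unique())
    ref_cell = CELL_REFERENCE if CELL_REFERENCE in cells else cells[0]
    families["cell_type"] = []
    for c in cells:
        if c == ref_cell:
            continue
        families["cell_type"].append(len(names))
        cols.append((samples["cell_type"] == c).to_numpy(float))
        names.append(f"cell[{c}]")

    reps = sorted(samples["replicate"].unique())
    families["replicate"] = []
    for r in reps[1:]:
        families["replicate"].append(len(names))
        cols.append((samples["replicate"] == r).to_numpy(float))
        names.append(f"rep[{r}]")

    return np.column_stack(cols), names, families


@dataclass(frozen=True)
class SubstrateFit:
    """OLS fit for one substrate."""

    substrate_id: str
    names: tuple
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    rss: float
    anova_F: float
    anova_p: float

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def coef_p(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "substrate_id": self.substrate_id,
            "coefficients": dict(zip(self.names, map(float, self.params))),
            "standard_errors": dict(zip(self.names, map(float, self.bse))),
            "pvalues": dict(zip(self.names, map(float, self.pvalues))),
            "df_resid": int(self.df_resid),
            "anova_F": float(self.anova_F),
            "anova_p": float(self.anova_p),
        }


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    for j, name in enumerate(names):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            raise ValueError(f"design matrix is rank deficient: covariate "
                             f"{name!r} is collinear")
    raise ValueError("design matrix is rank deficient")


def fit_linear_model(y, samples: pd.DataFrame, substrate_id: str = "",
                     null_model: str = "celltype") -> SubstrateFit:
    """OLS fit of one substrate's values on time, cell type and replicate.

    Missing values in ``y`` are dropped (with the matching design rows).
    ``null_model`` selects the nested comparison for the per-substrate
    ANOVA: ``"celltype"`` (default) drops the cell-type term from the
    full model, so the F-test targets the Treg-vs-Teff contrast;
    ``"intercept"`` compares against an intercept-only model.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(samples):
        raise ValueError("y and sample metadata differ in length")
    keep = ~np.isnan(y)
    sub = samples[keep].reset_index(drop=True)
    X, names, families = design_matrix(sub)
    yk = y[keep]
    if X.shape[0] <= X.shape[1]:
        raise ValueError("not enough observations for the model")
    _check_rank(X, names)

    res = sm.OLS(yk, X).fit()
    F, p = _nested_f(yk, X, names, families, null_model)
    return SubstrateFit(
        substrate_id=substrate_id, names=tuple(names),
        params=np.asarray(res.params), bse=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues), pvalues=np.asarray(res.pvalues),
        df_resid=int(res.df_resid), rss=float(res.ssr),
        anova_F=float(F), anova_p=float(p),
    )


def _null_columns(names, families, null_model: str):
    if null_model == "celltype":
        dropped = set(families["cell_type"])
    elif null_model == "intercept":
        dropped = {j for fam in families.values() for j in fam}
    else:
        raise ValueError(f"unknown null_model: {null_model!r}")
    return [j for j in range(len(names)) if j not in dropped]


def _nested_f(y, X, names, families, null_model: str):
    keep_cols = _null_columns(names, families, null_model)
    X0 = X[:, keep_cols]
    beta, rss, _, _ = _lstsq(X, y)
    _, rss0, _, _ = _lstsq(X0, y)
    df_full = X.shape[0] - X.shape[1]
    delta_df = X.shape[1] - X0.shape[1]
    return nested_anova_f(rss0, rss, delta_df, df_full)


def _lstsq(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid) if resid.ndim == 1 else (resid ** 2).sum()
    return beta, rss, resid, None


def nested_anova_f(rss_null, rss_full, delta_df, df_full):
    """F and p for a nested model comparison from residual sums of squares."""
    if delta_df < 1 or df_full < 1:
        raise ValueError("non-nested or saturated model comparison")
    num = (rss_null - rss_full) / delta_df
    den = rss_full / df_full
    if den == 0.0:
        F = 0.0 if num <= 0 else np.inf
    else:
        F = max(0.0, num / den)
    p = float(stats.f.sf(F, delta_df, df_full))
    return float(F), p


def anova_vs_null(y, samples: pd.DataFrame, null_model: str = "celltype",
                  m: int | None = None):
    """Full-vs-null nested ANOVA for one substrate.

    Returns ``(F, p)`` or ``(F, p, bonferroni_p)`` when the number of
    substrates tested ``m`` is given.
    """
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    sub = samples[keep].reset_index(drop=True)
    X, names, families = design_matrix(sub)
    F, p = _nested_f(y[keep], X, names, families, null_model)
    if m is None:
        return F, p
    return F, p, bonferroni(p, m)


def fit_many(values: pd.DataFrame, samples: pd.DataFrame,
             null_model: str = "celltype") -> pd.DataFrame:
    """Vectorized OLS over all substrates of a complete matrix.

    ``values`` must have no missing entries (the preprocessing stage
    guarantees this for retained substrates).  Solves the shared
    normal equations once and returns one row per substrate with
    coefficient estimates, standard errors, t statistics and two-sided
    p-values for every model term, plus family-level partial-F p-values
    (``p_fam_time`` etc.), the full-vs-null ANOVA F and p, and df_resid.
    """
    Y = values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("fit_many requires a complete matrix; run "
                         "preprocessing first or use fit_linear_model")
    X, names, families = design_matrix(samples)
    _check_rank(X, names)
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("not enough observations for the model")

    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv                      # (n_sub, p)
    resid = Y - B @ X.T
    rss = (resid ** 2).sum(axis=1)
    sigma2 = rss / df
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(se > 0, B / se, 0.0)
    P = 2.0 * stats.t.sf(np.abs(T), df)

    out = pd.DataFrame(index=values.index)
    for j, name in enumerate(names):
        out[f"beta_{name}"] = B[:, j]
        out[f"se_{name}"] = se[:, j]
        out[f"t_{name}"] = T[:, j]
        out[f"p_{name}"] = P[:, j]

    # family-level partial F tests (drop the family's columns)
    for fam, idx in families.items():
        if not idx:
            continue
        keep_cols = [j for j in range(p) if j not in set(idx)]
        rss0 = _rss_many(Y, X[:, keep_cols])
        ddf = len(idx)
        F = np.maximum(0.0, (rss0 - rss) / ddf) / np.where(rss > 0, rss / df, np.inf)
        out[f"F_fam_{fam}"] = F
        out[f"p_fam_{fam}"] = stats.f.sf(F, ddf, df)

    keep_cols = _null_columns(names, families, null_model)
    rss0 = _rss_many(Y, X[:, keep_cols])
    ddf = p - len(keep_cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.maximum(0.0, (rss0 - rss) / ddf) / np.where(rss > 0, rss / df, np.inf)
    out["anova_F"] = F
    out["anova_p"] = stats.f.sf(F, ddf, df)
    out["df_resid"] = df
    out.attrs["coef_names"] = names
    out.attrs["families"] = families
    return out


def _rss_many(Y, X0):
    B0 = Y @ X0 @ np.linalg.inv(X0.T @ X0)
    resid0 = Y - B0 @ X0.T
    return (resid0 ** 2).sum(axis=1)


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} (m / j) * p_(j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# descriptive summaries


def log2_fold_change(matrix, substrate_id: str, time_min: int,
                     numerator: str = CELL_NUMERATOR,
                     denominator: str = CELL_REFERENCE) -> float:
    """Mean log2 intensity difference, numerator minus denominator cell
    type, over non-missing replicates at one time point.  NaN when either
    side is entirely missing."""
    s = matrix.samples
    row = matrix.values.loc[substrate_id]
    out = []
    for cell in (numerator, denominator):
        cols = s[(s["cell_type"] == cell) & (s["time_min"] == time_min)]["sample_id"]
        if len(cols) == 0:
            raise ValueError(f"no samples for cell type {cell!r} at t={time_min}")
        vals = row[list(cols)].astype(float)
        out.append(float(vals.mean()) if vals.notna().any() else np.nan)
    return out[0] - out[1]


def fold_change_table(matrix, numerator: str = CELL_NUMERATOR,
                      denominator: str = CELL_REFERENCE) -> pd.DataFrame:
    """Per-substrate log2 fold change (numerator/denominator) per time."""
    s = matrix.samples
    times = sorted(s["time_min"].unique())
    out = pd.DataFrame(index=matrix.values.index)
    for t in times:
        means = {}
        for cell in (numerator, denominator):
            cols = list(s[(s["cell_type"] == cell)
                          & (s["time_min"] == t)]["sample_id"])
            means[cell] = matrix.values[cols].mean(axis=1)
        out[f"log2FC_t{t}"] = means[numerator] - means[denominator]
    return out


def kinetic_profile(matrix, substrate_id: str) -> dict:
    """Per cell type and time: replicate points and their mean.

    Returns ``{"points": tidy DataFrame, "means": DataFrame}``; means are
    over non-missing replicates, suitable for plotting an activity curve
    with replicate dots.
    """
    s = matrix.samples
    row = matrix.values.loc[substrate_id]
    points = s.copy()
    points["value"] = row[list(s["sample_id"])].to_numpy(dtype=float)
    points = points[["cell_type", "time_min", "replicate", "value"]]
    means = (points.dropna(subset=["value"])
             .groupby(["cell_type", "time_min"], sort=True)["value"]
             .mean().reset_index(name="mean"))
    return {"points": points.reset_index(drop=True), "means": means}


# ---------------------------------------------------------------------------
# the ranked differential table


def build_differential_table(matrix, annotation: pd.DataFrame | None = None,
                             alpha: float = 0.05,
                             null_model: str = "celltype") -> pd.DataFrame:
    """Fit every substrate and assemble the ranked differential table.

    Per substrate: the cell-type coefficient estimate and p-value, BH
    q-values within each parameter family (cell type from the coefficient
    p; time and replicate from their family partial-F p), the full-vs-null
    ANOVA with Bonferroni correction (m = substrates tested), and per-time
    log2 fold changes.  Rows are sorted by ascending cell-type p-value,
    ties broken by kinase name then substrate id.  ``significant`` marks
    q_celltype <= alpha.
    """
    fits = fit_many(matrix.values, matrix.samples, null_model=null_model)
    cell_cols = [c for c in fits.columns
                 if c.startswith("beta_cell[")]
    if len(cell_cols) != 1:
        raise ValueError("expected exactly one cell-type contrast")
    cell = cell_cols[0].removeprefix("beta_")

    m = len(fits)
    table = pd.DataFrame(index=fits.index)
    table["estimate_celltype"] = fits[f"beta_{cell}"]
    table["p_celltype"] = fits[f"p_{cell}"]
    table["q_celltype"] = bh_fdr(fits[f"p_{cell}"].to_numpy())
    table["q_time"] = bh_fdr(fits["p_fam_time"].to_numpy())
    table["q_replicate"] = bh_fdr(fits["p_fam_replicate"].to_numpy())
    table["anova_F"] = fits["anova_F"]
    table["anova_p"] = fits["anova_p"]
    table["bonferroni_p"] = np.minimum(1.0, m * fits["anova_p"])

    fc = fold_change_table(matrix)
    table = table.join(fc)
    table["significant"] = table["q_celltype"] <= alpha

    table = table.reset_index().rename(columns={"index": "substrate_id"})
    if "substrate_id" not in table.columns:  # index already named
        table = table.rename(columns={matrix.values.index.name: "substrate_id"})
    if annotation is not None:
        ann = annotation.rename(columns={"substrate": "substrate_protein"})
        table = table.merge(
            ann[["substrate_id", "kinase", "substrate_protein", "peptide",
                 "site"]],
            on="substrate_id", how="left",
        )
    else:
        for col in ("kinase", "substrate_protein", "peptide", "site"):
            table[col] = ""
    table["kinase"] = table["kinase"].fillna("")
    table = table.sort_values(
        ["p_celltype", "kinase", "substrate_id"], kind="stable"
    ).reset_index(drop=True)
    front = ["substrate_id", "kinase", "substrate_protein", "peptide", "site"]
    return table[front + [c for c in table.columns if c not in front]]
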
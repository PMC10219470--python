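"""Soil-community association: CCA, correlation heatmap, relative importance.

Three complementary views of how edaphic variables structure the fungal
community:

* **Canonical correspondence analysis** — the community table is chi-square
  standardized and regressed (row-weighted) on standardized soil variables;
  the eigendecomposition of the fitted matrix yields constrained axes.
  Collinear variables are removed beforehand by an iterative VIF screen
  (threshold 10), and each retained variable gets a Monte-Carlo permutation
  F-test.
* **Spearman heatmap** — phylum relative abundances against each soil
  variable, with significance marks at p < 0.05.
* **LMG relative importance** — the linear-model R2 for a community-derived
  response (e.g. summed keystone abundance) decomposed into non-negative
  per-predictor shares by averaging sequential R2 increments over all
  predictor orderings (exact enumeration; the shares sum to the full R2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_VIF_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# collinearity screening
# ---------------------------------------------------------------------------

def variance_inflation_factors(x: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R2_j) from regressing column j on the others
    (with intercept).  Perfectly collinear columns get +inf."""
    vals = x.to_numpy(float)
    n, p = vals.shape
    out = {}
    for j, name in enumerate(x.columns):
        others = np.column_stack([np.ones(n), np.delete(vals, j, axis=1)])
        y = vals[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_screen(x: pd.DataFrame, threshold: float = DEFAULT_VIF_THRESHOLD
               ) -> tuple[list[str], list[tuple[str, float]]]:
    """Iteratively drop the variable with the largest VIF until all are
    at or below ``threshold``.

    Returns (retained names in original order, dropped (name, vif) in drop
    order).  Ties on the maximum are broken by dropping the later column,
    so the result is deterministic and order-stable.
    """
    if x.shape[1] < 2:
        raise ValueError("need at least 2 variables to screen")
    if x.shape[0] <= x.shape[1]:
        raise ValueError(f"need more samples ({x.shape[0]}) than variables ({x.shape[1]})")
    current = x.copy()
    dropped: list[tuple[str, float]] = []
    while current.shape[1] >= 2:
        vifs = variance_inflation_factors(current)
        vmax = vifs.max()
        if vmax <= threshold:
            break
        worst = [name for name, v in vifs.items() if v == vmax][-1]
        dropped.append((worst, float(vmax)))
        current = current.drop(columns=[worst])
    return list(current.columns), dropped


# ---------------------------------------------------------------------------
# canonical correspondence analysis
# ---------------------------------------------------------------------------

def _chi_square_standardize(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Return (Q_bar, row weights r, column weights c, total inertia).

    Q_bar = D_r^-1/2 (P - r c^T) D_c^-1/2 with P the table scaled to sum 1;
    its squared Frobenius norm is the table's chi-square statistic divided
    by the grand total (the total inertia of correspondence analysis).
    """
    total = y.sum()
    p = y / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    q = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return q, r, c, float((q ** 2).sum())


def _weighted_standardize(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    mean = w @ x
    centered = x - mean
    sd = np.sqrt(w @ centered ** 2)
    sd[sd == 0] = 1.0
    return centered / sd


@dataclass
class CcaResult:
    """Constrained ordination output.

    ``axis_fractions`` are eigenvalue / total inertia (the percentages
    conventionally printed on CCA axes); scores use species-focused
    (type 2) scaling.
    """
    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    axis_fractions: np.ndarray
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    retained_variables: list[str] = field(default_factory=list)
    excluded_variables: list[tuple[str, float]] = field(default_factory=list)


def cca(table: pd.DataFrame, soil: pd.DataFrame) -> CcaResult:
    """Canonical correspondence analysis of a community on soil variables.

    ``table`` is samples x taxa (counts or relative abundances, all-zero
    rows/columns rejected); ``soil`` is samples x variables, assumed
    already VIF-screened.  The number of variables must be below n - 1.
    """
    soil = soil.loc[table.index]
    y = table.to_numpy(float)
    if (y.sum(axis=1) == 0).any() or (y.sum(axis=0) == 0).any():
        raise ValueError("community table has all-zero rows or columns")
    n, q = soil.shape
    if q > n - 1:
        raise ValueError(f"{q} variables for {n} samples; need variables <= samples - 1")
    qbar, r, c, total = _chi_square_standardize(y)
    x = _weighted_standardize(soil.to_numpy(float), r)
    xw = np.sqrt(r)[:, None] * x
    beta, *_ = np.linalg.lstsq(xw, qbar, rcond=None)
    fitted = xw @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    rank = min(q, len(s))
    keep = s[:rank] ** 2 > 1e-12 * max(total, 1.0)
    u, s, vt = u[:, :rank][:, keep], s[:rank][keep], vt[:rank][keep]
    eig = s ** 2
    axes = [f"CCA{i + 1}" for i in range(len(eig))]
    species = (vt.T / np.sqrt(c)[:, None]) * s          # type-2 scaling
    sites = u / np.sqrt(r)[:, None]                     # LC scores
    # biplot arrows: weighted correlation of each variable with the site axes
    biplot = np.array([[np.sum(r * x[:, j] * (np.sqrt(r) * sites[:, k]))
                        / np.sqrt(np.sum(r * x[:, j] ** 2) * np.sum(r * (np.sqrt(r) * sites[:, k]) ** 2))
                        for k in range(len(eig))] for j in range(q)])
    return CcaResult(
        eigenvalues=eig,
        total_inertia=total,
        constrained_inertia=float(eig.sum()),
        axis_fractions=eig / total,
        site_scores=pd.DataFrame(sites, index=table.index, columns=axes),
        species_scores=pd.DataFrame(species, index=table.columns, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=soil.columns, columns=axes),
        retained_variables=list(soil.columns),
    )


def _single_variable_inertia(qbar: np.ndarray, r: np.ndarray, x_col: np.ndarray) -> float:
    """Constrained inertia of a one-variable CCA (projection onto one
    weighted, standardized column)."""
    xs = _weighted_standardize(x_col[:, None], r)[:, 0]
    w = np.sqrt(r) * xs
    denom = w @ w
    if denom <= 0:
        return 0.0
    proj = qbar.T @ w
    return float(proj @ proj / denom)


def permutation_test_terms(table: pd.DataFrame, soil: pd.DataFrame,
                           n_permutations: int = 999, seed: int | None = 0
                           ) -> pd.DataFrame:
    """Marginal Monte-Carlo test per soil variable.

    Each variable is tested alone: F = lambda_v / ((total - lambda_v) /
    (n - 2)), and the null distribution is built by permuting the sample
    rows of the community matrix; p = (1 + exceedances) /
    (1 + n_permutations), so 999 permutations resolve p down to 0.001.
    """
    soil = soil.loc[table.index]
    y = table.to_numpy(float)
    n = y.shape[0]
    qbar, r, _, total = _chi_square_standardize(y)
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_permutations)]
    rows = []
    for name in soil.columns:
        x_col = soil[name].to_numpy(float)
        lam = _single_variable_inertia(qbar, r, x_col)
        f_obs = lam / ((total - lam) / (n - 2))
        exceed = 0
        for perm in perms:
            lam_p = _single_variable_inertia(qbar[perm], r[perm], x_col)
            f_p = lam_p / ((total - lam_p) / (n - 2))
            if f_p >= f_obs - 1e-12:
                exceed += 1
        rows.append({"variable": name, "inertia": lam, "F": f_obs,
                     "p": (1 + exceed) / (1 + n_permutations)})
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# phylum-soil correlation heatmap
# ---------------------------------------------------------------------------

@dataclass
class HeatmapResult:
    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame


def phylum_soil_heatmap(phylum_rel: pd.DataFrame, soil: pd.DataFrame,
                        alpha: float = 0.05) -> HeatmapResult:
    """Spearman rho and two-sided p for each (phylum, soil variable) pair.

    ``phylum_rel`` holds phylum relative abundances (samples x phyla).
    Constant phyla or variables are skipped with a warning; the
    ``significant`` frame marks p < alpha.
    """
    soil = soil.loc[phylum_rel.index]
    phyla = [p for p in phylum_rel.columns if np.ptp(phylum_rel[p].to_numpy(float)) > 0]
    svars = [v for v in soil.columns if np.ptp(soil[v].to_numpy(float)) > 0]
    skipped = (set(phylum_rel.columns) - set(phyla)) | (set(soil.columns) - set(svars))
    if skipped:
        warnings.warn(f"skipping constant column(s): {sorted(skipped)}", stacklevel=2)
    rho = pd.DataFrame(index=phyla, columns=svars, dtype=float)
    pval = pd.DataFrame(index=phyla, columns=svars, dtype=float)
    for ph in phyla:
        for v in svars:
            res = stats.spearmanr(phylum_rel[ph], soil[v])
            rho.loc[ph, v], pval.loc[ph, v] = float(res.statistic), float(res.pvalue)
    return HeatmapResult(rho=rho, p=pval, significant=pval < alpha)


# ---------------------------------------------------------------------------
# LMG relative importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceResult:
    shares: pd.Series
    r_squared: float


def _subset_r2(y: np.ndarray, x: np.ndarray, cols: tuple[int, ...]) -> float:
    n = len(y)
    design = np.column_stack([np.ones(n)] + [x[:, j] for j in cols])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - resid @ resid / tss if tss > 0 else 0.0


def lmg_importance(response, predictors: pd.DataFrame) -> ImportanceResult:
    """Exact LMG decomposition of the linear-model R2.

    The share of predictor j averages its R2 increment over all predictor
    orderings (computed by subset enumeration, feasible for <= 10
    predictors).  Shares are non-negative for ordinary designs and sum to
    the full-model R2 exactly.
    """
    p = predictors.shape[1]
    if p > 10:
        raise ValueError(f"{p} predictors exceed the exact-enumeration bound of 10")
    y = np.asarray(response, float)
    if predictors.shape[0] != len(y):
        raise ValueError("response and predictors disagree on sample count")
    if len(y) <= p:
        raise ValueError("need more samples than predictors")
    x = predictors.to_numpy(float)
    r2 = {(): 0.0}
    for size in range(1, p + 1):
        for cols in combinations(range(p), size):
            r2[cols] = _subset_r2(y, x, cols)
    shares = np.zeros(p)
    fact = math.factorial
    for j in range(p):
        rest = [k for k in range(p) if k != j]
        for size in range(p):
            w = fact(size) * fact(p - size - 1) / fact(p)
            for cols in combinations(rest, size):
                with_j = tuple(sorted(cols + (j,)))
                shares[j] += w * (r2[with_j] - r2[cols])
    return ImportanceResult(
        shares=pd.Series(shares, index=predictors.columns, name="lmg_share"),
        r_squared=r2[tuple(range(p))],
    )


def random_forest_importance(response, predictors: pd.DataFrame,
                             n_estimators: int = 500, seed: int | None = 0) -> pd.Series:
    """Optional cross-check: random-forest impurity importances for the
    same response (normalized to sum 1)."""
    from sklearn.ensemble import RandomForestRegressor

    rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    rf.fit(predictors.to_numpy(float), np.asarray(response, float))
    return pd.Series(rf.feature_importances_, index=predictors.columns, name="rf_importance")
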
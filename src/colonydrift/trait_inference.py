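"""Relating demographic noise to phenotypic traits.

Given a strain × trait table with the relative MSD as response, this module
provides plain and partial correlations, sparse trait selection by
L1-penalized (Lasso) regression with cross-validated penalty choice, and a
permutation test for gene-set (GO/KEGG-style term) shifts in the mean MSD.
Annotations are supplied as plain member lists; no database access happens
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LassoCV, lasso_path
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "correlate",
    "partial_correlation",
    "lasso_select",
    "LassoResult",
    "term_shift_test",
]


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with n ≥ 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = scipy.stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = scipy.stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def partial_correlation(x, y, controls) -> tuple[float, float]:
    """Correlation of x and y after removing linear effects of the controls.

    Both variables are residualized on the controls (plus an intercept) by
    least squares; the Pearson correlation of the residuals is returned with
    a t-distributed p-value on n − 2 − k degrees of freedom for k controls.
    An empty control set reduces exactly to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(controls, dtype=float)
    if Z.size == 0:
        Z = np.empty((len(x), 0))
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = len(x), Z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > k + 2 observations")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear controls: design is rank-deficient")
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero residual variance: partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return r, p


@dataclass
class LassoResult:
    coefficients: pd.Series  # on the standardized-predictor scale
    support: list  # trait names with nonzero coefficient
    r2: float  # in-sample R² of the selected model
    alpha: float  # chosen L1 penalty
    intercept: float


def lasso_select(
    traits: pd.DataFrame,
    response: str = "relative_msd",
    exclude: Sequence[str] = ("strain_id",),
    cv_folds: int = 5,
    seed: int | None = 0,
    selection_rule: str = "min",
) -> LassoResult:
    """Sparse linear trait selection by cross-validated Lasso.

    Predictors are centered and scaled to unit variance; the L1 penalty is
    chosen by ``cv_folds``-fold cross-validated mean squared error with
    seeded, shuffled fold assignment (``selection_rule="min"``; ``"1se"``
    picks the sparsest model within one standard error of the minimum).
    Returns standardized-scale coefficients, the nonzero support, and the
    in-sample R².  Constant trait columns are dropped with a warning.
    """
    cols = [c for c in traits.columns if c not in set(exclude) and c != response]
    X = traits[cols].to_numpy(dtype=float)
    y = traits[response].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"dropping constant trait columns: {dropped}", stacklevel=2)
        cols = [c for c, k in zip(cols, keep) if k]
        X = X[:, keep]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=100, max_iter=50_000).fit(Xs, y)
    alpha = float(model.alpha_)
    if selection_rule == "1se":
        mse = model.mse_path_.mean(axis=1)
        se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
        limit = mse.min() + se[int(np.argmin(mse))]
        # alphas_ descend; the largest alpha within one SE is the sparsest
        alpha = float(model.alphas_[np.flatnonzero(mse <= limit)[0]])
        alphas, coefs, _ = lasso_path(Xs, y, alphas=[alpha], max_iter=50_000)
        coef = coefs[:, 0]
        intercept = float(y.mean())
    elif selection_rule == "min":
        coef = model.coef_
        intercept = float(model.intercept_)
    else:
        raise ValueError(f"unknown selection_rule {selection_rule!r}")
    pred = Xs @ coef + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    series = pd.Series(coef, index=cols, name="coefficient")
    return LassoResult(
        coefficients=series,
        support=[c for c in cols if series[c] != 0.0],
        r2=r2,
        alpha=alpha,
        intercept=intercept,
    )


def term_shift_test(
    values: pd.Series,
    terms: Mapping[str, Sequence[str]],
    reference: str = "random-subsets",
    wt_values: Sequence[float] | None = None,
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Permutation test for gene-set shifts in mean relative MSD.

    ``values`` maps tested strains to their relative MSD.  For each term
    (member strains ⊆ tested universe), the observed statistic is the term's
    mean value.  Two null references are available and the chosen one is
    recorded per row:

    * ``"random-subsets"`` — null means of random same-size subsets of the
      tested strains (does the term differ from random knockouts?);
    * ``"wt-values"`` — two-sample permutation of term values against
      supplied wild-type replicate values (does the term differ from WT?).

    Two-sided p-values use the add-one (permutation-inclusive) correction,
    so p ≥ 1/(n_permutations + 1); q-values are Benjamini–Hochberg across
    terms.
    """
    if n_permutations < 1000:
        raise ValueError("n_permutations must be at least 1000")
    if reference not in ("random-subsets", "wt-values"):
        raise ValueError(f"unknown reference {reference!r}")
    if reference == "wt-values" and wt_values is None:
        raise ValueError("wt-values reference requires wt_values")
    universe = set(values.index)
    rng = np.random.default_rng(seed)
    vals = values.to_numpy(dtype=float)
    rows = []
    for term, members in terms.items():
        members = list(members)
        if not set(members) <= universe:
            raise ValueError(f"term {term!r} has members outside the tested universe")
        if not 1 <= len(members) <= len(values):
            raise ValueError(f"term {term!r} has invalid size")
        obs_vals = values.loc[members].to_numpy(dtype=float)
        obs = obs_vals.mean()
        if reference == "random-subsets":
            idx = np.argsort(
                rng.random((n_permutations, len(vals))), axis=1
            )[:, : len(members)]
            null = vals[idx].mean(axis=1)
        else:
            wt = np.asarray(wt_values, dtype=float)
            pooled = np.concatenate([obs_vals, wt])
            stat_obs = obs - wt.mean()
            perm = np.argsort(rng.random((n_permutations, len(pooled))), axis=1)
            grp = pooled[perm[:, : len(members)]]
            rest = pooled[perm[:, len(members):]]
            null = grp.mean(axis=1) - rest.mean(axis=1)
            obs = stat_obs
        centered = null - null.mean()
        p = (1 + np.sum(np.abs(centered) >= abs(obs - null.mean()))) / (n_permutations + 1)
        z = (obs - null.mean()) / null.std(ddof=1) if null.std(ddof=1) > 0 else np.nan
        rows.append(
            {
                "term": term,
                "n_members": len(members),
                "mean": float(obs_vals.mean()),
                "z": float(z),
                "p": float(p),
                "reference": reference,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = []
    return out
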
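"""Count testing core: per-unit NB-GLM and the spatial FDR procedure.

The GLM relates per-unit cell counts across samples to condition (and
an optional batch covariate) with a log link and per-sample size-factor
offsets.  Dispersion is estimated by pooling per-unit Cameron-Trivedi
moment estimates into a common value; the condition effect is assessed
with a likelihood-ratio test.  The spatial FDR is a
weighted Benjamini-Hochberg step-up where each testing unit is weighted
by the reciprocal of its local density, so discoveries are controlled
across volume rather than across units.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

_MAX_ALPHA = 10.0
_MIN_ALPHA = 1e-8


def _fit_glm(y, X, offset, family):
    model = sm.GLM(y, X, family=family, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100)


def _design_matrices(condition: np.ndarray, batch: np.ndarray | None):
    n = len(condition)
    cols_null = [np.ones(n)]
    if batch is not None:
        levels = sorted(set(batch))
        for lev in levels[1:]:
            cols_null.append((np.asarray(batch) == lev).astype(float))
    X_null = np.column_stack(cols_null)
    X_full = np.column_stack(cols_null + [condition.astype(float)])
    return X_full, X_null


def size_factors(unit_counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample size factors over testing units.

    Assumes most units are not differentially abundant: each sample's
    factor is the median ratio of its unit counts to the per-unit
    geometric mean (computed over units with no zero count).  Falls back
    to relative column totals when too few units qualify.
    """
    counts = np.atleast_2d(np.asarray(unit_counts, dtype=float))
    positive = (counts > 0).all(axis=1)
    if positive.sum() >= 3:
        sub = counts[positive]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    else:
        totals = counts.sum(axis=0)
        factors = totals / np.mean(np.maximum(totals, 1.0))
    return np.maximum(factors, 1e-8)


def nb_glm_test(
    unit_counts: np.ndarray,
    condition: np.ndarray,
    batch: np.ndarray | None = None,
    offsets: np.ndarray | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio NB regression of unit counts on condition.

    Parameters
    ----------
    unit_counts
        units x samples non-negative integer matrix.
    condition
        per-sample 0/1 (C1/C2) indicator; the tested coefficient.
    batch
        optional per-sample batch labels, entered as covariates.
    offsets
        per-sample log size factors; default is median-of-ratios
        normalization across units (so "no change" is anchored on the
        bulk of the units, as TMM-style normalization does, rather than
        on raw totals that the planted effect itself inflates).

    Returns a DataFrame with ``logFC`` (log2 fold-change of C2 vs C1),
    ``p_value`` and ``not_assessed`` per unit.  All-zero units get
    p = 1, logFC = 0 and the flag; a failed NB fit falls back to
    Poisson with a warning.
    """
    unit_counts = np.atleast_2d(np.asarray(unit_counts))
    condition = np.asarray(condition)
    if unit_counts.shape[1] != len(condition):
        raise ValueError("unit_counts columns must match condition length")
    for value in (0, 1):
        if (condition == value).sum() < 2:
            raise ValueError("need at least 2 samples per condition")
    if offsets is None:
        offsets = np.log(size_factors(unit_counts))
    X_full, X_null = _design_matrices(condition, batch)
    cond_col = X_full.shape[1] - 1
    ln2 = np.log(2.0)

    # Per-unit moment estimates of the NB dispersion are hopeless with a
    # handful of samples; pool them into one common dispersion (the
    # median across units), mirroring common-dispersion estimation in
    # count-based DE frameworks.
    poisson_fits = []
    alphas = []
    for y in unit_counts:
        y = y.astype(float)
        if y.sum() == 0:
            poisson_fits.append(None)
            continue
        try:
            pois = _fit_glm(y, X_full, offsets, sm.families.Poisson())
        except Exception:
            poisson_fits.append(None)
            continue
        poisson_fits.append(pois)
        mu = np.maximum(pois.fittedvalues, 1e-8)
        # Cameron-Trivedi moment estimator
        alphas.append(float(np.sum((y - mu) ** 2 - mu) / np.sum(mu**2)))
    common_alpha = float(np.median(alphas)) if alphas else _MIN_ALPHA
    common_alpha = float(np.clip(common_alpha, _MIN_ALPHA, _MAX_ALPHA))

    rows = []
    for y, pois in zip(unit_counts, poisson_fits):
        y = y.astype(float)
        if y.sum() == 0:
            rows.append((0.0, 1.0, True))
            continue
        try:
            family = sm.families.NegativeBinomial(alpha=common_alpha)
            full = _fit_glm(y, X_full, offsets, family)
            null = _fit_glm(y, X_null, offsets, family)
            if not (np.isfinite(full.llf) and np.isfinite(null.llf)):
                raise ValueError("non-finite likelihood")
        except Exception:
            warnings.warn("NB fit failed for a unit; falling back to Poisson")
            family = sm.families.Poisson()
            full = _fit_glm(y, X_full, offsets, family)
            null = _fit_glm(y, X_null, offsets, family)
        lrt = max(2.0 * (full.llf - null.llf), 0.0)
        p = float(stats.chi2.sf(lrt, df=1))
        logfc = float(full.params[cond_col] / ln2)
        rows.append((logfc, p, False))

    return pd.DataFrame(rows, columns=["logFC", "p_value", "not_assessed"])


def spatial_fdr(
    p_values: np.ndarray,
    density_weight: np.ndarray | None = None,
    alpha: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Benjamini-Hochberg step-up over testing units.

    Sorting p ascending, the rejection threshold is the largest p_(i)
    with ``p_(i) <= alpha * cumsum(w)_(i) / sum(w)``; all units at or
    below it are significant.  With equal weights this reduces exactly
    to classical Benjamini-Hochberg.  Also returns weighted-BH adjusted
    values (min over j >= i of p_(j) * W / cumw_(j), clipped at 1) used
    for per-cell score construction.

    Returns ``(significant, adjusted)`` aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    if n == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if density_weight is None:
        w = np.ones(n)
    else:
        w = np.asarray(density_weight, dtype=float)
        if len(w) != n:
            raise ValueError("p_values and density_weight lengths differ")
        if np.any(w <= 0):
            raise ValueError("density weights must be positive")

    order = np.argsort(p, kind="stable")
    cumw = np.cumsum(w[order])
    total = cumw[-1]
    crit = alpha * cumw / total
    below = np.flatnonzero(p[order] <= crit)
    significant = np.zeros(n, dtype=bool)
    if below.size:
        significant[order[: below[-1] + 1]] = True

    ratio = p[order] * total / cumw
    adjusted_sorted = np.minimum(np.minimum.accumulate(ratio[::-1])[::-1], 1.0)
    adjusted = np.empty(n)
    adjusted[order] = adjusted_sorted
    return significant, adjusted
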
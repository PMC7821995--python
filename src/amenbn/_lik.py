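"""Grouped Gaussian / multinomial likelihood machinery.

Everything that touches a conditional linear Gaussian local model — the BIC
score, the conditional-Gaussian likelihood-ratio test and maximum-likelihood
fitting — funnels through :func:`grouped_gaussian_fit`, which fits one OLS
regression per discrete-parent configuration, dropping covariates to keep
the design estimable. Keeping a single code path guarantees the score, the
test and the fitted equations agree on every convention (MLE variance,
drop order, parameter counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LOG_2PI = math.log(2.0 * math.pi)

# Relative floor on the per-configuration MLE variance: keeps the Gaussian
# log-likelihood finite when a configuration is fitted exactly (duplicated
# variables, interpolating designs) without masking genuine near-determinism.
VAR_FLOOR_REL = 1e-9
VAR_FLOOR_ABS = 1e-30


@dataclass
class GroupFit:
    """OLS fit for one discrete-parent configuration."""

    n: int
    kept: tuple[int, ...]          # column indices of retained covariates
    dropped: tuple[int, ...]       # columns removed to reach an estimable fit
    beta: np.ndarray               # intercept followed by kept-column slopes
    se: np.ndarray                 # matching standard errors (nan if n too small)
    rss: float
    sigma2: float                  # MLE variance max(rss/n, floor)
    loglik: float
    n_params: int                  # kept + intercept + variance


def _fit_one_group(
    y: np.ndarray, X: np.ndarray | None, drop_order: tuple[int, ...], var_floor: float
) -> GroupFit:
    n_g = y.shape[0]
    p = 0 if X is None else X.shape[1]
    kept = list(range(p))
    order = [c for c in drop_order if c < p] + [c for c in range(p) if c not in drop_order]
    if n_g == 0:
        return GroupFit(0, (), tuple(range(p)), np.empty(0), np.empty(0), 0.0, 0.0, 0.0, 0)
    while True:
        if n_g < len(kept) + 2 and kept:
            kept.remove(next(c for c in order if c in kept))
            continue
        design = np.ones((n_g, len(kept) + 1))
        if kept:
            design[:, 1:] = X[:, kept]
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1] and kept:
            kept.remove(next(c for c in order if c in kept))
            continue
        break
    resid = y - design @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n_g, var_floor)
    loglik = -0.5 * n_g * (LOG_2PI + math.log(sigma2) + rss / (n_g * sigma2))
    k_mean = len(kept) + 1
    se = np.full(k_mean, np.nan)
    if n_g > k_mean:
        s2_unbiased = rss / (n_g - k_mean)
        xtx_inv = np.linalg.pinv(design.T @ design)
        se = np.sqrt(np.maximum(s2_unbiased * np.diag(xtx_inv), 0.0))
    dropped = tuple(c for c in range(p) if c not in kept)
    return GroupFit(
        n_g, tuple(kept), dropped, beta, se, rss, sigma2, loglik, len(kept) + 2
    )


def grouped_gaussian_fit(
    y: np.ndarray,
    X: np.ndarray | None,
    groups: np.ndarray | None,
    n_groups: int,
    drop_order: tuple[int, ...] = (),
) -> list[GroupFit]:
    """Fit an independent Gaussian regression per group.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) continuous covariates, or None for intercept-only models.
    groups : (n,) integer configuration codes in [0, n_groups), or None for
        a single group.
    drop_order : priority order (column indices) in which covariates are
        removed when a group's design is rank-deficient or has fewer than
        ``p + 2`` rows; columns not listed are dropped last, in index order.

    Returns one :class:`GroupFit` per configuration code, empty ones flagged
    with ``n == 0``.
    """
    y = np.asarray(y, dtype=float)
    var_floor = max(VAR_FLOOR_REL * float(np.var(y)) if y.size else 0.0, VAR_FLOOR_ABS)
    if groups is None:
        return [_fit_one_group(y, X, drop_order, var_floor)]
    fits = []
    for g in range(n_groups):
        mask = groups == g
        Xg = X[mask] if X is not None else None
        fits.append(_fit_one_group(y[mask], Xg, drop_order, var_floor))
    return fits


def gaussian_loglik_params(fits: list[GroupFit]) -> tuple[float, int]:
    """Total log-likelihood and free-parameter count over non-empty groups."""
    ll = sum(f.loglik for f in fits)
    k = sum(f.n_params for f in fits if f.n > 0)
    return ll, k


def combine_codes(code_arrays: list[np.ndarray], sizes: list[int], n_rows: int):
    """Mixed-radix combination of level-code arrays into one config code.

    Returns ``(codes, n_configs)``; with no arrays every row is config 0.
    """
    if not code_arrays:
        return np.zeros(n_rows, dtype=np.int64), 1
    codes = np.zeros(n_rows, dtype=np.int64)
    total = 1
    for arr, size in zip(code_arrays, sizes):
        codes = codes * size + arr
        total *= size
    return codes, total


def multinomial_loglik(
    codes: np.ndarray, n_levels: int, groups: np.ndarray, n_groups: int
) -> tuple[float, int]:
    """Per-configuration multinomial MLE log-likelihood and parameter count.

    The parameter count is ``(n_levels - 1)`` per *declared* configuration,
    empty configurations included (the multinomial CPT is a full table).
    """
    counts = np.bincount(groups * n_levels + codes, minlength=n_groups * n_levels)
    counts = counts.reshape(n_groups, n_levels).astype(float)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * (np.log(counts) - np.log(row_tot))
    ll = float(np.nansum(np.where(counts > 0, terms, 0.0)))
    return ll, (n_levels - 1) * n_groups
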
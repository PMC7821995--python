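"""Conditional-independence tests for the constraint phase.

Three tests cover the mixed discrete/continuous setting:

* :func:`g2_test` — the G² (likelihood-ratio / 2·n·MI) test on stratified
  contingency tables, for all-discrete triples;
* :func:`fisher_z_test` — Fisher's z transform of the partial correlation,
  for all-continuous triples;
* :func:`cg_lrt_test` — a likelihood-ratio between nested conditional
  linear Gaussian local models, for anything mixed.

All three return a :class:`TestResult`. Constant (degenerate) variables are
reported as independent (statistic 0, p = 1) so the surrounding learning
loops stay total; the significance level used by the constraint phase
defaults to ``ALPHA_DEFAULT = 0.05``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from ._lik import combine_codes, gaussian_loglik_params, grouped_gaussian_fit
from .exceptions import DegenerateError, InsufficientDataError, NotDiscreteError
from .variables import DataTable

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of one conditional-independence test."""

    statistic: float
    df: int
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if self.statistic < 0:
            raise ValueError("statistic must be >= 0")


def _as_tuple(cond: Iterable[str] | None) -> tuple[str, ...]:
    return tuple(cond) if cond is not None else ()


# ---------------------------------------------------------------------------
# G² on stratified contingency tables
# ---------------------------------------------------------------------------

def g2_test(data: DataTable, x: str, y: str, cond: Iterable[str] = ()) -> TestResult:
    """G² = 2·n·MI test of X ⟂ Y | cond for discrete variables.

    The statistic is ``2 Σ o·ln(o/e)`` over the contingency cells of every
    conditioning stratum, with expected counts from the within-stratum
    margins. Zero cells contribute 0. Degrees of freedom use the *declared*
    level counts: ``(|X|−1)(|Y|−1)·Π|Z|``, not adjusted for empty strata.
    """
    cond = _as_tuple(cond)
    for name in (x, y, *cond):
        if not data.specs[name].is_discrete:
            raise NotDiscreteError(f"{name!r} is not discrete")
    if data.n < 1:
        raise InsufficientDataError("empty dataset")
    lx, ly = data.specs[x].n_levels, data.specs[y].n_levels
    df = max(1, (lx - 1) * (ly - 1) * int(np.prod([data.specs[z].n_levels for z in cond], dtype=np.int64)))
    cx, cy = data.codes(x), data.codes(y)
    if len(np.unique(cx)) < 2 or len(np.unique(cy)) < 2:
        # constant variable: zero mutual information by convention
        return TestResult(0.0, df, 1.0, "g2")
    strata, n_strata = combine_codes(
        [data.codes(z) for z in cond], [data.specs[z].n_levels for z in cond], data.n
    )
    counts = np.bincount(
        (strata * lx + cx) * ly + cy, minlength=n_strata * lx * ly
    ).reshape(n_strata, lx, ly).astype(float)
    row = counts.sum(axis=2, keepdims=True)
    col = counts.sum(axis=1, keepdims=True)
    tot = counts.sum(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row * col / tot
        terms = counts * np.log(counts / expected)
    stat = 2.0 * float(np.nansum(np.where(counts > 0, terms, 0.0)))
    stat = max(stat, 0.0)
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)), "g2")


# ---------------------------------------------------------------------------
# Fisher's z on partial correlations
# ---------------------------------------------------------------------------

def _residualize(v: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    if Z is None:
        return v - v.mean()
    design = np.column_stack([np.ones(len(v)), Z])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def fisher_z_test(data: DataTable, x: str, y: str, cond: Iterable[str] = ()) -> TestResult:
    """Fisher's z test of the partial correlation of X, Y given cond.

    The partial correlation is computed by correlating the residuals of X
    and Y after linear projection on the conditioning set;
    ``z = atanh(r)·sqrt(n − |cond| − 3)`` is referred to a standard normal.
    """
    cond = _as_tuple(cond)
    for name in (x, y, *cond):
        if not data.specs[name].is_continuous:
            raise NotDiscreteError(f"{name!r} is not continuous")
    n = data.n
    if n <= len(cond) + 3:
        raise InsufficientDataError(f"need n > |cond| + 3, got n={n}")
    Z = np.column_stack([data.column(z) for z in cond]) if cond else None
    rx = _residualize(data.column(x).astype(float), Z)
    ry = _residualize(data.column(y).astype(float), Z)
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    scale = max(float(np.var(data.column(x))) + float(np.var(data.column(y))), 1.0)
    tiny = 1e-14 * scale * n
    if sx <= tiny or sy <= tiny:
        if np.allclose(data.column(x), data.column(y)):
            return TestResult(float("inf"), 1, 0.0, "fisher_z")
        raise DegenerateError(f"residual variance ~ 0 for {x!r} or {y!r}")
    r = float(rx @ ry) / math.sqrt(sx * sy)
    r = min(max(r, -1.0), 1.0)
    dof = n - len(cond) - 3
    if abs(r) >= 1.0 - 1e-15:
        return TestResult(float("inf"), 1, 0.0, "fisher_z")
    z = abs(math.atanh(r)) * math.sqrt(dof)
    return TestResult(z, 1, float(2.0 * stats.norm.sf(z)), "fisher_z")


# ---------------------------------------------------------------------------
# Conditional-Gaussian likelihood ratio
# ---------------------------------------------------------------------------

def _cg_loglik(
    data: DataTable,
    response: str,
    cont_regressors: tuple[str, ...],
    disc_strata: tuple[str, ...],
) -> tuple[float, int]:
    y = data.column(response).astype(float)
    X = (
        np.column_stack([data.column(c) for c in cont_regressors])
        if cont_regressors
        else None
    )
    groups, n_groups = combine_codes(
        [data.codes(d) for d in disc_strata],
        [data.specs[d].n_levels for d in disc_strata],
        data.n,
    )
    p = len(cont_regressors)
    fits = grouped_gaussian_fit(y, X, groups, n_groups, tuple(range(p - 1, -1, -1)))
    return gaussian_loglik_params(fits)


def cg_lrt_test(data: DataTable, x: str, y: str, cond: Iterable[str] = ()) -> TestResult:
    """Likelihood-ratio test between nested CLG local models.

    The continuous member of (x, y) is taken as the response (x wins when
    both are continuous); the other variable enters the *full* model as an
    extra regressor if continuous or as extra stratification if discrete,
    and is absent from the reduced model. Conditioning variables split
    likewise into regressors and strata. ``2·(ℓ_full − ℓ_reduced)`` is
    referred to a chi-square on the free-parameter difference.

    When x, y and the whole conditioning set are continuous the call
    delegates to :func:`fisher_z_test`.
    """
    cond = _as_tuple(cond)
    spec = data.specs
    if spec[x].is_discrete and spec[y].is_discrete:
        # In a CLG-legal DAG every continuous node on a path between two
        # discrete nodes is a collider (continuous→discrete is illegal), so
        # conditioning on continuous variables can only open paths: the
        # discrete part of the conditioning set is the right one to use.
        return g2_test(data, x, y, tuple(z for z in cond if spec[z].is_discrete))
    if spec[x].is_continuous and spec[y].is_continuous:
        if all(spec[z].is_continuous for z in cond):
            return fisher_z_test(data, x, y, cond)
        response, other = x, y
    elif spec[x].is_continuous:
        response, other = x, y
    elif spec[y].is_continuous:
        response, other = y, x
    else:
        raise NotDiscreteError(
            "cg_lrt_test needs at least one continuous variable among x, y"
        )
    if data.n < 1:
        raise InsufficientDataError("empty dataset")
    if spec[other].is_discrete and spec[other].n_levels < 2:
        return TestResult(0.0, 1, 1.0, "cg_lrt")
    cond_cont = tuple(z for z in cond if spec[z].is_continuous)
    cond_disc = tuple(z for z in cond if spec[z].is_discrete)
    if spec[other].is_continuous:
        full_cont, full_disc = cond_cont + (other,), cond_disc
    else:
        full_cont, full_disc = cond_cont, cond_disc + (other,)
    ll_full, k_full = _cg_loglik(data, response, full_cont, full_disc)
    ll_red, k_red = _cg_loglik(data, response, cond_cont, cond_disc)
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    df = max(1, k_full - k_red)
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)), "cg_lrt")


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def ci_test(data: DataTable, x: str, y: str, cond: Iterable[str] = ()) -> TestResult:
    """Route to the appropriate test for the variable kinds involved."""
    cond = _as_tuple(cond)
    kinds = {data.specs[v].kind for v in (x, y, *cond)}
    if kinds == {"discrete"}:
        return g2_test(data, x, y, cond)
    if kinds == {"continuous"}:
        return fisher_z_test(data, x, y, cond)
    return cg_lrt_test(data, x, y, cond)
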
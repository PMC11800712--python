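"""Additive-hazards estimators: naive, two-stage, and control-function IV.

All three are solved by one semiparametric least-squares engine for the
model ``dN_i(t) = Y_i(t) [U_i' dB(t) + V_i' theta dt] + dM_i(t)`` with
nonparametric (time-varying) effects ``B`` for the columns of ``U`` and
constant effects ``theta`` for the columns of ``V``:

* constant-effects fit: ``U = [1]`` (baseline only), which reduces the
  engine to the classical least-squares martingale estimating equation with
  at-risk covariate centring;
* control-function (2SRI) fit: ``U = [1, residual, Z*residual]`` so the
  baseline and the first-stage-residual effects are unrestricted in time,
  while treatment and the measured confounder keep constant effects.

At each event time the time-varying block is profiled out by least squares
on the risk set; the remaining score identifies ``theta``.  All integrals
are exact under the counting-process convention (risk-set aggregates are
piecewise constant between exits), assembled with suffix cumulative sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .dgm import Cohort
from .first_stage import FirstStageFit

__all__ = [
    "AdditiveFit",
    "AdditiveFitError",
    "ExtrapolationError",
    "SurvivalPrediction",
    "fit_additive_constant",
    "fit_additive_two_stage",
    "fit_additive_2sri",
    "predict_survival_additive",
]


class AdditiveFitError(RuntimeError):
    pass


class ExtrapolationError(ValueError):
    pass


class SurvivalPrediction(NamedTuple):
    value: float
    n_invalid: int


@dataclass
class AdditiveFit:
    """Semiparametric additive-hazards fit.

    ``theta`` are the constant (per-year hazard-difference) effects for the
    columns of ``const_design``; ``cum_tv`` the cumulative time-varying
    coefficient paths for the columns of ``tv_design`` evaluated at the
    distinct exit times ``grid`` (first component is the cumulative
    baseline).  ``drift`` holds the between-event slopes so the paths can be
    evaluated exactly at any in-range time.
    """

    theta: np.ndarray
    cov: np.ndarray
    const_names: tuple[str, ...]
    tv_names: tuple[str, ...]
    grid: np.ndarray
    cum_tv: np.ndarray
    drift: np.ndarray
    n: int
    n_events: int
    t_max: float
    neg_increment_count: int
    const_design: np.ndarray
    tv_design: np.ndarray
    x_column: Optional[int] = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def cumulative_tv(self, t: float) -> np.ndarray:
        """Cumulative time-varying coefficient paths evaluated at ``t``."""
        if t > self.t_max + 1e-12:
            raise ExtrapolationError(
                f"t={t} beyond the observed range (max {self.t_max})"
            )
        if t <= 0:
            return np.zeros(self.cum_tv.shape[1])
        idx = np.searchsorted(self.grid, t, side="right") - 1
        if idx < 0:
            return t * self.drift[0]
        base = self.cum_tv[idx]
        if idx + 1 < len(self.grid):
            return base + (t - self.grid[idx]) * self.drift[idx + 1]
        return base

    def report(self) -> dict:
        return {
            "model": "additive",
            "n": self.n,
            "n_events": self.n_events,
            "coefficients": {
                name: {"estimate": float(th), "se": float(se)}
                for name, th, se in zip(self.const_names, self.theta, self.se)
            },
            "time_varying": list(self.tv_names),
            "negative_increment_count": self.neg_increment_count,
        }


def _suffix_sums(blocks: np.ndarray, first: np.ndarray) -> np.ndarray:
    """Sum of per-subject blocks over the suffix starting at each index."""
    csum = np.concatenate([np.zeros((1,) + blocks.shape[1:]), np.cumsum(blocks, axis=0)])
    return csum[-1] - csum[first]


def _fit_semiparametric(
    times: np.ndarray,
    events: np.ndarray,
    const_design: np.ndarray,
    tv_design: np.ndarray,
    const_names: Sequence[str],
    tv_names: Sequence[str],
) -> AdditiveFit:
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    V = np.atleast_2d(np.asarray(const_design, float))
    U = np.atleast_2d(np.asarray(tv_design, float))
    if V.shape[0] != len(times):
        V = V.T
    if U.shape[0] != len(times):
        U = U.T
    n, p = V.shape
    q = U.shape[1]
    if events.sum() < 1:
        raise AdditiveFitError("no events in the data")

    order = np.argsort(times, kind="stable")
    t_s, d_s, V_s, U_s = times[order], events[order], V[order], U[order]
    grid, first = np.unique(t_s, return_index=True)
    m = len(grid)
    seg = np.searchsorted(grid, t_s)  # distinct-time index per subject

    # risk-set aggregates at each distinct time (suffix over subjects with
    # exit time >= that time)
    Svv = _suffix_sums(np.einsum("ni,nj->nij", V_s, V_s), first)
    Svu = _suffix_sums(np.einsum("ni,nj->nij", V_s, U_s), first)
    Suu = _suffix_sums(np.einsum("ni,nj->nij", U_s, U_s), first)

    try:
        Suu_inv = np.linalg.inv(Suu)
    except np.linalg.LinAlgError:
        for l in range(m):
            if np.linalg.matrix_rank(Suu[l]) < q:
                raise AdditiveFitError(
                    f"time-varying design singular on the risk set at time {grid[l]:.6g}"
                ) from None
        raise

    proj = np.einsum("lij,ljk->lik", Svu, Suu_inv)  # (m, p, q)
    M = Svv - np.einsum("lij,lkj->lik", proj, Svu)  # V'(I-P)V per risk set
    dt = np.diff(np.concatenate([[0.0], grid]))
    A = np.einsum("l,lij->ij", dt, M)

    # event contributions
    ev = d_s == 1
    seg_ev = seg[ev]
    resid_ev = V_s[ev] - np.einsum("lij,lj->li", proj[seg_ev], U_s[ev])
    b = resid_ev.sum(axis=0)

    if p == 0:
        theta = np.zeros(0)
        cov = np.zeros((0, 0))
    else:
        try:
            theta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            cols = ", ".join(const_names)
            raise AdditiveFitError(
                f"estimating-equation matrix is rank deficient (columns: {cols})"
            ) from exc
        meat = np.einsum("li,lj->ij", resid_ev, resid_ev)
        A_inv = np.linalg.inv(A)
        cov = A_inv @ meat @ A_inv.T
        cov = 0.5 * (cov + cov.T)

    # cumulative time-varying paths: jumps at event times, drift in between
    bU = np.zeros((m, q))
    np.add.at(bU, seg_ev, U_s[ev])
    jumps = np.einsum("lij,lj->li", Suu_inv, bU)
    drift = np.einsum("lij,ljk,k->li", Suu_inv, np.transpose(Svu, (0, 2, 1)), theta)
    incr = jumps - dt[:, None] * drift
    cum_tv = np.cumsum(incr, axis=0)
    neg_count = int(np.sum(incr[:, 0] < 0))

    return AdditiveFit(
        theta=theta,
        cov=cov,
        const_names=tuple(const_names),
        tv_names=tuple(tv_names),
        grid=grid,
        cum_tv=cum_tv,
        drift=drift,
        n=n,
        n_events=int(events.sum()),
        t_max=float(times.max()),
        neg_increment_count=neg_count,
        const_design=V,
        tv_design=U,
    )


def fit_additive_constant(
    times,
    events,
    covariates,
    names: Sequence[str] | None = None,
    x_column: Optional[int] = 0,
) -> AdditiveFit:
    """Constant-effects additive-hazards fit (nonparametric baseline).

    Solves the least-squares martingale estimating equation
    ``sum_i int (W_i - Wbar(t)) [dN_i(t) - W_i' theta Y_i(t) dt] = 0`` and
    accumulates the baseline cumulative hazard from the residual increments;
    sandwich covariance.
    """
    W = np.atleast_2d(np.asarray(covariates, float))
    if W.shape[0] != len(np.asarray(times)):
        W = W.T
    if names is None:
        names = tuple(f"w{j}" for j in range(W.shape[1]))
    fit = _fit_semiparametric(
        times, events, W, np.ones((W.shape[0], 1)), names, ("baseline",)
    )
    fit.x_column = x_column
    return fit


def fit_additive_two_stage(cohort: Cohort, first_stage: FirstStageFit) -> AdditiveFit:
    """Two-stage additive IV fit: outcome regressed on (Xhat, CM).

    Caveat attached to the estimand: with a binary treatment this two-stage
    construction is biased for the causal hazard difference.
    """
    if not first_stage.converged:
        raise AdditiveFitError("first-stage fit did not converge")
    xhat = first_stage.fitted
    if np.ptp(xhat) < 1e-12:
        raise AdditiveFitError(
            "first-stage predictions are constant; treatment effect unidentified"
        )
    return fit_additive_constant(
        cohort.time,
        cohort.event,
        np.column_stack([xhat, cohort.cm]),
        names=("xhat", "cm"),
        x_column=0,
    )


def fit_additive_2sri(cohort: Cohort, first_stage: FirstStageFit) -> AdditiveFit:
    """Control-function (2SRI) additive IV fit.

    Constant effects for (X, CM); unrestricted time-varying effects for the
    baseline, the first-stage residual, and its interaction with Z.  The
    residual paths are returned as raw cumulative increments.
    """
    if not first_stage.converged:
        raise AdditiveFitError("first-stage fit did not converge")
    resid = first_stage.residuals
    U = np.column_stack([np.ones(len(cohort)), resid, cohort.z * resid])
    V = np.column_stack([cohort.x, cohort.cm])
    fit = _fit_semiparametric(
        cohort.time,
        cohort.event,
        V,
        U,
        ("x", "cm"),
        ("baseline", "residual", "z_residual"),
    )
    fit.x_column = 0
    return fit


def predict_survival_additive(
    fit: AdditiveFit, x_set: int, t: float
) -> SurvivalPrediction:
    """Standardized survival at ``t`` with every subject's treatment set.

    Each subject keeps their own measured covariates (and, for the
    control-function fit, their fitted residual and instrument terms); the
    treatment column is set to ``x_set``; per-subject survival
    ``exp(-U_i'B(t) - t * V_i'theta)`` is averaged.  Values outside [0, 1]
    are counted, not clipped.
    """
    if fit.x_column is None and fit.const_design.shape[1] > 0:
        raise AdditiveFitError("fit does not identify a treatment column")
    B_t = fit.cumulative_tv(t)
    V = fit.const_design.copy()
    if fit.x_column is not None:
        V[:, fit.x_column] = x_set
    cumhaz = fit.tv_design @ B_t + t * (V @ fit.theta)
    surv = np.exp(-cumhaz)
    n_invalid = int(np.sum((surv < 0) | (surv > 1)))
    return SurvivalPrediction(float(surv.mean()), n_invalid)
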
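"""First-stage logistic treatment model shared by all IV estimators.

The data-generating treatment model is probit; every IV analysis method
deliberately fits a logistic first stage, so the fitted model is mildly
mis-specified by construction.  Fitting is plain iteratively reweighted
least squares; non-convergence is an error, never a warning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dgm import Cohort

__all__ = ["FirstStageFit", "FirstStageError", "fit_treatment_model", "iv_strength_summary"]

_IRLS_TOL = 1e-8
_IRLS_MAX_ITER = 50


class FirstStageError(RuntimeError):
    pass


@dataclass
class FirstStageFit:
    """Logistic fit of X on (Z, CM) with intercept."""

    eta: np.ndarray  # (eta_0, eta_z, eta_cm)
    fitted: np.ndarray  # P(X=1 | Z, CM) per subject
    residuals: np.ndarray  # X - fitted
    converged: bool
    n_iter: int


def fit_treatment_model(cohort: Cohort, include_cm: bool = True) -> FirstStageFit:
    """Maximum-likelihood logistic regression of X on (Z, CM), by IRLS.

    ``include_cm=False`` drops the measured confounder (saturated-in-Z fit,
    useful for hand-countable checks).
    """
    x = np.asarray(cohort.x, float)
    if x.min() == x.max():
        raise FirstStageError("treatment X is constant; both groups must be non-empty")
    if cohort.z.min() == cohort.z.max():
        raise FirstStageError("instrument Z is constant; first stage unidentifiable")

    cols = [np.ones(len(cohort)), cohort.z]
    if include_cm:
        cols.append(cohort.cm)
    design = np.column_stack(cols)
    eta = np.zeros(design.shape[1])
    for it in range(1, _IRLS_MAX_ITER + 1):
        lin = design @ eta
        if np.max(np.abs(lin)) > 30.0:
            raise FirstStageError(
                "fitted log-odds diverged (perfect separation suspected)"
            )
        p = 1.0 / (1.0 + np.exp(-lin))
        weight = p * (1.0 - p)
        score = design.T @ (x - p)
        info = design.T @ (design * weight[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise FirstStageError(f"singular information matrix: {exc}") from exc
        eta += step
        if np.max(np.abs(step)) < _IRLS_TOL:
            fitted = 1.0 / (1.0 + np.exp(-(design @ eta)))
            return FirstStageFit(
                eta=eta, fitted=fitted, residuals=x - fitted, converged=True, n_iter=it
            )
    raise FirstStageError(f"IRLS did not converge in {_IRLS_MAX_ITER} iterations")


def iv_strength_summary(cohort: Cohort) -> tuple[float, float, float]:
    """Treatment probability by instrument group and their difference.

    Returns ``(p1, p0, diff)`` with ``p1 = mean(X | Z=1)``.  This is the
    canonical instrument-strength diagnostic here; an F-statistic gate is
    deliberately not provided because it scales with sample size.
    """
    z = np.asarray(cohort.z)
    in1 = z == 1
    if not in1.any() or in1.all():
        raise FirstStageError("both instrument groups must be non-empty")
    p1 = float(cohort.x[in1].mean())
    p0 = float(cohort.x[~in1].mean())
    return p1, p0, p1 - p0
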
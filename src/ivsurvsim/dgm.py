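"""Cohort simulation: covariates, probit treatment assignment, event times.

Event times come from inverting the cumulative hazard.  Multiplicative
scenarios invert in closed form for any baseline shape.  Additive scenarios
are closed-form for the exponential baseline and use a safeguarded,
vectorised bracketed root solve on ``scale * t**gamma + w * t = -log(u)``
for Weibull baselines, always targeting the increasing branch of the
cumulative hazard.  Draws whose cumulative hazard never reaches the required
level (a negative-hazard pathology of the additive model) raise
:class:`NegativeHazardError` with diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .scenario_config import CoefficientSet, ScenarioSpec

__all__ = [
    "Cohort",
    "NegativeHazardError",
    "simulate_covariates",
    "assign_treatment_probit",
    "simulate_event_time",
    "simulate_potential_times",
    "apply_administrative_censoring",
    "simulate_observational_cohort",
    "simulate_rct_cohort",
]


class NegativeHazardError(RuntimeError):
    """The additive hazard is not positive on the inversion path.

    Carries the number of offending draws and the worst linear-predictor
    value so the scenario can be re-calibrated.
    """

    def __init__(self, n_bad: int, worst_linpred: float):
        self.n_bad = int(n_bad)
        self.worst_linpred = float(worst_linpred)
        super().__init__(
            f"additive hazard non-positive on the solution path for {n_bad} "
            f"draw(s); worst linear predictor {worst_linpred:.6g}; "
            "the scenario needs re-calibration"
        )


@dataclass
class Cohort:
    """Per-subject simulation output, the unit every estimator consumes."""

    z: np.ndarray
    cm: np.ndarray
    cu: np.ndarray
    x: np.ndarray
    time: np.ndarray
    event: np.ndarray
    latent_time: Optional[np.ndarray] = None
    tau_max: float = 5.0
    negative_hazard_flags: int = 0

    def __post_init__(self) -> None:
        n = len(self.z)
        for name in ("cm", "cu", "x", "time", "event"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length differs from z")

    def __len__(self) -> int:
        return len(self.z)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self, include_latent: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "Z": self.z.astype(int),
                "CM": self.cm,
                "CU": self.cu,
                "X": self.x.astype(int),
                "T": self.time,
                "event": self.event.astype(int),
            }
        )
        if include_latent and self.latent_time is not None:
            df["latent_T"] = self.latent_time
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tau_max: float = 5.0) -> "Cohort":
        return cls(
            z=df["Z"].to_numpy(float),
            cm=df["CM"].to_numpy(float),
            cu=df["CU"].to_numpy(float),
            x=df["X"].to_numpy(float),
            time=df["T"].to_numpy(float),
            event=df["event"].to_numpy(int),
            latent_time=df["latent_T"].to_numpy(float) if "latent_T" in df else None,
            tau_max=tau_max,
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_covariates(n: int, seed) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Instrument Z ~ Bernoulli(0.5); CM, CU independent standard normal."""
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    rng = _as_rng(seed)
    z = (rng.random(n) < 0.5).astype(float)
    cm = rng.standard_normal(n)
    cu = rng.standard_normal(n)
    return z, cm, cu


def assign_treatment_probit(z, cm, cu, alpha, rng) -> np.ndarray:
    """Binary treatment from the probit model on (Z, CM, CU)."""
    a0, az, acm, acu = alpha
    p = ndtr(a0 + az * np.asarray(z) + acm * np.asarray(cm) + acu * np.asarray(cu))
    return (_as_rng(rng).random(len(p)) < p).astype(float)


def _invert_additive_cumhaz(
    w: np.ndarray, scale: float, gamma: float, target: np.ndarray
) -> np.ndarray:
    """Solve ``scale * t**gamma + w * t = target`` on the increasing branch.

    The cumulative hazard is strictly increasing whenever the instantaneous
    hazard ``scale*gamma*t**(gamma-1) + w`` is positive; for negative ``w``
    the solve is restricted to the branch where it is.  Unsolvable draws
    raise :class:`NegativeHazardError`.
    """
    w = np.asarray(w, float)
    target = np.asarray(target, float)
    if gamma == 1.0:
        rate = scale + w
        bad = rate <= 0
        if bad.any():
            raise NegativeHazardError(bad.sum(), w[bad].min())
        return target / rate

    lo = np.zeros_like(target)
    hi = np.full_like(target, 1.0)

    def cumhaz(t):
        return scale * t**gamma + w * t

    neg = w < 0
    growable = np.ones_like(target, dtype=bool)
    if neg.any():
        # stationary point of the cumulative hazard
        t_star = (-w[neg] / (scale * gamma)) ** (1.0 / (gamma - 1.0))
        if gamma > 1.0:
            # increasing branch starts at the minimum
            lo[neg] = t_star
            hi[neg] = np.maximum(hi[neg], 2.0 * t_star)
        else:
            # increasing branch ends at the maximum: if the peak cumulative
            # hazard stays below the target the distribution is defective
            # there and the event never occurs in finite time
            peak = scale * t_star**gamma + w[neg] * t_star
            defective = np.zeros_like(target, dtype=bool)
            defective[neg] = peak < target[neg]
            hi[neg] = t_star
            growable[neg] = False
            if defective.any():
                out = np.where(defective, np.inf, 0.0)
                solvable = ~defective
                if solvable.any():
                    out[solvable] = _invert_additive_cumhaz(
                        w[solvable], scale, gamma, target[solvable]
                    )
                return out

    # grow the remaining upper brackets geometrically
    for _ in range(400):
        short = growable & (cumhaz(hi) < target)
        if not short.any():
            break
        hi[short] *= 2.0
    else:  # pragma: no cover - cannot happen for solvable draws
        raise NegativeHazardError(int(short.sum()), w[short].min())

    # bisection to ~1e-12 relative accuracy, then a Newton polish
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        below = cumhaz(mid) < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    t = 0.5 * (lo + hi)
    deriv = scale * gamma * np.where(t > 0, t, 1e-300) ** (gamma - 1.0) + w
    safe = deriv > 0
    step = np.where(safe, (cumhaz(t) - target) / np.where(safe, deriv, 1.0), 0.0)
    t_new = t - step
    ok = (t_new >= lo) & (t_new <= hi)
    return np.where(ok, t_new, t)


def simulate_event_time(linpred, scale: float, gamma: float, form: str, u):
    """Invert the survival function at uniform draw(s) ``u``.

    Multiplicative: ``t = (-log(u) / (scale * exp(w)))**(1/gamma)``.
    Additive: solves ``scale * t**gamma + w * t = -log(u)``.
    Accepts scalars or arrays; returns times on the unrescaled clock.
    """
    w = np.asarray(linpred, float)
    u_arr = np.asarray(u, float)
    scalar = w.ndim == 0 and u_arr.ndim == 0
    w, u_arr = np.atleast_1d(w), np.atleast_1d(u_arr)
    if np.any((u_arr <= 0) | (u_arr >= 1)):
        raise ValueError("u must lie strictly inside (0, 1)")
    w, u_arr = np.broadcast_arrays(w, u_arr)
    target = -np.log(u_arr)
    if form == "multiplicative":
        t = (target / (scale * np.exp(w))) ** (1.0 / gamma)
    elif form == "additive":
        t = _invert_additive_cumhaz(w, scale, gamma, target)
    else:
        raise ValueError(f"unknown DGM form {form!r}")
    return float(t[0]) if scalar else t


def apply_administrative_censoring(
    latent_time: np.ndarray, tau_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Censor at ``tau_max``; an event at exactly ``tau_max`` stays an event."""
    latent_time = np.asarray(latent_time, float)
    time = np.minimum(latent_time, tau_max)
    event = (latent_time <= tau_max).astype(int)
    return time, event


def _linpred(coeffs: CoefficientSet, x, cm, cu) -> np.ndarray:
    return (
        coeffs.beta_0
        + coeffs.beta_x * np.asarray(x)
        + coeffs.beta_cm * np.asarray(cm)
        + coeffs.beta_cu * np.asarray(cu)
    )


def _draw_uniforms(rng: np.random.Generator, n: int) -> np.ndarray:
    u = rng.random(n)
    # keep draws strictly inside (0, 1)
    return np.clip(u, 1e-300, 1.0 - 1e-16)


def _latent_times(
    spec: ScenarioSpec, coeffs: CoefficientSet, w: np.ndarray, u: np.ndarray
) -> np.ndarray:
    t = simulate_event_time(w, coeffs.scale, coeffs.gamma, spec.dgm_form, u)
    if spec.dgm_form == "additive":
        t = t * coeffs.time_rescale
    return np.atleast_1d(t)


def simulate_observational_cohort(
    spec: ScenarioSpec, coeffs: CoefficientSet, n: int, seed
) -> Cohort:
    """Confounded cohort: covariates, probit treatment, event times, censoring."""
    rng = _as_rng(seed)
    z, cm, cu = simulate_covariates(n, rng)
    x = assign_treatment_probit(z, cm, cu, coeffs.alpha, rng)
    w = _linpred(coeffs, x, cm, cu)
    latent = _latent_times(spec, coeffs, w, _draw_uniforms(rng, n))
    time, event = apply_administrative_censoring(latent, spec.tau_max)
    flags = int(np.sum(w < 0)) if spec.dgm_form == "additive" else 0
    return Cohort(
        z, cm, cu, x, time, event,
        latent_time=latent, tau_max=spec.tau_max, negative_hazard_flags=flags,
    )


def simulate_rct_cohort(
    spec: ScenarioSpec,
    coeffs: CoefficientSet,
    n: int,
    seed,
    p_treat: float = 0.5,
    censor: bool = False,
) -> Cohort:
    """Ideal randomized cohort: treatment independent of all covariates.

    Full compliance; no censoring unless ``censor`` is requested.
    """
    if not 0.0 < p_treat < 1.0:
        raise ValueError(f"p_treat must be in (0, 1), got {p_treat}")
    rng = _as_rng(seed)
    z, cm, cu = simulate_covariates(n, rng)
    x = (rng.random(n) < p_treat).astype(float)
    w = _linpred(coeffs, x, cm, cu)
    latent = _latent_times(spec, coeffs, w, _draw_uniforms(rng, n))
    if censor:
        time, event = apply_administrative_censoring(latent, spec.tau_max)
    else:
        time, event = latent.copy(), np.ones(n, dtype=int)
    return Cohort(z, cm, cu, x, time, event, latent_time=latent, tau_max=spec.tau_max)


def simulate_potential_times(
    spec: ScenarioSpec,
    coeffs: CoefficientSet,
    cm: np.ndarray,
    cu: np.ndarray,
    u: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Counterfactual pair (T0, T1) per subject from a shared uniform draw.

    With a negative treatment coefficient the shared draw makes T1 > T0
    subject-wise (rank preservation inside the simulator).
    """
    w0 = _linpred(coeffs, np.zeros_like(cm), cm, cu)
    w1 = _linpred(coeffs, np.ones_like(cm), cm, cu)
    t0 = _latent_times(spec, coeffs, w0, u)
    t1 = _latent_times(spec, coeffs, w1, u)
    return t0, t1
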
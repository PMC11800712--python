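"""Monte-Carlo evaluation of the true causal estimands per scenario.

Each scenario's true contrasts are read off a huge simulated ideal RCT
(full compliance, no censoring): per follow-up year the cohort is censored
at the year end, an unadjusted Cox fit gives the marginal hazard ratio, an
unadjusted additive fit the marginal hazard difference, and the per-arm
empirical survivor functions the true survival probabilities (with only
administrative censoring at the year end these coincide with Kaplan-Meier).
Conditional contrasts add the measured confounder to the fitted models.

The treated-subgroup contrast needs one extra construction: treatment is
assigned observationally (probit), and for the treated subjects both
potential event times are generated from a shared uniform draw; an
unadjusted Cox fit on the stacked counterfactual data gives the hazard
ratio of treatment in the treated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dgm
from .additive_hazards import fit_additive_constant
from .cox_models import fit_cox
from .scenario_config import CoefficientSet, ScenarioSpec

__all__ = [
    "TruthEstimands",
    "true_marginal_contrasts",
    "true_conditional_contrasts",
    "true_ett",
    "compute_truth",
]

DEFAULT_N_MC = 2_000_000
DEFAULT_YEARS = (1, 2, 3, 4, 5)


@dataclass
class TruthEstimands:
    """Per-year true causal contrasts and survival, with MC standard errors."""

    years: tuple[int, ...]
    n_mc: int
    hr_marginal: Optional[np.ndarray] = None
    hr_marginal_se: Optional[np.ndarray] = None
    hd_marginal: Optional[np.ndarray] = None
    hd_marginal_se: Optional[np.ndarray] = None
    surv_treated: Optional[np.ndarray] = None
    surv_treated_se: Optional[np.ndarray] = None
    surv_untreated: Optional[np.ndarray] = None
    surv_untreated_se: Optional[np.ndarray] = None
    hr_conditional: Optional[np.ndarray] = None
    hr_conditional_se: Optional[np.ndarray] = None
    hd_conditional: Optional[np.ndarray] = None
    hd_conditional_se: Optional[np.ndarray] = None
    hr_ett: Optional[np.ndarray] = None
    hr_ett_se: Optional[np.ndarray] = None

    def at_year(self, year: int) -> dict:
        i = self.years.index(year)
        out = {"year": year, "n_mc": self.n_mc}
        for name in (
            "hr_marginal",
            "hd_marginal",
            "surv_treated",
            "surv_untreated",
            "hr_conditional",
            "hd_conditional",
            "hr_ett",
        ):
            arr = getattr(self, name)
            se = getattr(self, name + "_se")
            out[name] = None if arr is None else float(arr[i])
            out[name + "_se"] = None if se is None else float(se[i])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.at_year(y) for y in self.years])


def _check_n_mc(n_mc: int) -> None:
    if n_mc < 10_000:
        raise ValueError(f"n_mc must be at least 10,000, got {n_mc}")
    if n_mc < 1_000_000:
        import warnings

        warnings.warn(
            f"n_mc={n_mc} below 1e6; truth values carry wider MC error",
            stacklevel=3,
        )


def _censor(latent: np.ndarray, year: float) -> tuple[np.ndarray, np.ndarray]:
    return np.minimum(latent, year), (latent <= year).astype(int)


def _marginal_parts(
    rct: dgm.Cohort, years: Sequence[int]
) -> dict[str, np.ndarray]:
    out = {k: [] for k in ("hr", "hr_se", "hd", "hd_se", "s1", "s1_se", "s0", "s0_se")}
    latent = rct.latent_time
    x = rct.x
    treated = x == 1
    n1, n0 = int(treated.sum()), int((~treated).sum())
    for y in years:
        t, d = _censor(latent, float(y))
        cfit = fit_cox(t, d, x[:, None], names=("x",), keep_design=False)
        afit = fit_additive_constant(t, d, x[:, None], names=("x",))
        hr = float(np.exp(cfit.theta[0]))
        out["hr"].append(hr)
        out["hr_se"].append(hr * float(cfit.se[0]))
        out["hd"].append(float(afit.theta[0]))
        out["hd_se"].append(float(afit.se[0]))
        s1 = float(np.mean(latent[treated] > y))
        s0 = float(np.mean(latent[~treated] > y))
        out["s1"].append(s1)
        out["s1_se"].append(float(np.sqrt(s1 * (1 - s1) / n1)))
        out["s0"].append(s0)
        out["s0_se"].append(float(np.sqrt(s0 * (1 - s0) / n0)))
    return {k: np.asarray(v) for k, v in out.items()}


def _conditional_parts(rct: dgm.Cohort, years: Sequence[int]) -> dict[str, np.ndarray]:
    out = {k: [] for k in ("hr", "hr_se", "hd", "hd_se")}
    latent = rct.latent_time
    W = np.column_stack([rct.x, rct.cm])
    for y in years:
        t, d = _censor(latent, float(y))
        cfit = fit_cox(t, d, W, names=("x", "cm"), keep_design=False)
        afit = fit_additive_constant(t, d, W, names=("x", "cm"))
        hr = float(np.exp(cfit.theta[0]))
        out["hr"].append(hr)
        out["hr_se"].append(hr * float(cfit.se[0]))
        out["hd"].append(float(afit.theta[0]))
        out["hd_se"].append(float(afit.se[0]))
    return {k: np.asarray(v) for k, v in out.items()}


def true_marginal_contrasts(
    spec: ScenarioSpec,
    coeffs: CoefficientSet,
    n_mc: int = DEFAULT_N_MC,
    seed=None,
    years: Sequence[int] = DEFAULT_YEARS,
) -> TruthEstimands:
    """Marginal hazard ratio/difference and per-arm survival, per year."""
    _check_n_mc(n_mc)
    rct = dgm.simulate_rct_cohort(spec, coeffs, n_mc, seed)
    parts = _marginal_parts(rct, years)
    return TruthEstimands(
        years=tuple(years),
        n_mc=n_mc,
        hr_marginal=parts["hr"],
        hr_marginal_se=parts["hr_se"],
        hd_marginal=parts["hd"],
        hd_marginal_se=parts["hd_se"],
        surv_treated=parts["s1"],
        surv_treated_se=parts["s1_se"],
        surv_untreated=parts["s0"],
        surv_untreated_se=parts["s0_se"],
    )


def true_conditional_contrasts(
    spec: ScenarioSpec,
    coeffs: CoefficientSet,
    n_mc: int = DEFAULT_N_MC,
    seed=None,
    years: Sequence[int] = DEFAULT_YEARS,
) -> TruthEstimands:
    """Hazard contrasts conditional on the measured confounder, per year."""
    _check_n_mc(n_mc)
    rct = dgm.simulate_rct_cohort(spec, coeffs, n_mc, seed)
    parts = _conditional_parts(rct, years)
    return TruthEstimands(
        years=tuple(years),
        n_mc=n_mc,
        hr_conditional=parts["hr"],
        hr_conditional_se=parts["hr_se"],
        hd_conditional=parts["hd"],
        hd_conditional_se=parts["hd_se"],
    )


def true_ett(
    spec: ScenarioSpec,
    coeffs: CoefficientSet,
    n_mc: int = DEFAULT_N_MC,
    seed=None,
    years: Sequence[int] = DEFAULT_YEARS,
) -> TruthEstimands:
    """Hazard ratio of treatment in the treated subgroup, per year.

    Treatment is assigned observationally; both potential times for the
    treated share one uniform draw per subject; the stacked counterfactual
    data get an unadjusted Cox fit.
    """
    _check_n_mc(n_mc)
    rng = np.random.default_rng(seed)
    z, cm, cu = dgm.simulate_covariates(n_mc, rng)
    x = dgm.assign_treatment_probit(z, cm, cu, coeffs.alpha, rng)
    u = np.clip(rng.random(n_mc), 1e-300, 1.0 - 1e-16)
    treated = x == 1
    if not treated.any():
        raise ValueError("treated subgroup is empty")
    t0, t1 = dgm.simulate_potential_times(
        spec, coeffs, cm[treated], cu[treated], u[treated]
    )
    stacked_latent = np.concatenate([t1, t0])
    stacked_x = np.concatenate([np.ones(len(t1)), np.zeros(len(t0))])
    hrs, ses = [], []
    for y in years:
        t, d = _censor(stacked_latent, float(y))
        cfit = fit_cox(t, d, stacked_x[:, None], names=("x",), keep_design=False)
        hr = float(np.exp(cfit.theta[0]))
        hrs.append(hr)
        ses.append(hr * float(cfit.se[0]))
    return TruthEstimands(
        years=tuple(years),
        n_mc=n_mc,
        hr_ett=np.asarray(hrs),
        hr_ett_se=np.asarray(ses),
    )


def compute_truth(
    spec: ScenarioSpec,
    coeffs: CoefficientSet,
    n_mc: int = DEFAULT_N_MC,
    seed=None,
    years: Sequence[int] = DEFAULT_YEARS,
    include: Sequence[str] = ("marginal", "conditional", "ett"),
) -> TruthEstimands:
    """All requested estimand families, sharing the RCT draw where possible."""
    _check_n_mc(n_mc)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    child_rct, child_ett = ss.spawn(2)
    truth = TruthEstimands(years=tuple(years), n_mc=n_mc)
    if "marginal" in include or "conditional" in include:
        rct = dgm.simulate_rct_cohort(spec, coeffs, n_mc, np.random.default_rng(child_rct))
        if "marginal" in include:
            parts = _marginal_parts(rct, years)
            truth.hr_marginal, truth.hr_marginal_se = parts["hr"], parts["hr_se"]
            truth.hd_marginal, truth.hd_marginal_se = parts["hd"], parts["hd_se"]
            truth.surv_treated, truth.surv_treated_se = parts["s1"], parts["s1_se"]
            truth.surv_untreated, truth.surv_untreated_se = parts["s0"], parts["s0_se"]
        if "conditional" in include:
            parts = _conditional_parts(rct, years)
            truth.hr_conditional, truth.hr_conditional_se = parts["hr"], parts["hr_se"]
            truth.hd_conditional, truth.hd_conditional_se = parts["hd"], parts["hd_se"]
    if "ett" in include:
        ett = true_ett(spec, coeffs, n_mc, np.random.default_rng(child_ett), years)
        truth.hr_ett, truth.hr_ett_se = ett.hr_ett, ett.hr_ett_se
    return truth
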
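"""Replicated simulation runs, performance metrics, and report plumbing.

`run_scenario` drives the six analysis methods over replicated cohorts and
records effect estimates (on each method's native scale), confidence
intervals and standardized survival predictions.  `compute_metrics` turns
those into the bias / MC SE / MSE / relative bias / coverage / power table
against the Monte-Carlo truth, comparing Cox methods on the hazard-ratio
scale and additive methods on the hazard-difference scale.  Failed fits are
flagged and excluded from summaries with their counts reported, never
silently dropped.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import __version__
from .additive_hazards import (
    AdditiveFitError,
    fit_additive_2sri,
    fit_additive_constant,
    fit_additive_two_stage,
    predict_survival_additive,
)
from .cox_models import (
    CoxFitError,
    StructuralCoxNoSolutionError,
    fit_cox,
    fit_cox_two_stage,
    fit_structural_cox,
    predict_survival_cox,
)
from .dgm import Cohort, NegativeHazardError, simulate_observational_cohort
from .first_stage import FirstStageError, fit_treatment_model
from .scenario_config import CoefficientSet, ScenarioSpec, lookup_coefficients
from .truth_oracle import TruthEstimands

__all__ = [
    "METHODS",
    "SimulationResult",
    "censor_at_year",
    "run_scenario",
    "compute_metrics",
    "survival_prediction_error",
    "report",
]

METHODS = ("AN", "CN", "A2S", "ARI", "C2S", "CSt")
ADDITIVE_METHODS = frozenset({"AN", "A2S", "ARI"})
# native estimation scale per method: hazard difference or log hazard ratio
METHOD_SCALE = {
    "AN": "hd",
    "A2S": "hd",
    "ARI": "hd",
    "CN": "loghr",
    "C2S": "loghr",
    "CSt": "loghr",
}
_Z95 = float(norm.ppf(0.975))


@dataclass
class SimulationResult:
    """Raw per-replicate output of one scenario run."""

    scenario: str
    estimates: pd.DataFrame
    survival: pd.DataFrame
    n: int
    n_reps: int
    seed: int

    def failure_counts(self) -> pd.DataFrame:
        df = self.estimates
        return (
            df[~df["ok"]]
            .groupby(["method", "year"])
            .size()
            .rename("n_failed")
            .reset_index()
        )


def censor_at_year(cohort: Cohort, year: float) -> Cohort:
    """Administrative censoring at the end of the given year of follow-up."""
    if not 0 < year <= cohort.tau_max + 1e-12:
        raise ValueError(f"year must lie in (0, {cohort.tau_max}], got {year}")
    latent = cohort.latent_time if cohort.latent_time is not None else cohort.time
    time = np.minimum(latent, year)
    event = (latent <= year).astype(int)
    return Cohort(
        z=cohort.z,
        cm=cohort.cm,
        cu=cohort.cu,
        x=cohort.x,
        time=time,
        event=event,
        latent_time=latent,
        tau_max=float(year),
    )


def _replicate_seed(master_seed: int, scenario_label: str, rep: int) -> np.random.SeedSequence:
    """Reproducible per-replicate substream from (master seed, scenario, rep)."""
    scen_key = zlib.crc32(scenario_label.encode())
    return np.random.SeedSequence(entropy=(int(master_seed), scen_key, int(rep)))


def _wald_ci(est: float, se: float) -> tuple[float, float]:
    if not np.isfinite(se):
        return (np.nan, np.nan)
    return est - _Z95 * se, est + _Z95 * se


def _run_replicate(
    spec: ScenarioSpec,
    coeffs: CoefficientSet,
    methods: Sequence[str],
    years: Sequence[float],
    pred_years: Sequence[float],
    rep: int,
    master_seed: int,
    cst_bootstrap: int,
) -> tuple[list[dict], list[dict]]:
    seed = _replicate_seed(master_seed, spec.label, rep)
    est_rows: list[dict] = []
    surv_rows: list[dict] = []

    def record(method, year, est=np.nan, se=np.nan, ok=True, message=""):
        lo, hi = _wald_ci(est, se) if ok else (np.nan, np.nan)
        est_rows.append(
            {
                "scenario": spec.label,
                "rep": rep,
                "method": method,
                "year": year,
                "scale": METHOD_SCALE[method],
                "estimate": est,
                "se": se,
                "ci_lower": lo,
                "ci_upper": hi,
                "ok": ok,
                "message": message,
            }
        )

    def record_surv(method, year, arm, pred, n_invalid):
        surv_rows.append(
            {
                "scenario": spec.label,
                "rep": rep,
                "method": method,
                "year": year,
                "arm": arm,
                "pred": pred,
                "n_invalid_subjects": n_invalid,
            }
        )

    try:
        cohort = simulate_observational_cohort(spec, coeffs, spec.n, np.random.default_rng(seed))
    except NegativeHazardError as exc:
        for method in methods:
            for year in years:
                record(method, year, ok=False, message=str(exc))
        return est_rows, surv_rows

    fs = None
    fs_error: Optional[str] = None
    if any(m in methods for m in ("A2S", "ARI", "C2S")):
        try:
            fs = fit_treatment_model(cohort)
        except FirstStageError as exc:
            fs_error = str(exc)

    horizon = max(years)
    for year in years:
        c_y = censor_at_year(cohort, year)
        at_horizon = year == horizon
        for method in methods:
            try:
                if method == "AN":
                    fit = fit_additive_constant(
                        c_y.time, c_y.event,
                        np.column_stack([c_y.x, c_y.cm]), names=("x", "cm"),
                    )
                    record(method, year, float(fit.theta[0]), float(fit.se[0]))
                elif method == "CN":
                    fit = fit_cox(
                        c_y.time, c_y.event,
                        np.column_stack([c_y.x, c_y.cm]), names=("x", "cm"),
                    )
                    record(method, year, float(fit.theta[0]), float(fit.se[0]))
                elif method == "A2S":
                    if fs is None:
                        raise AdditiveFitError(fs_error or "first stage unavailable")
                    fit = fit_additive_two_stage(c_y, fs)
                    record(method, year, float(fit.theta[0]), float(fit.se[0]))
                elif method == "ARI":
                    if fs is None:
                        raise AdditiveFitError(fs_error or "first stage unavailable")
                    fit = fit_additive_2sri(c_y, fs)
                    record(method, year, float(fit.theta[0]), float(fit.se[0]))
                elif method == "C2S":
                    if fs is None:
                        raise CoxFitError(fs_error or "first stage unavailable")
                    fit = fit_cox_two_stage(c_y, fs)
                    record(method, year, float(fit.theta[0]), float(fit.se[0]))
                elif method == "CSt":
                    fit = fit_structural_cox(
                        c_y,
                        t_eval=float(year),
                        n_bootstrap=cst_bootstrap,
                        seed=np.random.default_rng(seed.spawn(1)[0]),
                    )
                    record(method, year, fit.theta, fit.se if fit.se is not None else np.nan)
                else:
                    raise ValueError(f"unknown method {method!r}")
            except (
                AdditiveFitError,
                CoxFitError,
                StructuralCoxNoSolutionError,
                FirstStageError,
            ) as exc:
                record(method, year, ok=False, message=str(exc))
                continue

            if at_horizon:
                for py in pred_years:
                    for arm in (0, 1):
                        try:
                            if method in ADDITIVE_METHODS:
                                pred = predict_survival_additive(fit, arm, float(py))
                                record_surv(method, py, arm, pred.value, pred.n_invalid)
                            elif method in ("CN", "C2S"):
                                value = predict_survival_cox(fit, arm, float(py))
                                record_surv(method, py, arm, value, 0)
                            elif method == "CSt" and fit.nuisance is not None:
                                value = predict_survival_cox(fit.nuisance, arm, float(py))
                                record_surv(method, py, arm, value, 0)
                        except ValueError as exc:
                            record_surv(method, py, arm, np.nan, 0)
    return est_rows, surv_rows


def run_scenario(
    spec: ScenarioSpec,
    coeffs: Optional[CoefficientSet] = None,
    methods: Sequence[str] = METHODS,
    n_reps: int = 1000,
    n: Optional[int] = None,
    seed: int = 0,
    years: Sequence[float] = (5,),
    pred_years: Optional[Sequence[float]] = None,
    n_jobs: int = 1,
    cst_bootstrap: int = 0,
) -> SimulationResult:
    """Run all requested methods over replicated cohorts of one scenario.

    Deterministic under ``seed`` and independent of ``n_jobs`` because each
    replicate owns a substream keyed by (seed, scenario label, replicate).
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if n is not None:
        spec = ScenarioSpec(
            spec.dgm_form, spec.baseline, spec.survival_level, spec.effect_size,
            spec.iv_strength, spec.confounding, tau_max=spec.tau_max, n=n,
        )
    if coeffs is None:
        coeffs = lookup_coefficients(spec)
    if pred_years is None:
        pred_years = [y for y in (1, 2, 3, 4, 5) if y <= max(years)]

    args = [
        (spec, coeffs, tuple(methods), tuple(years), tuple(pred_years), rep, seed, cst_bootstrap)
        for rep in range(n_reps)
    ]
    if n_jobs == 1:
        outputs = [_run_replicate(*a) for a in args]
    else:
        from joblib import Parallel, delayed

        outputs = Parallel(n_jobs=n_jobs)(delayed(_run_replicate)(*a) for a in args)

    est_rows = [row for est, _ in outputs for row in est]
    surv_rows = [row for _, surv in outputs for row in surv]
    est_cols = [
        "scenario", "rep", "method", "year", "scale",
        "estimate", "se", "ci_lower", "ci_upper", "ok", "message",
    ]
    surv_cols = ["scenario", "rep", "method", "year", "arm", "pred", "n_invalid_subjects"]
    return SimulationResult(
        scenario=spec.label,
        estimates=pd.DataFrame(est_rows, columns=est_cols),
        survival=pd.DataFrame(surv_rows, columns=surv_cols),
        n=spec.n,
        n_reps=n_reps,
        seed=seed,
    )


# truth attribute per (method scale, target)
_TARGET_FIELDS = {
    ("hd", "marginal"): "hd_marginal",
    ("hd", "conditional"): "hd_conditional",
    ("loghr", "marginal"): "hr_marginal",
    ("loghr", "conditional"): "hr_conditional",
    ("loghr", "ett"): "hr_ett",
}
DEFAULT_TARGETS = {
    "AN": ("marginal",),
    "A2S": ("marginal",),
    "ARI": ("marginal",),
    "CN": ("marginal", "conditional"),
    "C2S": ("marginal", "conditional"),
    "CSt": ("marginal", "ett"),
}


def compute_metrics(
    result: SimulationResult,
    truth: TruthEstimands,
    targets: Optional[dict] = None,
) -> pd.DataFrame:
    """Performance metrics per method, target estimand and year.

    Cox methods are compared on the hazard-ratio scale (estimates and CI
    bounds exponentiated), additive methods on the hazard-difference scale.
    ``mc_se`` is the sd of the comparison-scale estimates (ddof=1); ``mse``
    is the mean squared deviation from the truth, which equals the ddof=0
    variance plus squared bias; coverage and power are percentages.  Failed
    replicates are excluded with their count reported.
    """
    targets = DEFAULT_TARGETS if targets is None else targets
    rows = []
    df = result.estimates
    for (method, year), grp in df.groupby(["method", "year"], sort=True):
        if int(year) not in truth.years:
            continue
        scale = METHOD_SCALE[method]
        ok = grp[grp["ok"]]
        n_failed = int((~grp["ok"]).sum())
        for target in targets.get(method, ("marginal",)):
            fieldname = _TARGET_FIELDS.get((scale, target))
            if fieldname is None:
                continue
            truth_arr = getattr(truth, fieldname)
            if truth_arr is None:
                raise ValueError(
                    f"truth estimand {fieldname!r} missing for target {target!r}"
                )
            theta = float(truth_arr[truth.years.index(int(year))])
            if scale == "loghr":
                est = np.exp(ok["estimate"].to_numpy(float))
                lo = np.exp(ok["ci_lower"].to_numpy(float))
                hi = np.exp(ok["ci_upper"].to_numpy(float))
            else:
                est = ok["estimate"].to_numpy(float)
                lo = ok["ci_lower"].to_numpy(float)
                hi = ok["ci_upper"].to_numpy(float)
            null_value = 1.0 if scale == "loghr" else 0.0
            mean = float(est.mean()) if len(est) else np.nan
            mc_se = float(est.std(ddof=1)) if len(est) > 1 else np.nan
            bias = mean - theta
            mse = float(np.mean((est - theta) ** 2)) if len(est) else np.nan
            with_ci = np.isfinite(lo) & np.isfinite(hi)
            coverage = (
                float(100.0 * np.mean((lo[with_ci] <= theta) & (theta <= hi[with_ci])))
                if with_ci.any()
                else np.nan
            )
            power = (
                float(100.0 * np.mean((lo[with_ci] > null_value) | (hi[with_ci] < null_value)))
                if with_ci.any()
                else np.nan
            )
            rows.append(
                {
                    "scenario": result.scenario,
                    "method": method,
                    "target": target,
                    "year": year,
                    "comparison_scale": "hr" if scale == "loghr" else "hd",
                    "truth": theta,
                    "n_used": int(len(est)),
                    "n_failed": n_failed,
                    "mean": mean,
                    "mc_se": mc_se,
                    "bias": bias,
                    "relative_bias_pct": 100.0 * bias / theta if theta != 0 else np.nan,
                    "mse": mse,
                    "coverage_pct": coverage,
                    "power_pct": power,
                }
            )
    return pd.DataFrame(rows)


def survival_prediction_error(
    result: SimulationResult, truth: TruthEstimands
) -> pd.DataFrame:
    """Summaries of (predicted - true) survival per method, arm and year."""
    rows = []
    df = result.survival
    for (method, year, arm), grp in df.groupby(["method", "year", "arm"], sort=True):
        if int(year) not in truth.years:
            continue
        i = truth.years.index(int(year))
        true_surv = truth.surv_treated[i] if arm == 1 else truth.surv_untreated[i]
        preds = grp["pred"].to_numpy(float)
        valid = np.isfinite(preds)
        diffs = preds[valid] - true_surv
        n_invalid_rows = int(np.sum(~valid | (preds < 0) | (preds > 1)))
        rows.append(
            {
                "scenario": result.scenario,
                "method": method,
                "year": year,
                "arm": arm,
                "true_survival": float(true_surv),
                "n": int(valid.sum()),
                "mean_error": float(diffs.mean()) if diffs.size else np.nan,
                "sd_error": float(diffs.std(ddof=1)) if diffs.size > 1 else np.nan,
                "min_error": float(diffs.min()) if diffs.size else np.nan,
                "max_error": float(diffs.max()) if diffs.size else np.nan,
                "n_invalid_predictions": n_invalid_rows,
                "n_invalid_subject_flags": int(grp["n_invalid_subjects"].sum()),
            }
        )
    return pd.DataFrame(rows)


_FLOAT_FORMAT = "%.12g"


def report(
    results: Sequence[SimulationResult],
    metrics: Optional[pd.DataFrame],
    destination,
    manifest: Optional[pd.DataFrame] = None,
    survival_errors: Optional[pd.DataFrame] = None,
    run_info: Optional[dict] = None,
) -> list[Path]:
    """Write raw tables, metrics and a run log as deterministic text files."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write_csv(df: pd.DataFrame, name: str) -> None:
        path = dest / name
        df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
        written.append(path)

    if results:
        write_csv(pd.concat([r.estimates for r in results], ignore_index=True), "estimates.csv")
        surv = pd.concat([r.survival for r in results], ignore_index=True)
        write_csv(surv, "survival_predictions.csv")
    else:
        import warnings

        warnings.warn("empty result set; writing header-only tables")
        write_csv(
            pd.DataFrame(
                columns=[
                    "scenario", "rep", "method", "year", "scale",
                    "estimate", "se", "ci_lower", "ci_upper", "ok", "message",
                ]
            ),
            "estimates.csv",
        )
    if metrics is not None:
        write_csv(metrics, "metrics.csv")
    if survival_errors is not None:
        write_csv(survival_errors, "survival_errors.csv")
    if manifest is not None:
        write_csv(manifest, "scenario_manifest.csv")

    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "scenarios": [r.scenario for r in results],
        "seeds": sorted({r.seed for r in results}),
        "n_reps": sorted({r.n_reps for r in results}),
    }
    if run_info:
        log.update(run_info)
    log_path = dest / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    written.append(log_path)
    return written
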
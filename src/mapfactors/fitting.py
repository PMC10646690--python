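"""Simulation-based fitting of the factor weights and nested-model comparison.

The six free weights (group and subject task/RT/confidence factors; the noise
weight is fixed to 1) are fitted by minimizing the mean squared error between
six empirical summary values — within-subject reliability and
subject-to-group similarity for the three contrasts, computed on 100% of
voxels — and the same values computed from a full simulated cohort.  One
simulation seed is reused across objective evaluations (common random
numbers), so the optimizer sees a deterministic, smooth surface; a bounded
trust-region least-squares search (scipy's TRF, with finite-difference
Jacobians — no analytic derivatives of the simulator are required) is
restarted from several random points and the best restart is reported.

Model comparison refits a Subject-Only and a Group-Only variant (the
corresponding weights pinned to zero), then re-evaluates each best fit on a
shared set of fresh simulation seeds to obtain paired MSE samples, AIC, and
BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .engine import SimulationEngine, derive_seeds, make_engine
from .exceptions import InvalidParameterError
from .generative import FactorWeights, StudyDesign, default_design
from .reliability import DEFAULT_FRACTIONS, SummaryStatistics

#: Box bounds applied to every free weight during fitting.
DEFAULT_BOUNDS = (0.0, 3.0)
#: Number of empirical summary values the model is fitted to.
N_TARGETS = 6

_MODEL_MASKS = {
    # which of the six free weights (group task/rt/conf, subject task/rt/conf) are free
    "full": np.ones(6, dtype=bool),
    "group_only": np.array([True, True, True, False, False, False]),
    "subject_only": np.array([False, False, False, True, True, True]),
}


def _as_targets(empirical) -> np.ndarray:
    if isinstance(empirical, SummaryStatistics):
        return empirical.targets(1.0)
    empirical = np.asarray(empirical, dtype=float)
    if empirical.shape != (N_TARGETS,):
        raise InvalidParameterError(
            "empirical targets must be 6 values (reliability then similarity, "
            "each task/rt/confidence) or a SummaryStatistics"
        )
    return empirical


def objective(
    weights: FactorWeights,
    empirical,
    design: StudyDesign | None = None,
    base_seed: int = 0,
    engine: SimulationEngine | None = None,
) -> float:
    """MSE between simulated and empirical 100%-fraction summary values.

    Deterministic given (weights, base_seed): the simulation reuses common
    random numbers.  Pass a prebuilt ``engine`` to amortize the simulation
    cache across many evaluations (``design``/``base_seed`` are then ignored).
    """
    targets = _as_targets(empirical)
    if engine is None:
        engine = make_engine(design or default_design(), base_seed)
    simulated = engine.targets(weights)
    return float(np.mean((simulated - targets) ** 2))


def information_criteria(mse: float, k: int, n_obs: int = N_TARGETS) -> tuple[float, float]:
    """Gaussian-residual AIC and BIC from a mean squared error.

    AIC = n*ln(SSE/n) + 2k and BIC = n*ln(SSE/n) + k*ln(n) with n the number
    of fitted summary values; SSE/n is the MSE itself.
    """
    if mse <= 0:
        mse = np.finfo(float).tiny  # a perfect fit; keep the criteria finite
    aic = n_obs * np.log(mse) + 2 * k
    bic = n_obs * np.log(mse) + k * np.log(n_obs)
    return float(aic), float(bic)


@dataclass
class FitResult:
    """Outcome of a multi-restart fit."""

    weights: FactorWeights
    mse: float
    aic: float
    bic: float
    n_restarts: int
    restarts: list[dict] = field(default_factory=list)
    predicted_curves: SummaryStatistics | None = None
    converged: bool = True
    model: str = "full"

    def report(self) -> dict:
        return {
            "model": self.model,
            "weights": self.weights.as_dict(),
            "mse": self.mse,
            "aic": self.aic,
            "bic": self.bic,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "restarts": self.restarts,
        }


def _fit_masked(
    engine: SimulationEngine,
    targets: np.ndarray,
    mask: np.ndarray,
    n_restarts: int,
    seed: int,
    bounds: tuple[float, float],
    early_stop_mse: float,
) -> tuple[np.ndarray, float, list[dict], bool]:
    lo, hi = bounds
    n_free = int(mask.sum())

    def residuals(x_free: np.ndarray) -> np.ndarray:
        x = np.zeros(6)
        x[mask] = np.clip(x_free, lo, hi)
        w = FactorWeights.from_free_vector(x)
        return engine.targets(w) - targets

    rng = np.random.default_rng(seed)
    best_x, best_mse = None, np.inf
    restarts = []
    any_success = False
    for i in range(n_restarts):
        x0 = rng.uniform(lo, hi, size=n_free)
        res = optimize.least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", diff_step=1e-3
        )
        mse_i = float(np.mean(res.fun**2))
        restarts.append(
            {"restart": i, "x0": x0.tolist(), "mse": mse_i, "success": bool(res.success)}
        )
        any_success = any_success or bool(res.success)
        if mse_i < best_mse:
            best_mse, best_x = mse_i, np.asarray(res.x)
        if best_mse < early_stop_mse:
            # an (up to machine precision) perfect fit; further restarts
            # cannot improve the best-of-n result
            break
    x = np.zeros(6)
    x[mask] = np.clip(best_x, lo, hi)
    return x, best_mse, restarts, any_success


def fit_model(
    empirical,
    design: StudyDesign | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    model: str = "full",
    behavior: pd.DataFrame | None = None,
    engine: SimulationEngine | None = None,
    fractions=DEFAULT_FRACTIONS,
    predict: bool = True,
    early_stop_mse: float = 1e-14,
) -> FitResult:
    """Fit the factor weights to empirical summary values.

    Parameters
    ----------
    empirical
        SummaryStatistics (the 100%-fraction values are used) or a bare
        6-vector [reliability task/rt/conf, similarity task/rt/conf].
    design
        Simulated cohort dimensions; defaults to 50 subjects x 768 trials x
        10,000 voxels.
    n_restarts
        Independent random starting points; the best restart is reported
        (the protocol uses 10 to avoid local minima).  Restarting stops
        early once a restart reaches ``early_stop_mse`` (machine-precision
        fit), since best-of-n cannot improve further.
    model
        'full' (6 free weights), 'subject_only', or 'group_only' (the
        excluded weights are fixed at 0, leaving 3 free).
    predict
        Also evaluate the best-fitting weights at all ``fractions``
        (out-of-sample predictions of the voxel-selection curves).
    """
    if model not in _MODEL_MASKS:
        raise InvalidParameterError(f"model must be one of {sorted(_MODEL_MASKS)}, got {model!r}")
    targets = _as_targets(empirical)
    crn_seed, start_seed = derive_seeds(seed, 2)
    if engine is None:
        engine = make_engine(design or default_design(), crn_seed, behavior=behavior)
    mask = _MODEL_MASKS[model]
    x, mse, restarts, converged = _fit_masked(
        engine, targets, mask, n_restarts, start_seed, bounds, early_stop_mse
    )
    weights = FactorWeights.from_free_vector(x)
    aic, bic = information_criteria(mse, k=int(mask.sum()))
    predicted = engine.summary(weights, fractions) if predict else None
    return FitResult(
        weights=weights,
        mse=mse,
        aic=aic,
        bic=bic,
        n_restarts=n_restarts,
        restarts=restarts,
        predicted_curves=predicted,
        converged=converged,
        model=model,
    )


def weight_ratio(weights: FactorWeights) -> dict[str, float]:
    """Subject/group weight ratio per contrast (NaN where the group weight is 0)."""
    out = {}
    for name, w_s, w_g in (
        ("task", weights.w_task_subj, weights.w_task_group),
        ("rt", weights.w_rt_subj, weights.w_rt_group),
        ("confidence", weights.w_conf_subj, weights.w_conf_group),
    ):
        out[name] = w_s / w_g if w_g > 0 else float("nan")
    return out


def factor_proportions(weights: FactorWeights) -> dict[str, float]:
    """Percent of total summed weight carried by subject, group, and noise factors."""
    subject = float(weights.subject.sum())
    group = float(weights.group.sum())
    total = subject + group + weights.w_noise
    if total == 0:
        raise InvalidParameterError("all weights are zero; proportions undefined")
    return {
        "subject": 100.0 * subject / total,
        "group": 100.0 * group / total,
        "noise": 100.0 * weights.w_noise / total,
    }


@dataclass
class ModelComparison:
    """Paired MSE samples and information criteria for the three model variants."""

    fits: dict[str, FitResult]
    mse: dict[str, np.ndarray]  # model -> per-repetition MSE on fresh seeds
    aic: dict[str, float]
    bic: dict[str, float]
    paired_tests: dict[tuple[str, str], dict]

    def table(self) -> pd.DataFrame:
        rows = []
        for model, values in self.mse.items():
            rows.append(
                {
                    "model": model,
                    "mean_mse": values.mean(),
                    "sem_mse": values.std(ddof=1) / np.sqrt(len(values)),
                    "aic": self.aic[model],
                    "bic": self.bic[model],
                    "n_repetitions": len(values),
                }
            )
        return pd.DataFrame(rows)


def compare_models(
    empirical,
    design: StudyDesign | None = None,
    n_repetitions: int = 25,
    n_restarts: int = 10,
    seed: int = 0,
    behavior: pd.DataFrame | None = None,
    **fit_kwargs,
) -> ModelComparison:
    """Compare Full, Subject-Only, and Group-Only models.

    Each variant is fitted to the empirical values, then every best fit is
    re-simulated on ``n_repetitions`` fresh seeds shared across variants,
    giving paired MSE samples; AIC/BIC use the repetition-mean MSE with k = 6
    (full) or 3 (restricted) parameters, and two-sided paired t-tests compare
    the repetition-wise MSEs between variants.
    """
    design = design or default_design()
    targets = _as_targets(empirical)
    fit_seed, rep_seed = derive_seeds(seed, 2)
    fits = {
        model: fit_model(
            targets,
            design=design,
            n_restarts=n_restarts,
            seed=fit_seed,
            model=model,
            behavior=behavior,
            predict=False,
            **fit_kwargs,
        )
        for model in ("full", "subject_only", "group_only")
    }
    rep_seeds = derive_seeds(rep_seed, n_repetitions)
    mse = {model: np.empty(n_repetitions) for model in fits}
    for r, s in enumerate(rep_seeds):
        rep_engine = make_engine(design, s, behavior=behavior)
        for model, fit in fits.items():
            simulated = rep_engine.targets(fit.weights)
            mse[model][r] = np.mean((simulated - targets) ** 2)
    aic, bic = {}, {}
    for model, fit in fits.items():
        k = int(_MODEL_MASKS[model].sum())
        aic[model], bic[model] = information_criteria(float(mse[model].mean()), k=k)
    paired = {}
    for a, b in (("full", "subject_only"), ("full", "group_only"), ("subject_only", "group_only")):
        t = stats.ttest_rel(mse[a], mse[b])
        paired[(a, b)] = {"t": float(t.statistic), "p": float(t.pvalue), "df": n_repetitions - 1}
    return ModelComparison(fits=fits, mse=mse, aic=aic, bic=bic, paired_tests=paired)
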
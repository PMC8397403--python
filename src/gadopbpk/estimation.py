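"""Naive-pooled least-squares fitting of the PBPK model to deltaR1 data.

One parameter set is fitted to all animals' frame-interval deltaR1
observations (blood, spleen, liver; both field strengths pooled with unit
weights).  Residuals compare each observed frame value with the time-average
of the simulated deltaR1 over the same interval.  Parameter uncertainty is
quantified by the case bootstrap: whole animals (all their profiles
together) are resampled with replacement within arm and the model is refit
on every replicate.  Rifampicin inhibition is estimated by simultaneous
fitting of both study arms with a shared rest-of-body PS.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .mri import DeltaR1Profile, SECONDS_PER_HOUR, frame_average, \
    frame_time_grid, organ_deltaR1
from .params import GadoxetateParams, PhysiologyParams, RelaxivityTable
from .pbpk import DoseEvent, IntegrationError, simulate_pbpk

logger = logging.getLogger(__name__)

_PENALTY = 1e6
DEFAULT_LOG_BOUNDS = (-4.0, 2.0)  # clearances in 1e-4 .. 1e2 L/h


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitSpec:
    """What to estimate and from which data.

    free: parameter labels, either shared (``"PS"``) or arm-specific
    (``"CL_active@control"``).  PS is never arm-specific.  fixed: overrides
    applied to the base parameter set of every arm.  organs/arms: data
    subsets entering the objective.
    """

    free: tuple = ("CL_active", "CL_biliary", "PS")
    fixed: dict = field(default_factory=dict)
    organs: tuple = ("blood", "spleen", "liver")
    arms: tuple = ("control",)
    base: GadoxetateParams = GadoxetateParams()
    dose: DoseEvent = DoseEvent.bolus_per_kg()
    log_bounds: tuple = DEFAULT_LOG_BOUNDS
    #: starting values are drawn from this narrower, physiologically
    #: plausible range (0.01..10 L/h); the optimization bounds stay wide
    start_log_range: tuple = (-2.0, 1.0)
    n_starts: int = 5
    liver_model: int = 1
    seed: int = 0

    def __post_init__(self):
        for label in self.free:
            name, _, arm = label.partition("@")
            if name == "PS" and arm:
                raise EstimationError("PS is shared, never arm-specific")
            if name in self.fixed:
                raise EstimationError(f"{name} is both free and fixed")

    def params_for_arm(self, arm: str, theta: np.ndarray) -> GadoxetateParams:
        """Concrete parameter set for one arm given log10 free values."""
        values = dict(self.fixed)
        for label, th in zip(self.free, theta):
            name, _, label_arm = label.partition("@")
            if not label_arm or label_arm == arm:
                values[name] = 10.0 ** th
        return self.base.replace(**values)


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame  # one row per successful replicate
    n_failed: int = 0

    @property
    def mean(self) -> pd.Series:
        return self.replicates.mean()

    @property
    def cv_percent(self) -> pd.Series:
        return self.replicates.std(ddof=1) / self.replicates.mean() * 100.0

    @property
    def flagged(self) -> bool:
        """True when more than 5% of replicates failed to converge."""
        n_total = len(self.replicates) + self.n_failed
        return n_total > 0 and self.n_failed > 0.05 * n_total


@dataclass
class FitResult:
    estimates: dict
    objective: float
    success: bool
    spec: FitSpec
    residuals: np.ndarray = field(default=None, repr=False)
    bootstrap: BootstrapResult | None = None

    def params_for_arm(self, arm: str) -> GadoxetateParams:
        theta = np.log10([self.estimates[k] for k in self.spec.free])
        return self.spec.params_for_arm(arm, theta)


def _select(data: list[DeltaR1Profile], spec: FitSpec) -> list[DeltaR1Profile]:
    sel = [p for p in data if p.organ in spec.organs and p.arm in spec.arms]
    if not sel:
        raise EstimationError("no profiles match the fit specification")
    for arm in spec.arms:
        if not any(p.arm == arm for p in sel):
            raise EstimationError(f"no profiles for requested arm {arm!r}")
    return sel


def _residual_vector(theta, data, spec: FitSpec, phys: PhysiologyParams,
                     r1: RelaxivityTable) -> np.ndarray:
    """Concatenated (observed - simulated frame mean) over all profiles.

    One simulation per arm per evaluation (the estimate is naive-pooled);
    predictions are cached per unique (arm, organ, field, frame grid)."""
    res = []
    for arm in spec.arms:
        arm_profiles = [p for p in data if p.arm == arm]
        if not arm_profiles:
            continue
        params = spec.params_for_arm(arm, theta)
        t_starts = np.concatenate([p.t_start for p in arm_profiles])
        t_ends = np.concatenate([p.t_end for p in arm_profiles])
        grid = frame_time_grid(np.unique(t_starts), np.unique(t_ends))
        try:
            traj = simulate_pbpk(params, phys, spec.dose, grid,
                                 spec.liver_model)
        except (IntegrationError, ValueError) as exc:
            logger.warning("simulation failed during fit (%s); penalized",
                           exc)
            n_obs = sum(p.n_frames for p in arm_profiles)
            res.append(np.full(n_obs, _PENALTY))
            continue
        t_s = traj.t * SECONDS_PER_HOUR
        cache: dict = {}
        for p in arm_profiles:
            key = (p.organ, p.field_strength, p.t_start.tobytes(),
                   p.t_end.tobytes())
            if key not in cache:
                signal = organ_deltaR1(traj, phys, r1, p.organ,
                                       p.field_strength)
                cache[key] = frame_average(t_s, signal, p.t_start, p.t_end)
            res.append(p.deltaR1 - cache[key])
    return np.concatenate(res)


def objective(params_by_arm: dict[str, GadoxetateParams],
              data: list[DeltaR1Profile], phys: PhysiologyParams,
              r1: RelaxivityTable, organs=("blood", "spleen", "liver"),
              dose: DoseEvent = DoseEvent.bolus_per_kg(),
              liver_model: int = 1) -> float:
    """Pooled sum of squared frame residuals for explicit parameter sets."""
    spec = FitSpec(free=(), fixed={}, organs=tuple(organs),
                   arms=tuple(params_by_arm), dose=dose,
                   liver_model=liver_model)
    sel = _select(data, spec)
    total = 0.0
    for arm, params in params_by_arm.items():
        arm_spec = replace(spec, arms=(arm,), base=params)
        r = _residual_vector(np.array([]),
                             [p for p in sel if p.arm == arm],
                             arm_spec, phys, r1)
        total += float(r @ r)
    return total


def _starts(spec: FitSpec, rng_seed: int, n: int | None = None) -> np.ndarray:
    lo, hi = spec.start_log_range
    k = len(spec.free)
    sampler = qmc.LatinHypercube(d=k, seed=rng_seed)
    return qmc.scale(sampler.random(n or spec.n_starts), lo, hi)


def _fit(data: list[DeltaR1Profile], spec: FitSpec, phys: PhysiologyParams,
         r1: RelaxivityTable,
         x0: np.ndarray | list | None = None) -> FitResult:
    sel = _select(data, spec)
    lo, hi = spec.log_bounds
    bounds = (np.full(len(spec.free), lo), np.full(len(spec.free), hi))
    if x0 is not None:
        starts = list(np.atleast_2d(np.asarray(x0, dtype=float)))
    else:
        starts = list(_starts(spec, spec.seed))
    best = None
    for start in starts:
        try:
            sol = least_squares(
                _residual_vector, np.clip(start, lo, hi), bounds=bounds,
                args=(sel, spec, phys, r1), xtol=1e-10, ftol=1e-10,
                gtol=1e-10)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("start failed: %s", exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise EstimationError("all optimization starts failed")
    estimates = {label: float(10.0 ** th)
                 for label, th in zip(spec.free, best.x)}
    return FitResult(estimates=estimates, objective=float(2 * best.cost),
                     success=bool(best.status > 0), spec=spec,
                     residuals=best.fun)


def fit_control(data: list[DeltaR1Profile],
                spec: FitSpec | None = None,
                phys: PhysiologyParams = PhysiologyParams(),
                r1: RelaxivityTable = RelaxivityTable()) -> FitResult:
    """Estimate CL_active, CL_biliary and PS from control-arm profiles,
    with CL_passive, fu_liv_cell and CL_r fixed (in vitro / literature)."""
    spec = spec or FitSpec()
    return _fit(data, spec, phys, r1)


def fit_simultaneous(data: list[DeltaR1Profile],
                     spec: FitSpec | None = None,
                     phys: PhysiologyParams = PhysiologyParams(),
                     r1: RelaxivityTable = RelaxivityTable()) -> FitResult:
    """Fit control and rifampicin arms together: shared PS, arm-specific
    CL_active and CL_biliary."""
    spec = spec or FitSpec(
        free=("PS", "CL_active@control", "CL_biliary@control",
              "CL_active@rifampicin", "CL_biliary@rifampicin"),
        arms=("control", "rifampicin"))
    return _fit(data, spec, phys, r1)


def percent_inhibition(cl_control: float, cl_inhibited: float) -> float:
    """Percent reduction of a clearance in the inhibited arm."""
    if cl_control <= 0:
        raise ValueError("control clearance must be > 0")
    return 100.0 * (1.0 - cl_inhibited / cl_control)


def case_bootstrap(data: list[DeltaR1Profile], spec: FitSpec,
                   phys: PhysiologyParams = PhysiologyParams(),
                   r1: RelaxivityTable = RelaxivityTable(),
                   n_boot: int = 1000, seed: int = 0,
                   n_starts_per_replicate: int = 2) -> BootstrapResult:
    """Case (animal-level) bootstrap of the naive-pooled fit.

    Animals are resampled with replacement within arm; every replicate is
    refit from fresh random starts (best of ``n_starts_per_replicate``)
    so that practically unidentifiable parameters express their full
    dispersion instead of sticking to a warm start on a flat objective
    direction.
    """
    sel = _select(data, spec)
    by_arm: dict[str, dict[str, list[DeltaR1Profile]]] = {}
    for p in sel:
        by_arm.setdefault(p.arm, {}).setdefault(p.animal, []).append(p)
    if any(len(animals) < 2 for animals in by_arm.values()):
        raise EstimationError("case bootstrap needs >= 2 animals per arm")
    rng = np.random.default_rng(seed)
    rows, n_failed = [], 0
    boot_spec = spec
    lo, hi = spec.start_log_range
    for b in range(n_boot):
        resampled: list[DeltaR1Profile] = []
        for arm, animals in by_arm.items():
            ids = list(animals)
            for j, pick in enumerate(rng.choice(len(ids), size=len(ids))):
                for p in animals[ids[pick]]:
                    resampled.append(replace_animal(p, f"bs{b}_{arm}_{j}"))
        x0 = rng.uniform(lo, hi,
                         size=(n_starts_per_replicate, len(spec.free)))
        try:
            res = _fit(resampled, boot_spec, phys, r1, x0=x0)
        except EstimationError:
            n_failed += 1
            continue
        rows.append(res.estimates)
    result = BootstrapResult(pd.DataFrame(rows), n_failed=n_failed)
    if result.flagged:
        logger.warning("bootstrap: %d/%d replicates failed", n_failed, n_boot)
    return result


def replace_animal(p: DeltaR1Profile, new_id: str) -> DeltaR1Profile:
    return DeltaR1Profile(new_id, p.organ, p.field_strength, p.arm,
                          p.t_start, p.t_end, p.deltaR1, dict(p.meta))


def ablation_blood_only(data: list[DeltaR1Profile],
                        spec: FitSpec | None = None,
                        phys: PhysiologyParams = PhysiologyParams(),
                        r1: RelaxivityTable = RelaxivityTable(),
                        n_boot: int = 0, seed: int = 0,
                        include_spleen: bool = False,
                        organs: tuple | None = None
                        ) -> tuple[FitResult, pd.DataFrame]:
    """Refit using only the blood (optionally blood+spleen) profiles and
    report practical identifiability.

    Returns (fit result, report table).  With n_boot > 0 the report flags
    parameters whose bootstrap CV exceeds 100% as practically
    unidentifiable.  An explicit ``organs`` tuple overrides the default
    restriction (passing all organs reproduces the full fit exactly).
    """
    if organs is None:
        organs = ("blood", "spleen") if include_spleen else ("blood",)
    spec = replace(spec or FitSpec(), organs=organs)
    result = _fit(data, spec, phys, r1)
    report = pd.DataFrame({"estimate": pd.Series(result.estimates)})
    if n_boot > 0:
        boot = case_bootstrap(data, spec, phys, r1, n_boot=n_boot, seed=seed)
        result.bootstrap = boot
        report["bootstrap_mean"] = boot.mean
        report["bootstrap_cv_percent"] = boot.cv_percent
        report["practically_unidentifiable"] = boot.cv_percent > 100.0
    return result, report


def fit_result_table(result: FitResult) -> pd.DataFrame:
    """Estimate / bootstrap-CV table shaped like a parameter-estimate table."""
    table = pd.DataFrame({"estimate_L_per_h": pd.Series(result.estimates)})
    if result.bootstrap is not None:
        table["bootstrap_mean"] = result.bootstrap.mean
        table["bootstrap_cv_percent"] = result.bootstrap.cv_percent
    return table
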
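"""Monte Carlo uncertainty propagation and SRC global sensitivity analysis.

The bottom-up parameterization carries assay uncertainty: Vmax, Km_u,
CLpassive_u, fu_liv_cell, PS and CL_biliary are treated as independent
uniform random variables, propagated through IVIVE scaling and the PBPK
model.  Sensitivity is summarized with standardized regression coefficients
(SRC): a multiple linear regression of the scalar endpoint on the inputs,
with SRC_i = b_i * sd(x_i)/sd(y).  When the input-output map is linear the
squared SRCs partition the output variance (first-order Sobol' indices) and
the regression R^2 is ~1; results with R^2 < 0.7 are flagged unreliable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ivive import ScalingFactors, scale_to_whole_body
from .params import DoseEvent, GadoxetateParams, PhysiologyParams
from .pbpk import auc, simulate_pbpk, time_grid

R2_RELIABILITY_GATE = 0.7
AUC_HORIZON_H = 100.0


@dataclass(frozen=True)
class UncertainInput:
    """Independent uniform input on its stated units; degenerate
    (lower == upper) inputs are allowed and produce zero variance."""

    name: str
    lower: float
    upper: float

    def __post_init__(self):
        if self.lower <= 0:
            raise ValueError(f"{self.name}: lower bound must be > 0")
        if self.upper < self.lower:
            raise ValueError(f"{self.name}: upper must be >= lower")


def default_uncertain_inputs() -> list[UncertainInput]:
    """Per-animal min-max ranges of the in vitro kinetic estimates; PS and
    CL_biliary (no in vitro measurement) default to the range obtained by
    IVIVE-scaling the CLpassive_u range, since the bottom-up analysis sets
    both equal to CL_passive."""
    cl_lo = scale_to_whole_body(0.091)
    cl_hi = scale_to_whole_body(0.274)
    return [
        UncertainInput("Vmax", 221.7, 370.9),
        UncertainInput("Km_u", 79.8, 115.8),
        UncertainInput("CLpassive_u", 0.091, 0.274),
        UncertainInput("fu_liv_cell", 0.418, 0.759),
        UncertainInput("PS", cl_lo, cl_hi),
        UncertainInput("CL_biliary", cl_lo, cl_hi),
    ]


class BottomUpEndpoints:
    """Map one draw of the uncertain inputs to PBPK endpoints.

    In vitro draws are IVIVE-scaled to whole-body clearances; the model is
    simulated over the AUC horizon and scalar endpoints (blood, spleen,
    extracellular-liver and hepatocyte concentration AUCs over 0-100 h) are
    returned.  The hepatocyte AUC is the sensitivity endpoint of record.
    """

    def __init__(self, phys: PhysiologyParams = PhysiologyParams(),
                 dose: DoseEvent = DoseEvent.bolus_per_kg(),
                 factors: ScalingFactors = ScalingFactors(),
                 CL_r: float = 0.17, horizon: float = AUC_HORIZON_H,
                 n_grid: int = 800, profile_organ: str | None = None,
                 profile_times_h=None, field_strength: float = 4.7):
        self.phys, self.dose, self.factors = phys, dose, factors
        self.CL_r, self.horizon = CL_r, horizon
        self.t_grid = time_grid(horizon, n=n_grid)
        self.profile_organ = profile_organ
        self.field_strength = field_strength
        self.profile_times_h = None
        if profile_times_h is not None:
            self.profile_times_h = np.asarray(profile_times_h, dtype=float)
            self.t_grid = np.unique(np.concatenate(
                [self.t_grid, self.profile_times_h]))

    def params_from_draw(self, draw: dict) -> GadoxetateParams:
        return GadoxetateParams(
            CL_active=scale_to_whole_body(draw["Vmax"] / draw["Km_u"],
                                          self.factors),
            CL_passive=scale_to_whole_body(draw["CLpassive_u"], self.factors),
            CL_biliary=draw["CL_biliary"], PS=draw["PS"],
            fu_liv_cell=draw["fu_liv_cell"], CL_r=self.CL_r)

    def __call__(self, draw: dict) -> dict:
        traj = simulate_pbpk(self.params_from_draw(draw), self.phys,
                             self.dose, self.t_grid)
        t0, t1 = 0.0, self.horizon
        out = {
            "auc_liv_cell": auc(traj.t, traj.c_liv_cell, t0, t1),
            "auc_liv_extr": auc(traj.t, traj.c_liv_extr, t0, t1),
            "auc_blood": auc(traj.t, traj.c_b, t0, t1),
            "auc_spleen": auc(traj.t, traj.c_spl_extr, t0, t1),
        }
        if self.profile_organ is not None:
            from .mri import organ_deltaR1
            from .params import RelaxivityTable
            signal = organ_deltaR1(traj, self.phys, RelaxivityTable(),
                                   self.profile_organ, self.field_strength)
            values = np.interp(self.profile_times_h, traj.t, signal)
            out.update({f"dr1_{j}": v for j, v in enumerate(values)})
        return out


@dataclass
class MonteCarloResult:
    samples: pd.DataFrame
    outputs: pd.DataFrame
    n_failed: int

    def percentile_bands(self, column: str,
                         q=(2.5, 50.0, 97.5)) -> pd.Series:
        return self.outputs[column].quantile(np.asarray(q) / 100.0)

    def profile_bands(self, prefix: str = "dr1_",
                      q=(2.5, 50.0, 97.5)) -> pd.DataFrame:
        """Per-time-point percentile bands of a captured profile endpoint."""
        cols = [c for c in self.outputs.columns if c.startswith(prefix)]
        if not cols:
            raise ValueError("no profile columns captured")
        return self.outputs[cols].quantile(np.asarray(q) / 100.0).T


def monte_carlo(inputs: list[UncertainInput], endpoint, n: int = 10000,
                seed: int = 0) -> MonteCarloResult:
    """Independent uniform sampling of the inputs and per-sample endpoint
    evaluation; failed evaluations are excluded and counted."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    samples = pd.DataFrame(
        {inp.name: rng.uniform(inp.lower, inp.upper, size=n)
         for inp in inputs})
    rows, ok_idx, n_failed = [], [], 0
    for i, draw in enumerate(samples.to_dict("records")):
        try:
            rows.append(endpoint(draw))
            ok_idx.append(i)
        except Exception:
            n_failed += 1
    outputs = pd.DataFrame(rows, index=ok_idx)
    return MonteCarloResult(samples.loc[ok_idx], outputs, n_failed)


@dataclass
class GSAResult:
    table: pd.DataFrame  # index: input name; SRC, SRC2, ci bounds
    r_squared: float
    n_samples: int

    @property
    def reliable(self) -> bool:
        return self.r_squared >= R2_RELIABILITY_GATE

    def ranking(self) -> list[str]:
        """Input names ordered by decreasing SRC^2."""
        return list(self.table["SRC2"].sort_values(ascending=False).index)


def _src(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized regression coefficients via least squares."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.lstsq(A, y, rcond=None)[0][1:]
    return beta * X.std(axis=0, ddof=1) / y.std(ddof=1)


def src_gsa(samples: pd.DataFrame, output, n_boot: int = 1000,
            seed: int = 0, ci_level: float = 0.95) -> GSAResult:
    """SRC sensitivity indices with bootstrap confidence intervals.

    samples: one column per input; output: aligned scalar endpoint.
    Raises on rank-deficient (collinear) inputs.
    """
    y = np.asarray(output, dtype=float)
    X = samples.to_numpy(dtype=float)
    if len(y) != len(X):
        raise ValueError("samples and output must be aligned")
    if y.std(ddof=1) == 0:
        raise ValueError("output variance is zero")
    active = X.std(axis=0, ddof=1) > 0
    if np.linalg.matrix_rank(np.column_stack(
            [np.ones(len(y)), X[:, active]])) < 1 + active.sum():
        raise np.linalg.LinAlgError("collinear (rank-deficient) inputs")

    ols = sm.OLS(y, sm.add_constant(X[:, active])).fit()
    src = np.zeros(X.shape[1])
    src[active] = ols.params[1:] * X[:, active].std(axis=0, ddof=1) \
        / y.std(ddof=1)

    rng = np.random.default_rng(seed)
    boots = np.zeros((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, len(y), size=len(y))
        yb = y[idx]
        if yb.std(ddof=1) == 0:
            boots[b] = src
            continue
        boots[b, active] = _src(X[idx][:, active], yb)
    alpha = (1.0 - ci_level) / 2.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)
    table = pd.DataFrame(
        {"SRC": src, "SRC2": src ** 2, "ci_low": np.minimum(lo, src),
         "ci_high": np.maximum(hi, src)}, index=list(samples.columns))
    return GSAResult(table=table, r_squared=float(ols.rsquared),
                     n_samples=len(y))
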
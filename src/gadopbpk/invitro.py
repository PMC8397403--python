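"""Mechanistic two-compartment (cell/medium) hepatocyte uptake model.

Uptake of gadoxetate into plated rat hepatocytes is modeled as saturable
(Michaelis-Menten) transport plus a nonsaturable bidirectional passive
clearance; only the unbound intracellular fraction is available for passive
efflux.  Per-animal kinetic parameters are estimated by simultaneous least
squares across all nominal medium concentrations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

from .params import InVitroKineticParams, ParameterError

#: Hepatocyte cell volume, uL per 1e6 cells.
V_CELL_DEFAULT = 3.9
#: Medium volume per well of a 24-well plate, uL (config-overridable).
V_MEDIUM_DEFAULT = 500.0
#: Protein content of 1e6 hepatocytes, mg.
MG_PROTEIN_PER_1E6_CELLS = 1.0


class FitError(RuntimeError):
    """Raised when a kinetic fit fails; carries best-so-far parameters."""

    def __init__(self, msg: str, best=None):
        super().__init__(msg)
        self.best = best


@dataclass(frozen=True)
class InVitroState:
    """Initial condition of one well: concentrations in uM, volumes in uL."""

    c_cell: float
    c_medium: float
    V_cell: float = V_CELL_DEFAULT
    V_medium: float = V_MEDIUM_DEFAULT

    def __post_init__(self):
        if self.c_cell < 0 or self.c_medium < 0:
            raise ParameterError("concentrations must be >= 0")
        if self.V_cell <= 0 or self.V_medium <= 0:
            raise ParameterError("volumes must be > 0")


def protein_to_cells(protein_mg):
    """Convert well protein content (mg) to cell count in 1e6-cell units."""
    protein_mg = np.asarray(protein_mg, dtype=float)
    if np.any(protein_mg < 0):
        raise ParameterError("protein content must be >= 0")
    out = protein_mg / MG_PROTEIN_PER_1E6_CELLS
    return float(out) if out.ndim == 0 else out


def lysate_to_conc(amount_pmol, cells, V_cell: float = V_CELL_DEFAULT):
    """Intracellular concentration (uM) from lysate amount (pmol).

    ``cells`` is in 1e6-cell units; V_cell in uL/1e6 cells.
    """
    cells = np.asarray(cells, dtype=float)
    if np.any(cells <= 0):
        raise ZeroDivisionError("cell count must be > 0")
    return np.asarray(amount_pmol, dtype=float) / (cells * V_cell)


def backextrapolate_c0(times, concentrations, cutoff: float = 20.0) -> float:
    """Initial intracellular concentration by OLS back-extrapolation.

    Regress concentration on time over the early points (t <= cutoff min,
    inclusive) and return the intercept at t = 0; negative intercepts are
    clipped to zero with a warning.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    mask = t <= cutoff
    if mask.sum() < 2:
        raise ValueError(f"need >= 2 points with t <= {cutoff} min")
    slope, intercept = np.polyfit(t[mask], c[mask], 1)
    if intercept < 0:
        warnings.warn("negative back-extrapolated c0 clipped to 0")
        intercept = 0.0
    return float(intercept)


def _uptake_rhs(t, y, p: InVitroKineticParams, n_cells, V_cell, V_medium):
    """Flux in pmol/min per 1e6 cells; states are concentrations in uM."""
    c_cell, c_medium = y
    flux = (p.Vmax * c_medium / (p.Km_u + c_medium)
            + p.CLpassive_u * c_medium
            - p.CLpassive_u * p.fu_cell * c_cell)
    return [flux / V_cell, -n_cells * flux / V_medium]


def simulate_uptake(params: InVitroKineticParams, state0: InVitroState,
                    times, n_cells: float = 0.24,
                    rtol: float = 1e-9, atol: float = 1e-12):
    """Solve the coupled cell/medium uptake ODE.

    times are minutes, increasing from t = 0; n_cells is the well
    cellularity in 1e6-cell units.  Returns (c_cell, c_medium) arrays (uM).
    Total amount n_cells*V_cell*c_cell + V_medium*c_medium is conserved.
    """
    t = np.asarray(times, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if n_cells <= 0:
        raise ParameterError("cell count must be > 0")
    if t.size == 0:
        return np.array([]), np.array([])
    t0 = 0.0
    y0 = [state0.c_cell, state0.c_medium]
    if t[0] == t0 and t.size == 1:
        return np.array([y0[0]]), np.array([y0[1]])
    sol = solve_ivp(_uptake_rhs, (t0, t[-1]), y0, t_eval=t, method="LSODA",
                    rtol=rtol, atol=atol,
                    args=(params, n_cells, state0.V_cell, state0.V_medium))
    if not sol.success:
        raise RuntimeError(f"uptake integration failed: {sol.message}")
    return sol.y[0], sol.y[1]


def cl_active_u(Vmax: float, Km_u: float) -> float:
    """Unbound intrinsic active uptake clearance Vmax/Km,u
    (uL/min/1e6 cells), valid for unbound concentrations << Km,u."""
    if Km_u <= 0:
        raise ParameterError("Km_u must be > 0")
    return Vmax / Km_u


def fraction_active(CLactive_u: float, CLpassive_u: float) -> float:
    """Maximum fractional contribution of saturable uptake to total uptake."""
    if CLactive_u < 0 or CLpassive_u < 0:
        raise ParameterError("clearances must be >= 0")
    total = CLactive_u + CLpassive_u
    if total == 0:
        raise ParameterError("fraction_active undefined for two zero clearances")
    return CLactive_u / total


def linear_uptake_clearance(amounts_pmol, times_min, cells: float,
                            c_u: float) -> float:
    """Intrinsic uptake clearance from the initial linear uptake phase.

    Slope of amount (pmol) vs time (min) by OLS, normalized by cell count
    (1e6 cells) and unbound medium concentration (uM); result in
    uL/min/1e6 cells.
    """
    if c_u <= 0:
        raise ParameterError("medium concentration must be > 0")
    t = np.asarray(times_min, dtype=float)
    a = np.asarray(amounts_pmol, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 timepoints")
    slope = np.polyfit(t, a, 1)[0]
    return float(slope / cells / c_u)


# ---------------------------------------------------------------------------
# per-animal simultaneous fitting

_PARAM_NAMES = ("Vmax", "Km_u", "CLpassive_u", "fu_cell")
# log10 bounds wide enough to contain any plausible hepatocyte kinetics
_LOG_BOUNDS = {
    "Vmax": (0.0, 4.0),        # 1 .. 1e4 pmol/min/1e6 cells
    "Km_u": (0.0, 4.0),        # 1 .. 1e4 uM
    "CLpassive_u": (-3.0, 1.0),  # 1e-3 .. 10 uL/min/1e6 cells
    "fu_cell": (-2.0, 0.0),    # 0.01 .. 1
}


@dataclass
class InVitroFitResult:
    params: InVitroKineticParams
    cost: float
    success: bool
    n_obs: int
    residuals: np.ndarray

    @property
    def CLactive_u(self) -> float:
        return cl_active_u(self.params.Vmax, self.params.Km_u)


def _theta_to_params(theta) -> InVitroKineticParams:
    vals = 10.0 ** np.asarray(theta, dtype=float)
    vals[3] = min(vals[3], 1.0)
    return InVitroKineticParams(*vals)


def _predict_c_cell(params, group: pd.DataFrame, V_cell, V_medium, n_cells):
    """Predicted intracellular concentrations for one nominal concentration."""
    times = np.sort(group["time_min"].unique())
    state0 = InVitroState(0.0, float(group["nominal_conc_uM"].iloc[0]),
                          V_cell, V_medium)
    c_cell, _ = simulate_uptake(params, state0, times, n_cells,
                                rtol=1e-8, atol=1e-10)
    lut = dict(zip(times, c_cell))
    return group["time_min"].map(lut).to_numpy()


def fit_invitro(dataset: pd.DataFrame, V_cell: float = V_CELL_DEFAULT,
                V_medium: float = V_MEDIUM_DEFAULT, n_starts: int = 3,
                seed: int = 0) -> dict[int, InVitroFitResult]:
    """Fit the four kinetic parameters per animal, simultaneously across
    all nominal medium concentrations.

    ``dataset`` uses the in vitro CSV dialect (animal, well, nominal_conc_uM,
    time_min, lysate_pmol, protein_mg, censored).  Censored records are
    excluded.  The nominal medium concentration is the initial condition;
    residuals are unweighted on the intracellular concentration scale and the
    parameters are log-transformed to enforce positivity.
    """
    results: dict[int, InVitroFitResult] = {}
    for animal, adata in dataset.groupby("animal"):
        adata = adata.loc[~adata["censored"].astype(bool)].copy()
        if adata["nominal_conc_uM"].nunique() < 3:
            raise FitError(f"animal {animal}: need >= 3 concentrations")
        cells = protein_to_cells(adata["protein_mg"].to_numpy())
        adata["c_cell_obs"] = lysate_to_conc(
            adata["lysate_pmol"].to_numpy(), cells, V_cell)
        n_cells_mean = float(np.mean(cells))
        groups = [g for _, g in adata.groupby("nominal_conc_uM")]

        def residuals(theta):
            p = _theta_to_params(theta)
            res = []
            for g in groups:
                pred = _predict_c_cell(p, g, V_cell, V_medium, n_cells_mean)
                res.append(pred - g["c_cell_obs"].to_numpy())
            return np.concatenate(res)

        lo = np.array([_LOG_BOUNDS[n][0] for n in _PARAM_NAMES])
        hi = np.array([_LOG_BOUNDS[n][1] for n in _PARAM_NAMES])
        starts = [_heuristic_start(adata)]
        if n_starts > 1:
            sampler = qmc.LatinHypercube(d=4, seed=seed)
            extra = qmc.scale(sampler.random(n_starts - 1), lo, hi)
            starts.extend(list(extra))

        best = None
        for x0 in starts:
            try:
                sol = least_squares(residuals, np.clip(x0, lo, hi),
                                    bounds=(lo, hi), xtol=1e-12, ftol=1e-12,
                                    gtol=1e-12)
            except RuntimeError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitError(f"animal {animal}: all starts failed")
        results[animal] = InVitroFitResult(
            params=_theta_to_params(best.x), cost=float(best.cost),
            success=bool(best.status > 0), n_obs=len(adata),
            residuals=best.fun)
    return results


def _heuristic_start(adata: pd.DataFrame) -> np.ndarray:
    """Data-driven starting point: Km near the geometric mid concentration,
    Vmax from the largest early uptake rate."""
    concs = np.sort(adata["nominal_conc_uM"].unique())
    km0 = float(np.sqrt(concs[0] * concs[-1])) / 3.0
    early = adata[adata["time_min"] <= adata["time_min"].quantile(0.3)]
    rate = (early["c_cell_obs"] * V_CELL_DEFAULT / early["time_min"]).max()
    vmax0 = max(float(rate), 10.0)
    return np.log10([vmax0, km0, 0.2, 0.5])


def summarize_fits(results: dict[int, InVitroFitResult]) -> pd.DataFrame:
    """Per-animal parameter table with derived clearances, plus mean and CV%
    columns (layout of a per-animal kinetic summary table)."""
    rows = {}
    for animal, res in sorted(results.items()):
        p = res.params
        cla = cl_active_u(p.Vmax, p.Km_u)
        rows[animal] = {
            "Vmax": p.Vmax, "Km_u": p.Km_u, "CLpassive_u": p.CLpassive_u,
            "fu_cell": p.fu_cell, "CLactive_u": cla,
            "fraction_active": fraction_active(cla, p.CLpassive_u),
            "fraction_passive": 1.0 - fraction_active(cla, p.CLpassive_u),
        }
    table = pd.DataFrame(rows)
    table["mean"] = table.mean(axis=1)
    table["CV%"] = table.drop(columns="mean").std(axis=1, ddof=1) \
        / table["mean"] * 100.0
    return table
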
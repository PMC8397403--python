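"""Reduced 7-compartment gadoxetate PBPK model with a permeability-limited
liver.

Compartments: blood, spleen (extracellular), splanchnic organs
(extracellular), liver extracellular (tissue blood + interstitium),
hepatocytes, and rest-of-body (ROB) vascular and extravascular spaces joined
by a permeability-surface product PS.  Elimination is renal (CL_r from
blood) and biliary (CL_biliary from hepatocytes); cumulative urine and bile
amounts are carried as bookkeeping states.  The system is linear in
concentration, which the tests exploit (matrix-exponential oracle, dose
linearity).

An optional 5-subcompartment liver variant splits the hepatocellular and
extracellular liver spaces into five serial units with clearances and
volumes divided equally, the convention of dispersion-mimicking liver
models.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import DoseEvent, GadoxetateParams, PhysiologyParams


class IntegrationError(RuntimeError):
    pass


class IncompleteSimulationError(RuntimeError):
    pass


def system_matrix(params: GadoxetateParams, phys: PhysiologyParams,
                  liver_model: int = 1) -> np.ndarray:
    """Build M with y' = M y for the full state vector.

    State layout: [c_b, c_rob_v, c_rob_ev, c_spl_extr, c_splan_extr,
    c_liv_extr_1..n, c_liv_cell_1..n, A_urine, A_bile]; concentrations in
    umol/L, amounts in umol.
    """
    if liver_model not in (1, 5):
        raise ValueError("liver_model must be 1 or 5")
    n = liver_model
    p, ph = params, phys
    nstate = 5 + 2 * n + 2
    M = np.zeros((nstate, nstate))
    i_b, i_rv, i_re, i_sp, i_sn = 0, 1, 2, 3, 4
    i_le = [5 + k for k in range(n)]
    i_lc = [5 + n + k for k in range(n)]
    i_ur, i_bi = 5 + 2 * n, 5 + 2 * n + 1

    Q_h = ph.Q_h
    kliv = p.K_liv_extr_b
    # blood: hepatic-vein return + ROB return - arterial outflows - renal
    M[i_b, i_le[-1]] += Q_h / kliv / ph.V_b
    M[i_b, i_rv] += ph.Q_rob / ph.V_b
    M[i_b, i_b] -= (ph.Q_rob + Q_h + p.CL_r) / ph.V_b
    # ROB vascular / extravascular
    M[i_rv, i_b] += ph.Q_rob / ph.V_rob_v
    M[i_rv, i_rv] -= (ph.Q_rob + p.PS) / ph.V_rob_v
    M[i_rv, i_re] += p.PS / ph.V_rob_v
    M[i_re, i_rv] += p.PS / ph.V_rob_ev
    M[i_re, i_re] -= p.PS / ph.V_rob_ev
    # spleen and splanchnic extracellular (flow-limited)
    M[i_sp, i_b] += ph.Q_spl / ph.V_spl_extr
    M[i_sp, i_sp] -= ph.Q_spl / p.K_spl_extr_b / ph.V_spl_extr
    M[i_sn, i_b] += ph.Q_splan / ph.V_splan_extr
    M[i_sn, i_sn] -= ph.Q_splan / p.K_splan_extr_b / ph.V_splan_extr
    # liver: n serial extracellular/hepatocyte pairs
    V_le = ph.V_liv_extr / n
    V_lc = ph.V_liv_cell / n
    cl_up = (p.CL_active + p.CL_passive) / n
    cl_eff = p.CL_passive / n * p.fu_liv_cell
    cl_bil = p.CL_biliary / n * p.fu_liv_cell
    for k in range(n):
        le, lc = i_le[k], i_lc[k]
        if k == 0:
            M[le, i_sp] += ph.Q_spl / p.K_spl_extr_b / V_le
            M[le, i_sn] += ph.Q_splan / p.K_splan_extr_b / V_le
            M[le, i_b] += ph.Q_ha / V_le
        else:
            M[le, i_le[k - 1]] += Q_h / kliv / V_le
        M[le, le] -= (Q_h + cl_up) / kliv / V_le
        M[le, lc] += cl_eff / V_le
        M[lc, le] += cl_up / kliv / V_lc
        M[lc, lc] -= (cl_eff + cl_bil) / V_lc
    # excretion bookkeeping (amounts)
    M[i_ur, i_b] = p.CL_r
    for k in range(n):
        M[i_bi, i_lc[k]] = cl_bil
    return M


def rhs(state, params: GadoxetateParams, phys: PhysiologyParams,
        liver_model: int = 1):
    """Time derivatives of the full state vector (umol/L per h; umol per h)."""
    y = np.asarray(state, dtype=float)
    if np.any(np.isnan(y)):
        raise IntegrationError("NaN in state vector")
    return system_matrix(params, phys, liver_model) @ y


def state_volumes(phys: PhysiologyParams, liver_model: int = 1) -> np.ndarray:
    """Distribution volumes aligned with the concentration states (L);
    the two amount states get weight 1."""
    n = liver_model
    return np.array(
        [phys.V_b, phys.V_rob_v, phys.V_rob_ev, phys.V_spl_extr,
         phys.V_splan_extr]
        + [phys.V_liv_extr / n] * n + [phys.V_liv_cell / n] * n + [1.0, 1.0])


@dataclass
class PBPKTrajectory:
    """Dense solution of one simulation; concentrations in umol/L, t in h."""

    t: np.ndarray
    y: np.ndarray  # (nstate, nt)
    dose: DoseEvent
    phys: PhysiologyParams
    params: GadoxetateParams
    liver_model: int = 1
    _sol: object = field(default=None, repr=False)

    @property
    def c_b(self):
        return self.y[0]

    @property
    def c_rob_v(self):
        return self.y[1]

    @property
    def c_rob_ev(self):
        return self.y[2]

    @property
    def c_spl_extr(self):
        return self.y[3]

    @property
    def c_splan_extr(self):
        return self.y[4]

    @property
    def c_liv_extr(self):
        """Volume-averaged extracellular liver concentration (subunits have
        equal volumes, so this is the plain mean)."""
        n = self.liver_model
        return self.y[5:5 + n].mean(axis=0)

    @property
    def c_liv_cell(self):
        n = self.liver_model
        return self.y[5 + n:5 + 2 * n].mean(axis=0)

    @property
    def A_urine(self):
        return self.y[-2]

    @property
    def A_bile(self):
        return self.y[-1]

    def interpolate(self, t_new) -> "PBPKTrajectory":
        """Evaluate the dense output on a new time grid within the span."""
        t_new = np.asarray(t_new, dtype=float)
        if self._sol is None:
            raise ValueError("trajectory has no dense output")
        if t_new.min() < self.t[0] - 1e-12 or t_new.max() > self.t[-1] + 1e-12:
            raise ValueError("requested times outside simulation span")
        return PBPKTrajectory(t_new, self._sol(t_new), self.dose, self.phys,
                              self.params, self.liver_model, self._sol)

    def mass_balance_error(self) -> float:
        """Max relative deviation of total tracked amount from the dose."""
        vols = state_volumes(self.phys, self.liver_model)
        total = vols @ self.y
        return float(np.max(np.abs(total - self.dose.amount))
                     / self.dose.amount) if self.dose.amount > 0 else \
            float(np.max(np.abs(total)))


def simulate_pbpk(params: GadoxetateParams, phys: PhysiologyParams,
                  dose: DoseEvent, t_grid, liver_model: int = 1,
                  rtol: float = 1e-8, atol: float = 1e-10) -> PBPKTrajectory:
    """Integrate the PBPK system on an increasing time grid (hours).

    A bolus (duration 0) enters as the initial blood concentration
    amount/V_b; a finite-duration infusion adds a constant zero-order input
    to blood during [start, start+duration].
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be increasing with >= 2 points")
    M = system_matrix(params, phys, liver_model)
    nstate = M.shape[0]
    y0 = np.zeros(nstate)
    forcing = None
    if dose.duration == 0:
        y0[0] = dose.amount / phys.V_b
    else:
        rate = dose.amount / dose.duration  # umol/h

        def forcing(tt):
            u = np.zeros(nstate)
            if dose.start <= tt < dose.start + dose.duration:
                u[0] = rate / phys.V_b
            return u

    if forcing is None:
        def fun(tt, y):
            return M @ y
    else:
        def fun(tt, y):
            return M @ y + forcing(tt)

    sol = solve_ivp(fun, (t[0], t[-1]), y0, method="LSODA", t_eval=t,
                    dense_output=True, rtol=rtol, atol=atol,
                    jac=lambda tt, y: M)
    if not sol.success:
        raise IntegrationError(f"PBPK integration failed: {sol.message}")
    if np.any(np.isnan(sol.y)):
        raise IntegrationError("NaN in PBPK solution")
    return PBPKTrajectory(sol.t, sol.y, dose, phys, params, liver_model,
                          sol.sol)


def excretion_fractions(traj: PBPKTrajectory) -> tuple[float, float]:
    """(% of dose in urine, % of dose in bile) at the end of a simulation
    that has run to >= 99% total excretion."""
    dose = traj.dose.amount
    if dose <= 0:
        raise ValueError("dose must be > 0")
    excreted = traj.A_urine[-1] + traj.A_bile[-1]
    if excreted < 0.99 * dose:
        raise IncompleteSimulationError(
            f"only {100 * excreted / dose:.1f}% of dose excreted; "
            "extend the simulation horizon")
    return (100.0 * traj.A_urine[-1] / dose, 100.0 * traj.A_bile[-1] / dose)


def simulate_to_excretion(params: GadoxetateParams, phys: PhysiologyParams,
                          dose: DoseEvent, liver_model: int = 1,
                          horizon: float = 50.0, max_horizon: float = 6400.0
                          ) -> PBPKTrajectory:
    """Simulate with a doubling horizon until >= 99% of the dose has been
    excreted (renal + biliary)."""
    while True:
        t = time_grid(horizon)
        traj = simulate_pbpk(params, phys, dose, t, liver_model)
        if traj.A_urine[-1] + traj.A_bile[-1] >= 0.99 * dose.amount:
            return traj
        horizon *= 2
        if horizon > max_horizon:
            raise IncompleteSimulationError(
                "excretion incomplete after maximum horizon")


def time_grid(t_end: float, t_start: float = 0.0, n: int = 1200) -> np.ndarray:
    """Simulation grid dense at early times (square-root spacing)."""
    u = np.linspace(0.0, 1.0, n)
    return t_start + (t_end - t_start) * u ** 2


def auc(t, c, t0: float, t1: float) -> float:
    """Trapezoidal area of c(t) over [t0, t1] with endpoint interpolation."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if not (t[0] - 1e-12 <= t0 < t1 <= t[-1] + 1e-12):
        raise ValueError("[t0, t1] must lie within the profile support")
    mask = (t > t0) & (t < t1)
    tt = np.concatenate([[t0], t[mask], [t1]])
    cc = np.concatenate([[np.interp(t0, t, c)], c[mask], [np.interp(t1, t, c)]])
    return float(np.trapezoid(cc, tt))
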
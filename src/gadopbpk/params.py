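"""Parameter containers for the gadoxetate hepatic disposition model.

All whole-body clearances and flows are in L/h, volumes in L, concentrations
in umol/L, amounts in umol, times in hours inside the PBPK core.  The in
vitro containers use the assay's native units (pmol, uL, minutes).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class InVitroKineticParams:
    """Hepatocyte uptake kinetics from the plated-hepatocyte assay.

    Vmax : maximum saturable transport rate, pmol/min/1e6 cells.
    Km_u : unbound Michaelis constant, uM.
    CLpassive_u : nonsaturable bidirectional clearance, uL/min/1e6 cells.
    fu_cell : unbound fraction inside the cell (applies to efflux only).
    """

    Vmax: float
    Km_u: float
    CLpassive_u: float
    fu_cell: float

    def __post_init__(self) -> None:
        _require(self.Vmax >= 0, "Vmax must be >= 0")
        _require(self.Km_u > 0, "Km_u must be > 0")
        _require(self.CLpassive_u > 0, "CLpassive_u must be > 0")
        _require(0 < self.fu_cell <= 1, "fu_cell must be in (0, 1]")


@dataclass(frozen=True)
class GadoxetateParams:
    """Whole-body gadoxetate drug parameters (one set per study arm).

    CL_active, CL_passive : active/passive clearance across the hepatocyte
    membrane [L/h]; CL_biliary : hepatocyte-to-bile excretion clearance [L/h];
    CL_r : renal clearance from blood [L/h]; PS : rest-of-body permeability-
    surface product [L/h]; fu_liv_cell : unbound fraction in hepatocytes;
    K_* : extracellular-tissue-to-blood partition coefficients.
    """

    CL_active: float = 2.17
    CL_passive: float = 0.014
    CL_biliary: float = 0.07
    CL_r: float = 0.17
    PS: float = 0.62
    fu_liv_cell: float = 0.648
    K_liv_extr_b: float = 1.0
    K_spl_extr_b: float = 1.0
    K_splan_extr_b: float = 1.0

    def __post_init__(self) -> None:
        for name in ("CL_active", "CL_passive", "CL_biliary", "CL_r", "PS"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(0 < self.fu_liv_cell <= 1, "fu_liv_cell must be in (0, 1]")
        for name in ("K_liv_extr_b", "K_spl_extr_b", "K_splan_extr_b"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")

    def replace(self, **kwargs) -> "GadoxetateParams":
        return dataclasses.replace(self, **kwargs)


#: Table-style bottom-up scaled defaults (IVIVE means; PS and CL_biliary
#: assumed equal to CL_passive when no in vitro measurement exists).
BOTTOM_UP_DEFAULTS = dict(
    CL_active=0.23, CL_passive=0.014, CL_biliary=0.014, PS=0.014,
    CL_r=0.17, fu_liv_cell=0.648,
)

#: Top-down estimates obtained from blood+spleen+liver DCE-MRI profiles.
TOP_DOWN_DEFAULTS = dict(
    CL_active=2.17, CL_passive=0.014, CL_biliary=0.07, PS=0.62,
    CL_r=0.17, fu_liv_cell=0.648,
)


@dataclass(frozen=True)
class PhysiologyParams:
    """Rat compartment volumes [L] and blood flows [L/h].

    Defaults describe a 0.25 kg rat built from standard reference fractions:
    cardiac output 110 mL/min, total liver blood flow 18.3% of cardiac
    output (hepatic artery 2.1%, spleen ~1%, remaining splanchnic organs
    making up the portal vein), blood volume 7.4% of body weight, liver
    40 g/kg.  Extracellular (blood + interstitial) sub-volumes use typical
    tissue vascular/interstitial fractions.  V_liv and V_spl are whole-organ
    volumes used only for the relaxation-rate volume weighting.
    """

    V_b: float = 0.0185
    V_rob_v: float = 0.004
    V_rob_ev: float = 0.035
    V_spl_extr: float = 0.00018
    V_splan_extr: float = 0.002
    V_liv_extr: float = 0.0023
    V_liv_cell: float = 0.0078
    V_liv: float = 0.010
    V_spl: float = 0.0005
    Q_ha: float = 0.14
    Q_spl: float = 0.07
    Q_splan: float = 1.00
    Q_rob: float = 5.39

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _require(getattr(self, f.name) > 0, f"{f.name} must be > 0")

    @property
    def Q_h(self) -> float:
        """Total liver blood flow (hepatic vein outflow) [L/h]."""
        return self.Q_ha + self.Q_spl + self.Q_splan

    @property
    def Q_co(self) -> float:
        """Cardiac output [L/h]."""
        return self.Q_h + self.Q_rob

    def replace(self, **kwargs) -> "PhysiologyParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class DoseEvent:
    """Intravenous gadoxetate dose.

    amount: umol; start/duration in hours; duration 0 means an instantaneous
    bolus implemented as an initial condition in blood.
    """

    amount: float
    start: float = 0.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        _require(self.amount >= 0, "dose amount must be >= 0")
        _require(self.duration >= 0, "dose duration must be >= 0")
        _require(self.start >= 0, "dose start must be >= 0")

    @classmethod
    def bolus_per_kg(cls, dose_per_kg: float = 25.0,
                     body_weight: float = 0.25) -> "DoseEvent":
        """25 umol/kg bolus in a 0.25 kg rat by default."""
        return cls(amount=dose_per_kg * body_weight)


@dataclass(frozen=True)
class RelaxivityTable:
    """Field-strength-dependent relaxivities r1 [L mmol^-1 s^-1].

    Spleen and extracellular-liver relaxivities are taken equal to blood.
    """

    r1_blood: dict = field(default_factory=lambda: {4.7: 6.4, 7.0: 6.2})
    r1_hepatocytes: dict = field(default_factory=lambda: {4.7: 7.6, 7.0: 6.0})

    def __post_init__(self) -> None:
        for table in (self.r1_blood, self.r1_hepatocytes):
            for fs, r1 in table.items():
                _require(r1 > 0, f"relaxivity at {fs} T must be > 0")

    def blood(self, field_strength: float) -> float:
        return self._lookup(self.r1_blood, field_strength)

    def hepatocytes(self, field_strength: float) -> float:
        return self._lookup(self.r1_hepatocytes, field_strength)

    @staticmethod
    def _lookup(table: dict, field_strength: float) -> float:
        for fs, r1 in table.items():
            if abs(fs - field_strength) < 1e-9:
                return r1
        raise ParameterError(
            f"no relaxivity tabulated for field strength {field_strength} T")
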
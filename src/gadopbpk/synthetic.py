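"""Synthetic in vitro uptake and in vivo DCE-MRI datasets with known truth.

The study data (plated-hepatocyte uptake time courses and multi-animal
deltaR1 profiles at 4.7 and 7 T) are not publicly deposited, so every
downstream stage is exercised on synthetic datasets that carry the same
statistical structure: duplicate wells over a 0.01-10 mM concentration
range with LLOQ censoring at 0.2 uM; 57 s frames; lognormal inter-animal
variability on clearances; proportional lognormal noise on assay amounts
and additive Gaussian noise on deltaR1.  Ground truth is always returned
next to the observations, never embedded in them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import invitro
from .params import (DoseEvent, GadoxetateParams, InVitroKineticParams,
                     ParameterError, PhysiologyParams, RelaxivityTable)
from .pbpk import simulate_pbpk
from .mri import (DeltaR1Profile, ORGANS, SECONDS_PER_HOUR, frame_average,
                  frame_time_grid, organ_deltaR1)


class InvalidDesignError(ValueError):
    pass


DEFAULT_CONCENTRATIONS = (10.0, 30.0, 100.0, 300.0, 500.0, 1000.0, 3000.0,
                          10000.0)
DEFAULT_TIMEPOINTS = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 30.0, 60.0, 90.0,
                      120.0, 150.0)


@dataclass(frozen=True)
class InVitroDesign:
    """Plated-hepatocyte uptake assay design (uM, minutes)."""

    nominal_concentrations: tuple = DEFAULT_CONCENTRATIONS
    timepoints: tuple = DEFAULT_TIMEPOINTS
    replicates_per_condition: int = 2
    lloq: float = 0.2
    cells_per_well: float = 2.4e5
    V_medium: float = invitro.V_MEDIUM_DEFAULT
    V_cell: float = invitro.V_CELL_DEFAULT
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if any(c <= 0 for c in self.nominal_concentrations):
            raise InvalidDesignError("concentrations must be > 0")
        if np.any(np.diff(self.timepoints) <= 0):
            raise InvalidDesignError("timepoints must be strictly increasing")
        if self.lloq < 0:
            raise InvalidDesignError("lloq must be >= 0")
        if self.cells_per_well <= 0:
            raise InvalidDesignError("cells_per_well must be > 0")
        if self.V_medium <= 0 or self.V_cell <= 0:
            raise InvalidDesignError("volumes must be > 0")


#: study arm -> field strength (T) -> animal count, as in the source study
DEFAULT_ARM_COUNTS = {
    "control": {4.7: 33, 7.0: 43},
    "rifampicin": {4.7: 7, 7.0: 6},
}


@dataclass(frozen=True)
class InVivoDesign:
    """Multi-animal DCE-MRI study design (seconds, umol/kg, kg)."""

    n_animals_per_arm: dict = field(
        default_factory=lambda: {a: dict(d)
                                 for a, d in DEFAULT_ARM_COUNTS.items()})
    frame_duration: float = 57.0
    scan_duration: float = 1710.0
    dose_per_kg: float = 25.0
    body_weight: float = 0.25
    interanimal_cv: float = 0.2
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.frame_duration <= 0:
            raise InvalidDesignError("frame_duration must be > 0")
        if self.scan_duration < 2 * self.frame_duration:
            raise InvalidDesignError("scan must span at least 2 frames")
        if self.dose_per_kg < 0 or self.body_weight <= 0:
            raise InvalidDesignError(
                "dose must be >= 0 and body weight > 0")

    def frames(self) -> tuple[np.ndarray, np.ndarray]:
        """Full frames fitting within the scan (start/end, seconds)."""
        n = int(np.floor(self.scan_duration / self.frame_duration))
        starts = np.arange(n) * self.frame_duration
        return starts, starts + self.frame_duration


def generate_invitro_dataset(truth: InVitroKineticParams,
                             design: InVitroDesign,
                             animal: int = 1) -> pd.DataFrame:
    """One animal's uptake dataset in the in vitro CSV dialect.

    Lysate amounts are the deterministic uptake solution times the well
    cellularity, corrupted by mean-one proportional lognormal noise;
    records whose back-computed intracellular concentration falls below the
    LLOQ are flagged censored but never altered.
    """
    rng = np.random.default_rng(design.seed)
    n_cells = design.cells_per_well / 1e6  # 1e6-cell units
    sigma = np.sqrt(np.log1p(design.noise_cv ** 2))
    rows = []
    times = np.asarray(design.timepoints, dtype=float)
    for conc in design.nominal_concentrations:
        state0 = invitro.InVitroState(0.0, conc, design.V_cell,
                                      design.V_medium)
        c_cell, _ = invitro.simulate_uptake(truth, state0, times, n_cells)
        amount_true = c_cell * design.V_cell * n_cells  # pmol per well
        for rep in range(design.replicates_per_condition):
            if design.noise_cv > 0:
                mult = rng.lognormal(-0.5 * sigma ** 2, sigma,
                                     size=times.size)
            else:
                mult = np.ones(times.size)
            amount = amount_true * mult
            for t, a in zip(times, amount):
                rows.append({
                    "animal": animal,
                    "well": f"c{conc:g}_r{rep + 1}",
                    "nominal_conc_uM": conc,
                    "time_min": t,
                    "lysate_pmol": a,
                    "protein_mg": n_cells * invitro.MG_PROTEIN_PER_1E6_CELLS,
                })
    table = pd.DataFrame(rows)
    c_back = invitro.lysate_to_conc(table["lysate_pmol"].to_numpy(),
                                    invitro.protein_to_cells(
                                        table["protein_mg"].to_numpy()),
                                    design.V_cell)
    table["censored"] = c_back < design.lloq
    return table


def generate_invitro_study(truths: dict[int, InVitroKineticParams],
                           design: InVitroDesign) -> pd.DataFrame:
    """Multi-animal dataset; per-animal seeds derived from the design seed."""
    seeds = np.random.SeedSequence(design.seed).spawn(len(truths))
    parts = []
    for (animal, truth), ss in zip(sorted(truths.items()), seeds):
        d = InVitroDesign(**{**design.__dict__,
                             "seed": int(ss.generate_state(1)[0] % 2 ** 31)})
        parts.append(generate_invitro_dataset(truth, d, animal=animal))
    return pd.concat(parts, ignore_index=True)


def _animal_params(truth: GadoxetateParams, cv: float,
                   rng: np.random.Generator) -> GadoxetateParams:
    """Lognormal inter-animal variability on the four clearances only."""
    if cv <= 0:
        return truth
    sigma = np.sqrt(np.log1p(cv ** 2))
    draws = {name: getattr(truth, name)
             * rng.lognormal(-0.5 * sigma ** 2, sigma)
             for name in ("CL_active", "CL_passive", "CL_biliary", "CL_r")}
    return truth.replace(**draws)


def generate_dcemri_dataset(truth_control: GadoxetateParams,
                            truth_inhibited: GadoxetateParams | None,
                            physiology: PhysiologyParams,
                            design: InVivoDesign,
                            relaxivity: RelaxivityTable | None = None
                            ) -> tuple[list[DeltaR1Profile], pd.DataFrame]:
    """Multi-animal blood/spleen/liver deltaR1 profiles plus ground truth.

    Per animal, clearances are drawn lognormally around the arm truth;
    frame values are interval means of the forward-simulated deltaR1 over
    each frame plus additive Gaussian noise.  Returns (profiles,
    per-animal ground-truth table).
    """
    relaxivity = relaxivity or RelaxivityTable()
    rng = np.random.default_rng(design.seed)
    t_start, t_end = design.frames()
    t_grid = frame_time_grid(t_start, t_end)
    dose = DoseEvent.bolus_per_kg(design.dose_per_kg, design.body_weight)
    truths = {"control": truth_control, "rifampicin": truth_inhibited}
    profiles: list[DeltaR1Profile] = []
    truth_rows = []
    for arm, counts in design.n_animals_per_arm.items():
        if truths.get(arm) is None:
            raise InvalidDesignError(f"no truth parameters for arm {arm!r}")
        for fs, n_animals in counts.items():
            for i in range(n_animals):
                animal = f"{arm[:3]}_{fs:g}T_{i + 1:02d}"
                p = _animal_params(truths[arm], design.interanimal_cv, rng)
                traj = simulate_pbpk(p, physiology, dose, t_grid)
                truth_rows.append({
                    "animal": animal, "arm": arm, "field_T": fs,
                    "CL_active": p.CL_active, "CL_passive": p.CL_passive,
                    "CL_biliary": p.CL_biliary, "CL_r": p.CL_r, "PS": p.PS,
                    "fu_liv_cell": p.fu_liv_cell,
                })
                for organ in ORGANS:
                    signal = organ_deltaR1(traj, physiology, relaxivity,
                                           organ, fs)
                    means = frame_average(traj.t * SECONDS_PER_HOUR, signal,
                                          t_start, t_end)
                    if design.noise_sd > 0:
                        means = means + rng.normal(0.0, design.noise_sd,
                                                   size=means.size)
                    profiles.append(DeltaR1Profile(
                        animal=animal, organ=organ, field_strength=fs,
                        arm=arm, t_start=t_start.copy(), t_end=t_end.copy(),
                        deltaR1=means))
    return profiles, pd.DataFrame(truth_rows)
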
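"""Shared fixtures: synthetic study datasets generated once per session."""
import numpy as np
import pytest

from gadopbpk import (DoseEvent, FitSpec, GadoxetateParams,
                      InVitroKineticParams, InVivoDesign, PhysiologyParams,
                      RelaxivityTable, fit_control, fit_simultaneous,
                      generate_dcemri_dataset, generate_invitro_dataset)
from gadopbpk.synthetic import InVitroDesign

#: in vitro kinetic truth for one animal (assay-scale units)
ANIMAL1_TRUTH = InVitroKineticParams(Vmax=350.4, Km_u=114.1,
                                     CLpassive_u=0.091, fu_cell=0.759)

#: control-arm whole-body truth (top-down estimates, L/h)
CONTROL_TRUTH = GadoxetateParams(CL_active=2.17, CL_biliary=0.07, PS=0.62,
                                 CL_passive=0.014, fu_liv_cell=0.648,
                                 CL_r=0.17)

#: two-arm DDI truth: shared PS, inhibited uptake under rifampicin
DDI_CONTROL_TRUTH = GadoxetateParams(CL_active=2.38, CL_biliary=0.07,
                                     PS=0.71)
DDI_RIFAMPICIN_TRUTH = DDI_CONTROL_TRUTH.replace(CL_active=0.095,
                                                 CL_biliary=0.08)


@pytest.fixture(scope="session")
def phys():
    return PhysiologyParams()


@pytest.fixture(scope="session")
def relaxivity():
    return RelaxivityTable()


@pytest.fixture(scope="session")
def dose():
    return DoseEvent.bolus_per_kg()


@pytest.fixture(scope="session")
def invitro_noisefree():
    """Noise-free single-animal uptake dataset at the animal-1 truth."""
    design = InVitroDesign(noise_cv=0.0, seed=101)
    return generate_invitro_dataset(ANIMAL1_TRUTH, design), ANIMAL1_TRUTH


@pytest.fixture(scope="session")
def control_noisefree(phys):
    """Noise-free control-arm profiles (one animal per field strength)."""
    design = InVivoDesign(n_animals_per_arm={"control": {4.7: 1, 7.0: 1}},
                          interanimal_cv=0.0, noise_sd=0.0, seed=202)
    profiles, truth_table = generate_dcemri_dataset(CONTROL_TRUTH, None,
                                                    phys, design)
    return profiles, truth_table


@pytest.fixture(scope="session")
def control_fit_noisefree(control_noisefree, phys):
    profiles, _ = control_noisefree
    return fit_control(profiles, FitSpec(seed=1, n_starts=3), phys)


@pytest.fixture(scope="session")
def ddi_noisefree(phys):
    """Noise-free two-arm profiles at the simultaneous-fit truth."""
    design = InVivoDesign(
        n_animals_per_arm={"control": {4.7: 1, 7.0: 1},
                           "rifampicin": {4.7: 1, 7.0: 1}},
        interanimal_cv=0.0, noise_sd=0.0, seed=303)
    profiles, _ = generate_dcemri_dataset(DDI_CONTROL_TRUTH,
                                          DDI_RIFAMPICIN_TRUTH, phys, design)
    return profiles


@pytest.fixture(scope="session")
def ddi_fit_noisefree(ddi_noisefree, phys):
    return fit_simultaneous(ddi_noisefree, None, phys)


@pytest.fixture(scope="session")
def control_noisy(phys):
    """Noisy control arm at the study's animal counts (33 at 4.7 T,
    43 at 7 T), 20% inter-animal CV, 0.1 1/s additive frame noise."""
    design = InVivoDesign(n_animals_per_arm={"control": {4.7: 33, 7.0: 43}},
                          interanimal_cv=0.2, noise_sd=0.1, seed=404)
    profiles, truth_table = generate_dcemri_dataset(CONTROL_TRUTH, None,
                                                    phys, design)
    return profiles, truth_table


def relative_error(estimate, truth):
    return abs(estimate - truth) / abs(truth)
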
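"""Naive-pooled fitting machinery, bootstrap and ablations."""
import numpy as np
import pytest
from dataclasses import replace

from gadopbpk import (FitSpec, GadoxetateParams, InVivoDesign,
                      generate_dcemri_dataset, percent_inhibition)
from gadopbpk.estimation import (EstimationError, _fit, ablation_blood_only,
                                 case_bootstrap, fit_control,
                                 fit_simultaneous, objective)

from conftest import CONTROL_TRUTH, relative_error


class TestObjective:
    def test_self_consistency_zero(self, control_noisefree, phys,
                                   relaxivity):
        profiles, _ = control_noisefree
        ssr = objective({"control": CONTROL_TRUTH}, profiles, phys,
                        relaxivity)
        scale = sum(float(p.deltaR1 @ p.deltaR1) for p in profiles)
        assert ssr / scale < 1e-16

    def test_additive_over_animals(self, control_noisy, phys, relaxivity):
        profiles, _ = control_noisy
        animals = sorted({p.animal for p in profiles})[:2]
        both = [p for p in profiles if p.animal in animals]
        ssr_both = objective({"control": CONTROL_TRUTH}, both, phys,
                             relaxivity)
        ssr_sum = sum(
            objective({"control": CONTROL_TRUTH},
                      [p for p in profiles if p.animal == a], phys,
                      relaxivity)
            for a in animals)
        assert ssr_both == pytest.approx(ssr_sum, rel=1e-12)

    def test_perturbation_increases_objective(self, control_noisefree,
                                              phys, relaxivity):
        profiles, _ = control_noisefree
        at_truth = objective({"control": CONTROL_TRUTH}, profiles, phys,
                             relaxivity)
        perturbed = CONTROL_TRUTH.replace(
            CL_active=1.1 * CONTROL_TRUTH.CL_active)
        away = objective({"control": perturbed}, profiles, phys, relaxivity)
        assert away > at_truth

    def test_order_invariance(self, control_noisy, phys, relaxivity):
        profiles, _ = control_noisy
        sub = profiles[:12]
        a = objective({"control": CONTROL_TRUTH}, sub, phys, relaxivity)
        b = objective({"control": CONTROL_TRUTH}, sub[::-1], phys,
                      relaxivity)
        assert a == pytest.approx(b, rel=1e-14)


class TestFitControl:
    def test_start_at_truth_converges_immediately(self, control_noisefree,
                                                  phys, relaxivity):
        profiles, _ = control_noisefree
        spec = FitSpec(seed=0)
        x0 = np.log10([CONTROL_TRUTH.CL_active, CONTROL_TRUTH.CL_biliary,
                       CONTROL_TRUTH.PS])
        res = _fit(profiles, spec, phys, relaxivity, x0=x0)
        assert res.objective < 1e-16
        for name in spec.free:
            assert relative_error(res.estimates[name],
                                  getattr(CONTROL_TRUTH, name)) < 1e-8

    def test_missing_data_rejected(self, control_noisefree, phys,
                                   relaxivity):
        profiles, _ = control_noisefree
        with pytest.raises(EstimationError):
            fit_control([p for p in profiles if p.arm == "rifampicin"],
                        FitSpec(), phys, relaxivity)


class TestFitSimultaneous:
    def test_identical_arms_give_equal_estimates(self, control_noisefree,
                                                 phys, relaxivity):
        """Duplicating the control data as a mock inhibited arm must yield
        matching arm-specific estimates (symmetry)."""
        from gadopbpk.estimation import replace_animal
        profiles, _ = control_noisefree
        mirrored = []
        for p in profiles:
            mirrored.append(p)
            q = replace_animal(p, p.animal + "_dup")
            q.arm = "rifampicin"
            mirrored.append(q)
        spec = FitSpec(
            free=("PS", "CL_active@control", "CL_biliary@control",
                  "CL_active@rifampicin", "CL_biliary@rifampicin"),
            arms=("control", "rifampicin"), n_starts=2, seed=4)
        res = fit_simultaneous(mirrored, spec, phys, relaxivity)
        assert res.estimates["CL_active@control"] == pytest.approx(
            res.estimates["CL_active@rifampicin"], rel=1e-3)
        assert res.estimates["CL_biliary@control"] == pytest.approx(
            res.estimates["CL_biliary@rifampicin"], rel=1e-2)

    def test_ps_cannot_be_arm_specific(self):
        with pytest.raises(EstimationError):
            FitSpec(free=("PS@control",), arms=("control",))


class TestPercentInhibition:
    @pytest.mark.parametrize("ctrl,inh,expect", [
        (2.38, 0.095, 96.0),   # liver-informed simultaneous fit
        (1.82, 0.29, 84.0),    # blood-only analysis underestimates
        (0.5, 0.5, 0.0)])
    def test_reported_values(self, ctrl, inh, expect):
        assert percent_inhibition(ctrl, inh) == pytest.approx(expect,
                                                              abs=0.5)

    def test_scale_invariance(self):
        base = percent_inhibition(2.38, 0.095)
        for k in (0.1, 3.0, 42.0):
            assert percent_inhibition(2.38 * k, 0.095 * k) == \
                pytest.approx(base, rel=1e-12)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            percent_inhibition(0.0, 0.1)


class TestCaseBootstrap:
    def test_identical_animals_give_near_zero_cv(self, phys, relaxivity):
        design = InVivoDesign(n_animals_per_arm={"control": {4.7: 3}},
                              interanimal_cv=0.0, noise_sd=0.0, seed=6)
        profiles, _ = generate_dcemri_dataset(CONTROL_TRUTH, None, phys,
                                              design)
        spec = FitSpec(seed=0, n_starts=2)
        boot = case_bootstrap(profiles, spec, phys, relaxivity, n_boot=4,
                              seed=3)
        assert (boot.cv_percent < 0.5).all()

    def test_seed_reproducibility(self, control_noisy, phys, relaxivity):
        profiles = [p for p in control_noisy[0]
                    if p.animal.endswith(("01", "02", "03"))]
        spec = FitSpec(seed=0, n_starts=2)
        a = case_bootstrap(profiles, spec, phys, relaxivity, n_boot=3,
                           seed=11)
        b = case_bootstrap(profiles, spec, phys, relaxivity, n_boot=3,
                           seed=11)
        assert a.replicates.equals(b.replicates)

    def test_needs_two_animals(self, phys, relaxivity):
        design = InVivoDesign(n_animals_per_arm={"control": {4.7: 1}},
                              seed=1)
        profiles, _ = generate_dcemri_dataset(CONTROL_TRUTH, None, phys,
                                              design)
        with pytest.raises(EstimationError):
            case_bootstrap(profiles, FitSpec(), phys, relaxivity, n_boot=2)

    def test_interanimal_variability_reflected_in_cv(self, control_noisy,
                                                     phys, relaxivity):
        """20% inter-animal CV on clearances: bootstrap CV of CL_active
        lands in a plausible 1-40% band."""
        profiles = [p for p in control_noisy[0] if "4.7" in p.animal][:36]
        spec = FitSpec(seed=0, n_starts=2)
        boot = case_bootstrap(profiles, spec, phys, relaxivity, n_boot=8,
                              seed=5)
        assert 1.0 < boot.cv_percent["CL_active"] < 40.0


class TestAblation:
    def test_all_organ_path_reproduces_fit_control(self, control_noisefree,
                                                   phys, relaxivity):
        """Re-enabling every organ in the ablation path is the identity."""
        profiles, _ = control_noisefree
        spec = FitSpec(seed=2, n_starts=2)
        direct = fit_control(profiles, spec, phys, relaxivity)
        via_ablation, _ = ablation_blood_only(
            profiles, spec, phys, relaxivity,
            organs=("blood", "spleen", "liver"))
        for name in spec.free:
            assert via_ablation.estimates[name] == pytest.approx(
                direct.estimates[name], rel=1e-6)

    def test_blood_only_estimates_differ_on_noisy_data(self, control_noisy,
                                                       phys, relaxivity):
        profiles = [p for p in control_noisy[0]
                    if p.animal.endswith(("01", "02", "03", "04", "05"))]
        spec = FitSpec(seed=2, n_starts=3)
        full = fit_control(profiles, spec, phys, relaxivity)
        blood, _ = ablation_blood_only(profiles, spec, phys, relaxivity)
        assert blood.estimates["CL_active"] != pytest.approx(
            full.estimates["CL_active"], rel=1e-3)
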
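"""Synthetic rabbit-fiber assay generator and trace synthesizer."""

import numpy as np
import pandas as pd
import pytest

from purkinje_trials.biomarkers import Abnormality, compute_biomarkers, detect_abnormality
from purkinje_trials.synthetic_invitro import (EadSpec, EmaxEffect,
                                               FiberCohortConfig,
                                               SyntheticDoseEffect,
                                               apply_dose_effects,
                                               generate_fiber_cohort,
                                               load_reference_fixtures,
                                               summarize_assay,
                                               synthesize_trace,
                                               validate_assay_table)


class TestFiberCohort:
    def test_large_cohort_recovers_reference_means(self):
        """n=1000 fibers: sample mean APD90 at 1 Hz within 3 SE of 310 ms."""
        cohort = generate_fiber_cohort(FiberCohortConfig(n_fibers=1000, seed=1,
                                                         frequencies_hz=(1.0,)))
        se = 52 / np.sqrt(1000)
        assert cohort.APD90.mean() == pytest.approx(310.0, abs=3 * se)
        assert cohort.APD50.mean() == pytest.approx(239.0, abs=3 * 53 / np.sqrt(1000))

    def test_seeded_determinism(self):
        a = generate_fiber_cohort(FiberCohortConfig(n_fibers=20, seed=9))
        b = generate_fiber_cohort(FiberCohortConfig(n_fibers=20, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_sd_reproduces_means_exactly(self):
        profile = {1.0: {name: (mean, 0.0) for name, mean in
                         dict(APD10=8, APD25=50, APD50=239, APD75=290, APD90=310,
                              dVdtMax=616, APA=129, TOP=-91, EOP=-91).items()}}
        cohort = generate_fiber_cohort(FiberCohortConfig(
            n_fibers=5, seed=0, frequencies_hz=(1.0,), profile=profile))
        assert (cohort.APD90 == 310).all()
        assert (cohort.TOP == -91).all()

    def test_schema_validation_passes(self):
        cohort = generate_fiber_cohort(FiberCohortConfig(n_fibers=4, seed=2))
        validate_assay_table(cohort)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            FiberCohortConfig(n_fibers=0)
        with pytest.raises(ValueError):
            FiberCohortConfig(frequencies_hz=(2.0,))


class TestDoseEffects:
    def _cohort(self, n=10, seed=4):
        return generate_fiber_cohort(FiberCohortConfig(n_fibers=n, seed=seed,
                                                       frequencies_hz=(0.25, 1.0)))

    def test_zero_effect_is_identity(self):
        cohort = self._cohort()
        dosed = apply_dose_effects(cohort, "x", [1.0], SyntheticDoseEffect(), seed=0)
        merged = dosed.merge(cohort, on=["fiber_id", "frequency_hz"],
                             suffixes=("", "_ctrl"))
        assert np.allclose(merged.APD90, merged.APD90_ctrl)
        assert not dosed.ead_flag.any()

    def test_configured_effect_reproduced(self):
        """A +113% APD90 Emax with tiny EC50 reproduces the large rabbit-style
        prolongation at a single high dose."""
        cohort = self._cohort(n=50)
        effect = SyntheticDoseEffect(
            effects={"APD90": EmaxEffect(emax_pct=113.0, ec50_um=0.001)},
            noise_sd_frac=0.0)
        dosed = apply_dose_effects(cohort, "x", [10.0], effect, seed=0)
        summary = summarize_assay(cohort, dosed)
        row = summary[summary.frequency_hz == 1.0].iloc[0]
        assert row.pct_APD90 == pytest.approx(113.0, abs=0.1)

    def test_certain_ead_probability_flags_all_fibers_slow_only(self):
        cohort = self._cohort()
        effect = SyntheticDoseEffect(ead_probability={3.0: 1.0})
        dosed = apply_dose_effects(cohort, "x", [1.0, 3.0], effect, seed=0)
        top_slow = dosed[(dosed.concentration_um == 3.0) & (dosed.frequency_hz == 0.25)]
        top_normal = dosed[(dosed.concentration_um == 3.0) & (dosed.frequency_hz == 1.0)]
        assert top_slow.ead_flag.all()
        assert not top_normal.ead_flag.any()

    def test_descending_concentrations_rejected(self):
        with pytest.raises(ValueError):
            apply_dose_effects(self._cohort(), "x", [3.0, 1.0],
                               SyntheticDoseEffect(), seed=0)

    def test_emax_recovery_with_noise(self):
        """200 fibers, 5% multiplicative noise: the recovered mean percent
        change matches the configured Emax effect within 2 points."""
        cohort = generate_fiber_cohort(FiberCohortConfig(n_fibers=200, seed=6,
                                                         frequencies_hz=(1.0,)))
        effect = SyntheticDoseEffect(
            effects={"APD90": EmaxEffect(emax_pct=30.0, ec50_um=1.0)},
            noise_sd_frac=0.05)
        dosed = apply_dose_effects(cohort, "x", [100.0], effect, seed=13)
        summary = summarize_assay(cohort, dosed)
        expected = effect.effects["APD90"].pct_at(100.0)
        assert summary.pct_APD90.iloc[0] == pytest.approx(expected, abs=2.0)

    def test_generator_determinism(self):
        cohort = self._cohort()
        effect = SyntheticDoseEffect(
            effects={"APD90": EmaxEffect(20.0, 1.0)}, ead_probability={1.0: 0.5})
        a = apply_dose_effects(cohort, "x", [1.0], effect, seed=3)
        b = apply_dose_effects(cohort, "x", [1.0], effect, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestTraceSynthesis:
    RABBIT_1HZ = {"TOP": -91.0, "APA": 129.0, "dVdtMax": 616.0,
                  "APD50": 239.0, "APD90": 310.0}

    def test_round_trip_rabbit_targets(self):
        trace = synthesize_trace(self.RABBIT_1HZ, cycle_length=1000.0)
        bm = compute_biomarkers(trace)
        assert bm.APD90 == pytest.approx(310.0, abs=3.0)
        assert bm.APD50 == pytest.approx(239.0, abs=2.5)
        assert bm.TOP == pytest.approx(-91.0, abs=0.1)
        assert bm.APA == pytest.approx(129.0, rel=0.01)
        assert bm.dVdtMax == pytest.approx(616.0, rel=0.01)
        assert detect_abnormality(trace) is Abnormality.NONE

    def test_full_apd_ladder_round_trip(self):
        targets = {"TOP": -85.0, "APA": 110.0, "dVdtMax": 400.0,
                   "APD10": 20.0, "APD25": 80.0, "APD50": 200.0,
                   "APD75": 250.0, "APD90": 280.0}
        bm = compute_biomarkers(synthesize_trace(targets))
        for level in (10, 25, 50, 75, 90):
            assert getattr(bm, f"APD{level}") == pytest.approx(
                targets[f"APD{level}"], rel=0.01, abs=1.0)

    def test_inserted_ead_is_detected(self):
        # bump at 250 ms: between APD50 and APD90, membrane still above the
        # repolarized level, so the event reads as an EAD (not a DAD)
        trace = synthesize_trace(self.RABBIT_1HZ, ead_spec=EadSpec(250.0, 15.0))
        assert detect_abnormality(trace) is Abnormality.EAD

    def test_late_diastolic_bump_is_dad(self):
        trace = synthesize_trace(self.RABBIT_1HZ, ead_spec=EadSpec(700.0, 12.0))
        assert detect_abnormality(trace) is Abnormality.DAD

    def test_unsatisfiable_targets_rejected(self):
        with pytest.raises(ValueError):
            synthesize_trace({"APD50": 300.0, "APD90": 250.0})  # misordered
        with pytest.raises(ValueError):
            synthesize_trace({"APD90": 990.0}, cycle_length=1000.0)  # no room
        with pytest.raises(ValueError):
            synthesize_trace({})  # no APD target at all


class TestReferenceFixtures:
    def test_fixture_shape(self):
        fx = load_reference_fixtures()
        assert len(fx.drugs) == 14
        assert len(fx.outcomes) == 14
        risky = fx.outcomes.tdp_class.isin(["1", "2"])
        assert int(risky.sum()) == 11

    def test_control_reference_has_both_species_and_rates(self):
        ref = load_reference_fixtures().biomarker_reference
        for species in ("rabbit_invitro", "human_insilico"):
            assert set(ref[species]) == {0.25, 1.0, 3.0}
            for freq in ref[species]:
                assert set(ref[species][freq]) == {"APD90", "APD50", "dVdtMax",
                                                   "APA", "TOP"}

    def test_fixture_drug_names_match_library(self):
        fx = load_reference_fixtures()
        assert set(fx.outcomes.index) == {d.name for d in fx.drugs}
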
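"""Latin hypercube sampling and population calibration."""

import numpy as np
import pytest
from scipy import stats

from purkinje_trials.biomarkers import BiomarkerSet
from purkinje_trials.cell_model import CurrentId, ScalingVector
from purkinje_trials.population import (CalibrationRanges, Candidate,
                                        SamplingConfig, build_candidates,
                                        calibrate, lhs_sample)

from conftest import (PREPACE_BEATS, SLOW_ONLY_ABNORMAL,
                      population_from_rows, scaling_row, wide_ranges)


class TestLatinHypercube:
    def test_one_sample_per_bin_small(self):
        config = SamplingConfig(n_initial=4, seed=7)
        samples = lhs_sample(config)
        assert samples.shape == (4, 12)
        edges = np.linspace(0.5, 2.0, 5)
        for dim in range(12):
            counts, _ = np.histogram(samples[:, dim], bins=edges)
            assert np.all(counts == 1)

    def test_single_sample_in_range(self):
        samples = lhs_sample(SamplingConfig(n_initial=1, seed=3))
        assert samples.shape == (1, 12)
        assert np.all((samples >= 0.5) & (samples <= 2.0))

    def test_seeded_determinism(self):
        a = lhs_sample(SamplingConfig(n_initial=50, seed=11))
        b = lhs_sample(SamplingConfig(n_initial=50, seed=11))
        assert np.array_equal(a, b)

    def test_one_sample_per_bin_and_marginal_uniformity_n200(self):
        """Each of the 12 marginals is stratified and passes KS at the 1% level."""
        n = 200
        samples = lhs_sample(SamplingConfig(n_initial=n, seed=5))
        edges = np.linspace(0.5, 2.0, n + 1)
        for dim in range(12):
            counts, _ = np.histogram(samples[:, dim], bins=edges)
            assert np.all(counts == 1)
            ks = stats.kstest(samples[:, dim], stats.uniform(0.5, 1.5).cdf)
            assert ks.pvalue > 0.01

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SamplingConfig(n_initial=0)
        with pytest.raises(ValueError):
            SamplingConfig(low=2.0, high=0.5)


class TestCalibrationRanges:
    def test_all_nine_biomarkers_required(self):
        with pytest.raises(ValueError, match="missing"):
            CalibrationRanges({"APD90": (100, 400)})

    def test_min_below_max_required(self):
        bad = {name: (0.0, 1.0) for name in
               ("APD10", "APD25", "APD50", "APD75", "APD90",
                "dVdtMax", "APA", "TOP", "EOP")}
        bad["APD90"] = (400.0, 100.0)
        with pytest.raises(ValueError, match="min"):
            CalibrationRanges(bad)

    def test_yaml_round_trip(self, tmp_path):
        ranges = wide_ranges()
        path = tmp_path / "ranges.yaml"
        ranges.to_yaml(path)
        assert CalibrationRanges.from_yaml(path).ranges == ranges.ranges


def _fake_candidate(index, **biomarkers):
    defaults = dict(APD10=2.0, APD25=5.0, APD50=210.0, APD75=225.0, APD90=230.0,
                    dVdtMax=380.0, APA=113.0, TOP=-85.5, EOP=-86.0)
    defaults.update(biomarkers)
    return Candidate(index, ScalingVector.ones(),
                     state_1hz=None, biomarkers_1hz=BiomarkerSet(**defaults))


class TestCalibrateFilter:
    """Desk-scale filter behavior via constructed candidates (no simulation)."""

    def test_inside_ranges_retained(self, model):
        pop = calibrate(model, [_fake_candidate(0)], wide_ranges(),
                        extra_frequencies=())
        assert len(pop) == 1 and not pop.exclusions

    def test_apd90_out_of_range_excluded_with_reason(self, model):
        ranges = wide_ranges()
        ranges.ranges["APD90"] = (171.0, 391.0)
        pop = calibrate(model, [_fake_candidate(3, APD90=500.0)], ranges,
                        extra_frequencies=())
        assert len(pop) == 0
        assert pop.exclusions[0][0] == 3
        assert "APD90 out of range" in pop.exclusions[0][1]

    def test_failed_integration_excluded_not_raised(self, model):
        cand = Candidate(9, ScalingVector.ones(), failure="blew up")
        pop = calibrate(model, [cand], wide_ranges(), extra_frequencies=())
        assert len(pop) == 0 and "integration failure" in pop.exclusions[0][1]

    def test_empty_candidate_list_rejected(self, model):
        with pytest.raises(ValueError):
            calibrate(model, [], wide_ranges())

    def test_retained_subset_order_and_idempotence(self, model):
        cands = [_fake_candidate(0), _fake_candidate(1, APD90=500.0),
                 _fake_candidate(2), _fake_candidate(3, TOP=-50.0)]
        ranges = wide_ranges()
        ranges.ranges["APD90"] = (100.0, 400.0)
        ranges.ranges["TOP"] = (-95.0, -70.0)
        pop = calibrate(model, cands, ranges, extra_frequencies=())
        assert [m.index for m in pop.members] == [0, 2]
        again = calibrate(model, [Candidate(m.index, m.scalings, m.control_states.get(1.0),
                                            m.control_biomarkers[1.0])
                                  for m in pop.members],
                          ranges, extra_frequencies=())
        assert [m.index for m in again.members] == [0, 2]


class TestSimulatedCalibration:
    def test_baseline_candidate_matches_baseline_model(self, model, steady_1hz):
        from purkinje_trials.biomarkers import analyze_beat
        from purkinje_trials.cell_model import PacingProtocol
        cands = build_candidates(model, scaling_row()[None, :],
                                 prepace_beats=PREPACE_BEATS)
        assert cands[0].failure is None
        _, trace = model.pace(steady_1hz, PacingProtocol(1.0, 1))
        baseline = analyze_beat(trace)
        assert cands[0].biomarkers_1hz.APD90 == pytest.approx(baseline.APD90, rel=1e-12)

    def test_small_lhs_candidates_have_finite_biomarkers(self, model):
        samples = lhs_sample(SamplingConfig(n_initial=6, seed=2))
        cands = build_candidates(model, samples, prepace_beats=10)
        assert len(cands) == 6
        for c in cands:
            assert c.failure is None
            bm = c.biomarkers_1hz
            if bm.is_normal:
                assert np.isfinite(bm.APD90) and np.isfinite(bm.dVdtMax)

    def test_slow_pacing_control_abnormality_excluded(self, model):
        """A profile normal at 1 Hz but with an EAD at 0.25 Hz in control is
        rejected with a slow-pacing reason."""
        pop = population_from_rows(model, [scaling_row(SLOW_ONLY_ABNORMAL)],
                                   extra_frequencies=(0.25,))
        assert len(pop) == 0
        assert "0.25 Hz" in pop.exclusions[0][1]


class TestPopulationContainer:
    def test_hash_changes_with_membership(self, model, mixed_population):
        full_hash = mixed_population.population_hash()
        import copy
        smaller = copy.copy(mixed_population)
        smaller.members = mixed_population.members[:-1]
        assert smaller.population_hash() != full_hash

    def test_csv_and_manifest_export(self, tmp_path, mixed_population):
        import json
        import pandas as pd
        mixed_population.to_csv(tmp_path / "pop.csv")
        mixed_population.write_manifest(tmp_path / "manifest.json")
        df = pd.read_csv(tmp_path / "pop.csv")
        assert len(df) == len(mixed_population)
        assert set(c.name for c in CurrentId) <= set(df.columns)
        doc = json.loads((tmp_path / "manifest.json").read_text())
        assert doc["population_hash"] == mixed_population.population_hash()
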
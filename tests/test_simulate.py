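"""Synthetic cohort generator: ground-truth structure and noise moments."""
import numpy as np
import pytest

from nodulephylo import (Grade, SimulationConfig, ValidationError, expected_vaf,
                         filter_high_confidence, simulate_patient)
from nodulephylo.simulate import truth_to_json
from nodulephylo.types import check_no_overlap


class TestExpectedVaf:
    @pytest.mark.parametrize("purity,ccf,vaf", [
        (1.0, 1.0, 0.5),   # clonal het variant, pure tumor
        (0.6, 1.0, 0.3),
        (0.0, 1.0, 0.0),
        (0.8, 0.5, 0.2),
    ])
    def test_values(self, purity, ccf, vaf):
        assert expected_vaf(purity, ccf) == pytest.approx(vaf)

    @pytest.mark.parametrize("purity,ccf", [(1.2, 0.5), (-0.1, 0.5), (0.5, 2.0)])
    def test_out_of_range_rejected(self, purity, ccf):
        with pytest.raises(ValidationError):
            expected_vaf(purity, ccf)


class TestTruthStructure:
    def test_zero_rates_give_empty_tumors(self):
        config = SimulationConfig(n_trunk_snv=0, n_private_snv=0,
                                  n_cnv_events=0, poisson_counts=False, seed=1)
        truth, variants, segments, samples = simulate_patient(config, 0)
        for s in samples:
            assert truth.snv[s.sample_id] == {}
            assert truth.cnv[s.sample_id] == []
            assert variants[s.sample_id] == []

    def test_linear_fixed_counts_jaccard(self, linear_patient):
        """50 fixed trunk + 10 private per nodule, 2 nodules: the true sets
        share exactly the trunk, giving Jaccard 50/70."""
        _, (truth, _, _, samples) = linear_patient
        tumor = [s.sample_id for s in samples if s.grade.is_tumor]
        assert len(tumor) == 2
        a, b = (set(truth.snv[t]) for t in tumor)
        assert len(a & b) == 50
        assert len(a | b) == 70
        assert len(a & b) / len(a | b) == pytest.approx(50 / 70)

    def test_linear_trunk_is_clonal(self, linear_patient):
        _, (truth, _, _, samples) = linear_patient
        tumor = [s.sample_id for s in samples if s.grade.is_tumor]
        shared = truth.shared_snv_keys(tumor)
        for t in tumor:
            assert all(truth.snv[t][k] == 1.0 for k in shared)

    def test_independent_model_shares_nothing(self):
        config = SimulationConfig(model="independent", n_private_snv=50, seed=2)
        truth, _, _, samples = simulate_patient(config, 0)
        tumor = [s.sample_id for s in samples if s.grade.is_tumor]
        assert truth.shared_snv_keys(tumor) == set()

    def test_cirrhosis_has_no_somatic_events(self):
        config = SimulationConfig(seed=3)
        truth, variants, segments, samples = simulate_patient(config, 0)
        cirr = next(s.sample_id for s in samples if s.grade is Grade.CIRRHOSIS)
        assert truth.snv[cirr] == {} and truth.cnv[cirr] == []
        assert variants[cirr] == [] and segments[cirr] == []

    def test_cnv_segments_never_overlap(self):
        config = SimulationConfig(n_cnv_events=15, cnv_event_length=400_000,
                                  seed=4)
        truth, _, segments, samples = simulate_patient(config, 0)
        for sid in segments:
            check_no_overlap(segments[sid])  # raises on violation

    def test_grade_multipliers_scale_private_load(self):
        config = SimulationConfig(
            model="independent", n_private_snv=40, poisson_counts=False,
            grade_rate_multipliers={Grade.HCC: 3.0}, seed=6,
        )
        truth, _, _, samples = simulate_patient(config, 0)
        by_grade = {s.grade: len(truth.snv[s.sample_id]) for s in samples}
        assert by_grade[Grade.HCC] == 3 * by_grade[Grade.LGDN] == 120


@pytest.fixture(scope="module")
def big_clonal_sample():
    """>= 1000 clonal sites in one nodule for moment checks."""
    config = SimulationConfig(
        model="linear", n_trunk_snv=1500, n_private_snv=0,
        poisson_counts=False, purity=0.7, seed=7,
    )
    _, variants, _, samples = simulate_patient(config, 0)
    tumor = next(s.sample_id for s in samples if s.grade.is_tumor)
    return config, variants[tumor]


class TestObservationNoise:
    def test_mean_vaf_matches_expectation(self, big_clonal_sample):
        config, calls = big_clonal_sample
        vafs = np.array([v.vaf for v in calls])
        assert len(vafs) >= 1000
        assert abs(vafs.mean() - expected_vaf(config.purity, 1.0)) < 0.02

    def test_mean_depth_matches_configuration(self, big_clonal_sample):
        config, calls = big_clonal_sample
        depths = np.array([v.depth for v in calls])
        assert abs(depths.mean() - config.mean_depth) < 3.0

    def test_independent_model_post_filter_overlap_is_zero(self):
        config = SimulationConfig(model="independent", n_private_snv=50, seed=8)
        _, variants, _, samples = simulate_patient(config, 0)
        tumor = [s.sample_id for s in samples if s.grade.is_tumor]
        kept = [
            {v.key for v in filter_high_confidence(variants[t])} for t in tumor
        ]
        assert set.intersection(*kept) == set()

    def test_linear_post_filter_jaccard_near_truth(self, linear_patient):
        """Sequencing noise plus the high-confidence filter moves the
        observed trunk Jaccard less than 0.1 from the true 50/70."""
        _, (truth, variants, _, samples) = linear_patient
        tumor = [s.sample_id for s in samples if s.grade.is_tumor]
        kept = [
            {v.key for v in filter_high_confidence(variants[t])} for t in tumor
        ]
        observed = len(kept[0] & kept[1]) / len(kept[0] | kept[1])
        assert abs(observed - 50 / 70) < 0.1


class TestReproducibility:
    def test_identical_config_bytes(self):
        config = SimulationConfig(seed=12)
        a = simulate_patient(config, 1)
        b = simulate_patient(config, 1)
        assert truth_to_json(a[0]) == truth_to_json(b[0])
        assert a[1] == b[1] and a[2] == b[2] and a[3] == b[3]

    def test_patients_are_independent_streams(self):
        config = SimulationConfig(seed=12)
        truth0 = simulate_patient(config, 0)[0]
        truth1 = simulate_patient(config, 1)[0]
        assert truth_to_json(truth0) != truth_to_json(truth1)
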
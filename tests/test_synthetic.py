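"""Generator correctness: stationarity, analytic ground truth, cohorts."""

import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov

from phistress.iit_core import Bipartition, estimate_lagged_gaussian
from phistress.synthetic import (
    CHANNELS,
    CONDITIONS,
    RATING_ITEMS,
    ArtifactSpec,
    EffectModel,
    SyntheticSpec,
    generate_cohort,
    generate_recording,
    ground_truth,
)


class TestSpecValidation:
    def test_unstable_transition_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            SyntheticSpec(transition=np.eye(5) * 1.01)

    def test_non_contiguous_phases_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            SyntheticSpec(
                phases=(("Pre", 0.0, 500.0), ("Task", 600.0, 2400.0),
                        ("Post", 2400.0, 3300.0))
            )

    def test_defaults_are_study_scale(self):
        spec = SyntheticSpec()
        assert spec.fps == 500.0
        assert spec.phases[0][2] == 600.0 and spec.phases[-1][2] == 3300.0
        assert spec.channels == CHANNELS


class TestGenerateRecording:
    def test_seed_determinism(self, reduced_spec):
        a = generate_recording(reduced_spec, "Easy", seed=5)
        b = generate_recording(reduced_spec, "Easy", seed=5)
        assert a.equals(b)
        c = generate_recording(reduced_spec, "Easy", seed=6)
        assert not a.equals(c)

    def test_zero_transition_identity_innovation_is_white(self):
        spec = SyntheticSpec.reduced(
            transition=np.zeros((5, 5)),
            innovation=np.eye(5),
            task_multipliers={c: 1.0 for c in CONDITIONS},
        )
        rec = generate_recording(spec, "Moderate", seed=0)
        x = rec[list(CHANNELS)].to_numpy()
        cov = np.cov(x.T)
        assert np.allclose(cov, np.eye(5), atol=0.05)

    def test_sample_covariance_solves_lyapunov(self, reduced_spec):
        rec = generate_recording(reduced_spec, "Moderate", seed=3)
        pre = rec[rec.time_s < 60.0][list(CHANNELS)].to_numpy()
        a = reduced_spec.phase_transition("Pre", "Moderate")
        sigma = solve_discrete_lyapunov(a, reduced_spec.innovation)
        cov = np.cov(pre.T)
        assert np.allclose(cov, sigma, atol=0.25 * np.abs(sigma).max() + 0.1)

    def test_baseline_phase_is_covariance_stationary(self, moderate_recording):
        pre = moderate_recording[moderate_recording.time_s < 60.0][
            list(CHANNELS)
        ].to_numpy()
        half = len(pre) // 2
        c1, c2 = np.cov(pre[:half].T), np.cov(pre[half:].T)
        assert np.abs(c1 - c2).max() < 0.35

    def test_artifact_pulses_are_added(self):
        spec = SyntheticSpec.reduced(
            artifact=ArtifactSpec(period_s=100.0, amplitude=50.0, width_s=2.0)
        )
        rec = generate_recording(spec, "Moderate", seed=1)
        t = rec["time_s"].to_numpy()
        on = (t >= 100.0) & (t < 102.0)
        off = (t >= 110.0) & (t < 112.0)
        assert rec.loc[on, "Fz"].mean() - rec.loc[off, "Fz"].mean() > 25.0


class TestGroundTruth:
    def test_block_diagonal_truth_has_zero_phi_across_cut(self):
        a = np.zeros((5, 5))
        np.fill_diagonal(a, 0.5)
        a[0, 1] = a[1, 0] = 0.3  # Fz <-> Cz
        a[1, 2] = a[2, 1] = 0.15  # Cz <-> Pz
        a[2, 3] = a[3, 2] = 0.2  # Pz <-> ECG; EDA stays fully independent
        q = np.eye(5)
        spec = SyntheticSpec.reduced(
            transition=a, innovation=q, task_multipliers={c: 1.0 for c in CONDITIONS}
        )
        gt = ground_truth(spec, "Moderate", tau=1)
        truth = gt.phases["Pre"]
        # EDA is fully independent: the MIP cuts it off at Phi* = 0
        assert truth.mip.phi_mip == pytest.approx(0.0, abs=1e-9)
        assert truth.mip.mip == Bipartition.of(
            ("EDA",), ("Fz", "Cz", "Pz", "ECG")
        )

    def test_coupled_pair_is_the_main_complex(self):
        a = 0.02 * np.ones((5, 5)) + np.diag([0.5] * 5)
        a[0, 1] = a[1, 0] = 0.4  # Fz <-> Cz
        spec = SyntheticSpec.reduced(
            transition=a, task_multipliers={c: 1.0 for c in CONDITIONS}
        )
        gt = ground_truth(spec, "Moderate", tau=1)
        mains = gt.phases["Pre"].complexes.main_complexes
        assert frozenset(("Fz", "Cz")) in mains

    def test_truth_matches_estimation_at_scale(self, reduced_spec):
        gt = ground_truth(reduced_spec, "Moderate", tau=1)
        rec = generate_recording(reduced_spec, "Moderate", seed=8)
        pre = rec[rec.time_s < 60.0][list(CHANNELS)].to_numpy()
        m = estimate_lagged_gaussian(pre, tau=1, nodes=CHANNELS)
        truth = gt.phases["Pre"]
        assert np.allclose(m.cov_present, truth.sigma, atol=0.3)
        assert np.allclose(m.cov_cross, truth.cov_cross, atol=0.3)


class TestCohort:
    def test_cohort_is_complete_and_planted_params_saved(self, reduced_spec):
        cohort = generate_cohort(reduced_spec, n_participants=2, seed=0)
        assert set(cohort.recordings) == {
            (p, c) for p in ("P01", "P02") for c in CONDITIONS
        }
        r = cohort.ratings
        assert len(r) == 2 * 3 * 3 * len(RATING_ITEMS)
        assert r["value"].between(0, 100).all()
        assert len(cohort.planted["u"]) == 2
        assert cohort.planted["multipliers"].shape == (2, 3)

    def test_null_effect_model_removes_condition_differences(self, reduced_spec):
        cohort = generate_cohort(
            reduced_spec, n_participants=2, effect=EffectModel.null(), seed=1
        )
        mult = cohort.planted["multipliers"].to_numpy(dtype=float)
        assert np.allclose(mult, 1.0)

    def test_single_participant_boundary(self, reduced_spec):
        from phistress.scores import correlate_scores

        cohort = generate_cohort(reduced_spec, n_participants=1, seed=2)
        assert len(cohort.recordings) == 3
        with pytest.raises(ValueError, match="at least 3"):
            correlate_scores([1.0], [2.0])

    def test_rating_loading_plants_correlation_with_latent(self, reduced_spec):
        from phistress.scores import rating_deltas

        cohort = generate_cohort(reduced_spec, n_participants=40, seed=3)
        deltas = rating_deltas(cohort.ratings)
        boring = (
            deltas[(deltas.condition == "Easy") & (deltas.item == "Boring")]
            .set_index("participant")["dr"]
            .loc[cohort.planted["participants"]]
        )
        r = np.corrcoef(boring.to_numpy(), cohort.planted["u"])[0, 1]
        assert r > 0.35  # population rho = 0.6, n = 40
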
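"""Model space: bases, enumeration, comparison, updating, trajectories."""

import numpy as np
import pytest

from synaptrack.inversion import Posterior
from synaptrack.model_space import (
    FLAG_NAMES,
    ModelSpec,
    bayesian_update,
    compare_models,
    enumerate_models,
    expand_parameters,
    extract_trajectories,
    temporal_basis,
)
from synaptrack.priors import SP_SELF, CMCParameters


class TestTemporalBasis:
    def test_canonical_shape_and_rank(self):
        X = temporal_basis(9, 9, 3)
        assert X.shape == (18, 8)
        assert np.linalg.matrix_rank(X) == 8

    def test_order_zero_gives_segment_constants(self):
        X = temporal_basis(5, 5, 0)
        assert X.shape == (10, 2)
        assert np.allclose(X[:5, 0], X[0, 0]) and np.all(X[:5, 1] == 0)
        assert np.allclose(X[5:, 1], X[5, 1]) and np.all(X[5:, 0] == 0)

    def test_columns_orthonormal_within_segments(self):
        X = temporal_basis(9, 9, 3)
        assert np.allclose(X.T @ X, np.eye(8), atol=1e-10)

    def test_infeasible_geometry(self):
        with pytest.raises(ValueError):
            temporal_basis(3, 9, 3)


class TestEnumerateModels:
    def test_sixteen_models(self):
        models = enumerate_models()
        assert len(models) == 16
        assert len({m.model_id for m in models}) == 16

    def test_binary_counting_order(self):
        models = enumerate_models()
        assert models[0].flags == (False, False, False, False)  # null model
        assert models[-1].flags == (True, True, True, True)  # saturated
        assert models[12].flags == (True, True, False, False)

    def test_deterministic(self):
        a = [m.model_id for m in enumerate_models()]
        b = [m.model_id for m in enumerate_models()]
        assert a == b


class TestExpandParameters:
    basis = temporal_basis(3, 3, 1)

    def test_zero_coefficients_identical_windows(self):
        base = CMCParameters.zeros()
        out = expand_parameters(base, {"forward": np.zeros(4)}, self.basis)
        for p in out:
            for k in p.blocks:
                assert np.array_equal(p.blocks[k], base.blocks[k])

    def test_only_flagged_field_changes(self):
        base = CMCParameters.zeros()
        coef = {"intrinsic_primary": np.array([1.0, 0.0, 0.5, 0.0])}
        out = expand_parameters(base, coef, self.basis)
        for p in out:
            assert np.array_equal(p.blocks["extrinsic"], base.blocks["extrinsic"])
            ref = p.blocks["intrinsic"].copy()
            ref[0, SP_SELF] = 0.0
            assert np.array_equal(ref, base.blocks["intrinsic"])

    def test_constant_pre_column_shifts_pre_windows_equally(self):
        coef = np.zeros(4)
        coef[0] = 2.0  # constant column of the pre segment
        out = expand_parameters(CMCParameters.zeros(), {"forward": coef}, self.basis)
        fw = [p.blocks["extrinsic"][0] for p in out]
        assert np.allclose(fw[:3], fw[0]) and fw[0] != 0
        assert np.allclose(fw[3:], 0.0)

    def test_mismatched_coefficients_rejected(self):
        with pytest.raises(ValueError):
            expand_parameters(CMCParameters.zeros(), {"forward": np.zeros(3)}, self.basis)
        with pytest.raises(ValueError):
            expand_parameters(CMCParameters.zeros(), {"nope": np.zeros(4)}, self.basis)


class TestCompareModels:
    def test_equal_evidence_splits_evenly(self):
        res = compare_models({"a": [10.0], "b": [10.0]})
        assert res.probabilities["a"] == pytest.approx(0.5)

    def test_three_nats_is_twenty_to_one(self):
        res = compare_models({"a": [3.0], "b": [0.0]})
        odds = res.probabilities["a"] / res.probabilities["b"]
        assert odds == pytest.approx(np.exp(3.0), rel=1e-12)
        assert round(odds) == 20

    def test_pooling_adds_session_evidence(self):
        res = compare_models({"a": [1.0, 1.0, 1.0], "b": [0.0, 0.0, 0.0]})
        assert res.pooled["a"] - res.pooled["b"] == pytest.approx(3.0)

    def test_invariant_to_constant_shift(self):
        e = {"a": [3.0, 1.0], "b": [0.5, 0.2], "c": [-1.0, 2.0]}
        shifted = {k: [f + 123.4 for f in v] for k, v in e.items()}
        p1 = compare_models(e).probabilities
        p2 = compare_models(shifted).probabilities
        for k in p1:
            assert p1[k] == pytest.approx(p2[k], rel=1e-9)

    def test_incomplete_models_excluded(self):
        res = compare_models({"a": [1.0, 2.0], "b": None, "c": [1.0, np.nan], "d": [0.0]})
        assert set(res.probabilities) == {"a"}
        assert set(res.excluded) == {"b", "c", "d"}
        assert res.probabilities["a"] == pytest.approx(1.0)


def _toy_posterior(mean, cov, base_entries, coef_slices, converged=True):
    n = len(mean)
    return Posterior(
        mean=np.asarray(mean, dtype=float),
        cov=np.asarray(cov, dtype=float),
        free_energy=-10.0,
        accuracy=-8.0,
        complexity=2.0,
        trace=[-12.0, -10.0],
        converged=converged,
        base_entries=base_entries,
        coef_slices=coef_slices,
        labels=[str(i) for i in range(n)],
    )


class TestBayesianUpdate:
    def test_carried_parameter_updates_prior(self, priors):
        post = _toy_posterior(
            [0.7, -0.1],
            [[0.04, 0.01], [0.01, 0.02]],
            [("intrinsic", (0, SP_SELF)), ("gain", (0,))],
            {},
        )
        new = bayesian_update(post, priors)
        assert new.log_means["intrinsic"][0, SP_SELF] == pytest.approx(0.7)
        assert new.variances["intrinsic"][0, SP_SELF] == pytest.approx(0.04)

    def test_gain_resets_to_original_prior(self, priors):
        post = _toy_posterior(
            [0.7, -0.1],
            [[0.04, 0.01], [0.01, 0.02]],
            [("intrinsic", (0, SP_SELF)), ("gain", (0,))],
            {},
        )
        new = bayesian_update(post, priors)
        assert new.log_means["gain"][0] == priors.log_means["gain"][0]
        assert new.variances["gain"][0] == priors.variances["gain"][0]

    def test_joint_covariance_carried(self, priors):
        post = _toy_posterior(
            [0.7, 0.2],
            [[0.04, 0.015], [0.015, 0.09]],
            [("intrinsic", (0, SP_SELF)), ("intrinsic", (1, SP_SELF))],
            {},
        )
        new = bayesian_update(post, priors)
        names, cov = new.joint
        assert ("intrinsic", (0, SP_SELF)) in names
        assert cov[0, 1] == pytest.approx(0.015)

    def test_refuses_non_converged(self, priors):
        post = _toy_posterior([0.0], [[1.0]], [("gamma", ())], {}, converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            bayesian_update(post, priors)


class TestExtractTrajectories:
    spec = ModelSpec(flags=(True, False, False, False), order=1, n_pre=3, n_post=3)

    def _posterior(self, cov_scale):
        basis = self.spec.basis()
        n = 1 + basis.shape[1]
        mean = np.concatenate([[0.3], np.array([1.0, -0.2, 0.5, 0.1])])
        cov = cov_scale * np.eye(n)
        return _toy_posterior(
            mean, cov, [("intrinsic", (0, SP_SELF))],
            {"intrinsic_primary": slice(1, 1 + basis.shape[1])},
        )

    def test_zero_covariance_gives_zero_width_intervals(self):
        traj = extract_trajectories(self._posterior(0.0), self.spec)
        est = traj.params["intrinsic_primary"]
        assert np.allclose(est["lo90"], est["mean"])
        assert np.allclose(est["hi90"], est["mean"])

    def test_interval_centred_on_projected_mean(self):
        post = self._posterior(0.2)
        traj = extract_trajectories(post, self.spec)
        est = traj.params["intrinsic_primary"]
        basis = self.spec.basis()
        expected = post.mean[0] + basis @ post.mean[1:]
        assert np.allclose(est["mean"], expected)
        assert np.allclose(est["hi90"] - est["mean"], est["mean"] - est["lo90"])

    def test_frame_export(self, tmp_path):
        traj = extract_trajectories(self._posterior(0.1), self.spec, label="s1")
        df = traj.to_frame()
        assert set(df.columns) >= {"session", "window", "parameter", "mean", "lo90", "hi90"}
        assert len(df) == 6
        traj.to_csv(tmp_path / "t.csv")
        assert (tmp_path / "t.csv").exists()


class TestFlagBookkeeping:
    def test_flag_names_cover_model_spec(self):
        spec = ModelSpec(flags=(True, True, False, False))
        assert spec.flagged == ["intrinsic_primary", "intrinsic_secondary"]
        assert spec.model_id == "for-1100"
        assert len(FLAG_NAMES) == 4
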
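"""gPPI estimation: oracle equivalence, parameter recovery, symmetrization."""

import numpy as np
import pytest

from wmnet.gppi import (
    ConditionConnectivity,
    build_psych_matrix,
    devectorize_edges,
    gppi_fit,
    gppi_matrix,
    vectorize_edges,
)
from wmnet.simulate import (
    GroundTruth,
    simulate_design,
    simulate_roi_bold,
    study1_config,
)

from .oracles import normal_equation_betas

CONDS = ["encode", "maintain", "probe"]


@pytest.fixture(scope="module")
def run_setup():
    cfg = study1_config(
        n_subjects=1, n_runs=1, n_rois=3, noise_sd=1e-5, drift_amplitude=0.0, seed=5
    )
    events = simulate_design(cfg)
    X = build_psych_matrix(events, CONDS, cfg.n_scans, cfg.tr_s)
    return cfg, events, X


class TestBuildPsychMatrix:
    def test_one_column_per_condition(self, run_setup):
        cfg, events, X = run_setup
        assert X.shape == (cfg.n_scans, 3)

    def test_column_sums_equal_duration_in_scans(self, run_setup):
        cfg, events, X = run_setup
        # 18 trials x 10 s per stage at TR 2 s -> 90 scans worth of signal
        assert np.allclose(X.sum(axis=0), 18 * 10 / cfg.tr_s)

    def test_empty_condition_set_rejected(self, run_setup):
        cfg, events, _ = run_setup
        with pytest.raises(ValueError, match="non-empty"):
            build_psych_matrix(events, [], cfg.n_scans, cfg.tr_s)

    def test_absent_condition_rejected(self, run_setup):
        cfg, events, _ = run_setup
        with pytest.raises(ValueError, match="matches no events"):
            build_psych_matrix(events, ["rehearse"], cfg.n_scans, cfg.tr_s)


class TestGppiFit:
    def _bold(self, cfg, events, coupling_val=0.8):
        coup = np.zeros((3, 3))
        coup[1, 2] = coupling_val
        truth = GroundTruth(
            activation_amplitudes={"encode": np.array([0.0, 1.0, 0.0])},
            coupling={"maintain": coup},
        )
        return simulate_roi_bold(events, truth, cfg, np.random.default_rng(1))

    def test_recovers_injected_coupling_to_1e6(self, run_setup):
        cfg, events, X = run_setup
        bold = self._bold(cfg, events)
        m = gppi_fit(bold.data[:, 2], bold.data[:, 1], X, bold.nuisance, cfg.tr_s, CONDS)
        est = dict(zip(m.conditions, m.beta_j))
        assert abs(est["maintain"] - 0.8) < 1e-6
        assert abs(est["encode"]) < 1e-6 and abs(est["probe"]) < 1e-6

    def test_oracle_equivalence_with_normal_equations(self, run_setup):
        """Estimator matches an explicit (X'X)^-1 X'y solve to 1e-8."""
        cfg, events, X = run_setup
        bold = self._bold(cfg, events)
        from wmnet.gppi import _convolve_psych, _interaction_design

        hx = _convolve_psych(X, cfg.tr_s)
        X_full, _, n_base = _interaction_design(
            bold.data[:, 1], hx, bold.nuisance, CONDS
        )
        oracle = normal_equation_betas(X_full, bold.data[:, 2])
        m = gppi_fit(bold.data[:, 2], bold.data[:, 1], X, bold.nuisance, cfg.tr_s, CONDS)
        assert np.allclose(m.beta_j, oracle[n_base:], atol=1e-8)

    def test_independent_white_noise_target_gives_null_betas(self, run_setup):
        cfg, events, X = run_setup
        rng = np.random.default_rng(2)
        n = cfg.n_scans
        betas = []
        for _ in range(20):
            m = gppi_fit(
                rng.normal(size=n), rng.normal(size=n), X, None, cfg.tr_s, CONDS
            )
            betas.append(m.beta_j)
        assert abs(np.mean(betas)) < 0.05

    def test_constant_source_rejected_as_collinear(self, run_setup):
        cfg, events, X = run_setup
        rng = np.random.default_rng(3)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            gppi_fit(
                rng.normal(size=cfg.n_scans),
                np.ones(cfg.n_scans),
                X,
                None,
                cfg.tr_s,
                CONDS,
            )

    def test_bias_and_rmse_shrink_with_noise(self):
        """Recovery curve: RMSE decreases monotonically as noise drops."""
        rmses = []
        for noise in (1.0, 0.3, 0.03):
            cfg = study1_config(
                n_subjects=1, n_runs=1, n_rois=3,
                noise_sd=noise, drift_amplitude=0.0, seed=6,
            )
            events = simulate_design(cfg)
            X = build_psych_matrix(events, CONDS, cfg.n_scans, cfg.tr_s)
            errs = []
            for rep in range(8):
                bold = simulate_roi_bold(
                    events,
                    GroundTruth(
                        activation_amplitudes={"encode": np.array([0.0, 1.0, 0.0])},
                        coupling={"maintain": _coup(0.8)},
                    ),
                    cfg,
                    np.random.default_rng(100 + rep),
                )
                m = gppi_fit(
                    bold.data[:, 2], bold.data[:, 1], X, bold.nuisance, cfg.tr_s, CONDS
                )
                errs.append(dict(zip(m.conditions, m.beta_j))["maintain"] - 0.8)
            rmses.append(np.sqrt(np.mean(np.square(errs))))
        assert rmses[0] > rmses[1] > rmses[2]
        assert abs(np.mean(errs)) < 0.01  # lowest-noise bias

    def test_shuffled_psych_matrix_destroys_recovery(self, run_setup):
        cfg, events, X = run_setup
        bold = self._bold(cfg, events)
        rng = np.random.default_rng(4)
        X_shuf = X[rng.permutation(cfg.n_scans)]
        m = gppi_fit(
            bold.data[:, 2], bold.data[:, 1], X_shuf, bold.nuisance, cfg.tr_s, CONDS
        )
        est = dict(zip(m.conditions, m.beta_j))
        assert abs(est["maintain"]) < 0.1


def _coup(v):
    c = np.zeros((3, 3))
    c[1, 2] = v
    return c


class TestGppiMatrix:
    def test_edge_is_mean_of_the_two_directed_fits(self, run_setup):
        """Undirected edge equals (beta(i->j) + beta(j->i)) / 2."""
        cfg = study1_config(
            n_subjects=1, n_runs=1, n_rois=2, noise_sd=0.8, drift_amplitude=0.0, seed=8
        )
        events = simulate_design(cfg)
        X = build_psych_matrix(events, CONDS, cfg.n_scans, cfg.tr_s)
        coup = np.array([[0.0, 0.6], [0.0, 0.0]])  # asymmetric coupling
        truth = GroundTruth(coupling={"maintain": coup})
        bold = simulate_roi_bold(events, truth, cfg, np.random.default_rng(2))
        fwd = gppi_fit(bold.data[:, 1], bold.data[:, 0], X, bold.nuisance, cfg.tr_s, CONDS)
        rev = gppi_fit(bold.data[:, 0], bold.data[:, 1], X, bold.nuisance, cfg.tr_s, CONDS)
        conn = gppi_matrix(bold, X, bold.nuisance, conditions=CONDS)
        k = CONDS.index("maintain")
        expected = (fwd.beta_j[k] + rev.beta_j[k]) / 2
        assert conn.matrices["maintain"][0, 1] == pytest.approx(expected, abs=1e-10)

    def test_output_symmetric_with_nan_diagonal(self, run_setup):
        cfg, events, X = run_setup
        truth = GroundTruth(
            activation_amplitudes={"encode": np.array([1.0, 0.5, 0.2])},
            coupling={"maintain": _coup(0.5)},
        )
        cfg2 = study1_config(
            n_subjects=1, n_runs=1, n_rois=3, noise_sd=0.5, drift_amplitude=0.0, seed=7
        )
        bold = simulate_roi_bold(events, truth, cfg2, np.random.default_rng(0))
        conn = gppi_matrix(bold, X, bold.nuisance, conditions=CONDS)
        for mat in conn.matrices.values():
            off = ~np.eye(3, dtype=bool)
            assert np.allclose(mat[off], mat.T[off])
            assert np.all(np.isnan(np.diag(mat)))

    def test_single_roi_rejected(self, run_setup):
        cfg, events, X = run_setup
        from wmnet.types import BoldData

        bold = BoldData(data=np.random.default_rng(0).normal(size=(cfg.n_scans, 1)), tr=cfg.tr_s)
        with pytest.raises(ValueError, match=">= 2 ROIs"):
            gppi_matrix(bold, X)


class TestEdgeVectorization:
    def _conn(self, n=4):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(n, n))
        m = (m + m.T) / 2
        names = [f"r{i}" for i in range(n)]
        return ConditionConnectivity(matrices={"maintain": m}, roi_names=names)

    def test_4_rois_give_6_edge_features(self):
        stack = vectorize_edges(self._conn(4))
        assert stack.n_features == 6

    def test_round_trip_reproduces_off_diagonal(self):
        conn = self._conn(5)
        stack = vectorize_edges(conn)
        back = devectorize_edges(stack.features[0], 5)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(back[off], conn.matrices["maintain"][off])

    def test_edge_names_stable_across_calls(self):
        a = vectorize_edges(self._conn(4)).feature_names
        b = vectorize_edges(self._conn(4)).feature_names
        assert a == b == ["r0--r1", "r0--r2", "r0--r3", "r1--r2", "r1--r3", "r2--r3"]

    def test_asymmetric_input_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1], m[1, 0] = 1.0, 2.0
        with pytest.raises(ValueError):
            ConditionConnectivity(matrices={"x": m}, roi_names=["a", "b", "c"])
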
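"""Deconvolution, interaction designs, and the difference matrix."""

import numpy as np
import pytest

from taskconnectome.glm import build_design
from taskconnectome.gppi import (Deconvolver, DifferenceMatrix, PpiBetaStack,
                                 bonferroni_edge_threshold, build_gppi_design,
                                 deconvolve, difference_matrix,
                                 fit_gppi_all_targets, run_gppi_subject)
from taskconnectome.hrf import HRF, boxcar, convolve_hrf
from taskconnectome.synth import (GroundTruth, SynthConfig,
                                  generate_task_design,
                                  generate_task_timeseries)

TR = 0.72


@pytest.fixture
def design():
    return generate_task_design(tr=TR, n_volumes=176, n_sessions=1)


class TestDeconvolve:
    def test_round_trip_on_convolved_boxcar(self):
        box = boxcar([10, 60], [21, 21], TR, 176)
        bold = convolve_hrf(box, HRF(), TR)
        _, r2 = deconvolve(bold, TR, regularization=1.0)
        assert r2 > 0.99

    def test_infinite_regularization_kills_output(self):
        bold = np.sin(np.arange(176) / 5)
        neural, _ = deconvolve(bold, TR, regularization=1e12)
        assert np.abs(neural).max() < 1e-6

    def test_r2_decreases_monotonically_with_regularization(self, rng):
        bold = rng.standard_normal(176)
        r2s = [Deconvolver(176, TR, regularization=lam)(bold)[1]
               for lam in (0.01, 1.0, 100.0, 1e4)]
        assert all(a >= b for a, b in zip(r2s, r2s[1:]))

    def test_zero_variance_input_warns(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            neural, r2 = deconvolve(np.ones(100), TR)
        assert np.allclose(neural, 0)


class TestGppiDesign:
    def test_one_ppi_column_per_condition(self, design, rng):
        seed = rng.standard_normal(176)
        X = build_gppi_design(seed, design, 1)
        assert X.names.count("ppi_emotion") == 1
        assert X.names.count("ppi_shape") == 1
        assert "seed" in X.names
        assert "emotion" in X.names and "shape" in X.names

    def test_single_condition_rejected(self, rng):
        d = generate_task_design(tr=TR, n_volumes=176, n_sessions=1,
                                 conditions=("emotion",))
        with pytest.raises(ValueError, match="condition set"):
            build_gppi_design(rng.standard_normal(176), d, 1)

    def test_zero_seed_degenerate(self, design):
        with pytest.warns(UserWarning, match="zero-variance"):
            with pytest.raises(np.linalg.LinAlgError):
                X = build_gppi_design(np.zeros(176), design, 1)

    def test_ppi_column_not_collinear_with_seed(self, design, rng):
        seed = rng.standard_normal(176)
        X = build_gppi_design(seed, design, 1)
        ppi = X.values[:, X.names.index("ppi_emotion")]
        s = X.values[:, X.names.index("seed")]
        assert abs(np.corrcoef(ppi, s)[0, 1]) < 1.0 - 1e-6


class TestFitAllTargets:
    def test_seed_target_is_nan(self, design, rng):
        Y = rng.standard_normal((176, 5))
        X = build_gppi_design(Y[:, 2], design, 1)
        out = fit_gppi_all_targets(2, Y, X)
        assert np.isnan(out["emotion"][2])
        assert np.isfinite(np.delete(out["emotion"], 2)).all()

    def test_null_betas_near_zero_on_average(self, design, rng):
        betas = []
        for _ in range(20):
            Y = rng.standard_normal((176, 4))
            X = build_gppi_design(Y[:, 0], design, 1)
            betas.append(np.delete(fit_gppi_all_targets(0, Y, X)["emotion"], 0))
        b = np.concatenate(betas)
        assert abs(b.mean()) < 2 * b.std() / np.sqrt(b.size) + 0.05


class TestDifferenceMatrix:
    def test_full_scale_threshold_arithmetic(self):
        n_tests, thr = bonferroni_edge_threshold(273, 0.05)
        assert n_tests == 74256
        assert thr == pytest.approx(6.7335e-07, rel=1e-4)

    def test_all_zero_betas_give_empty_matrix(self):
        stacks = [PpiBetaStack(betas=np.zeros((6, 6, 2, 2)),
                               conditions=("emotion", "shape"))
                  for _ in range(5)]
        dm = difference_matrix(stacks)
        assert np.count_nonzero(dm.values) == 0

    def test_planted_signs_recovered(self, rng):
        # strong subject-level effects at two cells, opposite signs
        stacks = []
        for _ in range(30):
            b = rng.normal(0, 0.05, size=(6, 6, 2, 2))
            b[0, 1, 0, :] += 2.0   # emotion beta up for 0->1
            b[2, 3, 0, :] -= 2.0   # emotion beta down for 2->3
            stacks.append(PpiBetaStack(betas=b, conditions=("emotion", "shape")))
        dm = difference_matrix(stacks)
        assert dm.values[0, 1] == 1
        assert dm.values[2, 3] == -1
        assert np.count_nonzero(dm.values) == 2

    def test_directionality_independent(self, rng):
        stacks = []
        for _ in range(30):
            b = rng.normal(0, 0.05, size=(5, 5, 2, 1))
            b[1, 4, 0, :] += 2.0
            stacks.append(PpiBetaStack(betas=b, conditions=("emotion", "shape")))
        dm = difference_matrix(stacks)
        assert dm.values[1, 4] == 1 and dm.values[4, 1] == 0

    def test_reproducible_from_saved_stacks(self, rng):
        stacks = [PpiBetaStack(betas=rng.normal(size=(5, 5, 2, 2)),
                               conditions=("emotion", "shape"))
                  for _ in range(6)]
        a = difference_matrix(stacks)
        b = difference_matrix(stacks)
        assert np.array_equal(a.values, b.values)

    def test_entry_validation(self):
        v = np.zeros((3, 3), dtype=int)
        v[0, 1] = 2
        with pytest.raises(ValueError, match="row 0, column 1"):
            DifferenceMatrix(values=v)

    def test_needs_three_subjects(self, rng):
        stacks = [PpiBetaStack(betas=rng.normal(size=(4, 4, 2, 1)),
                               conditions=("emotion", "shape"))] * 2
        with pytest.raises(ValueError, match="3 subjects"):
            difference_matrix(stacks)


class TestSubjectRunner:
    def test_batched_matches_reference_path(self):
        # the vectorized cohort path must agree with the per-seed design path
        from taskconnectome.prep import ar1_coefficient, highpass_dct
        cfg = SynthConfig(n_nodes=8, n_modules=2, n_subjects=1)
        truth = GroundTruth.from_config(cfg)
        design = generate_task_design(tr=cfg.tr, n_volumes=176, n_sessions=1)
        ts, nuis = generate_task_timeseries(cfg, design, truth, 11)
        stack = run_gppi_subject(ts, design, nuisance=nuis.to_numpy())
        tsf = highpass_dct(ts, 200.0)
        Y = tsf.values
        base = build_design(design, 1, nuisance=nuis.to_numpy())
        b0, *_ = np.linalg.lstsq(base.values, Y, rcond=None)
        resid = Y - base.values @ b0
        rho = float(ar1_coefficient(resid).mean())
        cond = base.columns("condition")
        Y_adj = base.values[:, cond] @ b0[cond] + resid
        dec = Deconvolver(176, cfg.tr)
        for seed in (0, 5):
            X = build_gppi_design(Y_adj[:, seed], design, 1,
                                  nuisance=nuis.to_numpy(), deconvolver=dec)
            Xw = X.values[1:] - rho * X.values[:-1]
            Yw = Y[1:] - rho * Y[:-1]
            beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
            ref = beta[X.names.index("ppi_emotion")]
            got = stack.betas[seed, :, 0, 0]
            keep = np.arange(8) != seed
            assert np.allclose(got[keep], ref[keep], atol=1e-10)

    def test_planted_edge_beats_control_condition(self):
        # emotion-PPI beta exceeds shape-PPI beta for the planted edge
        cfg = SynthConfig(n_nodes=10, n_modules=2, n_subjects=1,
                          ppi_edges=((1, 7, "emotion", 1.5),))
        truth = GroundTruth.from_config(cfg)
        design = generate_task_design(tr=cfg.tr, n_volumes=176, n_sessions=2)
        wins = 0
        for seed in range(20):
            ts, nuis = generate_task_timeseries(cfg, design, truth, seed)
            st = run_gppi_subject(ts, design, nuisance=nuis.to_numpy())
            emo = st.betas[1, 7, 0, :].mean()
            sha = st.betas[1, 7, 1, :].mean()
            wins += emo > sha
        assert wins >= 19
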
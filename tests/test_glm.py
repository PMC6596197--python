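"""First-level GLM tests: design construction, filtering, estimation."""

import numpy as np
import pytest

from seqobs import design, glm, synth

TR = 2.6
T = 136


class TestDesignMatrix:
    def test_mvpa8_columns(self, scanning_schedule):
        X = glm.build_design(scanning_schedule.blocks_or_runs[0], "mvpa8", TR, T)
        seq_cols = [l for l in X.labels if l.startswith("seq_")]
        assert seq_cols == [f"seq_{i}" for i in range(8)]
        assert set(X.labels) - set(seq_cols) == {"error_video", "question", "cue"}

    def test_boxcar_sums_two_videos_per_sequence(self, scanning_schedule):
        """Each sequence's pre-convolution boxcar covers 2 x 13/2.6 = 10 volumes."""
        X = glm.build_design(scanning_schedule.blocks_or_runs[0], "mvpa8", TR, T)
        for q, label in enumerate(X.labels):
            if label.startswith("seq_"):
                assert X.boxcars[:, q].sum() == 2 * int(np.ceil(13.0 / TR))

    def test_univariate6_columns(self, scanning_schedule):
        X = glm.build_design(scanning_schedule.blocks_or_runs[0], "univariate6", TR, T)
        assert X.labels == glm.UNIVARIATE6_LABELS

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            glm.build_design([], "mvpa8", TR, T)

    def test_event_beyond_run_end_rejected(self):
        ev = [design.TrialEvent(onset=T * TR - 5.0, duration=13.0, label="video", sequence_id=0)]
        with pytest.raises(ValueError):
            glm.build_design(ev, "mvpa8", TR, T)

    def test_nuisance_can_be_dropped(self, scanning_schedule):
        X = glm.build_design(
            scanning_schedule.blocks_or_runs[0], "mvpa8", TR, T, include_nuisance=False
        )
        assert X.labels == [f"seq_{i}" for i in range(8)]


class TestHighpass:
    def test_constant_series_removed(self):
        out = glm.highpass(np.full(T, 7.3), TR)
        assert np.abs(out).max() < 1e-10

    @pytest.mark.parametrize(
        "freq,check",
        [(0.005, "attenuated"), (0.1, "preserved")],
    )
    def test_frequency_response(self, freq, check):
        """Amplitude below the 1/52 Hz cutoff is removed, above is kept.

        Measured by the FFT amplitude at the probe frequency before and
        after filtering.
        """
        n = 512
        t = np.arange(n) * TR
        x = np.sin(2 * np.pi * freq * t)
        y = glm.highpass(x, TR)
        k = int(round(freq * n * TR))
        amp_in = np.abs(np.fft.rfft(x))[k]
        amp_out = np.abs(np.fft.rfft(y))[k]
        if check == "attenuated":
            assert amp_out < 0.1 * amp_in
        else:
            assert amp_out == pytest.approx(amp_in, rel=0.05)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            glm.highpass(np.zeros(T), TR, cutoff=0.3)


class TestFit:
    def test_noiseless_recovery(self, rng):
        X = glm.DesignMatrix(
            X=rng.standard_normal((40, 3)),
            boxcars=np.ones((40, 3)),
            labels=["a", "b", "c"],
            tr=TR,
        )
        b_true = rng.standard_normal((3, 5))
        fit = glm.fit(X.X @ b_true, X, highpass_cutoff=None)
        assert np.allclose(fit.betas, b_true, atol=1e-10)

    def test_matches_normal_equations(self, rng):
        """Tiny 6x2 system equals the closed-form (X'X)^-1 X'y solution."""
        Xm = rng.standard_normal((6, 2))
        y = rng.standard_normal((6, 1))
        X = glm.DesignMatrix(X=Xm, boxcars=Xm, labels=["a", "b"], tr=TR)
        fit = glm.fit(y, X, highpass_cutoff=None)
        oracle = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        assert np.allclose(fit.betas, oracle, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        Xm = rng.standard_normal((50, 4))
        y = rng.standard_normal((50, 7))
        X = glm.DesignMatrix(X=Xm, boxcars=Xm, labels=list("abcd"), tr=TR)
        fit = glm.fit(y, X, highpass_cutoff=None)
        assert np.abs(Xm.T @ fit.residuals).max() < 1e-8

    def test_rank_deficient_rejected(self, rng):
        col = rng.standard_normal((30, 1))
        Xm = np.hstack([col, col])
        X = glm.DesignMatrix(X=Xm, boxcars=Xm, labels=["a", "b"], tr=TR)
        with pytest.raises(ValueError):
            glm.fit(rng.standard_normal(30), X, highpass_cutoff=None)

    def test_gls_beats_ols_under_ar1(self, rng):
        """With AR(1) noise, prewhitened GLS betas have lower variance."""
        n, reps, rho = 120, 200, 0.6
        Xm = rng.standard_normal((n, 2))
        X = glm.DesignMatrix(X=Xm, boxcars=Xm, labels=["a", "b"], tr=TR)
        ols_b, gls_b = [], []
        for _ in range(reps):
            e = np.empty(n)
            e[0] = rng.standard_normal()
            for t in range(1, n):
                e[t] = rho * e[t - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
            y = e[:, None]  # true betas are zero
            ols_b.append(glm.fit(y, X, whiten="none", highpass_cutoff=None).betas[:, 0])
            gls_b.append(glm.fit(y, X, whiten="ar1", highpass_cutoff=None).betas[:, 0])
        assert np.var(gls_b, axis=0).sum() < np.var(ols_b, axis=0).sum()


class TestContrast:
    def _fits(self, rng, n_runs=3):
        Xm = rng.standard_normal((30, 3))
        X = glm.DesignMatrix(X=Xm, boxcars=Xm, labels=["a", "b", "c"], tr=TR)
        return [
            glm.fit(rng.standard_normal((30, 3)), X, highpass_cutoff=None)
            for _ in range(n_runs)
        ]

    def test_sum_of_two_conditions(self, rng):
        fits = self._fits(rng)
        got = glm.contrast(fits, {"a": 0.5, "b": 0.5})
        mean = np.mean([f.betas for f in fits], axis=0)
        assert np.allclose(got, 0.5 * mean[0] + 0.5 * mean[1], atol=1e-12)

    def test_zero_weights(self, rng):
        fits = self._fits(rng)
        assert np.allclose(glm.contrast(fits, {}), 0.0)

    def test_unknown_label_rejected(self, rng):
        with pytest.raises(ValueError):
            glm.contrast(self._fits(rng), {"zzz": 1.0})


class TestEndToEnd:
    def test_zero_noise_recovery_through_pipeline(self, scanning_schedule, small_truth):
        """simulate -> GLM with no noise recovers the generating betas."""
        study = synth.simulate_bold(
            scanning_schedule, small_truth, "pre", seed=3, noise_scale=0.0
        )
        for y, X, B in zip(study.bold_runs[:3], study.designs[:3], study.true_betas[:3]):
            fit = glm.fit(y, X)
            assert np.abs(fit.betas - B).max() < 1e-6
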
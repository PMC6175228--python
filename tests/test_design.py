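"""Design-matrix construction: HRF, blocks, drift, physiological regressors."""

import numpy as np
import pytest

from fastwhiten.design import (
    DesignMatrix,
    EventSchedule,
    PhysioTrace,
    amplitude_regressors,
    assemble_design,
    block_regressor,
    canonical_hrf,
    dct_drift_basis,
    physio_fourier_regressors,
)


class TestCanonicalHrf:
    def test_peak_near_five_seconds(self):
        dt = 0.1
        h = canonical_hrf(dt)
        assert abs(np.argmax(h) * dt - 5.0) <= dt + 1e-9

    def test_zero_at_origin_and_unit_peak(self):
        h = canonical_hrf(0.5)
        assert h[0] == 0.0
        assert h.max() == 1.0

    def test_undershoot(self):
        h = canonical_hrf(0.2)
        assert h.min() < 0
        assert abs(h.min()) < h.max() / 4

    @pytest.mark.parametrize("dt", [0, -1, 5])
    def test_invalid_dt(self, dt):
        with pytest.raises(ValueError):
            canonical_hrf(dt)


class TestBlockRegressor:
    def test_empty_schedule_gives_zeros(self):
        sched = EventSchedule(onsets=[], durations=[])
        np.testing.assert_array_equal(
            block_regressor(sched, 10, 1.0), np.zeros(10)
        )

    def test_sixteen_block_paradigm(self):
        # 16 blocks of 32 s on / 32 s off spans exactly 1024 s at 1 s dt
        sched = EventSchedule.blocks(16, 32.0, 32.0)
        reg = block_regressor(sched, 1024, 1.0)
        assert reg.shape == (1024,)
        # 16 distinct plateaus: the regressor crosses half-max upward 16 times
        above = reg > 0.5 * reg.max()
        n_rises = int(np.sum(np.diff(above.astype(int)) == 1)) + int(above[0])
        assert n_rises == 16

    def test_impulse_proportional_to_hrf(self):
        tr = 1.0
        sched = EventSchedule(onsets=[0.0], durations=[tr / 16])
        reg = block_regressor(sched, 40, tr)
        h = canonical_hrf(tr / 16)
        mid = np.arange(40) * 16 + 8
        expected = np.zeros(40)
        valid = mid < h.size
        expected[valid] = h[mid[valid]]
        corr = np.corrcoef(reg, expected)[0, 1]
        assert corr > 0.999

    def test_event_beyond_end_warns(self):
        sched = EventSchedule(onsets=[100.0], durations=[2.0])
        with pytest.warns(UserWarning):
            reg = block_regressor(sched, 10, 1.0)
        np.testing.assert_array_equal(reg, np.zeros(10))

    def test_commutes_with_decimation(self):
        # events aligned to the coarse grid: building at the coarse interval
        # matches the fine-grid regressor read off at the coarse mid-volume
        # times (smooth-interpolation tolerance)
        sched = EventSchedule.blocks(4, 32.0, 32.0)
        fine = block_regressor(sched, 512, 1.0)
        coarse = block_regressor(sched, 128, 4.0)
        fine_times = np.arange(512) * 1.0 + 0.5
        coarse_times = np.arange(128) * 4.0 + 2.0
        expected = np.interp(coarse_times, fine_times, fine)
        # residual discrepancy comes from the coarser kernel discretisation
        # at the HRF rising edge
        np.testing.assert_allclose(coarse, expected, atol=0.03)


class TestDctDriftBasis:
    def test_column_count_rule(self):
        X = dct_drift_basis(153, 2.8, cutoff=128.0)
        assert X.shape == (153, 6)

    def test_orthogonal_zero_mean_unit_norm(self):
        X = dct_drift_basis(200, 1.0, cutoff=64.0)
        G = X.T @ X
        np.testing.assert_allclose(G, np.eye(X.shape[1]), atol=1e-8)
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-10)

    def test_doubling_n_doubles_columns(self):
        k1 = dct_drift_basis(300, 1.0).shape[1]
        k2 = dct_drift_basis(600, 1.0).shape[1]
        assert abs(k2 - 2 * k1) <= 1

    def test_short_series_warns_and_empty(self):
        with pytest.warns(UserWarning):
            X = dct_drift_basis(50, 1.0, cutoff=128.0)
        assert X.shape == (50, 0)


class TestPhysioRegressors:
    def make_trace(self, n=50, with_amplitude=False):
        t = np.arange(n, dtype=float)
        rng = np.random.default_rng(3)
        kw = {}
        if with_amplitude:
            kw = dict(
                respiration_amplitude=rng.standard_normal(n),
                cardiac_rate=60 + rng.standard_normal(n),
            )
        return PhysioTrace(
            time=t,
            cardiac_phase=np.mod(2 * np.pi * 1.0 * t, 2 * np.pi),
            respiratory_phase=np.mod(2 * np.pi * 0.3 * t, 2 * np.pi),
            **kw,
        )

    def test_twelve_columns_at_third_order(self):
        X = physio_fourier_regressors(self.make_trace())
        assert X.shape == (50, 12)
        assert np.all(np.abs(X) <= 1.0)

    def test_constant_zero_phase(self):
        tr = PhysioTrace(
            time=np.arange(5.0),
            cardiac_phase=np.zeros(5),
            respiratory_phase=np.zeros(5),
        )
        X = physio_fourier_regressors(tr)
        sin_cols = X[:, 0::2]
        cos_cols = X[:, 1::2]
        np.testing.assert_array_equal(sin_cols, 0)
        np.testing.assert_array_equal(cos_cols, 1)

    def test_nonstandard_order_warns(self):
        with pytest.warns(UserWarning):
            X = physio_fourier_regressors(self.make_trace(), order=2)
        assert X.shape == (50, 8)

    def test_recovers_injected_sinusoid(self):
        # a pure sinusoid at the cardiac frequency projects almost entirely
        # onto the first-harmonic columns
        trace = self.make_trace(n=200)
        X = physio_fourier_regressors(trace)
        y = np.sin(trace.cardiac_phase + 0.7)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r2 > 0.99

    def test_amplitude_regressors_shape_and_centering(self):
        trace = self.make_trace(with_amplitude=True)
        X = amplitude_regressors(trace, np.arange(50.0) + 0.5)
        assert X.shape == (50, 2)
        # constant streams -> exactly zero columns
        const = PhysioTrace(
            time=np.arange(50.0),
            cardiac_phase=np.zeros(50),
            respiratory_phase=np.zeros(50),
            respiration_amplitude=np.full(50, 3.0),
            cardiac_rate=np.full(50, 60.0),
        )
        Xc = amplitude_regressors(const, np.arange(50.0) + 0.5)
        np.testing.assert_array_equal(Xc, 0)

    def test_missing_stream_warns(self):
        with pytest.warns(UserWarning):
            X = amplitude_regressors(self.make_trace(), np.arange(50.0))
        assert X.shape == (50, 0)

    def test_heart_rate_step_response(self):
        n = 100
        rate = np.where(np.arange(n) < 50, 60.0, 80.0)
        trace = PhysioTrace(
            time=np.arange(float(n)),
            cardiac_phase=np.zeros(n),
            respiratory_phase=np.zeros(n),
            respiration_amplitude=np.zeros(n),
            cardiac_rate=rate,
        )
        X = amplitude_regressors(trace, np.arange(float(n)))
        hr = X[:, 1]
        # delayed, smoothed response: the peak change happens after the step
        assert np.argmax(np.abs(np.diff(hr))) >= 50


class TestAssembleDesign:
    def test_task_plus_intercept(self):
        task = np.sin(np.arange(20) / 3.0)
        X = assemble_design([task], 20, 1.0)
        assert X.n_columns == 2
        assert X.partition == {"task": "task", "intercept": "intercept"}
        assert X.intercept_index == 1

    def test_full_1024_design(self):
        sched = EventSchedule.blocks(16, 32.0, 32.0)
        reg = block_regressor(sched, 1024, 1.0)
        X = assemble_design([reg], 1024, 1.0)
        assert X.matrix.shape == (1024, 2)

    def test_duplicate_column_warns(self):
        col = np.arange(10.0) + 1
        with pytest.warns(UserWarning):
            assemble_design([col], 10, 1.0, nuisance=col[:, None])

    def test_rank_deficient_task_errors(self):
        col = np.arange(10.0)
        with pytest.raises(ValueError):
            assemble_design([col, 2 * col], 10, 1.0)

    def test_save_load_round_trip(self, tmp_path):
        task = np.cos(np.arange(30) / 5.0)
        X = assemble_design(
            [task], 30, 0.7, drift=dct_drift_basis(30, 0.7, cutoff=10.0)
        )
        path = tmp_path / "design.tsv"
        X.save(path)
        X2 = DesignMatrix.load(path)
        np.testing.assert_allclose(X2.matrix, X.matrix)
        assert X2.partition == X.partition
        assert X2.tr == X.tr

    def test_truncate_and_decimate(self):
        task = np.sin(np.arange(40) / 3.0)
        X = assemble_design([task], 40, 1.0)
        assert X.truncated(20).matrix.shape == (20, 2)
        Xd = X.decimated(2)
        assert Xd.matrix.shape == (20, 2)
        assert Xd.tr == 2.0
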
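"""Phase-space reconstruction, recurrence plots, and the ten factors."""

import numpy as np
import pytest

import cardiorqa as cq
from cardiorqa.rqa import FACTOR_NAMES

from conftest import random_symmetric_rp
from rqa_oracle import oracle_factors


class TestAMI:
    def test_constant_series_zero(self):
        ami = cq.average_mutual_information(np.full(500, 3.7), max_lag=10)
        np.testing.assert_array_equal(ami, 0.0)

    def test_ami_zero_equals_binned_entropy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        ami = cq.average_mutual_information(x, max_lag=5)
        bins = int(np.ceil(1 + np.log2(x.size)))
        counts, _ = np.histogram(x, bins=bins)
        p = counts[counts > 0] / counts.sum()
        entropy = -(p * np.log(p)).sum()
        assert ami[0] == pytest.approx(entropy, rel=1e-10)

    def test_iid_noise_has_negligible_lagged_ami(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=10_000)
        ami = cq.average_mutual_information(x, max_lag=10)
        assert np.all(ami[1:] < 0.05)

    def test_short_series_rejected(self):
        with pytest.raises(cq.ValidationError):
            cq.average_mutual_information(np.arange(10.0), max_lag=20)


class TestSelectTau:
    def test_noisy_sine_crossing_below_quarter_period(self):
        # measurement noise is what makes the 1/e criterion attainable;
        # the binned AMI of a noiseless sine stays high at every lag
        rng = np.random.default_rng(10)
        x = np.sin(2 * np.pi * np.arange(3000) / 100.0) + rng.normal(
            0, 0.25, 3000
        )
        ami = cq.average_mutual_information(x, max_lag=60)
        tau = cq.select_tau(ami)
        assert 1 <= tau < 25
        # the selected lag is the first 1/e crossing of the curve itself
        assert ami[tau] <= ami[0] / np.e
        assert np.all(ami[1:tau] > ami[0] / np.e)

    def test_white_noise_gives_tau_one(self):
        rng = np.random.default_rng(2)
        ami = cq.average_mutual_information(rng.normal(size=5000), max_lag=10)
        assert cq.select_tau(ami) == 1

    def test_no_crossing_falls_back_to_argmin(self):
        curve = np.array([1.0, 0.9, 0.8, 0.85])  # never below 1/e
        with pytest.warns(UserWarning, match="argmin"):
            assert cq.select_tau(curve) == 2


class TestFNN:
    def test_sine_unfolds_by_dimension_two(self):
        x = np.sin(2 * np.pi * np.arange(4000) / 100.0)
        fnn = cq.false_nearest_neighbors(x, tau=25, m_max=4)
        assert fnn[1] < 0.1

    def test_noise_stays_high_at_low_dimension(self):
        rng = np.random.default_rng(3)
        fnn = cq.false_nearest_neighbors(rng.normal(size=3000), tau=1, m_max=3)
        assert fnn[0] > 0.3

    def test_fractions_bounded(self):
        rng = np.random.default_rng(4)
        fnn = cq.false_nearest_neighbors(rng.normal(size=1500), tau=2, m_max=5)
        assert np.all((fnn >= 0) & (fnn <= 1))

    def test_constant_series_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            fnn = cq.false_nearest_neighbors(np.full(500, 2.0), tau=1, m_max=3)
        np.testing.assert_array_equal(fnn, 0.0)


class TestSelectM:
    @pytest.mark.parametrize(
        "fractions, expected",
        [([0.9, 0.05, 0.01], 2), ([0.09, 0.5, 0.5], 1)],
    )
    def test_rule(self, fractions, expected):
        assert cq.select_m(np.array(fractions)) == expected

    def test_fallback_warns(self):
        with pytest.warns(UserWarning, match="m_max"):
            assert cq.select_m(np.full(8, 0.5)) == 8


class TestEmbed:
    def test_point_count(self):
        ps = cq.embed(np.arange(10.0), tau=2, m=3)
        assert ps.shape == (6, 3)

    def test_identity_at_m_one(self):
        x = np.arange(7.0)
        np.testing.assert_array_equal(cq.embed(x, tau=3, m=1).ravel(), x)

    def test_round_trip_coordinates(self):
        x = np.arange(20.0) ** 2
        ps = cq.embed(x, tau=2, m=3)
        for i in range(ps.shape[0]):
            np.testing.assert_array_equal(ps[i], x[[i, i + 2, i + 4]])


class TestDistanceMatrix:
    def test_two_points_normalize_to_one(self):
        dm = cq.distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        np.testing.assert_allclose(dm, [[0, 1], [1, 0]])

    def test_symmetry_zero_diagonal_unit_max(self):
        rng = np.random.default_rng(5)
        dm = cq.distance_matrix(rng.normal(size=(40, 3)))
        np.testing.assert_allclose(dm, dm.T)
        np.testing.assert_array_equal(np.diag(dm), 0.0)
        assert dm.max() == pytest.approx(1.0)

    def test_degenerate_cloud_flagged(self):
        with pytest.warns(UserWarning, match="diameter"):
            dm = cq.distance_matrix(np.ones((5, 2)))
        np.testing.assert_array_equal(dm, 0.0)


class TestRecurrencePlot:
    def test_epsilon_one_saturates(self):
        rng = np.random.default_rng(6)
        dm = cq.distance_matrix(rng.normal(size=(15, 2)))
        rp = cq.recurrence_plot(dm, epsilon_fraction=1.0)
        # dm < 1 everywhere except the single diameter-defining pair
        assert rp.matrix.sum() >= 15 * 15 - 2

    def test_epsilon_to_zero_keeps_only_loi(self):
        rng = np.random.default_rng(7)
        dm = cq.distance_matrix(rng.normal(size=(15, 2)))
        rp = cq.recurrence_plot(dm, epsilon_fraction=1e-12)
        np.testing.assert_array_equal(rp.matrix, np.eye(15, dtype=bool))

    def test_periodic_sine_diagonals_at_period_multiples(self):
        period = 50
        x = np.sin(2 * np.pi * np.arange(500) / period)
        ps = cq.embed(x, tau=12, m=2)
        rp = cq.recurrence_plot(cq.distance_matrix(ps), epsilon_fraction=0.05)
        n = rp.n
        density = [
            np.diagonal(rp.matrix, k).mean() for k in range(1, n // 2)
        ]
        strong = np.flatnonzero(np.asarray(density) > 0.8) + 1
        assert strong.size  # recurrent diagonals exist
        assert np.all(np.abs((strong + period / 2) % period - period / 2) <= 2)


class TestFactors:
    def test_saturated_plot(self):
        rp = cq.RecurrencePlot(matrix=np.ones((12, 12), dtype=bool))
        fv = cq.rqa_factors(rp)
        assert fv.recr == 1.0
        # corner diagonals of a finite plot have length 1 and 2, so DTM
        # saturates just below 1 (exact value confirmed by the oracle)
        assert fv.dtm == pytest.approx(oracle_factors(rp.matrix)["dtm"])
        assert fv.dtm > 0.95
        assert fv.lam == 1.0

    def test_loi_only_plot(self):
        rp = cq.RecurrencePlot(matrix=np.eye(12, dtype=bool))
        fv = cq.rqa_factors(rp)
        assert fv.recr == 0.0
        assert "dtm" in fv.undefined

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 41))
        density = float(rng.uniform(0.05, 0.6))
        rp = random_symmetric_rp(rng, n, density)
        got = cq.rqa_factors(rp).as_dict()
        want = oracle_factors(rp.matrix)
        for name in FACTOR_NAMES:
            assert got[name] == pytest.approx(want[name], abs=1e-12), name

    def test_oracle_equivalence_across_theiler_and_lmin(self):
        rng = np.random.default_rng(99)
        for _ in range(70):
            n = int(rng.integers(4, 41))
            tw = int(rng.integers(0, 3))
            lm = int(rng.integers(2, 5))
            rp = random_symmetric_rp(rng, n, float(rng.uniform(0.1, 0.7)), tw, lm)
            got = cq.rqa_factors(rp).as_dict()
            want = oracle_factors(rp.matrix, theiler_window=tw, l_min=lm)
            for name in FACTOR_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-12), name

    def test_recr_monotone_in_epsilon(self):
        rng = np.random.default_rng(8)
        dm = cq.distance_matrix(rng.normal(size=(50, 3)))
        recrs = [
            cq.rqa_factors(cq.recurrence_plot(dm, eps)).recr
            for eps in (0.02, 0.05, 0.09, 0.2, 0.5, 0.9)
        ]
        assert all(a <= b for a, b in zip(recrs, recrs[1:]))

    def test_entr_zero_for_single_length_class(self):
        mat = np.eye(10, dtype=bool)
        for start in (0, 5):  # two diagonal lines of identical length 4
            for k in range(4):
                mat[start + k, (start + k + 3) % 10] = True
        mat = mat | mat.T
        rp = cq.RecurrencePlot(matrix=mat)
        fv = cq.rqa_factors(rp)
        assert fv.entr == 0.0
        assert fv.dmax >= 3

    def test_time_reversal_stability(self):
        rng = np.random.default_rng(9)
        rp = random_symmetric_rp(rng, 30, 0.3)
        rev = cq.RecurrencePlot(matrix=rp.matrix[::-1, ::-1])
        a, b = cq.rqa_factors(rp), cq.rqa_factors(rev)
        for name in ("recr", "dtm", "mean_diag", "dmax", "entr"):
            assert getattr(a, name) == pytest.approx(getattr(b, name))

    def test_empty_plot_rejected(self):
        with pytest.raises(cq.ValidationError):
            cq.RecurrencePlot(matrix=np.empty((0, 0)))


class TestPipeline:
    def test_det_more_deterministic_than_nse(self):
        """Clean periodic ECG shows higher recurrence and determinism than
        the same template buried in full-amplitude noise."""
        spec = cq.TachogramSpec(mean_hr=300.0, sd_hr=0.0, n_beats=80, seed=0)
        tacho = cq.build_tachogram(spec)
        emb = cq.EmbeddingParams(tau=3, m=3)

        def factors(cond, noise_fraction):
            params = cq.condition_params(cond).with_(trace_noise_fraction=noise_fraction)
            ecg = cq.synthesize_ecg(params, tacho, fs=250.0, seed=4)
            tab = cq.factor_table(ecg, epoch_s=4.0, n_epochs=3, embedding=emb)
            return tab

        det = factors("DET", 0.0)
        nse = factors("NSE", 1.0)
        assert (det["dtm"] > nse["dtm"]).all()
        assert (det["recr"] > nse["recr"]).all()

    def test_factor_table_shape_and_embedding_columns(self):
        ecg, _ = cq.simulate_recording("DET", n_beats=120, fs=250, seed=6)
        tab = cq.factor_table(ecg, epoch_s=4.0, n_epochs=4)
        assert len(tab) == 4
        assert set(FACTOR_NAMES) <= set(tab.columns)
        assert tab["tau"].nunique() == 1 and tab["m"].nunique() == 1
        assert (tab["epsilon"] == 0.09).all()

    def test_factor_table_deterministic(self):
        ecg, _ = cq.simulate_recording("AF", n_beats=100, fs=250, seed=13)
        a = cq.factor_table(ecg, epoch_s=4.0, n_epochs=3)
        b = cq.factor_table(ecg, epoch_s=4.0, n_epochs=3)
        assert a.equals(b)

    def test_recording_shorter_than_epoch_rejected(self):
        ecg = cq.ECGSignal(fs=250.0, samples=np.sin(np.arange(300) / 5.0))
        with pytest.raises(cq.ValidationError):
            cq.factor_table(ecg, epoch_s=10.0)
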
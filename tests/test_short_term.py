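import numpy as np
import pandas as pd
import pytest

from mdicp.correlograms import identity_variance
from mdicp.short_term import (delta_report, difference_series, holm_adjust,
                              normalize_per_subject, regress)
from tests.conftest import make_panel


class TestDifferenceSeries:
    def test_first_difference_arithmetic(self):
        frame = make_panel({"P1": {"x": [1.0, 2.0, 4.0]}})
        out = difference_series(frame, 1, columns=["x"])
        np.testing.assert_array_equal(out["d_x"].to_numpy(), [1.0, 2.0])

    def test_constant_series_gives_zeros(self):
        frame = make_panel({"P1": {"x": [5.0] * 6}})
        out = difference_series(frame, 2, columns=["x"])
        assert (out["d_x"] == 0).all()

    def test_gap_breaks_pairs(self):
        """A dropped middle hour means no 1-hour pair spans the hole."""
        frame = make_panel({"P1": {"x": [1.0, 2.0, 3.0, 4.0],
                                   "hour": [0, 1, 3, 4]}})
        out = difference_series(frame, 1, columns=["x"])
        assert list(out["hour"]) == [1, 4]

    def test_order_out_of_range_rejected(self):
        frame = make_panel({"P1": {"x": [1.0, 2.0]}})
        for k in (0, 5):
            with pytest.raises(ValueError):
                difference_series(frame, k, columns=["x"])

    def test_k4_on_short_series_yields_single_pair(self):
        frame = make_panel({"P1": {"x": np.arange(5.0)}})
        out = difference_series(frame, 4, columns=["x"])
        assert len(out) == 1

    def test_summing_differences_reconstructs_series(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        frame = make_panel({"P1": {"x": x}})
        out = difference_series(frame, 1, columns=["x"])
        np.testing.assert_allclose(x[0] + np.cumsum(out["d_x"]), x[1:], atol=1e-12)


class TestNormalizePerSubject:
    def test_means_zero_sds_one(self, aligned_small):
        z = normalize_per_subject(aligned_small)
        for _, g in z.groupby("patient_id"):
            assert abs(g["lactate_t"].mean()) < 1e-12
            assert np.std(g["lactate_t"].to_numpy()) == pytest.approx(1.0, abs=1e-12)

    def test_identity_variance_vanishes_after_normalization(self, aligned_small):
        z = normalize_per_subject(aligned_small)
        rep = identity_variance(z, "lactate_t")
        assert rep.r2["lactate_t"] < 0.01

    def test_hand_computed_z_scores(self):
        frame = make_panel({"P1": {"x": [1.0, 2.0, 3.0]},
                            "P2": {"x": [10.0, 20.0, 30.0]}})
        z = normalize_per_subject(frame, columns=["x"])
        sd1 = np.std([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z[z["patient_id"] == "P1"]["x"],
                                   [-1 / sd1, 0.0, 1 / sd1])

    def test_constant_patient_dropped(self):
        frame = make_panel({"P1": {"x": [1.0, 1.0, 1.0]},
                            "P2": {"x": [1.0, 2.0, 3.0]}})
        z = normalize_per_subject(frame, columns=["x"])
        assert set(z["patient_id"]) == {"P2"}

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        f1 = make_panel({"P1": {"x": x}, "P2": {"x": rng.normal(size=12)}})
        f2 = f1.copy()
        f2.loc[f2["patient_id"] == "P1", "x"] = 5.0 + 3.0 * x
        z1 = normalize_per_subject(f1, columns=["x"])
        z2 = normalize_per_subject(f2, columns=["x"])
        np.testing.assert_allclose(z1["x"], z2["x"], atol=1e-12)


def normal_equations_oracle(y, X):
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
    return beta, r2


class TestRegress:
    def test_noise_free_slope_and_r2(self):
        x = np.linspace(0, 1, 30)
        frame = make_panel({"P1": {"x": x, "y": 3 * x}})
        rep = regress(frame, "y", ["x"], mode="pooled")
        assert rep.coef["x"] == pytest.approx(3.0)
        assert rep.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(18, 2))
        y = 1.0 + X @ np.array([0.5, -1.2]) + rng.normal(size=18)
        frame = make_panel({"P1": {"a": X[:, 0], "b": X[:, 1], "y": y}})
        rep = regress(frame, "y", ["a", "b"], mode="pooled")
        beta, r2 = normal_equations_oracle(y, X)
        np.testing.assert_allclose(rep.coef.to_numpy(), beta, atol=1e-10)
        assert rep.r2 == pytest.approx(r2, abs=1e-10)

    def test_cooks_distance_matches_brute_force(self):
        """One gross leverage point: its Cook's distance from the hat
        matrix formula matches the direct leave-one-out computation and
        triggers exclusion on refit."""
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(size=9), [8.0]])
        y = 2 * x + rng.normal(scale=0.3, size=10)
        y[-1] += 12.0  # gross outlier at high leverage
        frame = make_panel({f"P{i}": {"x": [x[i]] * 1, "y": [y[i]] * 1}
                            for i in range(10)})
        rep = regress(frame, "y", ["x"], mode="subject_means")
        # brute-force: D_i = (e_i^2 / (p s^2)) * h_i / (1-h_i)^2
        A = np.column_stack([np.ones(10), x])
        H = A @ np.linalg.inv(A.T @ A) @ A.T
        e = y - H @ y
        p = 2
        s2 = e @ e / (10 - p)
        D = (e**2 / (p * s2)) * np.diag(H) / (1 - np.diag(H)) ** 2
        assert D[-1] > 1
        assert len(rep.excluded) == 1
        pid, d = rep.excluded[0]
        assert pid == "P9"
        assert d == pytest.approx(D[-1], rel=1e-8)

    def test_subject_means_df_referenced_to_patients(self):
        rng = np.random.default_rng(5)
        frame = make_panel({f"P{i}": {"x": rng.normal(size=30) + i,
                                      "y": rng.normal(size=30) + 0.5 * i}
                            for i in range(8)})
        rep = regress(frame, "y", ["x"], mode="subject_means")
        assert rep.n == 8  # one row per patient

    def test_collinear_design_rejected(self):
        frame = make_panel({"P1": {"x": np.arange(10.0), "y": np.arange(10.0)}})
        frame["x2"] = frame["x"] * 2
        with pytest.raises(ValueError, match="collinear"):
            regress(frame, "y", ["x", "x2"], mode="pooled")


class TestDeltaReport:
    def test_instantaneous_coupling_detected_by_delta_delta(self):
        """When marker changes track CPP changes, the difference-difference
        design sees more variance than level designs."""
        rng = np.random.default_rng(7)
        data = {}
        for i in range(10):
            cpp = np.cumsum(rng.normal(size=60)) + 70 + 10 * rng.normal()
            md = np.empty(60)
            md[0] = rng.normal()
            for t in range(1, 60):
                md[t] = md[t - 1] + 0.3 * (cpp[t] - cpp[t - 1]) + 0.1 * rng.normal()
            data[f"P{i}"] = {"lactate_t": md, "cpp_hour": cpp,
                             "icp_hour": rng.normal(14, 2, size=60)}
        frame = make_panel(data)
        rep = delta_report(frame, ks=(1,), responses=("cpp_hour",),
                           markers=["lactate_t"])
        uni = rep[rep["univariate"] & (rep["stratum"] == "all")]
        r2 = uni.set_index("response_kind")["r2"]
        assert r2["delta"] > r2["level"]
        assert r2["delta"] > 0.5

    def test_holm_adjustment_is_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.02, 0.5])
        adj = holm_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        np.testing.assert_allclose(adj, [0.004, 0.03, 0.04, 0.5])
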
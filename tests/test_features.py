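"""Preprocessing invariances, time functions, counts, global features, tanh."""

import numpy as np
import pytest

import sigaging as sg
from sigaging.errors import PreprocessingError
from sigaging.features import (
    TIME_FUNCTION_CATALOG,
    apply_tanh,
    compute_global_features,
    compute_time_functions,
    count_local_maxima,
    count_penups,
    fit_tanh,
    preprocess,
)

from conftest import random_signature


def _make_sig(x, y, p=None, dt=10.0):
    n = len(x)
    p = np.full(n, 500) if p is None else np.asarray(p)
    return sg.DynamicSignature(user_id="u", session_id="BID1", sample_idx=1,
                               month=0.0, t=np.arange(n) * dt,
                               x=np.asarray(x, float), y=np.asarray(y, float), p=p)


def _skewed_cloud(rng, n=200):
    # clearly skewed in x so the rotation-sign rule is unambiguous
    x = rng.gamma(2.0, 50.0, n)
    y = 0.3 * x + rng.normal(0, 10, n)
    return _make_sig(x, y)


class TestPreprocess:
    def test_idempotent(self, rng):
        sig = _skewed_cloud(rng)
        once = preprocess(sig)
        twice = preprocess(once)
        np.testing.assert_allclose(twice.x, once.x, atol=1e-9)
        np.testing.assert_allclose(twice.y, once.y, atol=1e-9)

    def test_translation_invariant(self, rng):
        sig = _skewed_cloud(rng)
        moved = sig.copy(x=sig.x + 100, y=sig.y - 50)
        a, b = preprocess(sig), preprocess(moved)
        np.testing.assert_allclose(a.x, b.x, atol=1e-9)
        np.testing.assert_allclose(a.y, b.y, atol=1e-9)

    def test_rotation_invariant(self, rng):
        sig = _skewed_cloud(rng)
        th = np.deg2rad(30)
        xr = sig.x * np.cos(th) - sig.y * np.sin(th)
        yr = sig.x * np.sin(th) + sig.y * np.cos(th)
        a, b = preprocess(sig), preprocess(sig.copy(x=xr, y=yr))
        np.testing.assert_allclose(a.x, b.x, atol=1e-6)
        np.testing.assert_allclose(a.y, b.y, atol=1e-6)

    def test_degenerate_cloud_rejected(self):
        sig = _make_sig(np.full(10, 5.0), np.full(10, 5.0))
        with pytest.raises(PreprocessingError):
            preprocess(sig)


class TestTimeFunctions:
    def test_constant_x_has_zero_derivative(self):
        sig = _make_sig(np.full(50, 3.0), np.arange(50.0))
        tfs = compute_time_functions(sig, ("dx",), standardize=False)
        np.testing.assert_allclose(tfs.values[:, 0], 0.0, atol=1e-9)

    def test_linear_x_derivative_is_100_units_per_s(self):
        sig = _make_sig(np.arange(80.0), np.zeros(80))
        tfs = compute_time_functions(sig, ("dx",), standardize=False)
        np.testing.assert_allclose(tfs.values[5:-5, 0], 100.0)

    def test_path_angle_of_45_degree_segment(self):
        v = np.arange(60.0)
        sig = _make_sig(v, v)
        tfs = compute_time_functions(sig, ("path_angle",), standardize=False)
        np.testing.assert_allclose(tfs.values[1:-1, 0], np.pi / 4, atol=1e-9)

    def test_unknown_name_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            compute_time_functions(random_signature(rng), ("x", "warp"))

    def test_full_catalog_finite_and_standardized(self, rng):
        sig = preprocess(random_signature(rng, n=100))
        tfs = compute_time_functions(sig, TIME_FUNCTION_CATALOG)
        assert np.all(np.isfinite(tfs.values))
        np.testing.assert_allclose(tfs.values.mean(axis=0), 0.0, atol=1e-9)


class TestCounts:
    @pytest.mark.parametrize("p,expected", [
        ([5, 5, 0, 0, 7, 7], 1),
        ([5, 0, 7, 0, 9], 2),
        ([5, 6, 7, 8], 0),
    ])
    def test_count_penups(self, p, expected):
        sig = _make_sig(np.arange(len(p), dtype=float),
                        np.ones(len(p)), p=np.asarray(p))
        assert count_penups(sig) == expected

    @pytest.mark.parametrize("series,expected", [
        ([0, 1, 0, 2, 0], 2),
        ([1, 2, 3, 4], 0),
        ([0, 2, 2, 0], 1),        # plateau counts once
        ([0, 2, 2, 3, 0], 1),
        ([3, 1, 2], 0),
    ])
    def test_count_local_maxima(self, series, expected):
        assert count_local_maxima(np.asarray(series, float)) == expected

    def test_short_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert count_local_maxima(np.array([1.0, 2.0])) == 0


class TestGlobalFeatures:
    def test_duration_and_avg_speed(self):
        # straight stroke: 300 units in 3 s at 100 Hz
        n = 301
        sig = _make_sig(np.linspace(0, 300, n), np.zeros(n))
        feats = compute_global_features(sig).as_dict()
        assert feats["duration"] == pytest.approx(3.0)
        assert feats["avg_speed"] == pytest.approx(100.0)

    def test_catalog_size_and_labels(self, rng):
        vec = compute_global_features(preprocess(random_signature(rng, n=150)))
        assert len(vec.names) >= 40
        assert set(vec.kind) == {"static", "dynamic"}
        for f in ("duration", "n_penups", "n_max_x", "n_max_y", "avg_speed"):
            assert f in vec.names

    def test_time_rescaling_splits_static_from_dynamic(self, rng):
        """Replaying the same trajectory at double speed leaves every static
        feature unchanged and doubles the average speed."""
        sig = preprocess(random_signature(rng, n=200))
        fast = sig.copy(t=sig.t / 2.0)
        a = compute_global_features(sig)
        b = compute_global_features(fast)
        for name, kind, va, vb in zip(a.names, a.kind, a.values, b.values):
            if kind == "static":
                assert va == pytest.approx(vb, rel=1e-6, abs=1e-9), name
        assert b.as_dict()["avg_speed"] == pytest.approx(
            2 * a.as_dict()["avg_speed"], rel=1e-9)
        assert b.as_dict()["duration"] == pytest.approx(
            a.as_dict()["duration"] / 2, rel=1e-9)


class TestTanh:
    def test_closed_forms(self, rng):
        vecs = [compute_global_features(preprocess(random_signature(rng, n=120)))
                for _ in range(5)]
        norm = fit_tanh(vecs)
        at_mu = apply_tanh(
            sg.GlobalFeatureVector(names=vecs[0].names, values=norm.mu.copy(),
                                   kind=vecs[0].kind), norm)
        np.testing.assert_allclose(at_mu.values, 0.5, atol=1e-12)
        shifted = apply_tanh(
            sg.GlobalFeatureVector(names=vecs[0].names,
                                   values=norm.mu + 100 * norm.sigma,
                                   kind=vecs[0].kind), norm)
        np.testing.assert_allclose(shifted.values, 0.5 * (np.tanh(1.0) + 1),
                                   atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        vecs = [compute_global_features(preprocess(random_signature(rng, n=120)))
                for _ in range(5)]
        norm = fit_tanh(vecs)
        grid = np.linspace(-1000, 1000, 41)
        prev = None
        for g in grid:
            out = apply_tanh(
                sg.GlobalFeatureVector(names=vecs[0].names,
                                       values=norm.mu + g * norm.sigma,
                                       kind=vecs[0].kind), norm).values
            assert np.all(out > 0) and np.all(out < 1)
            if prev is not None:
                assert np.all(out >= prev)
            prev = out

    def test_zero_variance_feature_maps_to_half(self):
        names = ("a", "b")
        kinds = ("static", "static")
        vecs = [sg.GlobalFeatureVector(names=names, values=np.array([1.0, i * 1.0]),
                                       kind=kinds) for i in range(4)]
        norm = fit_tanh(vecs)
        out = apply_tanh(vecs[0], norm)
        assert out.values[0] == pytest.approx(0.5)

    def test_fit_requires_two_vectors(self):
        with pytest.raises(ValueError):
            fit_tanh([sg.GlobalFeatureVector(names=("a",), values=np.array([1.0]),
                                             kind=("static",))])
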
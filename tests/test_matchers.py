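"""Matcher correctness: DTW vs path enumeration, Mahalanobis arithmetic,
GMM-HMM training/scoring properties."""

import numpy as np
import pytest

import sigaging as sg
from sigaging._ghmm import LeftRightGMMHMM, forward_log_likelihood
from sigaging.errors import SigagingError
from sigaging.features import TimeFunctionSet
from sigaging.matchers import DTWMatcher, GFMatcher, HMMMatcher, dtw_distance


def _tfs(arr, names=None):
    arr = np.atleast_2d(np.asarray(arr, float))
    if arr.shape[0] == 1 and arr.shape[1] > 1:
        arr = arr.T
    names = names or tuple(f"f{i}" for i in range(arr.shape[1]))
    return TimeFunctionSet(names=tuple(names), values=arr, source=("u", "BID1", 1))


# ---------------------------------------------------------------------------
# DTW oracle: exhaustive enumeration over all admissible warping paths

def _dtw_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Enumerate every monotone path with steps (1,0),(0,1),(1,1) and weights
    1,1,2 (first cell weight 2); return the minimal accumulated cost."""
    n, m = len(a), len(b)

    def local(i, j):
        return float(np.linalg.norm(a[i] - b[j]))

    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n:
            walk(i + 1, j, acc + local(i + 1, j))
        if j + 1 < m:
            walk(i, j + 1, acc + local(i, j + 1))
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc + 2 * local(i + 1, j + 1))

    walk(0, 0, 2 * local(0, 0))
    return best[0] / (n + m)


class TestDTW:
    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n, m = rng.integers(2, 7, size=2)
            k = int(rng.integers(1, 4))
            a, b = rng.normal(size=(n, k)), rng.normal(size=(m, k))
            fast = dtw_distance(_tfs(a), _tfs(b))
            slow = _dtw_bruteforce(a, b)
            assert fast == pytest.approx(slow, rel=1e-9, abs=1e-12)

    def test_example_sequence(self):
        # [0,1,2] vs [0,2]: optimal path cost 1, normalized by 5
        assert dtw_distance(_tfs([0, 1, 2]), _tfs([0, 2])) == pytest.approx(0.2)

    def test_self_distance_zero_and_symmetry(self, rng):
        for _ in range(20):
            a = rng.normal(size=(int(rng.integers(3, 30)), 4))
            b = rng.normal(size=(int(rng.integers(3, 30)), 4))
            assert dtw_distance(_tfs(a), _tfs(a)) == 0.0
            assert dtw_distance(_tfs(a), _tfs(b)) == pytest.approx(
                dtw_distance(_tfs(b), _tfs(a)), rel=1e-12)

    def test_perturbation_lipschitz_bound(self, rng):
        """Moving one sample by delta changes the distance by at most
        2*delta*path_length/(n+m) (every cell is visited at most once per
        axis step; max weight 2)."""
        for _ in range(20):
            n = int(rng.integers(4, 12))
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n + 2, 3))
            a2 = a.copy()
            delta = rng.normal(size=3) * 0.1
            a2[n // 2] += delta
            d1 = dtw_distance(_tfs(a), _tfs(b))
            d2 = dtw_distance(_tfs(a2), _tfs(b))
            bound = 2 * np.linalg.norm(delta) * (len(a) + len(b)) / (len(a) + len(b))
            assert abs(d1 - d2) <= bound + 1e-12

    def test_catalog_mismatch_rejected(self):
        a = np.zeros((3, 2))
        with pytest.raises(ValueError, match="catalog"):
            dtw_distance(_tfs(a, names=("a", "b")), _tfs(a, names=("a", "c")))

    def test_score_mapping(self):
        m = DTWMatcher()
        refs = [_tfs([0, 1, 2, 1]), _tfs([0, 1, 2, 0])]
        model = m.train(refs)
        assert m.score(model, refs[0]) == pytest.approx(1.0)  # exp(0)
        # a test at exactly d_ref scores e^-1
        assert model.d_ref > 0
        d = model.d_ref
        probe = _tfs([10, 11, 12, 11])
        s = m.score(model, probe)
        d_min = min(dtw_distance(r, probe) for r in model.references)
        assert s == pytest.approx(np.exp(-d_min / d))

    def test_empty_enrollment_rejected(self):
        with pytest.raises(SigagingError):
            DTWMatcher().train([])


class TestGF:
    def _vec(self, vals, names=None):
        vals = np.asarray(vals, float)
        names = names or tuple(f"g{i}" for i in range(len(vals)))
        return sg.GlobalFeatureVector(names=tuple(names), values=vals,
                                      kind=("static",) * len(vals))

    def test_hand_computed_mahalanobis(self):
        model = sg.GFModel(normalizer=None, mean=np.array([0.5, 0.5]),
                           var=np.array([0.04, 0.01]), names=("g0", "g1"))
        # bypass normalization: identity check on the quadratic form
        v = np.array([0.7, 0.4])
        d = -np.sqrt(np.sum((v - model.mean) ** 2 / model.var))
        assert d == pytest.approx(-np.sqrt(2.0))

    def test_score_maximum_at_mean_and_identity_reduction(self, rng):
        m = GFMatcher()
        vecs = [self._vec(rng.normal(size=6) + 10) for _ in range(5)]
        model = m.train(vecs)
        centered = sg.GlobalFeatureVector(
            names=vecs[0].names,
            values=model.normalizer.mu.copy(), kind=vecs[0].kind)
        assert m.score(model, centered) == pytest.approx(
            -np.sqrt(np.sum((0.5 - model.mean) ** 2 / model.var)))
        # the raw vector whose normalized image equals the model mean is the
        # global maximum: score exactly 0; any other probe scores below it
        exact = sg.GlobalFeatureVector(names=vecs[0].names,
                                       values=norm_inverse(model),
                                       kind=vecs[0].kind)
        assert m.score(model, exact) == pytest.approx(0.0, abs=1e-6)
        for _ in range(10):
            assert m.score(model, self._vec(rng.normal(size=6) + 10)) <= 1e-9

    def test_feature_permutation_invariance(self, rng):
        m = GFMatcher()
        vecs = [self._vec(rng.normal(size=5)) for _ in range(4)]
        probe = self._vec(rng.normal(size=5))
        s1 = m.score(m.train(vecs), probe)
        perm = np.array([3, 1, 4, 0, 2])
        names = tuple(np.array(vecs[0].names)[perm])
        vecs_p = [sg.GlobalFeatureVector(names=names, values=v.values[perm],
                                         kind=("static",) * 5) for v in vecs]
        probe_p = sg.GlobalFeatureVector(names=names, values=probe.values[perm],
                                         kind=("static",) * 5)
        m2 = GFMatcher()
        s2 = m2.score(m2.train(vecs_p), probe_p)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_single_vector_rejected(self, rng):
        with pytest.raises(SigagingError):
            GFMatcher().train([self._vec(rng.normal(size=3))])


class TestHMM:
    def _seqs(self, rng, n_seqs=3, length=60, dim=4, shift=0.0):
        out = []
        for _ in range(n_seqs):
            base = np.sin(np.linspace(0, 6, length))[:, None] * np.arange(1, dim + 1)
            out.append(base + shift + 0.1 * rng.normal(size=(length, dim)))
        return out

    def test_training_deterministic_given_seed(self, rng):
        seqs = self._seqs(np.random.default_rng(5))
        m1 = LeftRightGMMHMM(n_states=5, n_mix=2, seed=3, n_iter=5).fit(seqs)
        m2 = LeftRightGMMHMM(n_states=5, n_mix=2, seed=3, n_iter=5).fit(seqs)
        np.testing.assert_array_equal(m1.means, m2.means)
        np.testing.assert_array_equal(m1.transmat, m2.transmat)

    def test_baum_welch_loglik_nondecreasing(self):
        seqs = self._seqs(np.random.default_rng(6))
        m = LeftRightGMMHMM(n_states=5, n_mix=2, seed=0, n_iter=12, tol=0).fit(seqs)
        h = np.asarray(m.history)
        assert len(h) >= 2
        assert np.all(np.diff(h) >= -1e-6 * np.abs(h[:-1]))

    def test_left_right_structure_preserved(self):
        seqs = self._seqs(np.random.default_rng(7))
        m = LeftRightGMMHMM(n_states=5, n_mix=2, seed=0, n_iter=8).fit(seqs)
        np.testing.assert_allclose(m.transmat.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.triu(m.transmat, 2) == 0)
        assert np.all(np.tril(m.transmat, -1) == 0)
        np.testing.assert_allclose(m.weights.sum(axis=1), 1.0, atol=1e-9)
        assert m.covars.min() >= m.min_covar - 1e-12

    def test_forward_matches_bruteforce_enumeration(self):
        """P(O|model) via the forward algorithm equals the explicit sum over
        all state paths for a tiny 2-state, 4-frame model."""
        rng = np.random.default_rng(8)
        S, M, D, T = 2, 2, 3, 4
        means = rng.normal(size=(S, M, D))
        covars = rng.uniform(0.5, 2.0, size=(S, M, D))
        weights = rng.dirichlet(np.ones(M), size=S)
        start = np.array([1.0, 0.0])
        trans = np.array([[0.7, 0.3], [0.0, 1.0]])
        X = rng.normal(size=(T, D))

        def emis(s, x):
            tot = 0.0
            for m in range(M):
                z = np.sum((x - means[s, m]) ** 2 / covars[s, m]
                           + np.log(2 * np.pi * covars[s, m]))
                tot += weights[s, m] * np.exp(-0.5 * z)
            return tot

        total = 0.0
        for path in np.ndindex(*(S,) * T):
            p = start[path[0]] * emis(path[0], X[0])
            for t in range(1, T):
                p *= trans[path[t - 1], path[t]] * emis(path[t], X[t])
            total += p
        ll = forward_log_likelihood(X, start, trans, means, covars, weights)
        assert ll == pytest.approx(np.log(total), rel=1e-10)

    def test_forward_matches_hmmlearn(self):
        """Independent cross-check of the forward pass against hmmlearn on
        identical parameters."""
        import warnings

        from hmmlearn.hmm import GMMHMM

        seqs = self._seqs(np.random.default_rng(9))
        m = LeftRightGMMHMM(n_states=4, n_mix=2, seed=0, n_iter=6).fit(seqs)
        ref = GMMHMM(n_components=4, n_mix=2, covariance_type="diag",
                     init_params="")
        ref.startprob_, ref.transmat_ = m.startprob, m.transmat
        ref.means_, ref.covars_, ref.weights_ = m.means, m.covars, m.weights
        X = self._seqs(np.random.default_rng(10), n_seqs=1)[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expected = float(ref.score(X))
        assert m.loglik(X) == pytest.approx(expected, rel=1e-9)

    def test_own_sequences_score_higher_than_noise(self):
        rng = np.random.default_rng(11)
        seqs = self._seqs(rng)
        matcher = HMMMatcher(n_states=5, n_mix=2, seed=0)
        m = LeftRightGMMHMM(n_states=5, n_mix=2, seed=0, n_iter=8).fit(seqs)
        own = m.loglik(seqs[0]) / len(seqs[0])
        noise = rng.normal(size=seqs[0].shape) * 3
        assert own > m.loglik(noise) / len(noise)

    def test_state_count_reduced_for_short_sequences(self, rng):
        seqs = self._seqs(np.random.default_rng(12), length=9, dim=3)
        matcher = HMMMatcher(n_states=12, n_mix=2, seed=0, n_iter=3)
        tfs = [_tfs(s, names=("a", "b", "c")) for s in seqs]
        with pytest.warns(UserWarning, match="reducing"):
            model = matcher.train(tfs)
        assert model.n_states == 3

    def test_time_dilated_sequence_per_frame_score_stable(self):
        """Repeating every observation (time dilation through the allowed
        self-transitions) moves the per-frame score by no more than the
        per-frame transition-cost budget."""
        seqs = self._seqs(np.random.default_rng(13))
        m = LeftRightGMMHMM(n_states=4, n_mix=2, seed=0, n_iter=6).fit(seqs)
        X = seqs[0]
        X2 = np.repeat(X, 2, axis=0)
        a = m.loglik(X) / len(X)
        b = m.loglik(X2) / len(X2)
        budget = 2 * np.abs(np.log(m.transmat[m.transmat > 0])).max()
        assert abs(a - b) <= budget


def norm_inverse(model):
    # helper for TestGF: raw values whose normalized image is the model mean
    z = np.arctanh(np.clip(2 * model.mean - 1, -0.999999, 0.999999))
    return model.normalizer.mu + 100.0 * z * model.normalizer.sigma


class TestDTWProperties:
    def test_hypothesis_oracle_and_symmetry(self):
        """Property: DTW equals path enumeration and is symmetric on
        arbitrary short sequences."""
        from hypothesis import given, settings, strategies as st
        from hypothesis.extra import numpy as hnp

        seqs = hnp.arrays(np.float64, st.tuples(st.integers(2, 6), st.just(2)),
                          elements=st.floats(-10, 10, allow_nan=False))

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(seqs, seqs)
        def inner(a, b):
            d_ab = dtw_distance(_tfs(a), _tfs(b))
            assert d_ab == pytest.approx(_dtw_bruteforce(a, b),
                                         rel=1e-9, abs=1e-12)
            assert d_ab == pytest.approx(dtw_distance(_tfs(b), _tfs(a)),
                                         rel=1e-12, abs=1e-15)

        inner()
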
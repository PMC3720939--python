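"""Left-to-right Gaussian-mixture hidden Markov model (Baum-Welch + forward).

A compact, deterministic GMM-HMM tailored to signature verification:
left-to-right topology (self + single forward transitions), diagonal
covariances with a variance floor, mixture emissions per state.  The
E-step runs in log space (numba-accelerated forward/backward); the M-step
re-estimates transitions, mixture weights, means and variances.  All
initialization is deterministic given a seed (uniform segmentation of the
training sequences over the states, then k-means per state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f
        return deco


_LOG_ZERO = -1e30


def gmm_component_loglik(X: np.ndarray, means: np.ndarray, covars: np.ndarray,
                         weights: np.ndarray) -> np.ndarray:
    """Weighted per-component log densities, shape (T, S, M)."""
    diff = X[:, None, None, :] - means[None]
    ll = -0.5 * np.sum(diff * diff / covars[None]
                       + np.log(2.0 * np.pi * covars[None]), axis=3)
    return ll + np.log(np.maximum(weights[None], 1e-300))


def gmm_log_emissions(X: np.ndarray, means: np.ndarray, covars: np.ndarray,
                      weights: np.ndarray) -> np.ndarray:
    """Per-frame, per-state mixture log density, shape (T, S)."""
    ll = gmm_component_loglik(X, means, covars, weights)
    mx = ll.max(axis=2)
    return mx + np.log(np.sum(np.exp(ll - mx[..., None]), axis=2))


@njit(cache=False)
def _log_forward(log_emit, log_start, log_trans, alpha_out):
    T, S = log_emit.shape
    for s in range(S):
        alpha_out[0, s] = log_start[s] + log_emit[0, s]
    for t in range(1, T):
        for j in range(S):
            mx = _LOG_ZERO
            for i in range(S):
                v = alpha_out[t - 1, i] + log_trans[i, j]
                if v > mx:
                    mx = v
            if mx <= _LOG_ZERO:
                alpha_out[t, j] = _LOG_ZERO
                continue
            acc = 0.0
            for i in range(S):
                acc += np.exp(alpha_out[t - 1, i] + log_trans[i, j] - mx)
            alpha_out[t, j] = mx + np.log(acc) + log_emit[t, j]
    mx = _LOG_ZERO
    for s in range(S):
        if alpha_out[T - 1, s] > mx:
            mx = alpha_out[T - 1, s]
    if mx <= _LOG_ZERO:
        return _LOG_ZERO
    acc = 0.0
    for s in range(S):
        acc += np.exp(alpha_out[T - 1, s] - mx)
    return mx + np.log(acc)


@njit(cache=False)
def _log_backward(log_emit, log_trans, beta_out):
    T, S = log_emit.shape
    for s in range(S):
        beta_out[T - 1, s] = 0.0
    for t in range(T - 2, -1, -1):
        for i in range(S):
            mx = _LOG_ZERO
            for j in range(S):
                v = log_trans[i, j] + log_emit[t + 1, j] + beta_out[t + 1, j]
                if v > mx:
                    mx = v
            if mx <= _LOG_ZERO:
                beta_out[t, i] = _LOG_ZERO
                continue
            acc = 0.0
            for j in range(S):
                acc += np.exp(log_trans[i, j] + log_emit[t + 1, j]
                              + beta_out[t + 1, j] - mx)
            beta_out[t, i] = mx + np.log(acc)


@njit(cache=False)
def _xi_accumulate(log_alpha, log_beta, log_emit, log_trans, loglik, xi_out):
    T, S = log_emit.shape
    for t in range(T - 1):
        for i in range(S):
            for j in range(S):
                if log_trans[i, j] <= _LOG_ZERO:
                    continue
                v = (log_alpha[t, i] + log_trans[i, j] + log_emit[t + 1, j]
                     + log_beta[t + 1, j] - loglik)
                if v > -700.0:
                    xi_out[i, j] += np.exp(v)


def _safe_log(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, _LOG_ZERO)
    mask = p > 0
    out[mask] = np.log(p[mask])
    return out


def forward_log_likelihood(X: np.ndarray, startprob: np.ndarray,
                           transmat: np.ndarray, means: np.ndarray,
                           covars: np.ndarray, weights: np.ndarray) -> float:
    """log P(X | model) by the forward algorithm in log space."""
    X = np.asarray(X, dtype=float)
    log_emit = gmm_log_emissions(X, means, covars, weights)
    alpha = np.empty((len(X), len(startprob)))
    return float(_log_forward(np.ascontiguousarray(log_emit),
                              _safe_log(np.asarray(startprob, dtype=float)),
                              _safe_log(np.asarray(transmat, dtype=float)),
                              alpha))


@dataclass
class LeftRightGMMHMM:
    """Trainable left-to-right GMM-HMM with diagonal covariances."""

    n_states: int = 12
    n_mix: int = 4
    n_iter: int = 15
    tol: float = 1e-3
    min_covar: float = 1e-3
    seed: int = 0

    startprob: np.ndarray = field(default=None, repr=False)
    transmat: np.ndarray = field(default=None, repr=False)
    means: np.ndarray = field(default=None, repr=False)
    covars: np.ndarray = field(default=None, repr=False)
    weights: np.ndarray = field(default=None, repr=False)
    history: list = field(default_factory=list, repr=False)

    # ------------------------------------------------------------------
    def _init_params(self, seqs: list[np.ndarray]) -> None:
        from sklearn.cluster import KMeans

        S, M = self.n_states, self.n_mix
        D = seqs[0].shape[1]
        per_state: list[list[np.ndarray]] = [[] for _ in range(S)]
        for seq in seqs:
            bounds = np.linspace(0, len(seq), S + 1).astype(int)
            for st in range(S):
                per_state[st].append(seq[bounds[st]:bounds[st + 1]])
        means = np.zeros((S, M, D))
        covars = np.ones((S, M, D))
        weights = np.full((S, M), 1.0 / M)
        for st in range(S):
            pool = np.concatenate(per_state[st], axis=0)
            k = min(M, len(pool))
            km = KMeans(n_clusters=k, n_init=1, random_state=self.seed).fit(pool)
            for m in range(M):
                members = pool[km.labels_ == (m % k)]
                if len(members) == 0:
                    members = pool
                means[st, m] = members.mean(axis=0)
                covars[st, m] = np.maximum(members.var(axis=0), self.min_covar)
                weights[st, m] = max(len(members) / len(pool), 1e-3)
            weights[st] /= weights[st].sum()
        transmat = np.zeros((S, S))
        for st in range(S - 1):
            transmat[st, st] = 0.8
            transmat[st, st + 1] = 0.2
        transmat[S - 1, S - 1] = 1.0
        startprob = np.zeros(S)
        startprob[0] = 1.0
        self.startprob, self.transmat = startprob, transmat
        self.means, self.covars, self.weights = means, covars, weights

    # ------------------------------------------------------------------
    def fit(self, seqs: list[np.ndarray]) -> "LeftRightGMMHMM":
        """Baum-Welch until the total log-likelihood gain drops below
        ``tol`` or ``n_iter`` iterations are reached."""
        seqs = [np.asarray(s, dtype=float) for s in seqs]
        if min(len(s) for s in seqs) < self.n_states:
            raise ValueError("sequences must be at least n_states long")
        self._init_params(seqs)
        S, M = self.n_states, self.n_mix
        D = seqs[0].shape[1]
        self.history = []
        prev_ll = -np.inf
        for _it in range(self.n_iter):
            log_start = _safe_log(self.startprob)
            log_trans = _safe_log(self.transmat)
            xi = np.zeros((S, S))
            gmm_post_sum = np.zeros((S, M))
            mean_num = np.zeros((S, M, D))
            sq_num = np.zeros((S, M, D))
            gamma0 = np.zeros(S)
            total_ll = 0.0
            for seq in seqs:
                T = len(seq)
                comp_ll = gmm_component_loglik(seq, self.means, self.covars,
                                               self.weights)  # (T,S,M)
                mx = comp_ll.max(axis=2)
                log_emit = mx + np.log(np.sum(np.exp(comp_ll - mx[..., None]),
                                              axis=2))
                log_alpha = np.empty((T, S))
                log_beta = np.empty((T, S))
                ll = _log_forward(log_emit, log_start, log_trans, log_alpha)
                _log_backward(log_emit, log_trans, log_beta)
                total_ll += ll
                gamma = np.exp(np.clip(log_alpha + log_beta - ll, -700, 0))
                gamma0 += gamma[0]
                _xi_accumulate(log_alpha, log_beta, log_emit, log_trans, ll, xi)
                # per-component responsibilities within each state
                resp = np.exp(comp_ll - log_emit[..., None])   # (T,S,M)
                resp *= gamma[..., None]
                gmm_post_sum += resp.sum(axis=0)
                mean_num += np.einsum("tsm,td->smd", resp, seq)
                sq_num += np.einsum("tsm,td->smd", resp, seq ** 2)
            self.history.append(total_ll)
            if total_ll - prev_ll < self.tol and _it > 0:
                break
            prev_ll = total_ll
            # ---- M-step
            denom = np.maximum(xi.sum(axis=1, keepdims=True), 1e-300)
            new_trans = xi / denom
            # keep the left-to-right zero pattern exactly
            new_trans[self.transmat == 0] = 0.0
            rs = new_trans.sum(axis=1, keepdims=True)
            self.transmat = np.where(rs > 0, new_trans / np.maximum(rs, 1e-300),
                                     self.transmat)
            post = np.maximum(gmm_post_sum, 1e-300)
            self.weights = post / post.sum(axis=1, keepdims=True)
            self.means = mean_num / post[..., None]
            var = sq_num / post[..., None] - self.means ** 2
            self.covars = np.maximum(var, self.min_covar)
        return self

    # ------------------------------------------------------------------
    def loglik(self, X: np.ndarray) -> float:
        """log P(X | model) by the forward algorithm."""
        X = np.asarray(X, dtype=float)
        log_emit = gmm_log_emissions(X, self.means, self.covars, self.weights)
        alpha = np.empty((len(X), self.n_states))
        return float(_log_forward(log_emit, _safe_log(self.startprob),
                                  _safe_log(self.transmat), alpha))
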
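"""The three verification systems: DTW, global-feature Mahalanobis, GMM-HMM.

All matchers share the same contract: ``train(enrollment signatures) ->
model`` and ``score(model, test signature) -> similarity`` where a higher
score always means "more likely genuine".  The evaluation protocols never
need per-matcher branches.

* **DTW** — a subset of time functions is matched elastically with the
  symmetric three-step dynamic programming recursion (steps (1,0) and
  (0,1) with weight 1, (1,1) with weight 2, Euclidean local cost,
  normalized by the summed lengths).  The raw distance to the closest
  enrollment reference is mapped to a similarity by ``exp(-d_min/d_ref)``
  where ``d_ref`` is the mean pairwise distance among the references —
  per-user normalization that makes scores comparable across users.
* **GF** — global features are tanh-normalized into (0, 1); the client is
  a diagonal Gaussian (mean + floored per-feature variance) and the score
  is the negative Mahalanobis distance.
* **HMM** — a left-to-right hidden Markov model (default 12 states, 4
  diagonal Gaussian mixtures per state) trained with Baum-Welch on the
  time-function rows; the score is the per-frame forward log-likelihood.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._ghmm import LeftRightGMMHMM
from .errors import SigagingError
from .features import (
    DTW_FUNCTIONS,
    HMM_FUNCTIONS,
    GlobalFeatureVector,
    TanhNormalizer,
    TimeFunctionSet,
    apply_tanh,
    compute_global_features,
    compute_time_functions,
    fit_tanh,
    preprocess,
)
from .types import DynamicSignature

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f
        return deco


# ---------------------------------------------------------------------------
# DTW

@njit(fastmath=True, cache=False)
def _dtw_cost(a: np.ndarray, b: np.ndarray) -> float:
    # two-row dynamic program over the three-step symmetric recursion
    n, m, K = a.shape[0], b.shape[0], a.shape[1]
    prev = np.empty(m)
    cur = np.empty(m)
    for j in range(m):
        d = 0.0
        for k in range(K):
            diff = a[0, k] - b[j, k]
            d += diff * diff
        d = np.sqrt(d)
        prev[j] = 2.0 * d if j == 0 else prev[j - 1] + d
    for i in range(1, n):
        for j in range(m):
            d = 0.0
            for k in range(K):
                diff = a[i, k] - b[j, k]
                d += diff * diff
            d = np.sqrt(d)
            best = prev[j] + d
            if j > 0:
                if cur[j - 1] + d < best:
                    best = cur[j - 1] + d
                if prev[j - 1] + 2.0 * d < best:
                    best = prev[j - 1] + 2.0 * d
            cur[j] = best
        prev, cur = cur, prev
    return prev[m - 1]


def dtw_distance(a: TimeFunctionSet, b: TimeFunctionSet) -> float:
    """Normalized symmetric DTW distance between two time-function sets.

    Dynamic-programming minimum of the accumulated Euclidean local cost
    over the three admissible steps {(1,0): w=1, (0,1): w=1, (1,1): w=2}
    (the first cell carries weight 2, consistent with the diagonal step),
    divided by ``n_a + n_b``.  Symmetric by construction; zero iff the
    sequences are identical.
    """
    if a.names != b.names:
        raise ValueError(f"function catalog mismatch: {a.names} vs {b.names}")
    cost = _dtw_cost(np.ascontiguousarray(a.values, dtype=np.float64),
                     np.ascontiguousarray(b.values, dtype=np.float64))
    return float(cost) / (a.n + b.n)


@dataclass
class DTWModel:
    """Enrollment references plus their mean pairwise self-distance."""

    references: list[TimeFunctionSet]
    d_ref: float

    D_REF_FLOOR = 1e-6


@dataclass
class GFModel:
    """Tanh normalizer + diagonal Gaussian client model."""

    normalizer: TanhNormalizer
    mean: np.ndarray
    var: np.ndarray
    names: tuple[str, ...]

    VAR_FLOOR = 1e-6


class DTWMatcher:
    """System based on elastic matching of time functions."""

    name = "dtw"

    def __init__(self, functions: tuple[str, ...] = DTW_FUNCTIONS):
        self.functions = functions

    def prepare(self, sig: DynamicSignature) -> TimeFunctionSet:
        return compute_time_functions(preprocess(sig), self.functions)

    def train(self, enrollment: list) -> DTWModel:
        refs = [self._as_tfs(s) for s in enrollment]
        if not refs:
            raise SigagingError("empty enrollment")
        if len(refs) >= 2:
            ds = [dtw_distance(refs[i], refs[j])
                  for i in range(len(refs)) for j in range(i + 1, len(refs))]
            d_ref = max(float(np.mean(ds)), DTWModel.D_REF_FLOOR)
        else:
            d_ref = 1.0
        return DTWModel(references=refs, d_ref=d_ref)

    def score(self, model: DTWModel, test) -> float:
        tfs = self._as_tfs(test)
        d_min = min(dtw_distance(r, tfs) for r in model.references)
        return float(np.exp(-d_min / model.d_ref))

    def _as_tfs(self, obj) -> TimeFunctionSet:
        return obj if isinstance(obj, TimeFunctionSet) else self.prepare(obj)


class GFMatcher:
    """System based on global features and Mahalanobis distance.

    The tanh normalizer is preferably fitted once on a background
    population (all users' enrollment signatures) via
    :meth:`fit_population`, so every feature lives on one common (0, 1)
    scale; the per-user client model is then a diagonal Gaussian on that
    scale.  Without a population fit, the normalizer falls back to the
    user's own enrollment statistics.
    """

    name = "gf"

    def __init__(self) -> None:
        self.normalizer: TanhNormalizer | None = None

    def prepare(self, sig: DynamicSignature) -> GlobalFeatureVector:
        return compute_global_features(preprocess(sig))

    def fit_population(self, vectors: list[GlobalFeatureVector]) -> None:
        """Fit the shared tanh normalizer on a background population."""
        self.normalizer = fit_tanh(vectors)

    def train(self, enrollment: list) -> GFModel:
        vecs = [self._as_vec(s) for s in enrollment]
        if len(vecs) < 2:
            raise SigagingError("GF model needs >= 2 enrollment vectors")
        norm = self.normalizer if self.normalizer is not None else fit_tanh(vecs)
        normed = np.array([apply_tanh(v, norm).values for v in vecs])
        var = np.maximum(normed.var(axis=0), GFModel.VAR_FLOOR)
        return GFModel(normalizer=norm, mean=normed.mean(axis=0), var=var,
                       names=vecs[0].names)

    def score(self, model: GFModel, test) -> float:
        vec = self._as_vec(test)
        if vec.names != model.names:
            raise ValueError("feature catalog mismatch")
        v = apply_tanh(vec, model.normalizer).values
        return -float(np.sqrt(np.sum((v - model.mean) ** 2 / model.var)))

    def _as_vec(self, obj) -> GlobalFeatureVector:
        return obj if isinstance(obj, GlobalFeatureVector) else self.prepare(obj)


# ---------------------------------------------------------------------------
# HMM

@dataclass
class HMMModel:
    """Left-to-right GMM-HMM client model."""

    hmm: LeftRightGMMHMM
    names: tuple[str, ...]
    n_states: int
    n_mix: int
    history: list[float]  # Baum-Welch log-likelihood trajectory


class HMMMatcher:
    """System based on a left-to-right GMM hidden Markov model.

    Initialization is deterministic given the seed: uniform segmentation
    of each training sequence over the states, then k-means within each
    state to place the mixture components.  Baum-Welch runs until the
    log-likelihood gain drops below ``tol`` or ``n_iter`` iterations.
    The score of a test signature is its per-frame forward
    log-likelihood under the client model.
    """

    name = "hmm"

    def __init__(self, functions: tuple[str, ...] = HMM_FUNCTIONS,
                 n_states: int = 12, n_mix: int = 4, seed: int = 0,
                 n_iter: int = 15, tol: float = 1e-3):
        self.functions = functions
        self.n_states = n_states
        self.n_mix = n_mix
        self.seed = seed
        self.n_iter = n_iter
        self.tol = tol

    def prepare(self, sig: DynamicSignature) -> TimeFunctionSet:
        return compute_time_functions(preprocess(sig), self.functions)

    def train(self, enrollment: list) -> HMMModel:
        seqs = [self._as_tfs(s).values for s in enrollment]
        if len(seqs) < 2:
            raise SigagingError("HMM training needs >= 2 sequences")
        min_len = min(len(s) for s in seqs)
        n_states = self.n_states
        if min_len < n_states:
            n_states = max(2, min_len // 3)
            warnings.warn(
                f"sequences shorter than {self.n_states} states; "
                f"reducing to {n_states} states", stacklevel=2)
        hmm = LeftRightGMMHMM(n_states=n_states, n_mix=self.n_mix,
                              n_iter=self.n_iter, tol=self.tol,
                              seed=self.seed).fit(seqs)
        return HMMModel(hmm=hmm, names=self.functions, n_states=n_states,
                        n_mix=self.n_mix, history=list(hmm.history))

    def score(self, model: HMMModel, test) -> float:
        tfs = self._as_tfs(test)
        if tfs.names != model.names:
            raise ValueError("function catalog mismatch")
        return model.hmm.loglik(tfs.values) / tfs.n

    def _as_tfs(self, obj) -> TimeFunctionSet:
        return obj if isinstance(obj, TimeFunctionSet) else self.prepare(obj)


MATCHERS = {"dtw": DTWMatcher, "gf": GFMatcher, "hmm": HMMMatcher}


def make_matcher(system: str, **kwargs):
    """Instantiate one of the three systems by name ('dtw', 'gf', 'hmm')."""
    if system not in MATCHERS:
        raise ValueError(f"unknown system {system!r}; expected one of {sorted(MATCHERS)}")
    return MATCHERS[system](**kwargs)


# ---------------------------------------------------------------------------
# plain-text model serialization (versioned, human-readable JSON)

def save_model(model, path: str | Path) -> None:
    """Serialize a trained model to human-readable JSON."""
    if isinstance(model, DTWModel):
        payload = {
            "format": "sigaging-model/1", "system": "dtw", "d_ref": model.d_ref,
            "references": [
                {"names": list(r.names), "values": r.values.tolist(),
                 "source": list(r.source)}
                for r in model.references
            ],
        }
    elif isinstance(model, GFModel):
        payload = {
            "format": "sigaging-model/1", "system": "gf",
            "names": list(model.names),
            "norm_mu": model.normalizer.mu.tolist(),
            "norm_sigma": model.normalizer.sigma.tolist(),
            "mean": model.mean.tolist(), "var": model.var.tolist(),
        }
    elif isinstance(model, HMMModel):
        h = model.hmm
        payload = {
            "format": "sigaging-model/1", "system": "hmm",
            "names": list(model.names), "n_states": model.n_states,
            "n_mix": model.n_mix,
            "startprob": h.startprob.tolist(), "transmat": h.transmat.tolist(),
            "means": h.means.tolist(), "covars": h.covars.tolist(),
            "weights": h.weights.tolist(),
        }
    else:
        raise TypeError(f"not a model: {type(model)!r}")
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    """Load a model serialized by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "sigaging-model/1":
        raise SigagingError(f"{path}: not a sigaging model file")
    system = payload["system"]
    if system == "dtw":
        refs = [TimeFunctionSet(names=tuple(r["names"]),
                                values=np.asarray(r["values"], dtype=float),
                                source=tuple(r["source"]))
                for r in payload["references"]]
        return DTWModel(references=refs, d_ref=float(payload["d_ref"]))
    if system == "gf":
        names = tuple(payload["names"])
        norm = TanhNormalizer(names=names,
                              mu=np.asarray(payload["norm_mu"], dtype=float),
                              sigma=np.asarray(payload["norm_sigma"], dtype=float))
        return GFModel(normalizer=norm,
                       mean=np.asarray(payload["mean"], dtype=float),
                       var=np.asarray(payload["var"], dtype=float), names=names)
    if system == "hmm":
        h = LeftRightGMMHMM(n_states=payload["n_states"], n_mix=payload["n_mix"])
        h.startprob = np.asarray(payload["startprob"], dtype=float)
        h.transmat = np.asarray(payload["transmat"], dtype=float)
        h.means = np.asarray(payload["means"], dtype=float)
        h.covars = np.asarray(payload["covars"], dtype=float)
        h.weights = np.asarray(payload["weights"], dtype=float)
        return HMMModel(hmm=h, names=tuple(payload["names"]),
                        n_states=payload["n_states"], n_mix=payload["n_mix"],
                        history=[])
    raise SigagingError(f"{path}: unknown system {system!r}")
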
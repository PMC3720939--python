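"""Score protocols and biometric error-rate evaluation.

Two protocols are implemented on the six-session long-term grid:

* **Aging (experiments A-E)** — fixed template, varying test.  Each user's
  model is trained on the 4 first-session (BID1) samples; genuine scores
  are computed against the samples of each later session (BID2, BID3,
  BID4, Bure1, Bure2).  One shared impostor set is used for A-E: for each
  target user, the first sample of each of the six sessions of every other
  user, i.e. ``6 * (n_users - 1)`` impostor scores per user.
* **Template update (experiments F-I)** — varying template, fixed test
  (the Bure13 group, 5 samples per user).  F enrolls BID1 (baseline, no
  update); G enrolls Bure11 (complete update, 4 recent samples); H enrolls
  BID1+Bure11 (mixed update, 8 samples); I enrolls Bure11+Bure12 (complete
  update, 8 recent samples).  Impostors are designated as in the aging
  protocol but re-scored against each experiment's model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError
from .types import DynamicSignature, LongTermDataset

AGING_EXPERIMENTS: dict[str, str] = {
    "A": "BID2", "B": "BID3", "C": "BID4", "D": "Bure1", "E": "Bure2",
}

UPDATE_EXPERIMENTS: dict[str, tuple[tuple[str, ...], str]] = {
    "F": (("BID1",), "Bure13"),
    "G": (("Bure11",), "Bure13"),
    "H": (("BID1", "Bure11"), "Bure13"),
    "I": (("Bure11", "Bure12"), "Bure13"),
}

#: Storage sessions whose first sample provides the designated impostor
#: signature of each of the six acquisition sessions.
IMPOSTOR_SESSIONS: tuple[str, ...] = (
    "BID1", "BID2", "BID3", "BID4", "Bure11", "Bure21",
)


@dataclass
class ScoreSet:
    """Labeled genuine/impostor scores for one experiment cell."""

    experiment_id: str
    system: str
    genuine: list[tuple[str, float]] = field(default_factory=list)
    impostor: list[tuple[str, float]] = field(default_factory=list)

    def genuine_scores(self, user_id: str | None = None) -> np.ndarray:
        vals = [s for u, s in self.genuine if user_id is None or u == user_id]
        return np.asarray(vals, dtype=float)

    def impostor_scores(self, user_id: str | None = None) -> np.ndarray:
        vals = [s for u, s in self.impostor if user_id is None or u == user_id]
        return np.asarray(vals, dtype=float)


@dataclass
class DETResult:
    """Empirical detection error trade-off curve plus its equal error rate."""

    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray
    eer: float


class _FeatureCache:
    """Per-matcher cache of prepared feature objects, keyed by signature."""

    def __init__(self, matcher):
        self.matcher = matcher
        self._cache: dict[tuple[str, str, int], object] = {}

    def __call__(self, sig: DynamicSignature):
        key = sig.key
        if key not in self._cache:
            self._cache[key] = self.matcher.prepare(sig)
        return self._cache[key]


def _require_sessions(ds: LongTermDataset, user: str, sessions: tuple[str, ...]) -> None:
    for sid in sessions:
        if not ds.session_samples(user, sid):
            raise ProtocolError(f"user {user}: session {sid} missing from dataset")


def _fit_population(matcher, ds: LongTermDataset, cache: "_FeatureCache") -> None:
    """Fit a matcher's background-population statistics (if it has any)
    on the first-session enrollment signatures of every user."""
    if hasattr(matcher, "fit_population") and getattr(matcher, "normalizer", 1) is None:
        vectors = [cache(s) for user in ds.users
                   for s in ds.session_samples(user, "BID1")]
        matcher.fit_population(vectors)


def _impostor_probes(ds: LongTermDataset, target: str) -> list[DynamicSignature]:
    probes = []
    for other in ds.users:
        if other == target:
            continue
        for sid in IMPOSTOR_SESSIONS:
            key = (other, sid, 1)
            if key not in ds.signatures:
                raise ProtocolError(f"impostor probe missing: {key}")
            probes.append(ds.signatures[key])
    return probes


def run_aging_protocol(ds: LongTermDataset, matcher) -> list[ScoreSet]:
    """Experiments A-E: enroll on BID1, test on each later session.

    The impostor score list is computed once per user and shared (the same
    list object) by all five score sets.
    """
    cache = _FeatureCache(matcher)
    _fit_population(matcher, ds, cache)
    sets = {eid: ScoreSet(experiment_id=eid, system=matcher.name)
            for eid in AGING_EXPERIMENTS}
    shared_impostor: list[tuple[str, float]] = []
    for eid in AGING_EXPERIMENTS:
        sets[eid].impostor = shared_impostor

    for user in ds.users:
        _require_sessions(ds, user, ("BID1",) + tuple(AGING_EXPERIMENTS.values()))
        enroll = [cache(s) for s in ds.session_samples(user, "BID1")]
        model = matcher.train(enroll)
        for eid, test_session in AGING_EXPERIMENTS.items():
            for sig in ds.session_samples(user, test_session):
                sets[eid].genuine.append((user, matcher.score(model, cache(sig))))
        for probe in _impostor_probes(ds, user):
            shared_impostor.append((user, matcher.score(model, cache(probe))))
    return [sets[eid] for eid in AGING_EXPERIMENTS]


def run_update_protocol(ds: LongTermDataset, matcher) -> list[ScoreSet]:
    """Experiments F-I: varying enrollment, fixed Bure13 test set."""
    cache = _FeatureCache(matcher)
    _fit_population(matcher, ds, cache)
    out = []
    probes_per_user = {user: _impostor_probes(ds, user) for user in ds.users}
    for eid, (enroll_sessions, test_session) in UPDATE_EXPERIMENTS.items():
        ss = ScoreSet(experiment_id=eid, system=matcher.name)
        for user in ds.users:
            _require_sessions(ds, user, enroll_sessions + (test_session,))
            enroll = []
            for sid in enroll_sessions:
                # 4 signatures per enrollment session (the Bure groups hold
                # 5 samples; only the first 4 enter the template)
                samples = ds.session_samples(user, sid)[:4]
                enroll.extend(cache(s) for s in samples)
            model = matcher.train(enroll)
            for sig in ds.session_samples(user, test_session):
                ss.genuine.append((user, matcher.score(model, cache(sig))))
            for probe in probes_per_user[user]:
                ss.impostor.append((user, matcher.score(model, cache(probe))))
        out.append(ss)
    return out


# ---------------------------------------------------------------------------
# DET / EER

def compute_det(genuine, impostor) -> DETResult:
    """Empirical FAR/FRR step curves over the pooled threshold sweep.

    Acceptance rule: accept iff ``score >= threshold``.  FAR is therefore
    non-increasing and FRR non-decreasing in the threshold.  The EER is
    read at the first threshold where FRR >= FAR, linearly interpolated
    between the bracketing operating points (ties broken toward the lower
    threshold).
    """
    g = np.asarray(list(genuine), dtype=float)
    i = np.asarray(list(impostor), dtype=float)
    if g.size == 0 or i.size == 0:
        raise ValueError("genuine and impostor score lists must be non-empty")
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(i))):
        raise ValueError("scores must be finite")
    thr = np.unique(np.concatenate([g, i]))
    # evaluate on thresholds plus one above the max so FAR can reach 0
    thr = np.concatenate([thr, [thr[-1] + 1.0]])
    far = np.array([(i >= th).mean() for th in thr])
    frr = np.array([(g < th).mean() for th in thr])

    eer = None
    for idx in range(len(thr)):
        if frr[idx] >= far[idx]:
            if idx == 0 or frr[idx] == far[idx]:
                eer = 0.5 * (frr[idx] + far[idx])
            else:
                # linear interpolation between the bracketing points of the
                # (FRR - FAR) sign change
                d0 = far[idx - 1] - frr[idx - 1]
                d1 = far[idx] - frr[idx]
                w = d0 / (d0 - d1) if d0 != d1 else 0.0
                eer = float((1 - w) * 0.5 * (far[idx - 1] + frr[idx - 1])
                            + w * 0.5 * (far[idx] + frr[idx]))
            break
    assert eer is not None  # frr reaches 1 and far reaches 0 at the top
    return DETResult(thresholds=thr, far=far, frr=frr, eer=float(eer))


def eer(det: DETResult) -> float:
    """Equal error rate of a DET curve, in [0, 1]."""
    return det.eer


def eer_of_scores(genuine, impostor) -> float:
    return compute_det(genuine, impostor).eer


def score_stats(score_set: ScoreSet | np.ndarray) -> tuple[float, float]:
    """Sample mean and unbiased variance of the genuine scores."""
    if isinstance(score_set, ScoreSet):
        vals = score_set.genuine_scores()
    else:
        vals = np.asarray(score_set, dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 genuine scores for a variance")
    return float(vals.mean()), float(vals.var(ddof=1))
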
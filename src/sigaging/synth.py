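"""Synthetic multi-session signature generation with controllable aging drift.

Each simulated signer is a :class:`UserPrototype`: a fixed set of smooth
pen strokes (cubic splines through random control points in a unit box), a
base duration, a number of interior pen-ups and a pressure profile.  A
rendered sample is the prototype plus

* *intra-session jitter* — small random perturbations of control points,
  duration and pressure that differ from sample to sample, and
* *aging drift* — a systematic, month-dependent transformation applied to
  the prototype before jitter, so that aging is a trend and not noise.

The drift emulates the simplification of signatures observed over long
time spans: signatures become shorter (duration shrink), smoother (a
growing smoothing kernel removes curvature extrema, i.e. local maxima of
the coordinate functions), with fewer pen-ups (each interior pen-up is
merged with growing probability) and consequently faster (path length is
roughly conserved while duration shrinks).  Each user carries a random
multiplicative drift scale, making the amount of aging strongly
user-dependent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .errors import GenerationError
from .types import (
    DatasetManifest,
    DynamicSignature,
    LongTermDataset,
    SAMPLING_RATE_HZ,
)

#: Tablet scale: unit-box coordinates are mapped to this many tablet units.
TABLET_SCALE = 2000.0

_DENSE_PER_STROKE = 400  # dense samples per stroke before smoothing/resampling


def _seed_seq(*parts) -> np.random.SeedSequence:
    """Stable seed derivation: strings are hashed with crc32."""
    ints = []
    for p in parts:
        if isinstance(p, str):
            ints.append(zlib.crc32(p.encode()))
        else:
            ints.append(int(p) & 0x7FFFFFFF)
    return np.random.SeedSequence(ints)


@dataclass
class UserPrototype:
    """The stable identity of one simulated signer."""

    user_id: str
    seed: int
    strokes: list[np.ndarray]          # each (n_ctrl, 2) control points, unit box
    base_duration: float               # seconds
    base_penups: int                   # interior pen-ups = len(strokes) - 1
    pressure_phases: list[np.ndarray]  # per stroke, random Fourier phases
    complexity: int

    def __post_init__(self) -> None:
        if not self.strokes:
            raise ValueError("prototype needs at least one stroke")
        if not 1.0 <= self.base_duration <= 15.0:
            raise ValueError("base_duration must lie in [1, 15] s")


@dataclass
class DriftConfig:
    """Aging-drift and jitter parameters.

    Rates are per month of elapsed time; jitters are dimensionless noise
    scales applied per rendered sample.  ``per_user_scale_sigma`` is the
    log-normal sigma of the per-user multiplier applied to all three drift
    rates (clipped to ``per_user_scale_range``), which makes the degree of
    aging signer-dependent.
    """

    alpha_duration: float = 0.012   # fractional duration shrink / month
    alpha_smooth: float = 0.05      # smoothing-kernel growth / month
    alpha_penup: float = 0.02       # pen-up merge probability / month
    alpha_detail: float = 0.03      # stroke-detail removal fraction / month
    alpha_jitter: float = 0.12      # intra-sample jitter growth / month
    jitter_xy: float = 0.010        # control-point jitter, unit-box fraction
    jitter_time: float = 0.03       # fractional duration jitter
    jitter_pressure: float = 0.05   # fractional pressure-peak jitter
    per_user_scale_sigma: float = 0.75
    per_user_scale_range: tuple[float, float] = (0.2, 2.5)

    def __post_init__(self) -> None:
        for name in ("alpha_duration", "alpha_smooth", "alpha_penup",
                     "alpha_detail", "alpha_jitter", "jitter_xy",
                     "jitter_time", "jitter_pressure"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def zero(cls, **jitter) -> "DriftConfig":
        """No aging at all (jitter may still be supplied)."""
        return cls(alpha_duration=0.0, alpha_smooth=0.0, alpha_penup=0.0,
                   alpha_detail=0.0, alpha_jitter=0.0, **jitter)

    def user_scales(self, n_users: int, rng: np.random.Generator) -> np.ndarray:
        """Draw the per-user drift multipliers (log-normal, clipped)."""
        lo, hi = self.per_user_scale_range
        s = rng.lognormal(mean=-0.5 * self.per_user_scale_sigma ** 2,
                          sigma=self.per_user_scale_sigma, size=n_users)
        return np.clip(s, lo, hi)


def make_prototype(user_id: str, seed: int, complexity: int = 6) -> UserPrototype:
    """Create a reproducible signer prototype.

    ``complexity`` sets the number of control points per stroke, hence the
    number of curvature extrema the rendered coordinate functions exhibit.
    """
    if complexity < 2:
        raise ValueError("complexity must be >= 2")
    rng = np.random.default_rng(_seed_seq(seed, user_id, "proto"))
    n_strokes = int(rng.integers(2, 5))  # 1..4 interior pen-ups
    strokes = []
    for s in range(n_strokes):
        n_ctrl = complexity + 2
        # random-walk control points with a mild left-to-right progression,
        # rescaled into the unit box
        steps = rng.normal(size=(n_ctrl, 2))
        steps[:, 0] += 0.6
        pts = np.cumsum(steps, axis=0)
        pts -= pts.min(axis=0)
        span = np.maximum(pts.max(axis=0), 1e-6)
        pts = pts / span
        # place each stroke in its horizontal band of the signing box
        pts[:, 0] = (s + pts[:, 0]) / n_strokes
        pts[:, 1] = 0.2 + 0.6 * pts[:, 1]
        strokes.append(pts)
    base_duration = float(rng.uniform(2.0, 4.0))
    phases = [rng.uniform(0, 2 * np.pi, size=3) for _ in range(n_strokes)]
    return UserPrototype(
        user_id=user_id, seed=seed, strokes=strokes,
        base_duration=base_duration, base_penups=n_strokes - 1,
        pressure_phases=phases, complexity=complexity,
    )


def _simplify_stroke(ctrl: np.ndarray, p_remove: float,
                     thresholds: np.ndarray) -> np.ndarray:
    """Drop low-salience interior control points whose threshold is exceeded.

    Salience is the distance of a point to the chord of its neighbors;
    points are ranked per stroke so the least salient detail disappears
    first.  ``thresholds`` (one per interior point, fixed per signer) make
    the removal order signer-specific but reproducible, so simplification
    is a systematic drift, not sample noise.  At least 3 points survive.
    """
    n = len(ctrl)
    if p_remove <= 0 or n <= 3:
        return ctrl
    interior = np.arange(1, n - 1)
    chord = ctrl[interior + 1] - ctrl[interior - 1]
    chord_len = np.maximum(np.linalg.norm(chord, axis=1), 1e-12)
    rel = ctrl[interior] - ctrl[interior - 1]
    sal = np.abs(chord[:, 0] * rel[:, 1] - chord[:, 1] * rel[:, 0]) / chord_len
    ranks = np.argsort(np.argsort(sal))
    rank_norm = (ranks + 0.5) / len(interior)
    thr = np.clip(rank_norm + 0.2 * (thresholds[: len(interior)] - 0.5), 0, 1)
    drop = thr < p_remove
    # keep the most salient points if the cut would go below 3 points
    if n - drop.sum() < 3:
        keep_order = np.argsort(-sal)
        drop[:] = True
        drop[keep_order[: max(1, 3 - 2)]] = False
    keep = np.ones(n, dtype=bool)
    keep[interior[drop]] = False
    return ctrl[keep]


def _pressure_profile(progress: np.ndarray, phases: np.ndarray, peak: float) -> np.ndarray:
    """Smooth positive pressure bump over one stroke's [0, 1] progress."""
    bump = np.sin(np.pi * np.clip(progress, 0, 1)) ** 0.5
    wobble = 1.0 + 0.10 * np.sin(2 * np.pi * progress + phases[0]) \
                 + 0.05 * np.sin(4 * np.pi * progress + phases[1])
    return peak * np.clip(bump * wobble, 0.05, 1.2)


def render_signature(
    proto: UserPrototype,
    month: float,
    drift: DriftConfig,
    user_drift_scale: float = 1.0,
    sample_seed: int = 0,
    session_id: str = "BID1",
    sample_idx: int = 1,
) -> DynamicSignature:
    """Render one 100 Hz sample of a prototype at a given nominal month.

    Drift (duration shrink, trajectory smoothing, pen-up merging) is applied
    to the prototype as a function of ``month`` before sample jitter, so two
    renders at the same month differ only by jitter.
    """
    if month < 0:
        raise ValueError("month must be >= 0")
    rng = np.random.default_rng(_seed_seq(proto.seed, proto.user_id, sample_seed))
    s = float(user_drift_scale)

    # motor variability grows with aging: all jitters widen with month
    jfac = 1.0 + s * drift.alpha_jitter * month

    shrink = s * drift.alpha_duration * month
    duration = proto.base_duration * (1.0 - shrink)
    duration *= 1.0 + jfac * drift.jitter_time * rng.standard_normal()
    if duration <= 0.2:
        raise GenerationError(
            f"drift leaves duration {duration:.3f} s <= 0.2 s for "
            f"{proto.user_id} at month {month}"
        )

    # pen-up merging is systematic, not per-sample noise: each interior gap
    # carries a fixed per-user threshold and disappears for good once the
    # accumulated merge pressure exceeds it.  Marginally over users, a gap
    # is merged with probability min(1, scale*alpha_penup*month).
    gap_rng = np.random.default_rng(_seed_seq(proto.seed, proto.user_id, "gaps"))
    gap_thresholds = gap_rng.random(proto.base_penups)
    p_merge = min(1.0, s * drift.alpha_penup * month)
    keep_gap = gap_thresholds >= p_merge

    # group strokes between surviving pen-ups
    groups: list[list[np.ndarray]] = [[proto.strokes[0]]]
    for gi in range(proto.base_penups):
        if keep_gap[gi]:
            groups.append([])
        groups[-1].append(proto.strokes[gi + 1])

    sigma = 2.0 * (1.0 + s * drift.alpha_smooth * month)  # dense-grid units
    p_remove = min(0.8, s * drift.alpha_detail * month)
    detail_rng = np.random.default_rng(_seed_seq(proto.seed, proto.user_id, "detail"))

    dense_xy: list[np.ndarray] = []
    for group in groups:
        pieces = []
        for ctrl in group:
            thresholds = detail_rng.random(len(ctrl))
            ctrl = _simplify_stroke(ctrl, p_remove, thresholds)
            ctrl = ctrl + jfac * drift.jitter_xy * rng.standard_normal(ctrl.shape)
            u = np.linspace(0, 1, len(ctrl))
            spl_x = CubicSpline(u, ctrl[:, 0])
            spl_y = CubicSpline(u, ctrl[:, 1])
            ud = np.linspace(0, 1, _DENSE_PER_STROKE)
            pieces.append(np.column_stack([spl_x(ud), spl_y(ud)]))
        xy = np.concatenate(pieces, axis=0)
        xy[:, 0] = gaussian_filter1d(xy[:, 0], sigma, mode="nearest")
        xy[:, 1] = gaussian_filter1d(xy[:, 1], sigma, mode="nearest")
        dense_xy.append(xy)

    n_gaps = len(dense_xy) - 1
    gap_durs = rng.uniform(0.05, 0.20, size=n_gaps) if n_gaps else np.array([])
    total_gap = float(gap_durs.sum())
    if total_gap > 0.4 * duration:  # keep the pen on paper most of the time
        gap_durs *= 0.4 * duration / total_gap
        total_gap = 0.4 * duration
    pendown_total = duration - total_gap

    lengths = np.array([np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1))
                        for xy in dense_xy])
    lengths = np.maximum(lengths, 1e-9)
    stroke_durs = pendown_total * lengths / lengths.sum()

    dt = 1.0 / SAMPLING_RATE_HZ
    peak = 900.0 * (1.0 + jfac * drift.jitter_pressure * rng.standard_normal())
    peak = float(np.clip(peak, 300.0, 1023.0))

    xs, ys, ps = [], [], []
    for gi, xy in enumerate(dense_xy):
        n_samp = max(3, int(round(stroke_durs[gi] / dt)))
        prog = np.linspace(0, 1, n_samp)
        idx = prog * (len(xy) - 1)
        xs.append(np.interp(idx, np.arange(len(xy)), xy[:, 0]))
        ys.append(np.interp(idx, np.arange(len(xy)), xy[:, 1]))
        phases = proto.pressure_phases[min(gi, len(proto.pressure_phases) - 1)]
        pr = _pressure_profile(prog, phases, peak)
        ps.append(np.clip(np.round(pr), 1, 1023))
        if gi < len(dense_xy) - 1:
            n_gap = max(1, int(round(gap_durs[gi] / dt)))
            x0, y0 = xy[-1]
            x1, y1 = dense_xy[gi + 1][0]
            frac = np.linspace(0, 1, n_gap + 2)[1:-1]
            xs.append(x0 + frac * (x1 - x0))
            ys.append(y0 + frac * (y1 - y0))
            ps.append(np.zeros(n_gap))

    x = np.concatenate(xs) * TABLET_SCALE
    y = np.concatenate(ys) * TABLET_SCALE
    p = np.concatenate(ps).astype(int)
    n = len(x)
    t = np.arange(n) * (1000.0 * dt)
    return DynamicSignature(
        user_id=proto.user_id, session_id=session_id, sample_idx=sample_idx,
        month=float(month), t=t, x=x, y=y, p=p,
    )


def generate_longterm_db(
    n_users: int,
    manifest: DatasetManifest,
    drift: DriftConfig | None = None,
    master_seed: int = 0,
    complexity_range: tuple[int, int] = (4, 9),
) -> tuple[LongTermDataset, dict[str, float]]:
    """Generate a full long-term dataset.

    Returns the dataset and the planted per-user drift scales (the ground
    truth that the aging statistics downstream should recover).  Seeds fan
    out deterministically from ``master_seed`` per user and per sample, so
    adding users does not reshuffle existing ones.
    """
    drift = drift if drift is not None else DriftConfig()
    if manifest.n_users != n_users:
        manifest = replace(manifest, n_users=n_users)
    scale_rng = np.random.default_rng(_seed_seq(master_seed, "user-scales"))
    scales = drift.user_scales(n_users, scale_rng)

    signatures = {}
    user_scales: dict[str, float] = {}
    for ui, user_id in enumerate(manifest.user_ids):
        crng = np.random.default_rng(_seed_seq(master_seed, user_id, "complexity"))
        complexity = int(crng.integers(complexity_range[0], complexity_range[1] + 1))
        proto = make_prototype(user_id, seed=master_seed, complexity=complexity)
        scale = float(scales[ui])
        user_scales[user_id] = scale
        for si, (sid, idx, month) in enumerate(manifest.sample_order()):
            sample_seed = int(_seed_seq(master_seed, user_id, si).generate_state(1)[0])
            sig = render_signature(
                proto, month=month, drift=drift, user_drift_scale=scale,
                sample_seed=sample_seed, session_id=sid, sample_idx=idx,
            )
            signatures[sig.key] = sig
    return LongTermDataset(manifest=manifest, signatures=signatures), user_scales
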
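"""Signature preprocessing, time functions, and global features.

Two feature families feed the three verification systems:

* *time functions* — per-sample signals (coordinates, pressure, their
  derivatives, speed, path angle, curvature, acceleration) consumed by the
  elastic (DTW) and sequence (HMM) matchers;
* *global features* — scalars computed over the whole signature (duration,
  pen-up count, extrema counts, speed statistics, geometry, ...) consumed
  by the Mahalanobis matcher and by the feature-stability analysis.

Global features carry a ``static``/``dynamic`` label.  The labeling rule
is mechanical: a feature is *dynamic* iff its formula references the
timestamps or a time derivative, else it is *static*.  Operationally,
static features are invariant under a uniform time rescaling of the
signature (same trajectory replayed at a different speed) while dynamic
features are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import PreprocessingError
from .types import DynamicSignature

_EPS = 1e-12


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(sig: DynamicSignature) -> DynamicSignature:
    """Position and rotation alignment.

    The pen-down point cloud is translated so its centroid is at the
    origin and rotated so its principal axis is horizontal.  The 180-degree
    ambiguity is resolved by the writing direction: the start-to-end
    displacement along the principal axis is made non-negative.  That
    projection is a full-width-sized quantity, so small sample jitter
    cannot flip the orientation between renditions of one signature; only
    when the pen returns almost exactly to its starting abscissa
    (projection below 5% of the width) does the rule fall back to the
    sign of the skewness of ``x``.  Timestamps are rebased to zero.
    Idempotent up to numerical tolerance.
    """
    down = ~sig.penup
    if down.sum() < 2:
        raise PreprocessingError("fewer than 2 pen-down samples")
    pts = np.column_stack([sig.x, sig.y]).astype(float)
    cen = pts[down].mean(axis=0)
    pts -= cen
    cov = np.cov(pts[down].T)
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
        raise PreprocessingError("degenerate point cloud (all points identical)")
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    angle = np.arctan2(major[1], major[0])
    c, s = np.cos(-angle), np.sin(-angle)
    rot = np.array([[c, -s], [s, c]])
    pts = pts @ rot.T
    xd = pts[down, 0]
    width = xd.max() - xd.min()
    proj = pts[down][-1, 0] - pts[down][0, 0]  # writing direction along x
    if abs(proj) > 0.05 * width:
        flip = proj < 0
    else:
        flip = np.mean((xd - xd.mean()) ** 3) < 0
    if flip:  # pick the consistent 180-degree alternative
        pts = -pts
    return sig.copy(t=sig.t - sig.t[0], x=pts[:, 0], y=pts[:, 1])


# ---------------------------------------------------------------------------
# time functions

@dataclass
class TimeFunctionSet:
    """An n x K matrix of per-sample functions, with column names."""

    names: tuple[str, ...]
    values: np.ndarray
    source: tuple[str, str, int]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be n x len(names)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time functions contain NaN/Inf")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _deriv(v: np.ndarray, t_s: np.ndarray) -> np.ndarray:
    """Central-difference derivative with one-sided ends."""
    return np.gradient(v, t_s, edge_order=1)


#: Full time-function catalog.  ``x/y/p`` are the preprocessed signals.
TIME_FUNCTION_CATALOG: tuple[str, ...] = (
    "x", "y", "p",
    "dx", "dy", "dp",
    "speed", "path_angle", "d_angle",
    "log_curv_radius", "accel", "d_speed",
)

#: Default selected subsets (fixed configuration, not re-derived).
HMM_FUNCTIONS: tuple[str, ...] = (
    "x", "y", "p", "dx", "dy", "dp", "speed", "path_angle", "d_angle", "accel",
)
DTW_FUNCTIONS: tuple[str, ...] = (
    "x", "y", "dx", "dy", "speed", "path_angle", "d_angle", "accel", "d_speed",
)


def compute_time_functions(
    sig: DynamicSignature,
    catalog: tuple[str, ...] = TIME_FUNCTION_CATALOG,
    standardize: bool = True,
) -> TimeFunctionSet:
    """Compute the requested per-sample functions.

    Derivatives use central differences on the (nominally 100 Hz) time
    axis in seconds.  Each column is z-score standardized per signature
    (constant columns are left at zero) so that distances are comparable
    across heterogeneous units.
    """
    unknown = set(catalog) - set(TIME_FUNCTION_CATALOG)
    if unknown:
        raise ValueError(f"unknown time functions: {sorted(unknown)}")
    t_s = sig.t / 1000.0
    x, y, p = sig.x.astype(float), sig.y.astype(float), sig.p.astype(float)
    dx, dy, dp = _deriv(x, t_s), _deriv(y, t_s), _deriv(p, t_s)
    speed = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    # unwrap to avoid +-pi jumps in the angle derivative
    dtheta = _deriv(np.unwrap(theta), t_s)
    curv_radius = speed / (np.abs(dtheta) + _EPS)
    log_curv = np.log1p(curv_radius)
    ddx, ddy = _deriv(dx, t_s), _deriv(dy, t_s)
    accel = np.hypot(ddx, ddy)
    d_speed = _deriv(speed, t_s)
    cols = {
        "x": x, "y": y, "p": p, "dx": dx, "dy": dy, "dp": dp,
        "speed": speed, "path_angle": theta, "d_angle": dtheta,
        "log_curv_radius": log_curv, "accel": accel, "d_speed": d_speed,
    }
    mat = np.column_stack([cols[name] for name in catalog])
    if standardize:
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0)
        sd = np.where(sd < _EPS, 1.0, sd)
        mat = (mat - mu) / sd
    return TimeFunctionSet(names=tuple(catalog), values=mat, source=sig.key)


# ---------------------------------------------------------------------------
# interpretable counts

def count_penups(sig: DynamicSignature) -> int:
    """Number of maximal interior zero-pressure runs of a trimmed signature."""
    up = sig.penup.astype(int)
    starts = np.flatnonzero(np.diff(up) == 1) + 1
    # trimmed signatures start/end pen-down, so every run found is interior
    return int(len(starts)) if up.any() else 0


def count_local_maxima(series: np.ndarray) -> int:
    """Strict local maxima with plateaus counted once (at plateau start).

    A sample counts if it is strictly greater than the nearest *differing*
    neighbor on both sides.
    """
    v = np.asarray(series, dtype=float)
    if len(v) < 3:
        warnings.warn("series shorter than 3; no maxima defined", stacklevel=2)
        return 0
    # compress plateau runs to single representatives
    keep = np.concatenate([[True], np.diff(v) != 0])
    w = v[keep]
    if len(w) < 3:
        return 0
    return int(np.sum((w[1:-1] > w[:-2]) & (w[1:-1] > w[2:])))


# ---------------------------------------------------------------------------
# global features

@dataclass
class GlobalFeatureVector:
    """Named holistic features of one signature with static/dynamic labels."""

    names: tuple[str, ...]
    values: np.ndarray
    kind: tuple[str, ...]  # "static" | "dynamic", parallel to names
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values) or len(self.kind) != len(self.names):
            raise ValueError("names, values and kind must have equal length")
        if self.normalized and (np.any(self.values < 0) or np.any(self.values > 1)):
            raise ValueError("normalized features must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def _stats(v: np.ndarray) -> tuple[float, float, float]:
    return float(np.mean(v)), float(np.std(v)), float(np.max(v)) if len(v) else 0.0


def compute_global_features(sig: DynamicSignature) -> GlobalFeatureVector:
    """Compute the global feature catalog on a preprocessed signature.

    The catalog mixes geometric/shape quantities (static) with
    timing/velocity/acceleration quantities (dynamic); the five classically
    interpretable features (duration, n_penups, n_max_x, n_max_y,
    avg_speed) are always present.
    """
    if sig.n < 3:
        raise PreprocessingError("signature too short for global features")
    t_s = sig.t / 1000.0
    x, y = sig.x.astype(float), sig.y.astype(float)
    p = sig.p.astype(float)
    down = ~sig.penup
    if down.sum() < 3:
        raise PreprocessingError("too few pen-down samples")

    duration = float(t_s[-1] - t_s[0])
    seg = np.hypot(np.diff(x), np.diff(y))
    path_length = float(seg.sum())
    dx, dy = _deriv(x, t_s), _deriv(y, t_s)
    speed = np.hypot(dx, dy)
    ddx, ddy = _deriv(dx, t_s), _deriv(dy, t_s)
    accel = np.hypot(ddx, ddy)
    jerk = np.hypot(_deriv(ddx, t_s), _deriv(ddy, t_s))

    width = float(x[down].max() - x[down].min())
    height = float(y[down].max() - y[down].min())
    xd, yd = x[down], y[down]
    pd = p[down]

    # turning-angle statistics on the polyline (geometry only -> static)
    seg_angles = np.arctan2(np.diff(y), np.diff(x))
    turn = np.diff(np.unwrap(seg_angles))
    sign_changes = int(np.sum(np.diff(np.sign(turn[np.abs(turn) > 1e-9])) != 0))

    pen_down_time = float(np.sum(np.diff(t_s)[down[:-1]]))
    k = min(3, sig.n - 1)
    start_dir = float(np.arctan2(y[k] - y[0], x[k] - x[0]))
    end_dir = float(np.arctan2(y[-1] - y[-1 - k], x[-1] - x[-1 - k]))

    corr_xy = 0.0
    if np.std(xd) > _EPS and np.std(yd) > _EPS:
        corr_xy = float(np.corrcoef(xd, yd)[0, 1])

    vx_mean, vx_std, _ = _stats(dx)
    vy_mean, vy_std, _ = _stats(dy)

    feats: list[tuple[str, float, str]] = [
        # --- dynamic: formula references timestamps or derivatives
        ("duration", duration, "dynamic"),
        ("pendown_duration_ratio", pen_down_time / max(duration, _EPS), "dynamic"),
        ("avg_speed", path_length / max(duration, _EPS), "dynamic"),
        ("max_speed", float(speed.max()), "dynamic"),
        ("std_speed", float(speed.std()), "dynamic"),
        ("mean_speed_sampled", float(speed.mean()), "dynamic"),
        ("mean_vx", vx_mean, "dynamic"),
        ("std_vx", vx_std, "dynamic"),
        ("mean_vy", vy_mean, "dynamic"),
        ("std_vy", vy_std, "dynamic"),
        ("mean_abs_vx", float(np.mean(np.abs(dx))), "dynamic"),
        ("mean_abs_vy", float(np.mean(np.abs(dy))), "dynamic"),
        ("rms_accel", float(np.sqrt(np.mean(accel ** 2))), "dynamic"),
        ("max_accel", float(accel.max()), "dynamic"),
        ("rms_jerk", float(np.sqrt(np.mean(jerk ** 2))), "dynamic"),
        ("mean_dp", float(np.mean(np.abs(_deriv(p, t_s)))), "dynamic"),
        ("t_max_speed_ratio", float(t_s[int(np.argmax(speed))] / max(duration, _EPS)),
         "dynamic"),
        ("t_max_pressure_ratio", float(t_s[int(np.argmax(p))] / max(duration, _EPS)),
         "dynamic"),
        ("speed_corr_xy", float(np.corrcoef(dx, dy)[0, 1])
         if np.std(dx) > _EPS and np.std(dy) > _EPS else 0.0, "dynamic"),
        ("n_speed_maxima", float(count_local_maxima(speed)), "dynamic"),
        ("v_integral_ratio", float(np.mean(speed) / max(speed.max(), _EPS)), "dynamic"),
        # --- static: geometry, pressure levels, counts
        ("n_penups", float(count_penups(sig)), "static"),
        ("n_max_x", float(count_local_maxima(x)), "static"),
        ("n_max_y", float(count_local_maxima(y)), "static"),
        ("n_min_x", float(count_local_maxima(-x)), "static"),
        ("n_min_y", float(count_local_maxima(-y)), "static"),
        ("width", width, "static"),
        ("height", height, "static"),
        ("aspect_ratio", width / max(height, _EPS), "static"),
        ("path_length", path_length, "static"),
        ("path_to_diag_ratio", path_length / max(np.hypot(width, height), _EPS),
         "static"),
        ("mean_x", float(xd.mean()), "static"),
        ("mean_y", float(yd.mean()), "static"),
        ("std_x", float(xd.std()), "static"),
        ("std_y", float(yd.std()), "static"),
        ("skew_x", float(np.mean(((xd - xd.mean()) / max(xd.std(), _EPS)) ** 3)),
         "static"),
        ("skew_y", float(np.mean(((yd - yd.mean()) / max(yd.std(), _EPS)) ** 3)),
         "static"),
        ("corr_xy", corr_xy, "static"),
        ("start_direction", start_dir, "static"),
        ("end_direction", end_dir, "static"),
        ("turn_sign_changes", float(sign_changes), "static"),
        ("total_turn", float(np.sum(np.abs(turn))), "static"),
        ("mean_pressure", float(pd.mean()), "static"),
        ("std_pressure", float(pd.std()), "static"),
        ("max_pressure", float(pd.max()), "static"),
        ("pressure_range_ratio", float((pd.max() - pd.min()) / max(pd.max(), _EPS)),
         "static"),
        ("net_displacement_ratio",
         float(np.hypot(x[-1] - x[0], y[-1] - y[0]) / max(path_length, _EPS)),
         "static"),
    ]
    names, values, kinds = zip(*[(n, v, k) for n, v, k in feats])
    return GlobalFeatureVector(
        names=tuple(names), values=np.asarray(values, dtype=float),
        kind=tuple(kinds), normalized=False,
    )


#: The five interpretable trend features and the expected sign of their
#: long-term drift under signature simplification.
TREND_FEATURES: dict[str, int] = {
    "duration": -1, "n_max_x": -1, "n_max_y": -1, "n_penups": -1, "avg_speed": +1,
}


# ---------------------------------------------------------------------------
# tanh normalization

@dataclass
class TanhNormalizer:
    """Per-feature tanh-estimator mapping raw features into (0, 1).

    ``normalized = 0.5 * (tanh(0.01 * (v - mu) / sigma) + 1)``; the 0.01
    factor is the classical tanh-estimator gain, giving a gentle,
    outlier-robust squashing around the training location.
    """

    names: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray

    SIGMA_FLOOR = 1e-8

    def __post_init__(self) -> None:
        self.sigma = np.maximum(self.sigma, self.SIGMA_FLOOR)


def fit_tanh(train: list[GlobalFeatureVector]) -> TanhNormalizer:
    """Estimate per-feature location/scale from training vectors."""
    if len(train) < 2:
        raise ValueError("need >= 2 training vectors")
    names = train[0].names
    mat = np.array([v.values for v in train], dtype=float)
    return TanhNormalizer(names=names, mu=mat.mean(axis=0), sigma=mat.std(axis=0))


def apply_tanh(vec: GlobalFeatureVector, norm: TanhNormalizer) -> GlobalFeatureVector:
    """Map a raw feature vector into (0, 1) with the fitted estimators."""
    if vec.names != norm.names:
        raise ValueError("feature catalog mismatch between vector and normalizer")
    z = 0.01 * (vec.values - norm.mu) / norm.sigma
    out = 0.5 * (np.tanh(z) + 1.0)
    return GlobalFeatureVector(names=vec.names, values=out, kind=vec.kind,
                               normalized=True)
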
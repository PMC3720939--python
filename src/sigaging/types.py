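"""Core domain containers for dynamic signatures and long-term datasets.

A dynamic (on-line) signature is the time series captured by a digitizing
tablet while a person signs: pen coordinates ``x``, ``y`` and the pen-tip
``pressure`` sampled at a nominal 100 Hz, with pressure quantized to 1024
levels.  A pressure of exactly zero marks a *pen-up* sample (the pen is in
the air).

The long-term dataset structure mirrors a six-session acquisition campaign
spanning 15 months: four early sessions of 4 signatures each (``BID1`` ..
``BID4``, two months apart) followed by two later sessions of 15 signatures
each (``Bure1``, ``Bure2``), where each later session was captured as three
consecutive groups of five signatures (``Bure11/12/13``, ``Bure21/22/23``).
That yields 46 genuine samples per user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import SignatureValidationError

#: Storage-level session identifiers, in chronological order.  The Bure
#: sessions are stored split into their three five-signature groups.
STORAGE_SESSIONS: tuple[str, ...] = (
    "BID1", "BID2", "BID3", "BID4",
    "Bure11", "Bure12", "Bure13",
    "Bure21", "Bure22", "Bure23",
)

#: Top-level session identifiers (the six acquisition sessions).
TOP_SESSIONS: tuple[str, ...] = ("BID1", "BID2", "BID3", "BID4", "Bure1", "Bure2")

#: Mapping top-level session -> storage groups.
SESSION_GROUPS: dict[str, tuple[str, ...]] = {
    "BID1": ("BID1",),
    "BID2": ("BID2",),
    "BID3": ("BID3",),
    "BID4": ("BID4",),
    "Bure1": ("Bure11", "Bure12", "Bure13"),
    "Bure2": ("Bure21", "Bure22", "Bure23"),
}

PRESSURE_LEVELS = 1024
SAMPLING_RATE_HZ = 100.0


@dataclass
class DynamicSignature:
    """One sampled signature plus its identity/session metadata.

    Arrays must share one length ``n >= 2``; timestamps are in milliseconds
    and strictly increasing; pressure is integer-valued in ``[0, 1023]``.
    """

    user_id: str
    session_id: str
    sample_idx: int
    month: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.p = np.asarray(self.p, dtype=int)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def penup(self) -> np.ndarray:
        """Boolean pen-up mask, derived from zero pressure."""
        return self.p == 0

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.user_id, self.session_id, self.sample_idx)

    @property
    def duration_s(self) -> float:
        """Total duration in seconds (first to last sample)."""
        return float(self.t[-1] - self.t[0]) / 1000.0

    def validate(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.p) == n):
            raise SignatureValidationError(
                f"array length mismatch: t={n} x={len(self.x)} "
                f"y={len(self.y)} p={len(self.p)}"
            )
        if n < 2:
            raise SignatureValidationError(f"signature needs >= 2 samples, got {n}")
        if np.any(np.diff(self.t) <= 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise SignatureValidationError(
                f"timestamps not strictly increasing at sample {bad}"
            )
        if self.p.min() < 0 or self.p.max() > PRESSURE_LEVELS - 1:
            raise SignatureValidationError(
                f"pressure outside [0, {PRESSURE_LEVELS - 1}]: "
                f"range [{self.p.min()}, {self.p.max()}]"
            )
        if self.sample_idx < 1:
            raise SignatureValidationError("sample_idx must be >= 1")

    def copy(self, **overrides) -> "DynamicSignature":
        fields = dict(
            user_id=self.user_id, session_id=self.session_id,
            sample_idx=self.sample_idx, month=self.month,
            t=self.t.copy(), x=self.x.copy(), y=self.y.copy(), p=self.p.copy(),
        )
        fields.update(overrides)
        return DynamicSignature(**fields)


@dataclass(frozen=True)
class SessionSpec:
    """One top-level acquisition session of the manifest."""

    session_id: str
    month: float
    n_samples: int


@dataclass
class DatasetManifest:
    """Declares the users x sessions grid of a long-term dataset."""

    n_users: int
    sessions: list[SessionSpec]
    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(SESSION_GROUPS)
    )

    def __post_init__(self) -> None:
        if self.n_users < 2:
            raise ValueError("a dataset needs at least 2 users")
        months = [s.month for s in self.sessions]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError(f"session months must be strictly increasing: {months}")

    @property
    def samples_per_user(self) -> int:
        return sum(s.n_samples for s in self.sessions)

    @property
    def total_signatures(self) -> int:
        return self.n_users * self.samples_per_user

    @property
    def user_ids(self) -> list[str]:
        return [f"u{i:03d}" for i in range(1, self.n_users + 1)]

    def storage_cells(self) -> list[tuple[str, float, int]]:
        """Expand to storage sessions: (storage_session_id, month, n_samples).

        Top-level counts are split evenly over the session's groups
        (15 -> 5/5/5 for the Bure sessions).
        """
        cells = []
        for spec in self.sessions:
            groups = self.groups.get(spec.session_id, (spec.session_id,))
            base, extra = divmod(spec.n_samples, len(groups))
            for gi, gid in enumerate(groups):
                cells.append((gid, spec.month, base + (1 if gi < extra else 0)))
        return cells

    def sample_order(self) -> list[tuple[str, int, float]]:
        """Chronological (storage_session, sample_idx, month) order of one
        user's samples — the sample-by-sample axis of the trend curves."""
        order = []
        for sid, month, k in self.storage_cells():
            for idx in range(1, k + 1):
                order.append((sid, idx, month))
        return order


@dataclass
class LongTermDataset:
    """A manifest plus the signatures filling its cells."""

    manifest: DatasetManifest
    signatures: dict[tuple[str, str, int], DynamicSignature]

    @property
    def users(self) -> list[str]:
        return self.manifest.user_ids

    def get(self, user_id: str, session_id: str, sample_idx: int) -> DynamicSignature:
        return self.signatures[(user_id, session_id, sample_idx)]

    def session_samples(self, user_id: str, session_id: str) -> list[DynamicSignature]:
        """All samples of a top-level or storage session, in index order."""
        groups = SESSION_GROUPS.get(session_id, (session_id,))
        out = []
        for gid in groups:
            idx = 1
            while (user_id, gid, idx) in self.signatures:
                out.append(self.signatures[(user_id, gid, idx)])
                idx += 1
        return out

    def user_samples(self, user_id: str) -> list[DynamicSignature]:
        """One user's samples in chronological (session, index) order."""
        out = []
        for sid, idx, _month in self.manifest.sample_order():
            key = (user_id, sid, idx)
            if key in self.signatures:
                out.append(self.signatures[key])
        return out

    def __iter__(self) -> Iterator[DynamicSignature]:
        for sid, idx, _m in self.manifest.sample_order():
            for user in self.users:
                key = (user, sid, idx)
                if key in self.signatures:
                    yield self.signatures[key]

    def __len__(self) -> int:
        return len(self.signatures)
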
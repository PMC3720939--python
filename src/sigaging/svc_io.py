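"""Reading and writing SVC-format signature files and dataset directories.

The SVC plain-text layout (used by the first Signature Verification
Competition) is: a first line with the number of points ``N``, followed by
``N`` space-separated integer rows.  Two dialects are supported:

``seven_column``
    ``x y t button azimuth altitude pressure`` — the full tablet record.
    Pen-inclination columns (azimuth/altitude) are ignored on read and
    written as zero; the button status duplicates the pen-up information
    (``button = 0`` iff ``pressure = 0``).

``three_column``
    ``x y pressure`` with implicit 10 ms timestamps — a compact dialect for
    fixtures.

On read, leading and trailing zero-pressure samples are trimmed: a
signature starts and ends with the pen on paper.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import SignatureValidationError, SvcFormatError
from .types import (
    PRESSURE_LEVELS,
    SESSION_GROUPS,
    DatasetManifest,
    DynamicSignature,
    LongTermDataset,
    SessionSpec,
)

DIALECTS = ("seven_column", "three_column")

_FILENAME_RE = re.compile(r"^(?P<user>.+)_(?P<session>[A-Za-z0-9]+)_(?P<idx>\d+)\.svc$")


def read_svc(
    path: str | os.PathLike,
    dialect: str = "seven_column",
    *,
    user_id: str | None = None,
    session_id: str | None = None,
    sample_idx: int | None = None,
    month: float = 0.0,
) -> DynamicSignature:
    """Parse one SVC text file into a :class:`DynamicSignature`.

    Metadata defaults are derived from a ``<user>_<session>_<idx>.svc``
    filename when not supplied by the caller.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise SvcFormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise SvcFormatError(f"{path}: line 1: header is not a point count") from None
    rows = [ln for ln in lines[1:] if ln.strip()]
    if len(rows) != n:
        raise SvcFormatError(
            f"{path}: header declares {n} points but {len(rows)} rows follow"
        )
    ncol = 7 if dialect == "seven_column" else 3
    data = np.empty((n, ncol), dtype=float)
    for i, ln in enumerate(rows):
        parts = ln.split()
        if len(parts) != ncol:
            raise SvcFormatError(
                f"{path}: line {i + 2}: expected {ncol} columns, got {len(parts)}"
            )
        try:
            data[i] = [float(v) for v in parts]
        except ValueError:
            raise SvcFormatError(f"{path}: line {i + 2}: non-numeric value") from None

    if dialect == "seven_column":
        x, y, t, p = data[:, 0], data[:, 1], data[:, 2], data[:, 6]
    else:
        x, y, p = data[:, 0], data[:, 1], data[:, 2]
        t = np.arange(n) * 10.0
    p = np.clip(np.round(p), 0, PRESSURE_LEVELS - 1).astype(int)

    # trim pen-up margins: a signature starts and ends on paper
    down = np.flatnonzero(p > 0)
    if down.size < 2:
        raise SvcFormatError(f"{path}: fewer than 2 pen-down samples")
    sl = slice(down[0], down[-1] + 1)
    x, y, t, p = x[sl], y[sl], t[sl], p[sl]

    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
        raise SignatureValidationError(
            f"{path}: timestamps not strictly increasing at line {bad}"
        )

    meta = _FILENAME_RE.match(path.name)
    if user_id is None:
        user_id = meta.group("user") if meta else path.stem
    if session_id is None:
        session_id = meta.group("session") if meta else "BID1"
    if sample_idx is None:
        sample_idx = int(meta.group("idx")) if meta else 1
    return DynamicSignature(
        user_id=user_id, session_id=session_id, sample_idx=sample_idx,
        month=month, t=t, x=x, y=y, p=p,
    )


def write_svc(
    sig: DynamicSignature, path: str | os.PathLike, dialect: str = "seven_column"
) -> None:
    """Write a signature as canonical SVC text (integers, space-separated)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    sig.validate()
    n = sig.n
    xi = np.round(sig.x).astype(int)
    yi = np.round(sig.y).astype(int)
    ti = np.round(sig.t).astype(int)
    button = (sig.p > 0).astype(int)
    lines = [str(n)]
    if dialect == "seven_column":
        for i in range(n):
            lines.append(f"{xi[i]} {yi[i]} {ti[i]} {button[i]} 0 0 {sig.p[i]}")
    else:
        for i in range(n):
            lines.append(f"{xi[i]} {yi[i]} {sig.p[i]}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_manifest(n_users: int, months: tuple[float, ...] = (0, 2, 4, 6, 12, 15)) -> DatasetManifest:
    """The standard six-session grid: 4+4+4+4+15+15 = 46 samples per user.

    Nominal session months default to (0, 2, 4, 6, 12, 15): the four early
    sessions two months apart, the fifth six months after the fourth and the
    sixth three months later.
    """
    if n_users < 2:
        raise ValueError("n_users must be >= 2")
    if len(months) != 6:
        raise ValueError("exactly 6 session months required")
    counts = (4, 4, 4, 4, 15, 15)
    sessions = [
        SessionSpec(sid, float(m), k)
        for sid, m, k in zip(("BID1", "BID2", "BID3", "BID4", "Bure1", "Bure2"), months, counts)
    ]
    return DatasetManifest(n_users=n_users, sessions=sessions)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`; empty ``problems`` means clean."""

    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def __str__(self) -> str:
        return "OK" if self.ok else "\n".join(self.problems)


def validate_dataset(ds: LongTermDataset) -> ValidationReport:
    """Check a dataset against its manifest: missing cells, extras, invariants."""
    report = ValidationReport()
    expected = set()
    for user in ds.manifest.user_ids:
        for sid, idx, _m in ds.manifest.sample_order():
            expected.add((user, sid, idx))
    for key in sorted(expected - set(ds.signatures)):
        report.problems.append(f"missing cell: {key}")
    for key in sorted(set(ds.signatures) - expected):
        report.problems.append(f"unexpected key: {key}")
    for key, sig in ds.signatures.items():
        if sig.key != key:
            report.problems.append(f"key mismatch: stored under {key}, labeled {sig.key}")
        try:
            sig.validate()
        except SignatureValidationError as exc:
            report.problems.append(f"invalid signature {key}: {exc}")
    return report


# ---------------------------------------------------------------------------
# dataset directory layout: one directory per user, one .svc file per sample,
# plus a manifest.yaml at the root.

def save_dataset(ds: LongTermDataset, root: str | os.PathLike,
                 dialect: str = "seven_column") -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "users": ds.manifest.n_users,
        "sessions": [
            {"id": s.session_id, "month": s.month, "n_samples": s.n_samples}
            for s in ds.manifest.sessions
        ],
    }
    (root / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    for sig in ds:
        udir = root / sig.user_id
        udir.mkdir(exist_ok=True)
        write_svc(sig, udir / f"{sig.user_id}_{sig.session_id}_{sig.sample_idx}.svc",
                  dialect=dialect)


def load_dataset(root: str | os.PathLike, dialect: str = "seven_column") -> LongTermDataset:
    root = Path(root)
    raw = yaml.safe_load((root / "manifest.yaml").read_text())
    manifest = DatasetManifest(
        n_users=int(raw["users"]),
        sessions=[
            SessionSpec(s["id"], float(s["month"]), int(s["n_samples"]))
            for s in raw["sessions"]
        ],
    )
    months = {}
    for sid, month, _k in manifest.storage_cells():
        months[sid] = month
    signatures = {}
    for udir in sorted(d for d in root.iterdir() if d.is_dir()):
        for f in sorted(udir.glob("*.svc")):
            sig = read_svc(f, dialect=dialect)
            sig.month = months.get(sig.session_id, 0.0)
            signatures[sig.key] = sig
    return LongTermDataset(manifest=manifest, signatures=signatures)
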
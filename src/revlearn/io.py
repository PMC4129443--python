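"""Session-file format: plain CSV, one row per trial.

Columns: ``participant_id, block, trial, choice, outcome`` with a header
row; lines starting with ``#`` are comments.  ``trial`` is 1-based and must
be contiguous within each participant-block; ``choice`` in {1, 2};
``outcome`` in {1, 0}.  Parsing is line-tracked so every validation error
names the offending file row.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np

from .agents import Session

__all__ = [
    "SessionFileError",
    "DomainViolationError",
    "TrialNumberingError",
    "DuplicateTrialError",
    "read_sessions",
    "write_sessions",
]

HEADER = ["participant_id", "block", "trial", "choice", "outcome"]


class SessionFileError(ValueError):
    """Malformed session file (missing columns, unparsable fields...)."""


class DomainViolationError(SessionFileError):
    """A field outside its domain, e.g. choice = 3 or outcome = 0.5."""


class TrialNumberingError(SessionFileError):
    """Trials of a participant-block are not contiguous 1..T."""


class DuplicateTrialError(SessionFileError):
    """The same trial index appears twice within a participant-block."""


def _parse_int(value: str, name: str, row: int) -> int:
    try:
        f = float(value)
    except ValueError:
        raise SessionFileError(f"row {row}: {name}={value!r} is not numeric") from None
    if f != int(f):
        raise DomainViolationError(f"row {row}: {name}={value!r} is not an integer")
    return int(f)


def read_sessions(path: str | Path) -> list[Session]:
    """Read and validate a session file; one Session per participant-block.

    Sessions are returned in file order of first appearance.  Raises a
    :class:`SessionFileError` subclass naming the first offending row
    (1-based physical file line).
    """
    path = Path(path)
    records: dict[tuple[str, int], list[tuple[int, int, float, int]]] = {}
    order: list[tuple[str, int]] = []
    with path.open(newline="") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            row = next(csv.reader([line]))
            if not header_seen:
                got = [c.strip() for c in row]
                if got != HEADER:
                    raise SessionFileError(
                        f"row {lineno}: expected header {','.join(HEADER)}, "
                        f"got {','.join(got)}")
                header_seen = True
                continue
            if len(row) != len(HEADER):
                raise SessionFileError(
                    f"row {lineno}: expected {len(HEADER)} fields, got {len(row)}")
            pid = row[0].strip()
            block = _parse_int(row[1], "block", lineno)
            trial = _parse_int(row[2], "trial", lineno)
            choice = _parse_int(row[3], "choice", lineno)
            outcome_f = float(row[4]) if _is_float(row[4]) else None
            if outcome_f is None:
                raise SessionFileError(
                    f"row {lineno}: outcome={row[4]!r} is not numeric")
            if choice not in (1, 2):
                raise DomainViolationError(
                    f"row {lineno}: choice={choice} not in {{1, 2}}")
            if outcome_f not in (0.0, 1.0):
                raise DomainViolationError(
                    f"row {lineno}: outcome={row[4]} not in {{0, 1}}")
            if trial < 1:
                raise TrialNumberingError(
                    f"row {lineno}: trial={trial} must be >= 1")
            key = (pid, block)
            if key not in records:
                records[key] = []
                order.append(key)
            records[key].append((trial, choice, outcome_f, lineno))
        if not header_seen:
            raise SessionFileError("file contains no header row")

    sessions = []
    for key in order:
        pid, block = key
        rows = records[key]
        seen: dict[int, int] = {}
        for trial, _, _, lineno in rows:
            if trial in seen:
                raise DuplicateTrialError(
                    f"row {lineno}: trial {trial} of participant {pid!r} "
                    f"block {block} already defined at row {seen[trial]}")
            seen[trial] = lineno
        rows.sort(key=lambda r: r[0])
        trials = [r[0] for r in rows]
        if trials != list(range(1, len(rows) + 1)):
            missing = sorted(set(range(1, max(trials) + 1)) - set(trials))
            raise TrialNumberingError(
                f"participant {pid!r} block {block}: trials not contiguous "
                f"1..{len(rows)} (missing {missing[:5]}...)" if missing else
                f"participant {pid!r} block {block}: trials must start at 1")
        sessions.append(Session(
            choices=np.array([r[1] for r in rows], dtype=np.int8),
            outcomes=np.array([r[2] for r in rows], dtype=np.float64),
            participant_id=pid, block=block))
    return sessions


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_sessions(sessions: Sequence[Session] | Session, path: str | Path) -> None:
    """Write sessions to the tabular format; deterministic byte-for-byte."""
    if isinstance(sessions, Session):
        sessions = [sessions]
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(HEADER)
        for s in sessions:
            for t in range(s.n_trials):
                w.writerow([s.participant_id, s.block, t + 1,
                            int(s.choices[t]), int(s.outcomes[t])])
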
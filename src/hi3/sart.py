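"""Sustained Attention to Response Task (SART) scoring.

The SART presents a repeating stream of the digits 1..9; the participant
presses a key for every digit (GO trial) except 3 (NO-GO trial), where the
response must be withheld. A complete session is 23 cycles of 9 digits =
207 trials, of which 184 are GO and 23 NO-GO. A reaction time of 0 ms
encodes "no key press".

Two error types exist: a *commission error* is a key press on the NO-GO
digit; an *omission error* is no key press on a GO digit. A 9-digit cycle
counts as one *bad performance* when it contains at least 2 mistakes out
of its 9 possible actions, and the session score NBP (number of bad
performances) is the count of bad cycles, between 0 and 23.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("hi3.sart")

N_CYCLES = 23
CYCLE_LEN = 9
N_TRIALS = N_CYCLES * CYCLE_LEN  # 207
NOGO_DIGIT = 3
GO_PER_CYCLE = CYCLE_LEN - 1
N_GO_TRIALS = N_CYCLES * GO_PER_CYCLE  # 184
#: the canonical repeating 1..9 digit stream of a complete session
CANONICAL_DIGITS = np.tile(np.arange(1, CYCLE_LEN + 1), N_CYCLES)


@dataclass(frozen=True)
class SartSession:
    """A validated SART session: per-trial digits and reaction times.

    ``rt_ms == 0`` means no key press. ``pattern_ok`` records whether the
    digit stream followed the canonical repeating 1..9 order; sessions
    that deviate are flagged at parse time but still scorable, because a
    trial's recorded digit (not its position) determines GO vs NO-GO.
    """

    digits: np.ndarray
    rt_ms: np.ndarray
    subject_id: str = ""
    pattern_ok: bool = True

    def __post_init__(self) -> None:
        digits = np.asarray(self.digits, dtype=int)
        rt = np.asarray(self.rt_ms, dtype=float)
        object.__setattr__(self, "digits", digits)
        object.__setattr__(self, "rt_ms", rt)
        if digits.shape != rt.shape or digits.ndim != 1:
            raise ValidationError("digits and rt_ms must be 1-D and equal length")
        if len(digits) % CYCLE_LEN != 0 or len(digits) == 0:
            raise ValidationError(
                f"session length {len(digits)} is not a whole number of {CYCLE_LEN}-trial cycles"
            )

    @property
    def n_cycles(self) -> int:
        return len(self.digits) // CYCLE_LEN

    @property
    def is_complete(self) -> bool:
        return len(self.digits) == N_TRIALS

    def cycles(self):
        """Iterate (digits, rt_ms) per 9-trial cycle, in order."""
        for c in range(self.n_cycles):
            sl = slice(c * CYCLE_LEN, (c + 1) * CYCLE_LEN)
            yield self.digits[sl], self.rt_ms[sl]


@dataclass(frozen=True)
class SartSummary:
    """Session-level error totals; ``mean_go_rt_ms`` is None when no GO trial was answered."""

    commission_errors: int
    omission_errors: int
    nbp: int
    mean_go_rt_ms: float | None


def parse_sart_log(
    rows: pd.DataFrame,
    subject_id: str = "",
    allow_partial: bool = False,
    min_rt_ms: float = 0.0,
) -> SartSession:
    """Validate a trial log (columns ``trial, digit, rt_ms``, ordered by trial).

    Checks each row's digit domain (1..9) and RT sign, and the session
    length. With ``allow_partial`` a short session is truncated to its
    complete cycles (at least one required) instead of rejected. Responses
    faster than ``min_rt_ms`` are treated as no response (anticipation
    filter; default 0 = off, matching the scoring protocol which applies
    no anticipation cut-off).

    Raises :class:`~hi3.errors.ValidationError` naming the offending row.
    """
    required = {"digit", "rt_ms"}
    missing = required - set(rows.columns)
    if missing:
        raise ValidationError(f"SART log missing columns: {sorted(missing)}")
    digits = rows["digit"].to_numpy()
    rt = rows["rt_ms"].to_numpy(float)

    bad_digit = (digits < 1) | (digits > 9) | (digits != np.floor(digits))
    if bad_digit.any():
        row = int(np.argmax(bad_digit))
        raise ValidationError(
            f"subject {subject_id!r}: row {row}: digit {digits[row]} outside 1..9"
        )
    neg_rt = ~np.isfinite(rt) | (rt < 0)
    if neg_rt.any():
        row = int(np.argmax(neg_rt))
        raise ValidationError(
            f"subject {subject_id!r}: row {row}: invalid reaction time {rt[row]}"
        )
    digits = digits.astype(int)

    n = len(digits)
    if n != N_TRIALS:
        if not allow_partial:
            raise ValidationError(
                f"subject {subject_id!r}: incomplete session — {n} trials, expected {N_TRIALS}"
            )
        n_full = (n // CYCLE_LEN) * CYCLE_LEN
        if n_full == 0:
            raise ValidationError(
                f"subject {subject_id!r}: fewer than one complete cycle ({n} trials)"
            )
        logger.warning(
            "subject %r: partial session, scoring %d of %d cycles",
            subject_id, n_full // CYCLE_LEN, N_CYCLES,
        )
        digits, rt = digits[:n_full], rt[:n_full]

    if min_rt_ms > 0:
        anticip = (rt > 0) & (rt < min_rt_ms)
        if anticip.any():
            logger.warning(
                "subject %r: %d responses under %.0f ms treated as no response",
                subject_id, int(anticip.sum()), min_rt_ms,
            )
            rt = np.where(anticip, 0.0, rt)

    pattern_ok = bool(np.array_equal(digits, CANONICAL_DIGITS[: len(digits)]))
    if not pattern_ok:
        logger.warning("subject %r: digit stream deviates from the repeating 1..9 pattern",
                       subject_id)
    return SartSession(digits, rt, subject_id=subject_id, pattern_ok=pattern_ok)


def cycle_mistakes(digits, rt_ms) -> int:
    """Mistakes in one 9-trial cycle: commissions (press on 3) + omissions (no press on GO)."""
    digits = np.asarray(digits, dtype=int)
    rt = np.asarray(rt_ms, dtype=float)
    if digits.shape != (CYCLE_LEN,) or rt.shape != (CYCLE_LEN,):
        raise ValidationError(f"a cycle has exactly {CYCLE_LEN} trials")
    nogo = digits == NOGO_DIGIT
    commissions = int((nogo & (rt > 0)).sum())
    omissions = int((~nogo & (rt == 0)).sum())
    return commissions + omissions


def count_nbp(session: SartSession) -> int:
    """Number of bad performances: cycles with at least 2 mistakes."""
    return sum(1 for d, rt in session.cycles() if cycle_mistakes(d, rt) >= 2)


def summarize_session(session: SartSession) -> SartSummary:
    """Session totals: commission and omission errors, NBP, mean GO reaction time."""
    nogo = session.digits == NOGO_DIGIT
    responded = session.rt_ms > 0
    commissions = int((nogo & responded).sum())
    omissions = int((~nogo & ~responded).sum())
    go_rts = session.rt_ms[~nogo & responded]
    mean_rt = float(go_rts.mean()) if go_rts.size else None
    return SartSummary(
        commission_errors=commissions,
        omission_errors=omissions,
        nbp=count_nbp(session),
        mean_go_rt_ms=mean_rt,
    )


# ---------------------------------------------------------------------------
# CSV interface: per-subject `trial,digit,rt_ms`; summaries
# `subject_id,commissions,omissions,nbp,mean_go_rt_ms`
# ---------------------------------------------------------------------------

def read_sart_csv(path, subject_id: str | None = None, **parse_kwargs) -> SartSession:
    """Read and validate one subject's SART log from CSV."""
    from pathlib import Path

    path = Path(path)
    df = pd.read_csv(path)
    sid = subject_id if subject_id is not None else path.stem
    return parse_sart_log(df, subject_id=sid, **parse_kwargs)


def session_to_frame(session: SartSession) -> pd.DataFrame:
    """Serialize a session back to the ``trial,digit,rt_ms`` schema (lossless)."""
    return pd.DataFrame({
        "trial": np.arange(1, len(session.digits) + 1),
        "digit": session.digits,
        "rt_ms": session.rt_ms,
    })


def summary_frame(summaries: dict[str, SartSummary]) -> pd.DataFrame:
    """Tabulate per-subject summaries for the summary CSV schema."""
    rows = [
        {
            "subject_id": sid,
            "commissions": s.commission_errors,
            "omissions": s.omission_errors,
            "nbp": s.nbp,
            "mean_go_rt_ms": math.nan if s.mean_go_rt_ms is None else s.mean_go_rt_ms,
        }
        for sid, s in summaries.items()
    ]
    return pd.DataFrame(rows, columns=["subject_id", "commissions", "omissions", "nbp", "mean_go_rt_ms"])
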
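"""Sample entropy (SampEn) of resting-state beat-to-beat systolic blood pressure.

SampEn(m, r, N) quantifies the irregularity of a time series as the negative
log of the conditional probability that two length-``m`` template vectors
that match within a tolerance also match when extended to length ``m + 1``:

    SampEn = -ln( A^m(r) / B^m(r) )

where, for a series x of length N,

    B^m_i(r) = (number of j != i, j = 1..N-m, with d[x_m(i), x_m(j)] <= r*SD) / (N - m - 1)
    A^m_i(r) = same count for templates of length m + 1
    B^m(r)   = mean_i B^m_i(r),   A^m(r) = mean_i A^m_i(r),  i = 1..N-m

Distances are Chebyshev (max over components), tolerance is ``r`` times the
standard deviation of the analysed window, and self-matches are excluded.
Higher SampEn means a more irregular signal; in older adults, higher
resting sBP entropy has been associated with worse health outcomes, which
is why it enters the health index with "higher is worse" polarity.

Conventions (configurable where noted):

* the tolerance comparison is a closed ball (``<=``), so a constant series
  (SD = 0) still self-matches and yields SampEn = 0;
* SD is the population SD (divisor N) by default; sample SD available via
  ``EntropyParams.sd_ddof``;
* zero matches at either template length raise
  :class:`~hi3.errors.UndefinedEntropyError` rather than returning a number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InsufficientDataError, UndefinedEntropyError, ValidationError

logger = logging.getLogger("hi3.entropy")

#: default length of the resting-state analysis window, seconds
DEFAULT_WINDOW_S = 60.0
#: beats per second assumed when a series carries no timestamps
DEFAULT_BEAT_RATE_HZ = 1.0


@dataclass(frozen=True)
class BeatSeries:
    """One subject's beat-to-beat systolic blood pressure series.

    Parameters
    ----------
    values:
        sBP readings in mmHg, one per heartbeat; finite and positive.
    times:
        Optional beat-onset times in seconds, strictly increasing, same
        length as ``values``.
    subject_id:
        Opaque identifier carried through to outputs.
    """

    values: np.ndarray
    times: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValidationError("beat series must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValidationError("sBP values must be finite and > 0 mmHg")
        if self.times is not None:
            times = np.asarray(self.times, dtype=float)
            object.__setattr__(self, "times", times)
            if times.shape != values.shape:
                raise ValidationError("times must match values in length")
            if not np.all(np.isfinite(times)) or np.any(np.diff(times) <= 0):
                raise ValidationError("beat times must be finite and strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class EntropyParams:
    """SampEn parameters: embedding dimension ``m`` and similarity criterion ``r``.

    The defaults m = 1, r = 0.4 follow prior work selecting the optimal
    (m, r) pair for mortality prediction from 1-minute resting sBP series.
    ``sd_ddof`` chooses population (0, default) or sample (1) SD for the
    tolerance.
    """

    m: int = 1
    r: float = 0.4
    sd_ddof: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValidationError(f"embedding dimension m must be a positive integer, got {self.m}")
        if not (self.r > 0 and math.isfinite(self.r)):
            raise ValidationError(f"similarity criterion r must be positive, got {self.r}")
        if self.sd_ddof not in (0, 1):
            raise ValidationError("sd_ddof must be 0 (population) or 1 (sample)")


@dataclass(frozen=True)
class MatchCounts:
    """Averaged template-match fractions B^m(r), A^m(r) for a series of length n."""

    b_mean: float
    a_mean: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.a_mean <= self.b_mean + 1e-12 and self.b_mean <= 1.0 + 1e-12):
            raise ValidationError(
                f"match fractions must satisfy 0 <= A <= B <= 1, got A={self.a_mean}, B={self.b_mean}"
            )


def select_resting_window(
    series: BeatSeries,
    duration_s: float = DEFAULT_WINDOW_S,
    expected_beat_rate_hz: float = DEFAULT_BEAT_RATE_HZ,
) -> BeatSeries:
    """Return the final ``duration_s`` seconds of a beat series.

    The last minute of supine rest is the analysis window for SampEn: it is
    the most stationary stretch after the stabilisation period. When the
    series is time-stamped the window is the suffix of beats with onset time
    at or after ``t_max - duration_s`` (closed on the left, so a series
    spanning exactly the window is returned unchanged). Without timestamps
    the window is the last ``round(duration_s * expected_beat_rate_hz)``
    beats.

    Raises
    ------
    InsufficientDataError
        If the series is shorter than the requested window. Truncation is
        never silent.
    """
    if duration_s <= 0:
        raise ValidationError("window duration must be positive")
    if series.times is not None:
        span = float(series.times[-1] - series.times[0])
        if span < duration_s:
            raise InsufficientDataError(
                f"subject {series.subject_id!r}: series spans {span:.1f} s "
                f"< requested {duration_s:.1f} s window"
            )
        keep = series.times >= series.times[-1] - duration_s
        return BeatSeries(series.values[keep], series.times[keep], series.subject_id)
    if expected_beat_rate_hz <= 0:
        raise ValidationError("expected beat rate must be positive for untimed series")
    n_keep = int(round(duration_s * expected_beat_rate_hz))
    if n_keep < 1:
        raise ValidationError("window shorter than one beat")
    if n_keep > len(series):
        raise InsufficientDataError(
            f"subject {series.subject_id!r}: {len(series)} beats available, "
            f"{n_keep} required for a {duration_s:.0f} s window at "
            f"{expected_beat_rate_hz} beats/s"
        )
    return BeatSeries(series.values[-n_keep:], None, series.subject_id)


def _match_fractions(emb: np.ndarray, tol: float, denom: int) -> np.ndarray:
    """Per-template fraction of other templates within Chebyshev distance tol."""
    dist = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=-1)
    matches = (dist <= tol).sum(axis=1) - 1  # exclude the self-match on the diagonal
    return matches / denom


def match_counts(x, params: EntropyParams = EntropyParams()) -> MatchCounts:
    """Averaged template-match fractions of a series under (m, r).

    Both template lengths use the first ``N - m`` starting positions, each
    count is divided by ``N - m - 1`` (self-matches excluded), and the
    tolerance is ``r`` times the SD of the full input window. A constant
    series has SD 0 and tolerance 0; exact ties still match under ``<=``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("input series must be 1-D")
    n = x.size
    m = params.m
    if n < m + 2:
        raise InsufficientDataError(f"need at least m + 2 = {m + 2} points, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("series contains non-finite values")
    tol = params.r * float(x.std(ddof=params.sd_ddof))
    n_templates = n - m
    denom = n - m - 1
    emb_m = sliding_window_view(x, m)[:n_templates]
    emb_m1 = sliding_window_view(x, m + 1)  # exactly n - m rows
    b_mean = float(_match_fractions(emb_m, tol, denom).mean())
    a_mean = float(_match_fractions(emb_m1, tol, denom).mean())
    return MatchCounts(b_mean=b_mean, a_mean=a_mean, n=n)


def sample_entropy(x, params: EntropyParams = EntropyParams()) -> float:
    """SampEn = -ln(A^m(r) / B^m(r)) of a series.

    Returns 0.0 when every length-m match also matches at length m + 1
    (perfectly regular signal). Raises
    :class:`~hi3.errors.UndefinedEntropyError` when either match count is
    zero, leaving the exclusion decision to the caller.
    """
    counts = match_counts(x, params)
    if counts.b_mean == 0.0 or counts.a_mean == 0.0:
        raise UndefinedEntropyError(
            f"no template matches at tolerance r={params.r} (A={counts.a_mean}, "
            f"B={counts.b_mean}, N={counts.n}); SampEn undefined"
        )
    if counts.a_mean == counts.b_mean:
        return 0.0
    return float(-math.log(counts.a_mean / counts.b_mean))


def resting_sampen(
    series: BeatSeries,
    params: EntropyParams = EntropyParams(),
    duration_s: float = DEFAULT_WINDOW_S,
    expected_beat_rate_hz: float = DEFAULT_BEAT_RATE_HZ,
) -> float:
    """SampEn of the final resting-state window of a beat series."""
    window = select_resting_window(series, duration_s, expected_beat_rate_hz)
    return sample_entropy(window.values, params)


# ---------------------------------------------------------------------------
# CSV interface: per-subject series `beat,time_s,sbp_mmhg` (time_s optional)
# ---------------------------------------------------------------------------

def read_beat_csv(path, subject_id: str | None = None) -> BeatSeries:
    """Read one subject's beat series from CSV with header ``beat,time_s,sbp_mmhg``.

    ``time_s`` may be absent. The subject id defaults to the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "sbp_mmhg" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'sbp_mmhg'")
    times = df["time_s"].to_numpy(float) if "time_s" in df.columns else None
    return BeatSeries(
        df["sbp_mmhg"].to_numpy(float),
        times,
        subject_id if subject_id is not None else path.stem,
    )


def write_beat_csv(series: BeatSeries, path) -> None:
    """Write a beat series to the ``beat,time_s,sbp_mmhg`` schema."""
    cols: dict = {"beat": np.arange(1, len(series) + 1)}
    if series.times is not None:
        cols["time_s"] = series.times
    cols["sbp_mmhg"] = series.values
    pd.DataFrame(cols).to_csv(path, index=False)


def entropy_results_frame(results: list[dict]) -> pd.DataFrame:
    """Assemble per-subject entropy rows ``subject_id,n_beats,sampen,defined``."""
    return pd.DataFrame(results, columns=["subject_id", "n_beats", "sampen", "defined"])
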
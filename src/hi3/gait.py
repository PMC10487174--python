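"""Usual gait speed (UGS) from steady-state walk records.

UGS is the arithmetic mean of a subject's steady-state walking speeds in
cm/s, normally over two walks at self-selected pace on a pressure-sensing
walkway. Acceleration and deceleration phases are excluded upstream by the
walkway software; this module takes the steady-state speeds as given.
Slower gait is the "worse" direction in the health index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("hi3.gait")


def compute_ugs(walk_speeds) -> float:
    """Mean of the provided walk speeds (cm/s).

    At least one finite positive speed is required; a single-walk record is
    accepted with a logged warning rather than rejected, so subjects with
    one missing walk degrade gracefully instead of dropping out.
    """
    speeds = np.asarray(walk_speeds, dtype=float)
    if speeds.ndim != 1 or speeds.size == 0:
        raise ValidationError("at least one walk speed is required")
    if not np.all(np.isfinite(speeds)) or np.any(speeds <= 0):
        raise ValidationError(f"walk speeds must be finite and positive, got {speeds.tolist()}")
    if speeds.size == 1:
        logger.warning("single-walk record: UGS computed from one walk")
    return float(speeds.mean())


@dataclass(frozen=True)
class GaitRecord:
    """One subject's walks and derived usual gait speed (cm/s)."""

    walk_speeds: tuple
    subject_id: str = ""
    ugs: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "walk_speeds", tuple(float(s) for s in self.walk_speeds))
        object.__setattr__(self, "ugs", compute_ugs(self.walk_speeds))


def read_gait_csv(path) -> dict[str, GaitRecord]:
    """Read walk records from CSV ``subject_id,walk1_cms,walk2_cms`` (walk2 optional per row)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "walk1_cms" not in df.columns:
        raise ValidationError(f"{path}: gait CSV needs columns subject_id, walk1_cms[, walk2_cms]")
    records: dict[str, GaitRecord] = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        speeds = [row["walk1_cms"]]
        if "walk2_cms" in df.columns and not (
            row["walk2_cms"] is None or (isinstance(row["walk2_cms"], float) and math.isnan(row["walk2_cms"]))
        ):
            speeds.append(row["walk2_cms"])
        records[sid] = GaitRecord(speeds, subject_id=sid)
    return records


def ugs_frame(records: dict[str, GaitRecord]) -> pd.DataFrame:
    """Tabulate per-subject UGS for the ``subject_id,ugs_cms`` schema."""
    return pd.DataFrame(
        [{"subject_id": sid, "ugs_cms": rec.ugs} for sid, rec in records.items()],
        columns=["subject_id", "ugs_cms"],
    )
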
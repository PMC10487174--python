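"""Composition of the 3-item health index (HI) and risk-group assignment.

The HI combines three objective measurements, each independently associated
with mortality risk in older adults:

* ``sampen`` — sample entropy of resting beat-to-beat systolic blood
  pressure (higher = worse),
* ``nbp`` — number of bad performances on the SART attention task
  (higher = worse),
* ``ugs`` — usual gait speed in cm/s (lower = worse).

Each component is min–max normalized to the full range observed in a
reference cohort, with the gait component inverted so that 1 is always the
worst pole, and the HI is the unweighted mean of the three normalized
components, on [0, 1] with 0 = lowest risk and 1 = highest risk. Values
outside the reference range clamp to [0, 1] with a logged warning, so a
new subject more extreme than the reference cohort cannot push the index
off scale.

Risk groups are assigned from two cut-offs (defaults 0.45 and 0.65, the
data-driven values found on the reference cohort): hi < low_medium → Low,
low_medium <= hi < medium_high → Medium, hi >= medium_high → High. The
half-open convention places a score equal to a cut-off in the worse group.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("hi3.health_index")

COMPONENTS = ("sampen", "nbp", "ugs")
#: fixed risk polarity of each component
WORSE_DIRECTION = {"sampen": "higher", "nbp": "higher", "ugs": "lower"}
RISK_GROUPS = ("Low", "Medium", "High")


@dataclass(frozen=True)
class ComponentRange:
    """Reference min/max and risk polarity for one component."""

    min: float
    max: float
    worse_direction: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.min) and math.isfinite(self.max) and self.min < self.max):
            raise ValidationError(f"need finite min < max, got [{self.min}, {self.max}]")
        if self.worse_direction not in ("higher", "lower"):
            raise ValidationError(f"worse_direction must be 'higher' or 'lower', got {self.worse_direction!r}")


@dataclass(frozen=True)
class ReferenceRanges:
    """Per-component normalization ranges fit from (or configured for) a reference cohort."""

    sampen: ComponentRange
    nbp: ComponentRange
    ugs: ComponentRange

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            got = getattr(self, name).worse_direction
            if got != WORSE_DIRECTION[name]:
                raise ValidationError(
                    f"{name}: worse_direction must be {WORSE_DIRECTION[name]!r} (got {got!r})"
                )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {name: asdict(getattr(self, name)) for name in COMPONENTS}, indent=2))

    @classmethod
    def from_json(cls, path) -> "ReferenceRanges":
        raw = json.loads(Path(path).read_text())
        kwargs = {}
        for name in COMPONENTS:
            if name not in raw:
                raise ValidationError(f"reference-range JSON missing component {name!r}")
            entry = raw[name]
            kwargs[name] = ComponentRange(
                min=float(entry["min"]),
                max=float(entry["max"]),
                worse_direction=entry.get("worse_direction", WORSE_DIRECTION[name]),
            )
        return cls(**kwargs)


@dataclass(frozen=True)
class RiskCutoffs:
    """HI thresholds separating Low/Medium and Medium/High risk groups."""

    low_medium: float = 0.45
    medium_high: float = 0.65

    def __post_init__(self) -> None:
        if not (0.0 < self.low_medium < self.medium_high < 1.0):
            raise ValidationError(
                f"cut-offs must satisfy 0 < low_medium < medium_high < 1, "
                f"got {self.low_medium}, {self.medium_high}"
            )


@dataclass(frozen=True)
class HealthIndexResult:
    """Raw components, their normalized values, the composite HI, and the risk group."""

    components_raw: dict
    components_norm: dict
    hi: float
    risk_group: str


def fit_reference_ranges(cohort_components: pd.DataFrame) -> ReferenceRanges:
    """Observed min/max per component over a reference cohort.

    ``cohort_components`` needs columns ``sampen, nbp, ugs`` with at least
    two complete subjects; a zero-variance component leaves its range
    undefined and is an error.
    """
    missing = set(COMPONENTS) - set(cohort_components.columns)
    if missing:
        raise ValidationError(f"cohort table missing component columns: {sorted(missing)}")
    complete = cohort_components.dropna(subset=list(COMPONENTS))
    if len(complete) < 2:
        raise ValidationError("need at least 2 subjects with complete components")
    kwargs = {}
    for name in COMPONENTS:
        col = complete[name].astype(float)
        lo, hi = float(col.min()), float(col.max())
        if lo == hi:
            raise ValidationError(f"component {name!r} has zero range in the reference cohort")
        kwargs[name] = ComponentRange(min=lo, max=hi, worse_direction=WORSE_DIRECTION[name])
    return ReferenceRanges(**kwargs)


def normalize_component(value: float, crange: ComponentRange) -> float:
    """Min–max scale a component onto [0, 1] with 1 at the worse pole.

    Out-of-range inputs clamp to the nearer endpoint with a warning.
    """
    if value is None or not math.isfinite(value):
        raise ValidationError(f"component value must be finite, got {value}")
    scaled = (float(value) - crange.min) / (crange.max - crange.min)
    if scaled < 0.0 or scaled > 1.0:
        logger.warning(
            "component value %g outside reference range [%g, %g]; clamped",
            value, crange.min, crange.max,
        )
        scaled = min(max(scaled, 0.0), 1.0)
    return 1.0 - scaled if crange.worse_direction == "lower" else scaled


def assign_risk_group(hi: float, cutoffs: RiskCutoffs = RiskCutoffs()) -> str:
    """Map an HI score to Low / Medium / High (cut-off values fall in the worse group)."""
    if not (0.0 <= hi <= 1.0):
        raise ValidationError(f"HI must lie in [0, 1], got {hi}")
    if hi < cutoffs.low_medium:
        return "Low"
    if hi < cutoffs.medium_high:
        return "Medium"
    return "High"


def compute_hi(
    sampen: float,
    nbp: float,
    ugs: float,
    ranges: ReferenceRanges,
    cutoffs: RiskCutoffs = RiskCutoffs(),
) -> HealthIndexResult:
    """Compose the 3-item HI for one subject.

    All three components must be present and finite; the composite is the
    unweighted mean of the normalized components, so equal weight is given
    to cardiovascular signal irregularity, attentional lapses, and mobility.
    """
    raw = {"sampen": sampen, "nbp": nbp, "ugs": ugs}
    for name, value in raw.items():
        if value is None or not math.isfinite(float(value)):
            raise ValidationError(f"incomplete subject: component {name!r} missing or non-finite")
    norm = {name: normalize_component(float(raw[name]), getattr(ranges, name)) for name in COMPONENTS}
    hi = sum(norm.values()) / len(COMPONENTS)
    return HealthIndexResult(
        components_raw=raw,
        components_norm=norm,
        hi=hi,
        risk_group=assign_risk_group(hi, cutoffs),
    )


def results_frame(results: dict[str, HealthIndexResult]) -> pd.DataFrame:
    """Tabulate per-subject results for the ``subject_id,sampen,nbp,ugs,hi,risk_group`` schema."""
    rows = [
        {
            "subject_id": sid,
            "sampen": r.components_raw["sampen"],
            "nbp": r.components_raw["nbp"],
            "ugs": r.components_raw["ugs"],
            "hi": r.hi,
            "risk_group": r.risk_group,
        }
        for sid, r in results.items()
    ]
    return pd.DataFrame(rows, columns=["subject_id", "sampen", "nbp", "ugs", "hi", "risk_group"])
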
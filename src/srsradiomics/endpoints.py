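"""Post-SRS progression labeling from serial volumetric measurements.

A BM is labeled as progressed when any follow-up volume exceeds the
pretreatment baseline by at least max(25% of baseline, 27 mm^3).  The
relative criterion is the classic volumetric progression rule; the 27 mm^3
absolute floor is the three-dimensional adaptation of the RANO-BM 3 mm
unidimensional change floor ((3 mm)^3 = 27 mm^3), which prevents clinically
insignificant absolute changes in small BMs from counting as progression.
Change is always judged against the original baseline, never the nadir.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

#: Absolute progression floor in mm^3 = (3 mm)^3, from RANO-BM's 3 mm rule.
ABSOLUTE_FLOOR_MM3 = 27.0
#: Relative progression criterion: >= 25% volume increase over baseline.
RELATIVE_FRACTION = 0.25


class ThresholdRule(str, Enum):
    RELATIVE25 = "relative25"
    ABSOLUTE27 = "absolute27"


@dataclass(frozen=True)
class SizeSeries:
    """Serial size measurements of one BM.

    The baseline is either a direct volume or three perpendicular maximum
    diameters (SI, ML, PA) in mm whose product approximates volume.
    ``pseudo_progression`` marks lesions adjudicated (outside this package)
    as pseudo-progression; they are forced to label 0.
    """

    bm_id: str
    followup_volumes: tuple[float, ...]
    baseline_volume: float | None = None
    baseline_diameters: tuple[float, float, float] | None = None
    pseudo_progression: bool = False

    def resolved_baseline(self) -> float:
        if self.baseline_volume is not None:
            if self.baseline_volume <= 0:
                raise ValueError(f"{self.bm_id}: baseline volume must be positive")
            return float(self.baseline_volume)
        if self.baseline_diameters is None:
            raise ValueError(f"{self.bm_id}: no baseline measurement")
        return approximate_volume(*self.baseline_diameters)


@dataclass(frozen=True)
class ProgressionLabel:
    bm_id: str
    progressed: int
    triggering_followup_index: int | None
    threshold_mm3: float
    rule: ThresholdRule

    def __post_init__(self) -> None:
        if (self.progressed == 1) != (self.triggering_followup_index is not None):
            raise ValueError("progressed=1 iff a triggering follow-up index is set")


def approximate_volume(d1: float, d2: float, d3: float) -> float:
    """Approximate BM volume (mm^3) as the product of the maximum diameters
    measured in three perpendicular directions (mm)."""
    if d1 <= 0 or d2 <= 0 or d3 <= 0:
        raise ValueError(f"diameters must be positive, got {(d1, d2, d3)}")
    return float(d1 * d2 * d3)


def progression_threshold(baseline_volume: float) -> tuple[float, ThresholdRule]:
    """Volume increase (mm^3) required to call progression, and which rule
    dominated.  Equals max(0.25*baseline, 27 mm^3); at the 108 mm^3 boundary
    where both rules give 27 mm^3 the relative rule is reported."""
    if baseline_volume <= 0:
        raise ValueError("baseline volume must be positive")
    relative = RELATIVE_FRACTION * baseline_volume
    if relative >= ABSOLUTE_FLOOR_MM3:
        return relative, ThresholdRule.RELATIVE25
    return ABSOLUTE_FLOOR_MM3, ThresholdRule.ABSOLUTE27


def label_progression(series: SizeSeries) -> ProgressionLabel:
    """Label one BM from its size series.

    Progression is declared at the first follow-up whose volume exceeds
    baseline by at least the progression threshold.  Requires at least one
    follow-up (the study inclusion criterion).
    """
    if not series.followup_volumes:
        raise ValueError(f"{series.bm_id}: at least one follow-up is required")
    if any(v <= 0 for v in series.followup_volumes):
        raise ValueError(f"{series.bm_id}: follow-up volumes must be positive")
    baseline = series.resolved_baseline()
    threshold, rule = progression_threshold(baseline)
    trigger: int | None = None
    if not series.pseudo_progression:
        for i, vol in enumerate(series.followup_volumes):
            if vol - baseline >= threshold:
                trigger = i
                break
    return ProgressionLabel(
        bm_id=series.bm_id,
        progressed=int(trigger is not None),
        triggering_followup_index=trigger,
        threshold_mm3=threshold,
        rule=rule,
    )


def label_progression_table(series_list: Sequence[SizeSeries]) -> pd.DataFrame:
    """Label a batch of BMs, one output row per BM."""
    rows = []
    for s in series_list:
        lab = label_progression(s)
        rows.append({
            "bm_id": lab.bm_id,
            "progressed": lab.progressed,
            "triggering_followup_index": lab.triggering_followup_index,
            "threshold_mm3": lab.threshold_mm3,
            "rule": lab.rule.value,
        })
    return pd.DataFrame(rows)


def read_size_series(path: str | Path) -> list[SizeSeries]:
    """Read size series from CSV.

    Columns: ``bm_id``, then either ``baseline_volume_mm3`` or the three
    diameters ``baseline_d1_mm,baseline_d2_mm,baseline_d3_mm``, optional
    ``pseudo_progression`` (0/1), and one or more ``followup_*`` volume
    columns in chronological order (empty cells allowed after the first).
    """
    frame = pd.read_csv(path)
    followup_cols = [c for c in frame.columns if c.startswith("followup")]
    if not followup_cols:
        raise ValueError(f"{path}: no followup_* columns found")
    out = []
    for idx, row in frame.iterrows():
        followups = tuple(float(row[c]) for c in followup_cols if pd.notna(row[c]))
        kwargs: dict = {}
        if "baseline_volume_mm3" in frame.columns and pd.notna(row.get("baseline_volume_mm3")):
            kwargs["baseline_volume"] = float(row["baseline_volume_mm3"])
        else:
            try:
                kwargs["baseline_diameters"] = tuple(
                    float(row[f"baseline_d{i}_mm"]) for i in (1, 2, 3))
            except KeyError as exc:
                raise ValueError(f"{path} row {idx}: no baseline measurement") from exc
        if "pseudo_progression" in frame.columns and pd.notna(row.get("pseudo_progression")):
            kwargs["pseudo_progression"] = bool(int(row["pseudo_progression"]))
        out.append(SizeSeries(bm_id=str(row["bm_id"]),
                              followup_volumes=followups, **kwargs))
    return out
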
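"""Head-injury records: von Mises -> injury-degree classification and
dataset summary statistics.

The injury response parameter is the peak von Mises stress of brain tissue
(kPa) in a vehicle collision.  It is banded into five injury degrees with
half-open, left-closed intervals at the conventional thresholds:

    J1 minor injury          [0, 6) kPa
    J2 cerebral contusion    [6, 11) kPa
    J3 moderate injury       [11, 15) kPa
    J4 cerebral concussion   [15, 27) kPa
    J5 severe injury         [27, inf) kPa

A record couples the subject characteristics with the traffic participation
state (0 = pedestrian, 1 = cyclist), the vehicle collision speed (km/h) and
the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SubjectCharacteristics

__all__ = [
    "INJURY_THRESHOLDS_KPA",
    "INJURY_CLASSES",
    "INJURY_CLASS_NAMES",
    "InjuryRecord",
    "InjuryDataset",
    "classify_injury",
    "dataset_summary",
    "severe_share",
]

#: lower bounds of J2..J5 (J1 starts at 0)
INJURY_THRESHOLDS_KPA = (6.0, 11.0, 15.0, 27.0)
INJURY_CLASSES = ("J1", "J2", "J3", "J4", "J5")
INJURY_CLASS_NAMES = {
    "J1": "minor injury",
    "J2": "cerebral contusion",
    "J3": "moderate injury",
    "J4": "cerebral concussion",
    "J5": "severe injury",
}


def classify_injury(von_mises_kpa: float | np.ndarray) -> str | np.ndarray:
    """Map peak brain von Mises stress (kPa) to an injury degree J1..J5.

    Intervals are half-open, left-closed: a value exactly at a threshold
    belongs to the upper class (6.0 kPa -> J2).
    """
    arr = np.asarray(von_mises_kpa, dtype=float)
    if (arr < 0).any():
        raise ValueError("von Mises stress must be non-negative")
    idx = np.searchsorted(INJURY_THRESHOLDS_KPA, arr, side="right")
    if np.ndim(von_mises_kpa) == 0:
        return INJURY_CLASSES[int(idx)]
    return np.array(INJURY_CLASSES, dtype=object)[idx].astype(str)


@dataclass(frozen=True)
class InjuryRecord:
    subject: SubjectCharacteristics
    state: int                 # 0 = pedestrian, 1 = cyclist
    speed: float               # km/h
    von_mises: float           # kPa, peak brain tissue value
    injury_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.state not in (0, 1):
            raise ValueError("state must be 0 (pedestrian) or 1 (cyclist)")
        if not self.von_mises > 0:
            raise ValueError("von Mises stress must be positive")
        expected = classify_injury(self.von_mises)
        if not self.injury_class:
            object.__setattr__(self, "injury_class", expected)
        elif self.injury_class != expected:
            raise ValueError(
                f"injury class {self.injury_class} inconsistent with "
                f"{self.von_mises} kPa (expected {expected})"
            )


@dataclass
class InjuryDataset:
    records: list[InjuryRecord]
    design_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("dataset must not be empty")

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": np.arange(1, len(self.records) + 1),
                "gender": [r.subject.gender for r in self.records],
                "age": [r.subject.age for r in self.records],
                "height": [r.subject.height for r in self.records],
                "bmi": [r.subject.bmi for r in self.records],
                "state": [r.state for r in self.records],
                "speed_kmh": [r.speed for r in self.records],
                "von_mises_kpa": [r.von_mises for r in self.records],
                "injury_class": [r.injury_class for r in self.records],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, design_meta: dict | None = None) -> "InjuryDataset":
        records = [
            InjuryRecord(
                subject=SubjectCharacteristics(
                    gender=int(row.gender), age=float(row.age),
                    height=float(row.height), bmi=float(row.bmi),
                ),
                state=int(row.state),
                speed=float(row.speed_kmh),
                von_mises=float(row.von_mises_kpa),
            )
            for row in df.itertuples()
        ]
        return cls(records=records, design_meta=design_meta or {})


def severe_share(df: pd.DataFrame, mask: pd.Series) -> float:
    """Fraction of J5 (severe) records within a boolean subset; NaN if empty."""
    sub = df.loc[mask]
    if len(sub) == 0:
        return float("nan")
    return float((sub["injury_class"] == "J5").mean())


def _class_shares(df: pd.DataFrame, key: pd.Series) -> pd.DataFrame:
    tab = (
        df.groupby(key)["injury_class"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    return tab.reindex(columns=[c for c in INJURY_CLASSES if c in tab.columns])


def dataset_summary(ds: InjuryDataset) -> dict[str, pd.DataFrame]:
    """Summary tables of the dataset.

    Returns per-speed von Mises mean and 90% interval, injury-class share
    distributions binned by height (< / >= 1.7 m), gender, age decade and
    5 kg/m^2 BMI band, and a pedestrian-vs-cyclist mean comparison.  Empty
    bins are absent from the tables, not reported as zero.
    """
    df = ds.to_dataframe()
    by_speed = df.groupby("speed_kmh")["von_mises_kpa"].agg(
        mean="mean",
        q05=lambda v: v.quantile(0.05),
        q95=lambda v: v.quantile(0.95),
        n="size",
    )
    height_band = pd.Series(
        np.where(df["height"] < 1.7, "<1.7 m", ">=1.7 m"),
        index=df.index, name="height_band",
    )
    age_decade = pd.Series(
        (df["age"] // 10 * 10).astype(int).astype(str) + "s",
        index=df.index, name="age_decade",
    )
    bmi_band = pd.Series(
        (df["bmi"] // 5 * 5).astype(int).map(lambda lo: f"{lo}-{lo + 5}"),
        index=df.index, name="bmi_band",
    )
    by_state = df.groupby("state")["von_mises_kpa"].agg(["mean", "std", "size"])
    by_state.index = by_state.index.map({0: "pedestrian", 1: "cyclist"})
    return {
        "by_speed": by_speed,
        "class_share_by_height": _class_shares(df, height_band),
        "class_share_by_gender": _class_shares(df, df["gender"].map({0: "female", 1: "male"})),
        "class_share_by_age": _class_shares(df, age_decade),
        "class_share_by_bmi": _class_shares(df, bmi_band),
        "by_state": by_state,
    }
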
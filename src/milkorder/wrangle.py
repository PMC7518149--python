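"""Conversion of raw ordinal milking logs to entry-quantile matrices.

The raw observational unit is a long-format milk log: one record per
(day, cow) giving the ordinal position at which the cow entered the
parlor that morning.  Because herd size fluctuates day to day (illness,
RFID read failures), ordinal positions are normalised by the number of
cows recorded that milking, yielding an *entry quantile* in (0, 1]
(1 = last cow through the door).  The cows x days quantile matrix is the
central object of every downstream analysis.

Standard record filters are provided: a warm-up exclusion while the herd
stabilises, windows around management changes, a minimum daily herd
coverage, and a minimum per-cow attendance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MilkLog",
    "QuantileMatrix",
    "DataIntegrityError",
    "EmptyResultError",
    "to_quantiles",
    "filter_days",
    "filter_cows",
    "subset_healthy",
]

PEN = "pen"
PASTURE = "pasture"


class DataIntegrityError(ValueError):
    """Raised when a milk log violates its structural contract."""


class EmptyResultError(ValueError):
    """Raised when a filter leaves no rows or columns."""


@dataclass
class MilkLog:
    """Long-format parlor entry records.

    Parameters
    ----------
    records : DataFrame with columns ``day`` (int), ``subperiod``
        (``"pen"`` or ``"pasture"``), ``cow_id``, ``position``
        (ordinal, 1-based).
    herd_size : Series mapping day -> number of cows recorded that day.
        Derived from ``records`` when omitted.
    enrolled : optional Series mapping day -> number of cows enrolled in
        the herd that day; the denominator of the daily-coverage filter.
    """

    records: pd.DataFrame
    herd_size: pd.Series | None = None
    enrolled: pd.Series | None = None

    def __post_init__(self) -> None:
        req = {"day", "subperiod", "cow_id", "position"}
        missing = req - set(self.records.columns)
        if missing:
            raise DataIntegrityError(f"milk log missing columns: {sorted(missing)}")
        if self.herd_size is None:
            self.herd_size = self.records.groupby("day")["position"].size()
        dup = self.records.duplicated(subset=["day", "cow_id"], keep=False)
        if dup.any():
            offenders = (
                self.records.loc[dup, ["day", "cow_id"]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise DataIntegrityError(
                "duplicate (day, cow) records: " + ", ".join(map(str, offenders))
            )
        for day, grp in self.records.groupby("day"):
            pos = grp["position"].to_numpy()
            n_d = int(self.herd_size.loc[day])
            if len(np.unique(pos)) != len(pos) or pos.min() < 1 or pos.max() > n_d:
                raise DataIntegrityError(
                    f"day {day}: positions must be distinct integers in 1..{n_d}"
                )

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.records["day"].unique())

    @property
    def cow_ids(self) -> np.ndarray:
        return np.sort(self.records["cow_id"].unique())

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, enrolled: pd.Series | None = None
    ) -> "MilkLog":
        return cls(pd.read_csv(path), enrolled=enrolled)


@dataclass
class QuantileMatrix:
    """Cows x days matrix of entry quantiles in (0, 1]; NaN marks absence.

    ``values`` is indexed by cow id with day-index columns.  ``subperiods``
    labels each day ``"pen"`` or ``"pasture"``.  ``provenance`` accumulates
    a human-readable trail of every filter applied.
    """

    values: pd.DataFrame
    subperiods: pd.Series
    enrolled: pd.Series | None = None
    provenance: list = field(default_factory=list)

    @property
    def n_cows(self) -> int:
        return self.values.shape[0]

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    @property
    def days(self) -> pd.Index:
        return self.values.columns

    @property
    def cow_ids(self) -> pd.Index:
        return self.values.index

    def day_counts(self) -> pd.Series:
        """Cows recorded per day (non-missing cells per column)."""
        return self.values.notna().sum(axis=0)

    def attendance(self) -> pd.Series:
        """Fraction of days each cow was recorded."""
        return self.values.notna().mean(axis=1)

    def copy(self) -> "QuantileMatrix":
        return QuantileMatrix(
            self.values.copy(),
            self.subperiods.copy(),
            None if self.enrolled is None else self.enrolled.copy(),
            list(self.provenance),
        )

    def _take_days(self, keep: Sequence, note: str) -> "QuantileMatrix":
        keep = list(keep)
        return QuantileMatrix(
            self.values.loc[:, keep],
            self.subperiods.loc[keep],
            None if self.enrolled is None else self.enrolled.loc[keep],
            self.provenance + [note],
        )

    def to_csv(self, path: str | Path) -> None:
        """Wide CSV plus a JSON sidecar for subperiods and provenance."""
        path = Path(path)
        self.values.to_csv(path, index_label="cow_id")
        sidecar = {
            "subperiods": {str(k): v for k, v in self.subperiods.items()},
            "enrolled": None
            if self.enrolled is None
            else {str(k): int(v) for k, v in self.enrolled.items()},
            "provenance": self.provenance,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "QuantileMatrix":
        path = Path(path)
        values = pd.read_csv(path, index_col="cow_id")
        values.columns = values.columns.astype(int)
        side = json.loads(path.with_suffix(".json").read_text())
        sub = pd.Series({int(k): v for k, v in side["subperiods"].items()})
        enr = side.get("enrolled")
        enrolled = (
            None if enr is None else pd.Series({int(k): v for k, v in enr.items()})
        )
        return cls(values, sub, enrolled, side.get("provenance", []))


def to_quantiles(log: MilkLog) -> QuantileMatrix:
    """Normalise ordinal entry positions to entry quantiles.

    A cow entering at position *p* on a day when *N_d* cows were recorded
    receives quantile ``p / N_d``; a cow always entering last therefore
    always scores 1 regardless of daily herd size.  Cows absent on a day
    get NaN.
    """
    rec = log.records
    n_d = log.herd_size
    quant = rec["position"].to_numpy(float) / n_d.loc[rec["day"]].to_numpy(float)
    wide = (
        rec.assign(quantile=quant)
        .pivot(index="cow_id", columns="day", values="quantile")
        .sort_index()
    )
    sub = rec.drop_duplicates("day").set_index("day")["subperiod"].sort_index()
    wide = wide.loc[:, sub.index]
    return QuantileMatrix(wide, sub, log.enrolled, ["to_quantiles"])


def filter_days(
    qm: QuantileMatrix,
    warmup: int = 55,
    drop_windows: Iterable[tuple[int, int]] | None = None,
    min_coverage: float = 0.75,
) -> QuantileMatrix:
    """Drop warm-up, management-transition and under-covered days.

    ``warmup`` removes the first ``warmup`` distinct observation days
    (rolling enrolment / queue stabilisation).  ``drop_windows`` is a list
    of inclusive ``(start, end)`` day ranges (e.g. around the move to
    pasture and trial end).  Days where fewer than ``min_coverage`` of the
    enrolled herd was recorded are dropped; the denominator is
    ``qm.enrolled`` when available, else the row count of the matrix.
    """
    if warmup >= qm.n_days:
        raise ValueError(f"warmup={warmup} >= number of days {qm.n_days}")
    days = list(qm.days)
    dropped: dict = {}
    keep = days[warmup:]
    for d in days[:warmup]:
        dropped[d] = "warmup"
    if drop_windows:
        for lo, hi in drop_windows:
            for d in list(keep):
                if lo <= d <= hi:
                    keep.remove(d)
                    dropped[d] = f"window [{lo}, {hi}]"
    if min_coverage > 0:
        denom = (
            qm.enrolled
            if qm.enrolled is not None
            else pd.Series(qm.n_cows, index=qm.days)
        )
        counts = qm.day_counts()
        for d in list(keep):
            cov = counts.loc[d] / denom.loc[d]
            if cov < min_coverage:
                keep.remove(d)
                dropped[d] = f"coverage {cov:.3f} < {min_coverage}"
    if not keep:
        raise EmptyResultError("all days filtered out")
    note = (
        f"filter_days(warmup={warmup}, windows={list(drop_windows or [])}, "
        f"min_coverage={min_coverage}) dropped {len(dropped)} days: {dropped}"
    )
    return qm._take_days(keep, note)


def filter_cows(qm: QuantileMatrix, min_attendance: float = 0.5) -> QuantileMatrix:
    """Drop cows recorded in fewer than ``min_attendance`` of the surviving
    milkings.  The boundary is inclusive: exactly 50% attendance is kept."""
    if not 0 <= min_attendance <= 1:
        raise ValueError("min_attendance must lie in [0, 1]")
    att = qm.attendance()
    keep = att[att >= min_attendance].index
    note = (
        f"filter_cows(min_attendance={min_attendance}) "
        f"dropped {qm.n_cows - len(keep)} of {qm.n_cows} cows"
    )
    return QuantileMatrix(
        qm.values.loc[keep],
        qm.subperiods.copy(),
        None if qm.enrolled is None else qm.enrolled.copy(),
        qm.provenance + [note],
    )


def subset_healthy(qm: QuantileMatrix, attributes: pd.DataFrame) -> QuantileMatrix:
    """Restrict to cows with no recorded health events.

    ``attributes`` must cover every cow in ``qm`` and carry either a
    ``health_events`` column (list/str; empty means healthy) or an integer
    ``n_health_events`` column.
    """
    missing = qm.cow_ids.difference(attributes.index)
    if len(missing):
        raise KeyError(f"cows missing from attribute table: {list(missing)}")
    attrs = attributes.loc[qm.cow_ids]
    if "n_health_events" in attrs.columns:
        healthy = attrs["n_health_events"] == 0
    elif "health_events" in attrs.columns:
        healthy = attrs["health_events"].map(
            lambda ev: (len(ev) == 0) if isinstance(ev, (list, tuple)) else (not ev)
        )
    else:
        raise KeyError("attribute table lacks health_events / n_health_events")
    keep = qm.cow_ids[healthy.to_numpy(bool)]
    if len(keep) == 0:
        raise EmptyResultError("no healthy cows remain")
    return QuantileMatrix(
        qm.values.loc[keep],
        qm.subperiods.copy(),
        None if qm.enrolled is None else qm.enrolled.copy(),
        qm.provenance + [f"subset_healthy kept {len(keep)} of {qm.n_cows} cows"],
    )
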
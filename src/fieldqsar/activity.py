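"""Activity data handling: assay arithmetic, unit conversion, train/test splits.

Activities are half-maximal inhibitory concentrations (IC50, µM) converted to
pIC50 = -log10(IC50 in mol/L) for modelling.  The train/test partition of a
QSAR dataset must keep the test-set activity range inside the training range
(otherwise external prediction is extrapolation) and the test fraction near
20-25% of the data; :func:`validate_split` checks both without mutating
anything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityRecord",
    "QsarDataset",
    "DataSplit",
    "SplitReport",
    "inhibition_percent",
    "pic50_from_ic50",
    "ic50_from_pic50",
    "validate_split",
    "read_activity_table",
    "write_activity_table",
]

# printed pIC50 and IC50 agree to <= 5e-4 for a faithfully transcribed table
PIC50_CONSISTENCY_TOL = 5e-4

TEST_FRACTION_RANGE = (0.20, 0.25)


def inhibition_percent(absorbance_control: float, absorbance_sample: float) -> float:
    """Percent inhibition from a fluorescence/absorbance pair.

    ``100 * (control - sample) / control``.  Negative values are legal
    (activation); a nonpositive control reading is not.
    """
    if not math.isfinite(absorbance_control) or absorbance_control <= 0:
        raise ValueError(
            f"control absorbance must be positive, got {absorbance_control!r}"
        )
    if absorbance_sample < 0 or not math.isfinite(absorbance_sample):
        raise ValueError(f"sample absorbance must be nonnegative, got {absorbance_sample!r}")
    return 100.0 * (absorbance_control - absorbance_sample) / absorbance_control


def pic50_from_ic50(ic50_um: float) -> float:
    """pIC50 from an IC50 given in micromolar: ``-log10(ic50_um * 1e-6)``."""
    if not (ic50_um > 0) or not math.isfinite(ic50_um):
        raise ValueError(f"IC50 must be a positive finite number in µM, got {ic50_um!r}")
    return -math.log10(ic50_um * 1e-6)


def ic50_from_pic50(pic50: float) -> float:
    """Inverse of :func:`pic50_from_ic50`; returns µM."""
    return 10.0 ** (6.0 - pic50)


@dataclass(frozen=True)
class ActivityRecord:
    """One compound's activity entry.

    Either ``ic50`` (µM) or ``pic50`` may be given; when both are present they
    must agree to within ``PIC50_CONSISTENCY_TOL`` unless ``strict=False`` at
    dataset construction (printed tables occasionally carry a misprint).
    """

    compound_id: str
    ic50: Optional[float] = None
    pic50: Optional[float] = None
    is_test: bool = False

    def __post_init__(self):
        if self.ic50 is None and self.pic50 is None:
            raise ValueError(f"record {self.compound_id}: need ic50 or pic50")
        if self.ic50 is not None and self.ic50 <= 0:
            raise ValueError(f"record {self.compound_id}: IC50 must be positive")

    @property
    def role(self) -> str:
        return "test" if self.is_test else "train"

    def resolved_pic50(self) -> float:
        if self.pic50 is not None:
            return float(self.pic50)
        return pic50_from_ic50(self.ic50)

    def is_consistent(self, tol: float = PIC50_CONSISTENCY_TOL) -> bool:
        """True unless both activity columns are present and disagree."""
        if self.ic50 is None or self.pic50 is None:
            return True
        return abs(pic50_from_ic50(self.ic50) - self.pic50) <= tol


@dataclass
class QsarDataset:
    """Activity records plus (optionally) their aligned 3D structures."""

    records: list
    structures: Optional[Mapping[str, object]] = None

    def __post_init__(self):
        ids = [r.compound_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dupes}")
        if self.structures is not None:
            unknown = set(self.structures) - set(ids)
            if unknown:
                raise ValueError(f"structures without activity records: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def compound_ids(self) -> list:
        return [r.compound_id for r in self.records]

    def pic50(self) -> pd.Series:
        return pd.Series(
            [r.resolved_pic50() for r in self.records],
            index=self.compound_ids,
            name="pic50",
        )

    def split(self) -> "DataSplit":
        train = [r.compound_id for r in self.records if not r.is_test]
        test = [r.compound_id for r in self.records if r.is_test]
        train_mean = float(np.mean([r.resolved_pic50() for r in self.records if not r.is_test]))
        return DataSplit(train_ids=train, test_ids=test, train_mean_pic50=train_mean)

    def inconsistent_ids(self, tol: float = PIC50_CONSISTENCY_TOL) -> list:
        """Compound ids whose printed IC50 and pIC50 disagree beyond ``tol``."""
        return [r.compound_id for r in self.records if not r.is_consistent(tol)]


@dataclass(frozen=True)
class DataSplit:
    train_ids: tuple
    test_ids: tuple
    train_mean_pic50: float

    def __init__(self, train_ids: Iterable[str], test_ids: Iterable[str], train_mean_pic50: float):
        object.__setattr__(self, "train_ids", tuple(train_ids))
        object.__setattr__(self, "test_ids", tuple(test_ids))
        object.__setattr__(self, "train_mean_pic50", float(train_mean_pic50))
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"ids in both train and test: {sorted(overlap)}")


@dataclass(frozen=True)
class SplitReport:
    """Outcome of the partition-rule checks. ``passed`` aggregates all three."""

    containment_ok: bool
    fraction_ok: bool
    disjoint_ok: bool
    test_fraction: float
    train_range: tuple
    test_range: tuple

    @property
    def passed(self) -> bool:
        return self.containment_ok and self.fraction_ok and self.disjoint_ok


def validate_split(dataset: QsarDataset, split: Optional[DataSplit] = None) -> SplitReport:
    """Check a train/test partition against the dataset-design rules.

    (i) max(test) <= max(train) and min(test) >= min(train) on pIC50,
    (ii) test fraction within [0.20, 0.25] of the whole set,
    (iii) train and test disjoint and jointly covering the dataset.
    """
    if split is None:
        split = dataset.split()
    known = set(dataset.compound_ids)
    used = set(split.train_ids) | set(split.test_ids)
    unknown = used - known
    if unknown:
        raise ValueError(f"split references unknown compound ids: {sorted(unknown)}")
    if used != known:
        raise ValueError(f"split does not cover the dataset; missing {sorted(known - used)}")

    pic50 = dataset.pic50()
    y_train = pic50.loc[list(split.train_ids)]
    y_test = pic50.loc[list(split.test_ids)]
    disjoint_ok = not (set(split.train_ids) & set(split.test_ids))
    frac = len(split.test_ids) / len(dataset)
    lo, hi = TEST_FRACTION_RANGE
    fraction_ok = lo <= frac <= hi
    if len(y_test) == 0 or len(y_train) == 0:
        containment_ok = False
        test_range = (math.nan, math.nan) if len(y_test) == 0 else (y_test.min(), y_test.max())
        train_range = (math.nan, math.nan) if len(y_train) == 0 else (y_train.min(), y_train.max())
    else:
        containment_ok = bool(y_test.max() <= y_train.max() and y_test.min() >= y_train.min())
        test_range = (float(y_test.min()), float(y_test.max()))
        train_range = (float(y_train.min()), float(y_train.max()))
    return SplitReport(
        containment_ok=containment_ok,
        fraction_ok=fraction_ok,
        disjoint_ok=disjoint_ok,
        test_fraction=frac,
        train_range=train_range,
        test_range=test_range,
    )


def read_activity_table(path, strict: bool = False) -> QsarDataset:
    """Read a delimited activity table (comma or tab auto-detected).

    Expected columns: ``compound_id`` and at least one of ``ic50_uM`` /
    ``pic50``; optional boolean ``is_test``.  With ``strict=True`` a row whose
    IC50 and pIC50 disagree raises instead of being carried as printed.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "compound_id" not in cols:
        raise ValueError(f"{path}: missing required column 'compound_id'")

    def _num(row, key):
        if key not in cols:
            return None
        raw = row[cols[key]]
        return None if raw is None or pd.isna(raw) or raw == "" else float(raw)

    records = []
    for _, row in df.iterrows():
        ic50 = _num(row, "ic50_um")
        pic50 = _num(row, "pic50")
        raw_test = row[cols["is_test"]] if "is_test" in cols else None
        if raw_test is None or pd.isna(raw_test):
            is_test = False
        else:
            is_test = str(raw_test).strip().lower() in ("1", "1.0", "true", "yes")
        rec = ActivityRecord(
            compound_id=str(row[cols["compound_id"]]),
            ic50=ic50,
            pic50=pic50,
            is_test=is_test,
        )
        if strict and not rec.is_consistent():
            raise ValueError(
                f"compound {rec.compound_id}: IC50 {ic50} µM inconsistent with pIC50 {pic50}"
            )
        records.append(rec)
    return QsarDataset(records=records)


def write_activity_table(dataset: QsarDataset, path) -> None:
    df = pd.DataFrame(
        {
            "compound_id": dataset.compound_ids,
            "ic50_uM": [r.ic50 for r in dataset.records],
            "pic50": [r.pic50 for r in dataset.records],
            "is_test": [int(r.is_test) for r in dataset.records],
        }
    )
    df.to_csv(path, index=False)
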
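"""Long-format study datasets: the unit of model fitting.

A :class:`StudyDataset` wraps a pandas DataFrame with one row per ECG record
and columns ``ID, SPECIES, SEX, DOSE, OCC, TIME, CONC, RR, QT``:

* ``TIME`` is hours since dosing on that occasion (may be negative pre-dose
  and exceed 24 h); the clock time entering the circadian term is
  ``(meta["dose_clock_h"] + TIME) mod 24``.
* ``CONC`` is plasma concentration in nM at the ECG time; missing values are
  written as empty CSV fields.
* ``RR`` and ``QT`` are interval lengths in ms.

``meta`` records provenance: generator seed and parameters, or file origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["StudyDataset", "COLUMNS"]

COLUMNS = ["ID", "SPECIES", "SEX", "DOSE", "OCC", "TIME", "CONC", "RR", "QT"]

DEFAULT_DOSE_CLOCK_H = 8.0


@dataclass
class StudyDataset:
    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        """Enforce the structural invariants: positive RR and QT, QT < RR, and
        unique (subject, occasion, time) keys."""
        df = self.df
        if (df["RR"] <= 0).any() or (df["QT"] <= 0).any():
            raise ValueError("RR and QT must be positive for every record")
        if (df["QT"] >= df["RR"]).any():
            bad = int((df["QT"] >= df["RR"]).sum())
            raise ValueError(f"QT must be < RR for every record ({bad} violations)")
        if df.duplicated(subset=["ID", "OCC", "TIME"]).any():
            raise ValueError("(subject, occasion, time) keys must be unique")
        if (df["CONC"].dropna() < 0).any():
            raise ValueError("CONC must be >= 0 where present")

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def dose_clock_h(self) -> float:
        return float(self.meta.get("dose_clock_h", DEFAULT_DOSE_CLOCK_H))

    def clock_time_h(self) -> np.ndarray:
        """Clock time (h in [0, 24)) of each record, for the circadian term."""
        return (self.dose_clock_h + self.df["TIME"].to_numpy(float)) % 24.0

    # ------------------------------------------------------------------ IO
    def to_csv(self, path: str | Path) -> None:
        """Write records as CSV (missing CONC as empty field); meta goes to a
        sidecar ``<path>.meta.json``."""
        path = Path(path)
        self.df.to_csv(path, index=False, na_rep="")
        if self.meta:
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(self.meta, indent=1, default=str))

    @classmethod
    def read_csv(cls, path: str | Path) -> "StudyDataset":
        path = Path(path)
        df = pd.read_csv(path, dtype={"ID": str, "SPECIES": str, "SEX": str})
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {"origin": str(path)}
        return cls(df, meta)

    def subset(self, mask) -> "StudyDataset":
        return StudyDataset(self.df[mask].reset_index(drop=True), dict(self.meta))
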
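"""Observation container: one row per birth.

Records are held as a :class:`pandas.DataFrame` with columns
``birthweight_g`` (positive, grams), ``death`` (0/1) and optionally
``covariate`` (0/1).  :class:`BirthRecord` is the scalar view of one row;
all fitting functions accept either a DataFrame or an iterable of
records/tuples and normalize through :func:`as_frame`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

BIRTHWEIGHT = "birthweight_g"
DEATH = "death"
COVARIATE = "covariate"


@dataclass(frozen=True)
class BirthRecord:
    """A single observation: birthweight in grams, a binary mortality
    outcome, and an optional binary covariate (e.g. preterm indicator)."""

    birthweight_g: float
    death: int
    covariate: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.birthweight_g) or self.birthweight_g <= 0:
            raise ValueError(f"birthweight must be positive, got {self.birthweight_g}")
        if self.death not in (0, 1):
            raise ValueError(f"death must be 0 or 1, got {self.death}")
        if self.covariate is not None and self.covariate not in (0, 1):
            raise ValueError(f"covariate must be 0 or 1, got {self.covariate}")


RecordsLike = Union[pd.DataFrame, Iterable[BirthRecord]]


def as_frame(records: RecordsLike) -> pd.DataFrame:
    """Coerce records to a validated DataFrame (copy-free for valid frames)."""
    if isinstance(records, pd.DataFrame):
        return validate_records(records)
    rows = list(records)
    if rows and isinstance(rows[0], BirthRecord):
        frame = pd.DataFrame(
            {
                BIRTHWEIGHT: [r.birthweight_g for r in rows],
                DEATH: [r.death for r in rows],
            }
        )
        covs = [r.covariate for r in rows]
        if any(c is not None for c in covs):
            frame[COVARIATE] = covs
        return validate_records(frame)
    frame = pd.DataFrame(rows, columns=[BIRTHWEIGHT, DEATH])
    return validate_records(frame)


def validate_records(frame: pd.DataFrame) -> pd.DataFrame:
    """Check the record-frame contract; raise ``ValueError`` on violation."""
    for col in (BIRTHWEIGHT, DEATH):
        if col not in frame.columns:
            raise ValueError(f"records frame missing required column {col!r}")
    if len(frame) == 0:
        raise ValueError("records frame is empty")
    bw = frame[BIRTHWEIGHT].to_numpy(dtype=float)
    if not np.all(np.isfinite(bw)) or np.any(bw <= 0):
        raise ValueError("birthweights must be finite and positive")
    d = frame[DEATH].to_numpy()
    if not np.isin(d, (0, 1)).all():
        raise ValueError("death indicator must be 0 or 1")
    if COVARIATE in frame.columns:
        c = frame[COVARIATE].dropna().to_numpy()
        if not np.isin(c, (0, 1)).all():
            raise ValueError("covariate must be 0 or 1 when present")
    return frame
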
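"""Labelled per-condition data containers.

A study consists of two conditions (low and high spatial interference,
``LI``/``HI``), each with a subjects-by-regions table of mean c-Fos
positive-cell counts and a per-subject behavior table of exploration
times.  Both containers are thin, validated wrappers around a pandas
DataFrame so every downstream artifact keeps subject and region labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Network node set: perirhinal areas 35/36, dorsolateral entorhinal
#: cortex, and the dorsal hippocampal subfields.
DEFAULT_REGIONS: tuple[str, ...] = (
    "PRH35", "PRH36", "DLENT", "DG", "CA3", "CA2", "CA1",
)


class TableValidationError(ValueError):
    """A count or behavior table violates its structural contract."""


@dataclass(frozen=True)
class CountTable:
    """Subjects x regions matrix of mean c-Fos counts for one condition.

    Values are per-animal means over three tissue sections, hence
    non-negative reals rather than integers.
    """

    condition: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.empty:
            raise TableValidationError(f"{self.condition}: empty count table")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise TableValidationError(
                f"{self.condition}: duplicate subjects {dupes}")
        if df.columns.duplicated().any():
            raise TableValidationError(
                f"{self.condition}: duplicate region labels")
        numeric = df.apply(pd.to_numeric, errors="coerce")
        arr = numeric.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            cells = [
                (str(df.index[i]), str(df.columns[j]))
                for i, j in zip(*np.where(~np.isfinite(arr)))
            ]
            raise TableValidationError(
                f"{self.condition}: non-numeric or missing cells at "
                f"(subject, region) = {cells}")
        if (arr < 0).any():
            raise TableValidationError(
                f"{self.condition}: negative counts present")

    @property
    def subjects(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def regions(self) -> list[str]:
        return [str(r) for r in self.data.columns]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class BehaviorTable:
    """Per-subject exploration times and discrimination index.

    Columns: ``t_old`` (seconds at the older object location, tOO),
    ``t_recent`` (seconds at the recent location, tRO) and the derived
    ``d2 = (t_old - t_recent) / (t_old + t_recent)``; index = subject.
    Positive d2 means the older location was preferred, the signature of
    spatiotemporal memory.
    """

    condition: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        required = {"t_old", "t_recent", "d2"}
        if not required.issubset(df.columns):
            raise TableValidationError(
                f"{self.condition}: behavior table needs columns {required}")
        if df.index.duplicated().any():
            raise TableValidationError(
                f"{self.condition}: duplicate subjects in behavior table")
        times = df[["t_old", "t_recent"]].to_numpy(float)
        if not np.isfinite(times).all() or (times < 0).any():
            raise TableValidationError(
                f"{self.condition}: exploration times must be finite and >= 0")
        total = times.sum(axis=1)
        expect = np.where(total > 0, (times[:, 0] - times[:, 1])
                          / np.where(total > 0, total, 1.0), np.nan)
        got = df["d2"].to_numpy(float)
        ok = np.isclose(got[total > 0], expect[total > 0], atol=1e-9)
        if not ok.all():
            raise TableValidationError(
                f"{self.condition}: d2 column inconsistent with times")

    @classmethod
    def from_times(cls, condition: str, subjects, t_old, t_recent
                   ) -> "BehaviorTable":
        t_old = np.asarray(t_old, dtype=float)
        t_recent = np.asarray(t_recent, dtype=float)
        total = t_old + t_recent
        if (total <= 0).any():
            bad = [str(s) for s, t in zip(subjects, total) if t <= 0]
            raise TableValidationError(
                f"{condition}: zero total exploration for subjects {bad}; "
                "discrimination index undefined")
        d2 = (t_old - t_recent) / total
        df = pd.DataFrame(
            {"t_old": t_old, "t_recent": t_recent, "d2": d2},
            index=pd.Index([str(s) for s in subjects], name="subject"),
        )
        return cls(condition=condition, data=df)

    @property
    def d2(self) -> np.ndarray:
        return self.data["d2"].to_numpy(dtype=float)

    @property
    def subjects(self) -> list[str]:
        return [str(s) for s in self.data.index]
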
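"""Study x acupoint incidence data: container, CSV round-trip, usage statistics.

The central object is a binary incidence matrix over a corpus of clinical
studies: entry ``I(x, i) = 1`` iff acupoint *x* (a standard meridian code such
as ``"BL23"``) appears in the prescription of study *i*.  Per-acupoint usage
frequency is ``P(x) = n_x / m`` where ``n_x`` is the column sum and *m* the
number of studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrescriptionDataset",
    "UsageStats",
    "load_incidence",
    "write_incidence",
    "usage_stats",
    "filter_by_frequency",
    "percent",
]


class IncidenceError(ValueError):
    """Raised for malformed or inconsistent incidence data."""


@dataclass(frozen=True)
class PrescriptionDataset:
    """An m x p binary incidence matrix with study and acupoint labels.

    Parameters
    ----------
    study_ids
        Ordered study identifiers (length m).
    acupoint_labels
        Ordered, unique acupoint codes (length p); column order of
        ``incidence`` follows this order exactly.
    incidence
        m x p array with entries in {0, 1}.
    """

    study_ids: tuple[str, ...]
    acupoint_labels: tuple[str, ...]
    incidence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "study_ids", tuple(str(s) for s in self.study_ids))
        object.__setattr__(
            self, "acupoint_labels", tuple(str(a) for a in self.acupoint_labels)
        )
        inc = np.asarray(self.incidence)
        if inc.ndim != 2:
            raise IncidenceError("incidence must be a 2-d matrix")
        m, p = inc.shape
        if m < 1 or p < 1:
            raise IncidenceError("incidence needs at least one study and one acupoint")
        if len(self.study_ids) != m:
            raise IncidenceError(
                f"{len(self.study_ids)} study ids for {m} incidence rows"
            )
        if len(self.acupoint_labels) != p:
            raise IncidenceError(
                f"{len(self.acupoint_labels)} acupoint labels for {p} incidence columns"
            )
        if len(set(self.acupoint_labels)) != p:
            dupes = sorted(
                {a for a in self.acupoint_labels if self.acupoint_labels.count(a) > 1}
            )
            raise IncidenceError(f"duplicate acupoint labels: {dupes}")
        if any(not a for a in self.acupoint_labels):
            raise IncidenceError("empty acupoint label")
        if not np.isin(inc, (0, 1)).all():
            bad = np.argwhere(~np.isin(inc, (0, 1)))[0]
            raise IncidenceError(
                f"incidence entry at row {bad[0]}, column {bad[1]} is not 0/1"
            )
        inc = inc.astype(np.uint8)
        inc.setflags(write=False)
        object.__setattr__(self, "incidence", inc)

    @property
    def m(self) -> int:
        """Number of studies (rows)."""
        return self.incidence.shape[0]

    @property
    def p(self) -> int:
        """Number of acupoints (columns)."""
        return self.incidence.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.incidence[:, self.acupoint_labels.index(label)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PrescriptionDataset):
            return NotImplemented
        return (
            self.study_ids == other.study_ids
            and self.acupoint_labels == other.acupoint_labels
            and np.array_equal(self.incidence, other.incidence)
        )

    def __hash__(self) -> int:
        return hash((self.study_ids, self.acupoint_labels, self.incidence.tobytes()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.incidence,
            index=pd.Index(self.study_ids, name="study_id"),
            columns=list(self.acupoint_labels),
        )
        return df


@dataclass(frozen=True)
class UsageStats:
    """Per-acupoint usage counts ``n_x`` and frequencies ``P(x) = n_x / m``."""

    labels: tuple[str, ...]
    counts: np.ndarray
    m: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.m

    def percent(self, label: str) -> float:
        """Usage frequency of ``label`` as a percentage, half-up at 1 decimal."""
        n = int(self.counts[self.labels.index(label)])
        return percent(n, self.m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "acupoint": list(self.labels),
                "count": self.counts.astype(int),
                "frequency": self.frequencies,
                "frequency_pct": [percent(int(n), self.m) for n in self.counts],
            }
        )


def percent(n: int, m: int) -> float:
    """Render a count out of m as a percentage rounded half-up to 1 decimal.

    Half-up (rather than banker's) rounding matches the conventional rendering
    of usage tables, e.g. 27 of 53 studies -> 50.9.
    """
    if m <= 0:
        raise IncidenceError("m must be positive")
    return float(
        (Decimal(n) * 100 / Decimal(m)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def load_incidence(path: str | Path) -> PrescriptionDataset:
    """Read an incidence CSV (header = acupoint codes, first column = study_id).

    Cells must parse to 0 or 1; a malformed cell raises an error naming its
    row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise IncidenceError(f"{path} is empty") from exc
    if df.shape[1] < 2:
        raise IncidenceError(f"{path}: need a study_id column plus >=1 acupoint")
    study_col = df.columns[0]
    labels = tuple(df.columns[1:])
    values = np.zeros((df.shape[0], len(labels)), dtype=np.uint8)
    for j, lab in enumerate(labels):
        col = df[lab].str.strip()
        bad = ~col.isin(["0", "1"])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise IncidenceError(
                f"{path}: cell at study {df[study_col].iloc[i]!r}, "
                f"acupoint {lab!r} is {col.iloc[i]!r}, expected 0 or 1"
            )
        values[:, j] = col.astype(np.uint8)
    return PrescriptionDataset(
        study_ids=tuple(df[study_col]), acupoint_labels=labels, incidence=values
    )


def write_incidence(ds: PrescriptionDataset, path: str | Path) -> Path:
    """Write the incidence CSV dialect: comma-separated, UTF-8, LF endings."""
    path = Path(path)
    lines = ["study_id," + ",".join(ds.acupoint_labels)]
    for sid, row in zip(ds.study_ids, ds.incidence):
        lines.append(sid + "," + ",".join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def usage_stats(ds: PrescriptionDataset) -> UsageStats:
    """Column sums and frequencies ``P(x) = n_x / m`` for every acupoint."""
    counts = ds.incidence.sum(axis=0).astype(np.int64)
    return UsageStats(labels=ds.acupoint_labels, counts=counts, m=ds.m)


def filter_by_frequency(
    ds: PrescriptionDataset, min_freq: float = 0.05
) -> PrescriptionDataset:
    """Keep acupoints with usage frequency strictly above ``min_freq``.

    The inequality is strict: an acupoint at exactly ``min_freq`` is dropped.
    Column order is preserved; studies are untouched.
    """
    if not 0 <= min_freq <= 1:
        raise IncidenceError("min_freq must be in [0, 1]")
    freqs = ds.incidence.sum(axis=0) / ds.m
    keep = freqs > min_freq
    if not keep.any():
        raise IncidenceError("no acupoints survive filter")
    return PrescriptionDataset(
        study_ids=ds.study_ids,
        acupoint_labels=tuple(np.array(ds.acupoint_labels)[keep]),
        incidence=ds.incidence[:, keep],
    )
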
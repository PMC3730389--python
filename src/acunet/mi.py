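"""Pointwise mutual-information statistic for acupoint pairs.

The association statistic is a single pointwise-MI term weighted by the pair's
co-usage frequency,

    MI(x, y) = P(x, y) * ln( P(x, y) / (P(x) * P(y)) ),

with P(x) = n_x / m the usage frequency of acupoint x over m studies and
P(x, y) = n_xy / m the fraction of studies using both.  This is *not* the full
Shannon mutual information of the 2x2 contingency table: it is the one term of
that sum belonging to joint presence, so frequently co-used pairs score high
even when the full-table MI would not.  Values are in nats (natural log).

The statistic is zero at independence (P(x,y) = P(x)P(y)), positive for pairs
co-used more often than independence predicts, and negative below it.  The
limit convention 0 * ln(0) = 0 applies when a pair never co-occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .incidence import PrescriptionDataset

__all__ = ["MIMatrix", "pair_mi", "mi_matrix"]


class MIError(ValueError):
    pass


@dataclass(frozen=True)
class MIMatrix:
    """Symmetric p x p matrix of pairwise MI values with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.labels), len(self.labels)):
            raise MIError("values shape does not match labels")
        if not np.allclose(vals, vals.T):
            raise MIError("MI matrix must be symmetric")
        if np.any(np.diag(vals) != 0):
            raise MIError("MI matrix diagonal must be zero")
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def p(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (i < j) values as a flat array."""
        iu = np.triu_indices(self.p, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_long(self) -> pd.DataFrame:
        """3-column long format (acupoint_a, acupoint_b, mi), i < j pairs."""
        ii, jj = np.triu_indices(self.p, k=1)
        return pd.DataFrame(
            {
                "acupoint_a": [self.labels[i] for i in ii],
                "acupoint_b": [self.labels[j] for j in jj],
                "mi": self.values[ii, jj],
            }
        )


def pair_mi(n_x: int, n_y: int, n_xy: int, m: int) -> float:
    """MI for one pair from integer tallies.

    Parameters are the marginal usage counts ``n_x``, ``n_y``, the co-usage
    count ``n_xy`` and the number of studies ``m``.  Requires ``n_x, n_y >= 1``
    (a never-used acupoint has an undefined marginal) and
    ``0 <= n_xy <= min(n_x, n_y) <= m``.  Returns 0.0 when ``n_xy == 0``.
    """
    if m < 1:
        raise MIError("m must be >= 1")
    if n_x < 1 or n_y < 1:
        raise MIError("undefined marginal: n_x and n_y must be >= 1")
    if not 0 <= n_xy <= min(n_x, n_y) or max(n_x, n_y) > m:
        raise MIError(
            f"counts out of bounds: n_xy={n_xy}, n_x={n_x}, n_y={n_y}, m={m}"
        )
    if n_xy == 0:
        return 0.0
    p_xy = n_xy / m
    return float(p_xy * np.log(p_xy / ((n_x / m) * (n_y / m))))


def mi_matrix(ds: PrescriptionDataset) -> MIMatrix:
    """Assemble the full pairwise MI matrix from an incidence dataset.

    Co-usage counts come from the Gram matrix of the incidence columns; every
    retained acupoint must appear in at least one study (apply
    :func:`~acunet.incidence.filter_by_frequency` first otherwise).
    """
    inc = ds.incidence.astype(np.int64)
    counts = inc.sum(axis=0)
    if (counts == 0).any():
        zero = [ds.acupoint_labels[i] for i in np.flatnonzero(counts == 0)]
        raise MIError(
            f"acupoints never used: {zero}; drop them with filter_by_frequency"
        )
    m = ds.m
    co = inc.T @ inc  # co[i, j] = n_ij; diagonal = n_i
    p_xy = co / m
    indep = np.outer(counts, counts) / (m * m)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = p_xy * np.log(p_xy / indep)
    vals[co == 0] = 0.0
    np.fill_diagonal(vals, 0.0)
    return MIMatrix(labels=ds.acupoint_labels, values=vals)
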
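"""Twin-pair data containers.

One record per twin pair: two phenotype values and a 2 x K block of
covariate values.  Missing entries are carried as NaN; a cell is either
observed (finite) or missing, never both.  Pairs with no observed entry at
all are rejected at construction time — they carry no information for any
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .params import Zygosity

__all__ = ["TwinPairRecord", "TwinDataset"]


@dataclass(frozen=True)
class TwinPairRecord:
    """One family's phenotypes and covariates, NaN-encoded missingness."""

    family_id: str
    zygosity: Zygosity
    y: np.ndarray  # shape (2,)
    X: np.ndarray  # shape (2, K)

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float).reshape(-1)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if y.shape != (2,):
            raise ValueError("y must have exactly two entries")
        if X.shape[0] != 2:
            raise ValueError("X must have shape (2, K)")
        if np.isnan(y).all() and np.isnan(X).all():
            raise ValueError(
                f"record {self.family_id!r} has no observed entry; "
                "zero-information pairs are rejected"
            )
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)

    @property
    def K(self) -> int:
        return self.X.shape[1]


class TwinDataset:
    """Column-oriented collection of twin-pair records.

    Attributes
    ----------
    family_id : ndarray of str, shape (n,)
    zygosity : ndarray of ``Zygosity``, shape (n,)
    y : ndarray, shape (n, 2), NaN = missing phenotype
    X : ndarray, shape (n, 2, K), NaN = missing covariate
    """

    def __init__(
        self,
        family_id: Sequence,
        zygosity: Sequence[Zygosity],
        y: np.ndarray,
        X: np.ndarray,
    ) -> None:
        self.family_id = np.asarray([str(f) for f in family_id], dtype=object)
        zyg = np.asarray(
            [z if isinstance(z, Zygosity) else Zygosity.from_token(z) for z in zygosity],
            dtype=object,
        )
        self.zygosity = zyg
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        n = len(self.family_id)
        if self.y.shape != (n, 2):
            raise ValueError(f"y must have shape ({n}, 2), got {self.y.shape}")
        if self.X.ndim != 3 or self.X.shape[:2] != (n, 2):
            raise ValueError(f"X must have shape ({n}, 2, K), got {self.X.shape}")
        if len(zyg) != n:
            raise ValueError("zygosity length mismatch")
        empty = np.isnan(self.y).all(axis=1) & np.isnan(self.X).all(axis=(1, 2))
        if empty.any():
            bad = self.family_id[empty][:5].tolist()
            raise ValueError(
                f"{int(empty.sum())} pair(s) have no observed entry (e.g. {bad}); "
                "zero-information pairs are rejected at load time"
            )

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.family_id)

    @property
    def n_pairs(self) -> int:
        return len(self)

    @property
    def K(self) -> int:
        return self.X.shape[2]

    def __iter__(self) -> Iterator[TwinPairRecord]:
        return iter(self.records())

    def records(self) -> list[TwinPairRecord]:
        return [
            TwinPairRecord(self.family_id[i], self.zygosity[i], self.y[i], self.X[i])
            for i in range(len(self))
        ]

    @classmethod
    def from_records(cls, records: Iterable[TwinPairRecord]) -> "TwinDataset":
        recs = list(records)
        if not recs:
            raise ValueError("cannot build a dataset from zero records")
        K = recs[0].K
        if any(r.K != K for r in recs):
            raise ValueError("all records must share the same number of covariates")
        return cls(
            family_id=[r.family_id for r in recs],
            zygosity=[r.zygosity for r in recs],
            y=np.stack([r.y for r in recs]),
            X=np.stack([r.X for r in recs]),
        )

    def subset(self, mask: np.ndarray) -> "TwinDataset":
        mask = np.asarray(mask)
        return TwinDataset(self.family_id[mask], self.zygosity[mask], self.y[mask], self.X[mask])

    def copy(self) -> "TwinDataset":
        return TwinDataset(self.family_id.copy(), self.zygosity.copy(), self.y.copy(), self.X.copy())

    # -- missingness bookkeeping -------------------------------------------
    @property
    def y_observed(self) -> np.ndarray:
        """Boolean mask (n, 2) of observed phenotypes."""
        return ~np.isnan(self.y)

    @property
    def X_observed(self) -> np.ndarray:
        """Boolean mask (n, 2, K) of observed covariates."""
        return ~np.isnan(self.X)

    def zygosity_codes(self) -> np.ndarray:
        """Integer codes: 1 for MZ, 0 for DZ."""
        return np.asarray([1 if z is Zygosity.MZ else 0 for z in self.zygosity], dtype=int)

    def stacked_values(self) -> np.ndarray:
        """Per-pair joint vectors (n, 2+2K) in (y1, y2, x1-block, x2-block) order."""
        n = len(self)
        return np.concatenate(
            [self.y, self.X[:, 0, :], self.X[:, 1, :]], axis=1
        ).reshape(n, 2 + 2 * self.K)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_mz = int((self.zygosity_codes() == 1).sum())
        return (
            f"TwinDataset(n_pairs={len(self)}, K={self.K}, "
            f"n_mz={n_mz}, n_dz={len(self) - n_mz})"
        )
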
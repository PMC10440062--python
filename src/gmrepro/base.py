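"""Core containers for 2D landmark data.

Landmark indices are 1-based everywhere a user sees them (scheme files,
error messages), matching the conventional numbering of landmarking
figures; conversion to 0-based array indices happens once, inside the
containers.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FACTOR_COLUMNS = ("specimen_id", "group", "operator", "trial")


class SchemeError(ValueError):
    """Invalid landmark scheme definition."""


@dataclasses.dataclass(frozen=True)
class LandmarkScheme:
    """Which landmarks are fixed, which slide, and which serve special roles.

    Parameters
    ----------
    n_landmarks
        Total number of landmarks per configuration (k).
    fixed, semi
        Disjoint 1-based index sets partitioning ``1..k``. Semi-landmarks
        are allowed to slide along the chord between their two neighbours
        during superimposition.
    slide_neighbours
        Map ``semi-landmark -> (previous, next)`` neighbour indices
        defining the sliding tangent.
    unbend
        Ordered landmarks that lie on a naturally straight body axis,
        used to correct arching (first and last define the reference
        chord).
    excluded
        Landmarks dropped before any statistics (they may still be used
        for unbending).
    """

    n_landmarks: int
    fixed: frozenset
    semi: frozenset
    slide_neighbours: Mapping[int, tuple]
    unbend: tuple = ()
    excluded: frozenset = frozenset()

    def __post_init__(self):
        k = self.n_landmarks
        if k < 3:
            raise SchemeError("a scheme needs at least 3 landmarks")
        fixed = frozenset(int(i) for i in self.fixed)
        semi = frozenset(int(i) for i in self.semi)
        object.__setattr__(self, "fixed", fixed)
        object.__setattr__(self, "semi", semi)
        object.__setattr__(self, "excluded", frozenset(int(i) for i in self.excluded))
        object.__setattr__(self, "unbend", tuple(int(i) for i in self.unbend))
        object.__setattr__(
            self,
            "slide_neighbours",
            {int(s): (int(p), int(n)) for s, (p, n) in dict(self.slide_neighbours).items()},
        )
        full = frozenset(range(1, k + 1))
        if fixed | semi != full or fixed & semi:
            raise SchemeError("fixed and semi must disjointly partition 1..n_landmarks")
        if set(self.slide_neighbours) != set(semi):
            raise SchemeError("slide_neighbours must cover exactly the semi-landmarks")
        for s, (p, n) in self.slide_neighbours.items():
            if p == n or s in (p, n):
                raise SchemeError(f"semi-landmark {s} needs two distinct neighbours, not ({p}, {n})")
            if not (1 <= p <= k and 1 <= n <= k):
                raise SchemeError(f"neighbour of semi-landmark {s} out of range")
        if not self.excluded <= full:
            raise SchemeError("excluded indices out of range")
        for i in self.unbend:
            if not 1 <= i <= k:
                raise SchemeError(f"unbend index {i} out of range")

    # ------------------------------------------------------------------
    # 0-based views used by numerical code
    @property
    def semi0(self) -> np.ndarray:
        return np.array(sorted(self.semi), dtype=int) - 1

    @property
    def prev0(self) -> np.ndarray:
        return np.array([self.slide_neighbours[s + 1][0] for s in self.semi0]) - 1

    @property
    def next0(self) -> np.ndarray:
        return np.array([self.slide_neighbours[s + 1][1] for s in self.semi0]) - 1

    @property
    def unbend0(self) -> np.ndarray:
        return np.array(self.unbend, dtype=int) - 1

    def drop_excluded(self) -> "LandmarkScheme":
        """Scheme over the retained landmarks, renumbered consecutively.

        Raises if a semi-landmark or one of its sliding neighbours is
        excluded (the sliding geometry would be undefined). Unbend
        references are cleared: unbending precedes exclusion.
        """
        if not self.excluded:
            return dataclasses.replace(self, unbend=())
        kept = [i for i in range(1, self.n_landmarks + 1) if i not in self.excluded]
        new_of_old = {old: new for new, old in enumerate(kept, start=1)}
        for s, (p, n) in self.slide_neighbours.items():
            if {s, p, n} & self.excluded:
                raise SchemeError(
                    f"cannot exclude landmark(s) {sorted({s, p, n} & self.excluded)}: "
                    f"required by sliding semi-landmark {s}"
                )
        return LandmarkScheme(
            n_landmarks=len(kept),
            fixed=frozenset(new_of_old[i] for i in self.fixed if i in new_of_old),
            semi=frozenset(new_of_old[i] for i in self.semi),
            slide_neighbours={
                new_of_old[s]: (new_of_old[p], new_of_old[n])
                for s, (p, n) in self.slide_neighbours.items()
            },
            unbend=(),
            excluded=frozenset(),
        )

    @property
    def kept0(self) -> np.ndarray:
        """0-based indices of landmarks retained for statistics."""
        return np.array(
            [i for i in range(self.n_landmarks) if (i + 1) not in self.excluded], dtype=int
        )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_landmarks": self.n_landmarks,
            "fixed": sorted(self.fixed),
            "semi": sorted(self.semi),
            "slide_neighbours": {s: list(pn) for s, pn in sorted(self.slide_neighbours.items())},
            "unbend": list(self.unbend),
            "excluded": sorted(self.excluded),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LandmarkScheme":
        return cls(
            n_landmarks=int(d["n_landmarks"]),
            fixed=frozenset(d["fixed"]),
            semi=frozenset(d.get("semi", ())),
            slide_neighbours={int(s): tuple(pn) for s, pn in dict(d.get("slide_neighbours", {})).items()},
            unbend=tuple(d.get("unbend", ())),
            excluded=frozenset(d.get("excluded", ())),
        )


@dataclasses.dataclass
class LandmarkConfiguration:
    """One digitisation of one specimen: k ordered (x, y) landmarks.

    Coordinates are in consistent units: millimetres if a scale factor
    was applied when reading, otherwise pixels.
    """

    points: np.ndarray
    specimen_id: str = ""
    group: str = ""
    operator: str = ""
    trial: int = 1
    scale: float | None = None
    image_ref: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("points must be a (k >= 3) x 2 array")
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"non-finite coordinate in configuration {self.specimen_id!r}")
        if self.trial < 1:
            raise ValueError("trial must be >= 1")
        self.points = pts

    @property
    def k(self) -> int:
        return self.points.shape[0]


@dataclasses.dataclass
class ShapeDataset:
    """N landmark configurations stacked with an aligned factor table.

    The unit every statistical routine consumes: ``coords`` is an
    (N, k, 2) block and ``factors`` a DataFrame with columns
    ``specimen_id, group, operator, trial`` whose rows align with the
    coordinate block. (specimen_id, operator, trial) triples are unique.
    """

    coords: np.ndarray
    factors: pd.DataFrame
    scheme: LandmarkScheme

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 2:
            raise ValueError("coords must be (N, k, 2)")
        if coords.shape[1] != self.scheme.n_landmarks:
            raise ValueError(
                f"coords have {coords.shape[1]} landmarks but scheme expects "
                f"{self.scheme.n_landmarks}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in dataset")
        fac = self.factors.reset_index(drop=True)
        missing = [c for c in FACTOR_COLUMNS if c not in fac.columns]
        if missing:
            raise ValueError(f"factor table missing columns {missing}")
        if len(fac) != coords.shape[0]:
            raise ValueError("factor table rows must align with coordinate block")
        dup = fac.duplicated(subset=["specimen_id", "operator", "trial"])
        if dup.any():
            t = fac.loc[dup.idxmax(), ["specimen_id", "operator", "trial"]]
            raise ValueError(
                "duplicate (specimen_id, operator, trial) triple: "
                f"({t['specimen_id']}, {t['operator']}, {t['trial']})"
            )
        self.coords = coords
        self.factors = fac

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def flat(self) -> np.ndarray:
        """(N, 2k) row-per-specimen view (x1, y1, x2, y2, ...)."""
        return self.coords.reshape(self.n, -1)

    def subset(self, mask) -> "ShapeDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ShapeDataset(self.coords[idx], self.factors.iloc[idx], self.scheme)

    def reorder(self, order: Sequence[int]) -> "ShapeDataset":
        return self.subset(np.asarray(order, dtype=int))

    def where(self, **conditions) -> "ShapeDataset":
        """Row filter on factor columns, e.g. ``ds.where(operator="Op.1", trial=1)``."""
        mask = np.ones(self.n, dtype=bool)
        for col, val in conditions.items():
            series = self.factors[col]
            if isinstance(val, (list, tuple, set, frozenset, np.ndarray)):
                mask &= series.isin(list(val)).to_numpy()
            else:
                mask &= (series == val).to_numpy()
        return self.subset(mask)

    def drop_excluded(self) -> "ShapeDataset":
        """Remove the scheme's excluded landmarks and renumber."""
        if not self.scheme.excluded:
            return ShapeDataset(self.coords, self.factors, self.scheme.drop_excluded())
        return ShapeDataset(
            self.coords[:, self.scheme.kept0, :], self.factors, self.scheme.drop_excluded()
        )


def shuffle_blind(dataset: ShapeDataset, seed: int):
    """Seeded random row permutation used to blind operators to grouping.

    Returns the shuffled dataset and the key (an index array): applying
    ``shuffled.reorder(key)`` restores the original order.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.n)
    key = np.argsort(perm)
    return dataset.reorder(perm), key
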
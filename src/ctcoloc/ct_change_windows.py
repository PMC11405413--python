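"""Modeled cortical-thickness change maps over sliding lifespan windows.

The normative ("modeled") CT input is a grid of CT values per parcel x age
x percentile x sex.  Relative CT change between ages i and j is
``dCT(i,j) = (CT_j - CT_i) / CT_i`` per parcel, and lifespan change is
scanned with a sliding window (default 5-year length, 1-year step, ages
5-90, i.e. 81 windows; an extra broad window such as (5, 30) can be
appended).  Window endpoints must lie on the age grid; no interpolation is
performed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .parcel_core import ParcelMap, ParcelTableError, check_aligned

__all__ = [
    "PERCENTILES",
    "SEXES",
    "CTTrajectorySet",
    "CTChangeMap",
    "relative_change",
    "build_windows",
    "extract_change_series",
    "residualize_on_baseline",
]

PERCENTILES = (1, 5, 25, 50, 75, 95, 99)
SEXES = ("female", "male")


@dataclasses.dataclass
class CTTrajectorySet:
    """Modeled CT per parcel x age x percentile x sex.

    ``ct`` has shape (n_parcels, n_ages, n_percentiles, n_sexes) in mm and
    must be strictly positive.  ``sex="average"`` slices are computed as
    the mean of the female and male grids.
    """

    parcel_ids: tuple[str, ...]
    ages: np.ndarray
    ct: np.ndarray
    percentiles: tuple[int, ...] = PERCENTILES
    sexes: tuple[str, ...] = SEXES
    hemisphere: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.parcel_ids = tuple(str(p) for p in self.parcel_ids)
        self.ages = np.asarray(self.ages, float)
        self.ct = np.asarray(self.ct, float)
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("age grid must be strictly increasing")
        want = (len(self.parcel_ids), self.ages.size,
                len(self.percentiles), len(self.sexes))
        if self.ct.shape != want:
            raise ValueError(f"ct shape {self.ct.shape} != {want}")
        if not np.all(self.ct > 0):
            raise ValueError("modeled CT must be strictly positive")

    def age_index(self, age: float) -> int:
        idx = np.flatnonzero(np.isclose(self.ages, age))
        if idx.size == 0:
            raise ValueError(
                f"age {age} is not on the model grid "
                f"({self.ages[0]}..{self.ages[-1]}); no interpolation"
            )
        return int(idx[0])

    def slice_map(self, age: float, percentile: int = 50,
                  sex: str = "average") -> ParcelMap:
        """CT map at one grid age/percentile/sex ('average' = (F+M)/2)."""
        ia = self.age_index(age)
        ip = self.percentiles.index(percentile)
        if sex == "average":
            vals = self.ct[:, ia, ip, :].mean(axis=1)
        else:
            vals = self.ct[:, ia, ip, self.sexes.index(sex)]
        return ParcelMap(self.parcel_ids, vals,
                         f"CT_age{age:g}_p{percentile}_{sex}", self.hemisphere)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: parcel, age, percentile, sex, ct."""
        idx = pd.MultiIndex.from_product(
            [self.parcel_ids, self.ages, self.percentiles, self.sexes],
            names=["parcel", "age", "percentile", "sex"])
        return pd.DataFrame({"ct": self.ct.ravel()}, index=idx).reset_index()

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "CTTrajectorySet":
        parcels = list(dict.fromkeys(df["parcel"].astype(str)))
        ages = np.sort(df["age"].unique())
        pcts = tuple(int(p) for p in sorted(df["percentile"].unique()))
        sexes = tuple(sorted(df["sex"].unique()))
        piv = df.set_index(["parcel", "age", "percentile", "sex"])["ct"]
        ct = np.empty((len(parcels), ages.size, len(pcts), len(sexes)))
        for i, p in enumerate(parcels):
            sub = piv.loc[p].unstack(["percentile", "sex"]).sort_index()
            for jp, pc in enumerate(pcts):
                for js, sx in enumerate(sexes):
                    ct[i, :, jp, js] = sub[(pc, sx)].to_numpy()
        return cls(tuple(parcels), ages, ct, pcts, sexes)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_long_frame().to_csv(path, sep="\t", index=False,
                                    float_format="%.17g")
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CTTrajectorySet":
        return cls.from_long_frame(
            pd.read_csv(path, sep="\t", float_precision="round_trip"))


@dataclasses.dataclass(frozen=True)
class CTChangeMap:
    """Relative CT change over one window, unitless per parcel."""

    window: tuple[float, float]
    map: ParcelMap
    percentile: int = 50
    sex: str = "average"

    def __post_init__(self) -> None:
        i, j = self.window
        if not j > i:
            raise ValueError(f"window end must exceed start: {self.window}")

    @property
    def center(self) -> float:
        """Reporting label: window midpoint (e.g. (5,10) -> 7.5)."""
        return 0.5 * (self.window[0] + self.window[1])

    @property
    def values(self) -> np.ndarray:
        return self.map.values

    @property
    def parcel_ids(self) -> tuple[str, ...]:
        return self.map.parcel_ids


def relative_change(ct_i: ParcelMap, ct_j: ParcelMap,
                    window: tuple[float, float] | None = None,
                    percentile: int = 50, sex: str = "average") -> CTChangeMap:
    """dCT(i,j) = (CT_j - CT_i) / CT_i, elementwise over parcels."""
    check_aligned(ct_i, ct_j)
    if np.any(ct_i.values <= 0):
        raise ValueError("baseline CT must be strictly positive")
    vals = (ct_j.values - ct_i.values) / ct_i.values
    if window is None:
        window = (0.0, 1.0)
    pmap = ParcelMap(ct_i.parcel_ids, vals,
                     f"dCT_{window[0]:g}_{window[1]:g}", ct_i.hemisphere)
    return CTChangeMap(window, pmap, percentile, sex)


def build_windows(start: float = 5, end: float = 90, length: float = 5,
                  step: float = 1,
                  extra_windows: list[tuple[float, float]] | None = None,
                  ) -> list[tuple[float, float]]:
    """Sliding windows (i, i+length), i = start, start+step, ..., end-length.

    The defaults produce the 81 lifespan windows (5,10)..(85,90); appending
    the broad (5, 30) developmental window gives 82.
    """
    if length <= 0 or step <= 0:
        raise ValueError("length and step must be positive")
    if end < start + length:
        raise ValueError(
            f"range [{start}, {end}] shorter than window length {length}")
    n = int(np.floor((end - start - length) / step + 1e-9)) + 1
    windows = [(start + k * step, start + k * step + length) for k in range(n)]
    for w in extra_windows or []:
        i, j = w
        if not j > i:
            raise ValueError(f"invalid extra window {w}")
        windows.append((float(i), float(j)))
    return windows


def extract_change_series(trajectories: CTTrajectorySet,
                          windows: list[tuple[float, float]],
                          percentile: int = 50, sex: str = "average",
                          ) -> list[CTChangeMap]:
    """One relative-change map per window from the selected CT slice.

    The sex-average convention takes the mean of female and male CT before
    the change computation.  Window endpoints must be on the age grid.
    """
    out = []
    for (i, j) in windows:
        ct_i = trajectories.slice_map(i, percentile, sex)
        ct_j = trajectories.slice_map(j, percentile, sex)
        out.append(relative_change(ct_i, ct_j, (i, j), percentile, sex))
    return out


def residualize_on_baseline(change: CTChangeMap, baseline: ParcelMap,
                            ) -> CTChangeMap:
    """Baseline-CT correction: residualize dCT on baseline CT across parcels.

    Sensitivity mode: removes the linear across-parcel dependence of the
    change map on the baseline CT map (intercept included).
    """
    check_aligned(change.map, baseline)
    X = np.column_stack([np.ones(baseline.n_parcels), baseline.values])
    beta, *_ = np.linalg.lstsq(X, change.values, rcond=None)
    resid = change.values - X @ beta
    pmap = change.map.with_values(resid, name=change.map.name + "_blcorr")
    return CTChangeMap(change.window, pmap, change.percentile, change.sex)
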
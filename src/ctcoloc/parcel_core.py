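"""Parcellated brain maps: data model, I/O and standardization.

A :class:`ParcelMap` holds one scalar per cortical parcel (e.g. a receptor
density z-score, cortical thickness in mm, or a percent change) together
with parcel identity and hemisphere tags.  An :class:`AtlasSet` is an
ordered, parcel-aligned collection of such maps.  Every downstream stage of
the pipeline operates on these two containers; cross-map operations refuse
mismatched parcel orderings rather than silently reindexing.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParcelMap",
    "AtlasSet",
    "ParcelTableError",
    "destrieux_labels",
    "read_parcel_table",
    "write_parcel_table",
    "zscore_map",
    "check_aligned",
]


class ParcelTableError(ValueError):
    """Raised for malformed parcel tables or inconsistent parcel sets."""


# FreeSurfer aparc.a2009s (Destrieux) cortical region base names, 74 per
# hemisphere.  Used as an optional registry to validate user tables against
# the 148-parcel convention.
_DESTRIEUX_BASE = (
    "G_and_S_frontomargin", "G_and_S_occipital_inf", "G_and_S_paracentral",
    "G_and_S_subcentral", "G_and_S_transv_frontopol", "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant", "G_and_S_cingul-Mid-Post",
    "G_cingul-Post-dorsal", "G_cingul-Post-ventral", "G_cuneus",
    "G_front_inf-Opercular", "G_front_inf-Orbital", "G_front_inf-Triangul",
    "G_front_middle", "G_front_sup", "G_Ins_lg_and_S_cent_ins",
    "G_insular_short", "G_occipital_middle", "G_occipital_sup",
    "G_oc-temp_lat-fusifor", "G_oc-temp_med-Lingual",
    "G_oc-temp_med-Parahip", "G_orbital", "G_pariet_inf-Angular",
    "G_pariet_inf-Supramar", "G_parietal_sup", "G_postcentral",
    "G_precentral", "G_precuneus", "G_rectus", "G_subcallosal",
    "G_temp_sup-G_T_transv", "G_temp_sup-Lateral", "G_temp_sup-Plan_polar",
    "G_temp_sup-Plan_tempo", "G_temporal_inf", "G_temporal_middle",
    "Lat_Fis-ant-Horizont", "Lat_Fis-ant-Vertical", "Lat_Fis-post",
    "Pole_occipital", "Pole_temporal", "S_calcarine", "S_central",
    "S_cingul-Marginalis", "S_circular_insula_ant", "S_circular_insula_inf",
    "S_circular_insula_sup", "S_collat_transv_ant", "S_collat_transv_post",
    "S_front_inf", "S_front_middle", "S_front_sup", "S_interm_prim-Jensen",
    "S_intrapariet_and_P_trans", "S_oc_middle_and_Lunatus",
    "S_oc_sup_and_transversal", "S_occipital_ant", "S_oc-temp_lat",
    "S_oc-temp_med_and_Lingual", "S_orbital_lateral",
    "S_orbital_med-olfact", "S_orbital-H_Shaped", "S_parieto_occipital",
    "S_pericallosal", "S_postcentral", "S_precentral-inf-part",
    "S_precentral-sup-part", "S_suborbital", "S_subparietal",
    "S_temporal_inf", "S_temporal_sup", "S_temporal_transverse",
)


def destrieux_labels() -> tuple[str, ...]:
    """148 Destrieux parcel labels, left hemisphere first (``L_``/``R_``)."""
    return tuple(f"L_{n}" for n in _DESTRIEUX_BASE) + tuple(
        f"R_{n}" for n in _DESTRIEUX_BASE
    )


def _infer_hemispheres(parcel_ids: Sequence[str]) -> tuple[str, ...]:
    """Infer L/R tags from id prefixes; fall back to a half split."""
    out = []
    for pid in parcel_ids:
        low = pid.lower()
        if low.startswith(("l_", "lh", "left")):
            out.append("L")
        elif low.startswith(("r_", "rh", "right")):
            out.append("R")
        else:
            out.append("")
    if all(out):
        return tuple(out)
    half = len(parcel_ids) // 2
    return tuple("L" if i < half else "R" for i in range(len(parcel_ids)))


@dataclasses.dataclass(frozen=True)
class ParcelMap:
    """One scalar value per cortical parcel.

    Parameters
    ----------
    parcel_ids : ordered parcel label strings (identity is by label).
    values : one real value per parcel; NaN/inf are rejected.
    name : map name (e.g. atlas or marker name).
    hemisphere : per-parcel ``"L"``/``"R"`` tags; inferred from label
        prefixes when omitted.
    standardized : whether the map is z-scored across parcels.
    """

    parcel_ids: tuple[str, ...]
    values: np.ndarray
    name: str = "map"
    hemisphere: tuple[str, ...] = ()
    standardized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "parcel_ids", tuple(str(p) for p in self.parcel_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size != len(self.parcel_ids):
            raise ParcelTableError(
                f"map '{self.name}': {vals.size} values for "
                f"{len(self.parcel_ids)} parcels"
            )
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            dupes = sorted({p for p in self.parcel_ids if self.parcel_ids.count(p) > 1})
            raise ParcelTableError(f"duplicated parcel ids: {dupes[:5]}")
        if not np.all(np.isfinite(vals)):
            bad = [self.parcel_ids[i] for i in np.flatnonzero(~np.isfinite(vals))[:5]]
            raise ParcelTableError(f"map '{self.name}': non-finite values at {bad}")
        hemi = self.hemisphere or _infer_hemispheres(self.parcel_ids)
        if len(hemi) != len(self.parcel_ids):
            raise ParcelTableError("hemisphere tags must match parcel count")
        object.__setattr__(self, "hemisphere", tuple(hemi))
        if self.standardized:
            if abs(vals.mean()) > 1e-9 or abs(vals.std() - 1.0) > 1e-9:
                raise ParcelTableError(
                    f"map '{self.name}' flagged standardized but mean/SD are "
                    f"{vals.mean():.3g}/{vals.std():.3g}"
                )

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def with_values(self, values: np.ndarray, name: str | None = None,
                    standardized: bool | None = None) -> "ParcelMap":
        """Same parcels, new values."""
        return ParcelMap(
            self.parcel_ids,
            np.asarray(values, float),
            name if name is not None else self.name,
            self.hemisphere,
            self.standardized if standardized is None else standardized,
        )

    def validate_against(self, registry: Sequence[str]) -> None:
        """Check the parcel set equals ``registry`` (order included)."""
        missing = [p for p in registry if p not in set(self.parcel_ids)]
        extra = [p for p in self.parcel_ids if p not in set(registry)]
        if missing or extra:
            raise ParcelTableError(
                f"parcel set mismatch: missing {missing[:5]}, "
                f"unexpected {extra[:5]}"
            )
        if tuple(self.parcel_ids) != tuple(registry):
            raise ParcelTableError("parcel order differs from registry order")


@dataclasses.dataclass
class AtlasSet:
    """Ordered, parcel-aligned collection of maps.

    ``modality`` carries an optional per-map tag (``ni``/``ce``/``mr``),
    ``provenance`` free-text per map.
    """

    maps: list[ParcelMap]
    modality: dict[str, str] = dataclasses.field(default_factory=dict)
    provenance: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.maps:
            raise ParcelTableError("AtlasSet needs at least one map")
        names = [m.name for m in self.maps]
        if len(set(names)) != len(names):
            raise ParcelTableError(f"map names not unique: {names}")
        ref = self.maps[0].parcel_ids
        for m in self.maps[1:]:
            if m.parcel_ids != ref:
                raise ParcelTableError(
                    f"map '{m.name}' has a different parcel set/order than "
                    f"'{self.maps[0].name}'"
                )

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.maps]

    @property
    def parcel_ids(self) -> tuple[str, ...]:
        return self.maps[0].parcel_ids

    @property
    def n_parcels(self) -> int:
        return self.maps[0].n_parcels

    def __len__(self) -> int:
        return len(self.maps)

    def __getitem__(self, name: str) -> ParcelMap:
        for m in self.maps:
            if m.name == name:
                return m
        raise KeyError(name)

    def matrix(self) -> np.ndarray:
        """(n_parcels, n_maps) value matrix in map order."""
        return np.column_stack([m.values for m in self.maps])

    def subset(self, names: Iterable[str]) -> "AtlasSet":
        names = list(names)
        return AtlasSet(
            [self[n] for n in names],
            {n: self.modality[n] for n in names if n in self.modality},
            {n: self.provenance[n] for n in names if n in self.provenance},
        )

    def zscored(self) -> "AtlasSet":
        return AtlasSet([zscore_map(m) for m in self.maps],
                        dict(self.modality), dict(self.provenance))


def check_aligned(*objs) -> tuple[str, ...]:
    """Assert identical parcel id order across maps/sets; return the ids."""
    ids = [tuple(o.parcel_ids) for o in objs]
    for other in ids[1:]:
        if other != ids[0]:
            raise ParcelTableError(
                "parcel orderings differ between inputs; reindexing is not "
                "done implicitly"
            )
    return ids[0]


def read_parcel_table(path: str | Path, id_column: str = "parcel",
                      registry: Sequence[str] | None = None) -> AtlasSet:
    """Read a delimited parcel table (one row per parcel) into an AtlasSet.

    The delimiter is inferred from the suffix (``.csv`` → comma, otherwise
    tab).  All non-id columns must be numeric; column order becomes map
    order.  If ``registry`` is given, the parcel set must match it and
    missing parcels are named in the error.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#",
                     float_precision="round_trip")
    if id_column not in df.columns:
        raise ParcelTableError(
            f"{path.name}: id column '{id_column}' not found "
            f"(columns: {list(df.columns)})"
        )
    ids = df[id_column].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({p for p in ids if ids.count(p) > 1})
        raise ParcelTableError(f"{path.name}: duplicated parcel ids {dupes[:5]}")
    hemi_col = next((c for c in df.columns if c.lower() == "hemisphere"), None)
    value_cols = [c for c in df.columns if c not in (id_column, hemi_col)]
    if not value_cols:
        raise ParcelTableError(f"{path.name}: no numeric value columns")
    maps = []
    for col in value_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParcelTableError(
                f"{path.name}: non-numeric cell at row {row + 2}, "
                f"column '{col}': {df[col].iloc[row]!r}"
            )
        hemi = tuple(df[hemi_col].astype(str)) if hemi_col else ()
        maps.append(ParcelMap(ids, numeric.to_numpy(float), str(col), hemi))
    atlases = AtlasSet(maps)
    if registry is not None:
        missing = [p for p in registry if p not in set(ids)]
        if missing or len(ids) != len(registry):
            raise ParcelTableError(
                f"{path.name}: expected {len(registry)} parcels, got "
                f"{len(ids)}; missing {missing[:5]}"
            )
        atlases.maps[0].validate_against(registry)
    return atlases


def write_parcel_table(atlases: AtlasSet | ParcelMap, path: str | Path,
                       id_column: str = "parcel") -> Path:
    """Write maps to TSV/CSV (delimiter from suffix). Full float precision."""
    if isinstance(atlases, ParcelMap):
        atlases = AtlasSet([atlases])
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame({id_column: list(atlases.parcel_ids)})
    df["hemisphere"] = list(atlases.maps[0].hemisphere)
    for m in atlases.maps:
        df[m.name] = m.values
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def zscore_map(pmap: ParcelMap) -> ParcelMap:
    """Z-standardize across parcels (population SD, denominator n).

    Idempotent; raises on constant maps.
    """
    v = pmap.values
    sd = v.std()  # population convention
    if sd == 0 or not np.isfinite(sd):
        raise ParcelTableError(f"map '{pmap.name}' is constant; cannot z-score")
    z = (v - v.mean()) / sd
    # guard against float drift so the standardized invariant holds exactly
    z = (z - z.mean()) / z.std()
    return pmap.with_values(z, standardized=True)
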
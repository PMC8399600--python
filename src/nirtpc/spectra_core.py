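"""Core data model for NIR spectra sets.

A :class:`SpectraSet` couples a uniform wavenumber grid (cm⁻¹, stored
descending as FT-NIR instruments emit them), an absorbance matrix
(samples × wavenumbers, diffuse-reflectance absorbance units) and a
per-sample metadata table. It is the currency every pipeline stage
consumes and produces.

Metadata columns
----------------
``sample_id``
    Unique per spectrum (per scan when samples are scanned repeatedly).
``concentration``
    Reference total-polyphenol concentration in mg L⁻¹ gallic acid
    equivalents; may be missing (NaN) for unknowns.
``replicate_group``
    Scans of the same physical sample share a group and are averaged by
    :func:`average_replicates`.
``role``
    One of ``calibration``, ``validation``, ``blank``, ``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    GridError,
    MetadataError,
    RegionError,
)

META_COLUMNS = ("sample_id", "concentration", "replicate_group", "role")
ROLES = frozenset({"calibration", "validation", "blank", "unknown"})

#: Full instrument range, cm⁻¹.
FULL_RANGE = (4000.0, 10000.0)

#: Wavenumber intervals retained for model building: the water band at
#: 5344–4960 cm⁻¹ (OH stretch of residual moisture) and the noisy ends
#: 10000–9612 and 4068–4000 cm⁻¹ are excluded.
MODEL_REGIONS = ((5344.0, 9612.0), (4068.0, 4960.0))


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis in cm⁻¹, possibly with excluded gaps.

    ``values`` must be strictly monotonic and lie inside the 4000–10000
    cm⁻¹ NIR window. Spacing must be uniform (relative tolerance 1e-9)
    up to gaps that are whole multiples of the base spacing — the shape
    a uniform instrument grid takes after region exclusion. A grid like
    (10000, 9992, 9985) with incommensurate steps 8 and 7 is rejected.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise GridError("grid needs at least two wavenumbers")
        d = np.diff(v)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise GridError("wavenumber grid must be strictly monotonic")
        base = np.abs(d).min()
        ratio = np.abs(d) / base
        if not np.allclose(ratio, np.round(ratio), rtol=1e-9, atol=1e-9):
            raise GridError(
                f"non-uniform grid spacing: {sorted(set(np.round(np.abs(d), 6)))[:4]}"
            )
        lo, hi = float(v.min()), float(v.max())
        if lo < FULL_RANGE[0] - 1e-9 or hi > FULL_RANGE[1] + 1e-9:
            raise GridError(f"grid [{lo}, {hi}] outside NIR window {FULL_RANGE}")

    @property
    def step(self) -> float:
        """Signed base spacing in grid order (negative for descending grids)."""
        d = np.diff(self.values)
        i = int(np.argmin(np.abs(d)))
        return float(d[i])

    @property
    def spacing(self) -> float:
        """Magnitude of the base spacing, cm⁻¹."""
        return abs(self.step)

    def __len__(self) -> int:
        return int(self.values.size)

    @classmethod
    def default(cls, low: float = 4000.0, high: float = 10000.0, spacing: float = 8.0) -> "WavenumberGrid":
        """Descending grid covering [low, high] at the given spacing."""
        return cls(np.arange(high, low - spacing / 2, -spacing))


@dataclass(frozen=True)
class RegionSpec:
    """Closed wavenumber intervals to keep for model building."""

    keep_intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.keep_intervals)
        object.__setattr__(self, "keep_intervals", ivs)
        for lo, hi in ivs:
            if not lo < hi:
                raise RegionError(f"interval [{lo}, {hi}] must satisfy low < high")
        ordered = sorted(ivs)
        for (_, hi1), (lo2, _) in zip(ordered, ordered[1:]):
            if lo2 <= hi1:
                raise RegionError("keep intervals must not overlap")

    def mask(self, grid: WavenumberGrid) -> np.ndarray:
        """Boolean mask over grid columns lying inside any interval."""
        v = grid.values
        m = np.zeros(v.size, dtype=bool)
        for lo, hi in self.keep_intervals:
            m |= (v >= lo) & (v <= hi)
        return m

    @classmethod
    def model_default(cls) -> "RegionSpec":
        return cls(MODEL_REGIONS)


def _validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    meta = meta.loc[:, list(META_COLUMNS)].reset_index(drop=True)
    meta["concentration"] = pd.to_numeric(meta["concentration"], errors="coerce").astype(float)
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["replicate_group"] = meta["replicate_group"].astype(str)
    bad_roles = set(meta["role"]) - ROLES
    if bad_roles:
        raise MetadataError(f"unknown roles {sorted(bad_roles)}; allowed {sorted(ROLES)}")
    conc = meta["concentration"]
    if (conc.dropna() < 0).any():
        raise MetadataError("concentrations must be non-negative")
    cal_missing = (meta["role"] == "calibration") & conc.isna()
    if cal_missing.any():
        raise MetadataError(
            "calibration samples require a reference concentration: "
            f"{meta.loc[cal_missing, 'sample_id'].tolist()}"
        )
    return meta


@dataclass
class SpectraSet:
    """Wavenumber grid + absorbance matrix + aligned sample metadata."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.absorbance, dtype=float)
        if A.ndim != 2:
            raise FormatError("absorbance must be a 2-D matrix")
        if A.shape[1] != len(self.grid):
            raise FormatError(
                f"absorbance has {A.shape[1]} columns but grid has {len(self.grid)}"
            )
        if not np.all(np.isfinite(A)):
            raise FormatError("absorbance contains non-finite values")
        self.absorbance = A
        self.meta = _validate_meta(self.meta)
        if len(self.meta) != A.shape[0]:
            raise FormatError(
                f"{A.shape[0]} spectra but {len(self.meta)} metadata rows"
            )

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    def with_absorbance(self, A: np.ndarray) -> "SpectraSet":
        """Copy with the absorbance matrix replaced (same grid and meta)."""
        return SpectraSet(self.grid, A, self.meta.copy())

    def select(self, rows) -> "SpectraSet":
        """Row subset by boolean mask or integer index."""
        idx = np.asarray(rows)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectraSet(
            self.grid,
            self.absorbance[idx],
            self.meta.iloc[idx].reset_index(drop=True),
        )

    def concentrations(self) -> np.ndarray:
        return self.meta["concentration"].to_numpy(dtype=float)


def read_spectra(spectra_path, meta_path) -> SpectraSet:
    """Load a spectra CSV (first column sample_id, header = wavenumbers)
    and a metadata CSV into a validated :class:`SpectraSet`.

    Sample order is taken from the spectra file; the metadata rows must
    list the same sample_ids in the same order.
    """
    try:
        df = pd.read_csv(spectra_path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse spectra CSV {spectra_path}: {exc}") from exc
    try:
        grid = WavenumberGrid(np.array([float(c) for c in df.columns]))
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header in {spectra_path}: {exc}") from exc
    A = df.to_numpy()
    if A.size == 0:
        A = A.astype(float)
    if A.dtype == object or not np.issubdtype(A.dtype, np.number):
        raise FormatError(f"non-numeric absorbance values in {spectra_path}")
    meta = pd.read_csv(meta_path)
    meta = _validate_meta(meta)
    if len(meta) != len(df):
        raise FormatError(
            f"{len(df)} spectra in {spectra_path} but {len(meta)} metadata rows in {meta_path}"
        )
    if list(meta["sample_id"].astype(str)) != [str(i) for i in df.index]:
        raise FormatError("sample_id order differs between spectra and metadata files")
    return SpectraSet(grid, A, meta)


def write_spectra(s: SpectraSet, spectra_path, meta_path) -> None:
    """Write the spectra and metadata CSVs read back by :func:`read_spectra`.

    Round-trips to better than 1e-12 relative (full float precision via
    repr formatting).
    """
    for p in (spectra_path, meta_path):
        Path(p).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        s.absorbance,
        index=pd.Index(s.meta["sample_id"], name="sample_id"),
        columns=[format(float(w), ".17g") for w in s.grid.values],
    )
    df.to_csv(spectra_path, float_format="%.17g")
    s.meta.to_csv(meta_path, index=False, float_format="%.17g")


def reduce_regions(s: SpectraSet, r: RegionSpec) -> SpectraSet:
    """Keep only the wavenumber columns inside the RegionSpec's closed intervals.

    Column order is preserved; an empty selection raises
    :class:`~nirtpc.exceptions.RegionError`.
    """
    m = r.mask(s.grid)
    if m.sum() < 2:
        raise RegionError(
            f"regions {r.keep_intervals} select {int(m.sum())} wavenumbers; need >= 2"
        )
    return SpectraSet(
        WavenumberGrid(s.grid.values[m]),
        s.absorbance[:, m],
        s.meta.copy(),
    )


def average_replicates(s: SpectraSet) -> SpectraSet:
    """Average consecutive scans of the same sample.

    Rows sharing ``replicate_group`` are replaced by their arithmetic
    mean (one row per group, in order of first appearance). The group
    members must agree on concentration and role.
    """
    meta = s.meta
    if meta["replicate_group"].isna().any():
        raise MetadataError("replicate_group must be populated for averaging")
    rows = []
    out_meta = []
    for group, sub in meta.groupby("replicate_group", sort=False):
        conc = sub["concentration"]
        vals = conc.dropna().unique()
        if len(vals) > 1 or (len(vals) == 1 and conc.isna().any()):
            raise MetadataError(
                f"replicate group {group!r} mixes concentrations {conc.tolist()}"
            )
        roles = sub["role"].unique()
        if len(roles) > 1:
            raise MetadataError(f"replicate group {group!r} mixes roles {list(roles)}")
        rows.append(s.absorbance[sub.index.to_numpy()].mean(axis=0))
        out_meta.append(
            {
                "sample_id": str(group),
                "concentration": vals[0] if len(vals) else np.nan,
                "replicate_group": group,
                "role": roles[0],
            }
        )
    return SpectraSet(s.grid, np.vstack(rows), pd.DataFrame(out_meta))
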
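"""Spectral libraries, property tables and preprocessing.

Reads and writes wide-format spectral libraries (one column per wavelength),
converts reflectance to apparent absorbance log10(1/R), aggregates per-depth
soil records to a single profile value by thickness weighting, applies the
log transform used to normalise right-skewed properties, screens outliers at
a standard-deviation threshold, and computes descriptive statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "SpectralLibrary",
    "PropertyTable",
    "SummaryStats",
    "read_spectral_library",
    "write_spectral_library",
    "read_property_table",
    "to_absorbance",
    "depth_weighted_average",
    "log_transform",
    "back_transform",
    "remove_outliers",
    "summary_stats",
]


@dataclass
class SpectralLibrary:
    """Per-sample spectra on a common, strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array of float, shape (p,)
        Wavelength grid in nm, strictly increasing.
    spectra : array of float, shape (n, p)
        One row per sample. Reflectance values must lie in (0, 1];
        absorbance values are unconstrained positive-or-negative reals.
    sample_ids : sequence of str
        Unique sample labels, one per row.
    mode : {"reflectance", "absorbance"}
    x, y : arrays of float, shape (n,), optional
        Planar sample coordinates (same length unit as the property table).
    """

    wavelengths: np.ndarray
    spectra: np.ndarray
    sample_ids: list
    mode: str = "reflectance"
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.sample_ids = list(self.sample_ids)
        if self.mode not in ("reflectance", "absorbance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.wavelengths.ndim != 1 or not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if self.spectra.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ValueError(
                f"spectra shape {self.spectra.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths.size} wavelengths"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain missing or non-finite values")
        if self.mode == "reflectance":
            if np.any(self.spectra <= 0) or np.any(self.spectra > 1):
                bad = np.where((self.spectra <= 0) | (self.spectra > 1))[0]
                raise ValueError(
                    f"reflectance outside (0, 1] for sample(s) "
                    f"{[self.sample_ids[i] for i in np.unique(bad)[:5]]}"
                )
        for coord in ("x", "y"):
            v = getattr(self, coord)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (len(self.sample_ids),) or not np.all(np.isfinite(v)):
                    raise ValueError(f"{coord} must be finite with one value per sample")
                setattr(self, coord, v)

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size


@dataclass
class PropertyTable:
    """Georeferenced sample properties, optionally with per-depth records.

    ``data`` holds one row per record with columns ``id``, ``x``, ``y``,
    optional ``depth_top``/``depth_bottom`` (cm) and one column per property.
    """

    data: pd.DataFrame
    property_names: list = field(default_factory=list)

    def __post_init__(self):
        df = self.data
        for col in ("id", "x", "y"):
            if col not in df.columns:
                raise ValueError(f"property table missing column {col!r}")
        if not np.all(np.isfinite(df[["x", "y"]].to_numpy(float))):
            raise ValueError("coordinates must be finite")
        if not self.property_names:
            reserved = {"id", "x", "y", "depth_top", "depth_bottom"}
            self.property_names = [c for c in df.columns if c not in reserved]

    @property
    def has_depths(self) -> bool:
        return {"depth_top", "depth_bottom"} <= set(self.data.columns)

    def values(self, prop: str) -> np.ndarray:
        return self.data[prop].to_numpy(dtype=float)

    def locations(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    min: float
    median: float
    max: float
    cv: float
    skewness: float


def read_spectral_library(path, delimiter: str = ",", mode: str = "reflectance") -> SpectralLibrary:
    """Read a wide-format spectral library CSV: ``id,x,y,<wl1>,<wl2>,...``."""
    df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    if df.shape[1] < 4:
        raise ValueError("expected columns id,x,y plus at least one wavelength")
    try:
        wavelengths = np.array([float(c) for c in df.columns[3:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header: {exc}") from None
    spectra = df.iloc[:, 3:].to_numpy()
    if spectra.dtype == object or not np.issubdtype(spectra.dtype, np.number):
        raise ValueError("non-numeric cells in spectral data")
    return SpectralLibrary(
        wavelengths=wavelengths,
        spectra=spectra.astype(float),
        sample_ids=[str(s) for s in df.iloc[:, 0]],
        mode=mode,
        x=df.iloc[:, 1].to_numpy(float),
        y=df.iloc[:, 2].to_numpy(float),
    )


def write_spectral_library(lib: SpectralLibrary, path, delimiter: str = ",") -> None:
    """Write a library in the wide CSV layout read_spectral_library expects.

    Values are written with shortest round-trip float formatting so that a
    load/write/load cycle is bit-identical.
    """
    x = lib.x if lib.x is not None else np.zeros(lib.n_samples)
    y = lib.y if lib.y is not None else np.zeros(lib.n_samples)
    cols = {"id": lib.sample_ids, "x": x, "y": y}
    header = ["id", "x", "y"] + [repr(w) if w != int(w) else str(int(w)) for w in lib.wavelengths]
    with open(path, "w") as fh:
        fh.write(delimiter.join(header) + "\n")
        for i in range(lib.n_samples):
            row = [str(cols["id"][i]), repr(float(x[i])), repr(float(y[i]))]
            row += [repr(float(v)) for v in lib.spectra[i]]
            fh.write(delimiter.join(row) + "\n")


def read_property_table(path, delimiter: str = ",") -> PropertyTable:
    df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    df = df.rename(columns={df.columns[0]: "id"})
    return PropertyTable(data=df)


def to_absorbance(lib: SpectralLibrary) -> SpectralLibrary:
    """Convert reflectance R to apparent absorbance log10(1/R)."""
    if lib.mode != "reflectance":
        raise ValueError("library is already in absorbance mode")
    if np.any(lib.spectra <= 0):
        bad = np.unique(np.where(lib.spectra <= 0)[0])
        raise ValueError(
            f"non-positive reflectance in sample(s) {[lib.sample_ids[i] for i in bad[:5]]}"
        )
    return replace(lib, spectra=np.log10(1.0 / lib.spectra), mode="absorbance")


def depth_weighted_average(table: PropertyTable) -> PropertyTable:
    """Aggregate per-depth records to one record per sample.

    Each property is averaged over a sample's depth layers with the layer
    thickness (depth_bottom - depth_top, cm) as the weight; coordinates are
    carried through unchanged. Overlapping layers trigger a warning but the
    stated thicknesses are used as given.
    """
    if not table.has_depths:
        raise ValueError("table has no depth_top/depth_bottom columns")
    df = table.data.copy()
    thick = df["depth_bottom"].to_numpy(float) - df["depth_top"].to_numpy(float)
    if np.any(thick < 0):
        raise ValueError("negative layer thickness")
    df["_w"] = thick

    out_rows = []
    for sid, grp in df.groupby("id", sort=False):
        w = grp["_w"].to_numpy(float)
        if w.sum() <= 0:
            raise ValueError(f"zero total thickness for sample {sid!r}")
        g = grp.sort_values("depth_top")
        tops, bots = g["depth_top"].to_numpy(float), g["depth_bottom"].to_numpy(float)
        if len(g) > 1 and np.any(tops[1:] < bots[:-1] - 1e-9):
            warnings.warn(f"overlapping depth intervals for sample {sid!r}; "
                          "using thicknesses as given")
        row = {"id": sid, "x": grp["x"].iloc[0], "y": grp["y"].iloc[0]}
        for prop in table.property_names:
            v = grp[prop].to_numpy(float)
            row[prop] = float(np.sum(w * v) / w.sum())
        out_rows.append(row)
    return PropertyTable(data=pd.DataFrame(out_rows), property_names=table.property_names)


def log_transform(values) -> np.ndarray:
    """Natural-log transform toward normality for right-skewed properties."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("log transform requires strictly positive values")
    return np.log(v)


def back_transform(values) -> np.ndarray:
    """Inverse of :func:`log_transform` (plain exponentiation, no bias correction)."""
    return np.exp(np.asarray(values, dtype=float))


def remove_outliers(values, k: float = 2.5):
    """Flag values more than ``k`` standard deviations from the mean.

    A single (non-iterated) pass: mean and sd (ddof=1) come from the full
    input. Returns ``(kept_mask, n_removed)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values for outlier screening")
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("zero standard deviation; no outliers removed")
        return np.ones(v.size, dtype=bool), 0
    kept = np.abs(v - v.mean()) <= k * sd
    return kept, int((~kept).sum())


def summary_stats(values) -> SummaryStats:
    """Descriptive statistics: n, mean, sd (ddof=1), min/median/max, cv, skewness.

    cv = sd/mean; skewness is the adjusted Fisher-Pearson standardized
    moment coefficient (sample-size corrected).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return SummaryStats(
        n=int(v.size),
        mean=mean,
        sd=sd,
        min=float(v.min()),
        median=float(np.median(v)),
        max=float(v.max()),
        cv=sd / mean if mean != 0 else float("nan"),
        skewness=float(_stats.skew(v, bias=False)),
    )
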
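"""Maximal-overlap wavelet multiresolution analysis of spectra.

Each spectrum is decomposed additively into detail series D_1..D_J at dyadic
scales lambda_i = 2^i plus a smooth series S at the coarsest scale, all
full-length and aligned to the wavelength grid (undecimated transform).
Boundaries are handled by reflecting the spectrum to twice its length and
treating the result as circular, so the analysis never sees a hard edge.

The pyramid follows the standard maximal-overlap DWT recursion: the level-j
coefficients are obtained by filtering the level-(j-1) scaling coefficients
with the wavelet/scaling filters upsampled by 2^(j-1); detail and smooth
series come from running the adjoint cascade back down with all other
levels zeroed, which makes S + sum_i D_i an exact reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

__all__ = [
    "WaveletSpec",
    "MRADecomposition",
    "WaveletFeatureMatrix",
    "decompose",
    "decompose_library",
    "modwt_mra",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Daubechies extremal-phase wavelet, number of levels and boundary rule.

    ``vanishing_moments=4`` selects the filter of length 8 (pywt ``db4``).
    ``levels`` J defaults to 6, giving detail scales 2, 4, ..., 64 samples.
    """

    vanishing_moments: int = 4
    levels: int = 6
    boundary: str = "reflection"

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.vanishing_moments < 1:
            raise ValueError("vanishing_moments must be >= 1")
        if self.boundary not in ("reflection", "periodic"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def wavelet_name(self) -> str:
        return f"db{self.vanishing_moments}"

    def filters(self):
        """MODWT scaling and wavelet filters (unit-energy filters / sqrt 2)."""
        w = pywt.Wavelet(self.wavelet_name)
        g = np.asarray(w.dec_lo, dtype=float)[::-1] / np.sqrt(2.0)
        L = g.size
        h = np.array([(-1) ** l * g[L - 1 - l] for l in range(L)])
        return g, h

    @property
    def scale_labels(self) -> list:
        return [f"D{i}" for i in range(1, self.levels + 1)] + ["S"]


@dataclass
class MRADecomposition:
    """Additive MRA of one spectrum: details[i] is D_{i+1}, plus smooth S."""

    details: list
    smooth: np.ndarray
    sample_id: str | None = None

    @property
    def levels(self) -> int:
        return len(self.details)

    def reconstruct(self) -> np.ndarray:
        return self.smooth + np.sum(self.details, axis=0)


_TRANSFER_CACHE: dict = {}


def _transfer_functions(N: int, spec: WaveletSpec) -> np.ndarray:
    """Real transfer functions of the J+1 MRA components on a length-N circle.

    The pyramid filters level j-1 scaling coefficients with the wavelet /
    scaling filters upsampled by 2^(j-1); the detail (smooth) series applies
    the adjoint cascade back down. In the frequency domain each component is
    therefore multiplication by |H_j|^2 prod_{i<j} |G_i|^2 (resp.
    prod_i |G_i|^2), which is real and non-negative, and the J+1 transfer
    functions sum to one (perfect reconstruction).
    """
    key = (N, spec.wavelet_name, spec.levels)
    if key in _TRANSFER_CACHE:
        return _TRANSFER_CACHE[key]
    g, h = spec.filters()
    J = spec.levels
    freqs = np.arange(N // 2 + 1)
    lags = np.arange(g.size)
    transfers = np.empty((J + 1, freqs.size))
    G_running = np.ones(freqs.size)  # prod of |G_i|^2 for i < current level
    for j in range(1, J + 1):
        phase = np.exp(-2j * np.pi * np.outer(freqs, (1 << (j - 1)) * lags) / N)
        Hj = phase @ h
        Gj = phase @ g
        transfers[j - 1] = G_running * np.abs(Hj) ** 2
        G_running = G_running * np.abs(Gj) ** 2
    transfers[J] = G_running
    _TRANSFER_CACHE[key] = transfers
    return transfers


def modwt_mra(X: np.ndarray, spec: WaveletSpec) -> list:
    """Circular MODWT-based MRA of the rows of ``X``.

    Returns ``[D1, ..., DJ, S]``, each with the shape of ``X``; the sum of
    all components reconstructs ``X`` exactly (perfect reconstruction of
    the orthonormal-per-level cascade). Implemented as zero-phase circular
    filtering with the cascade's composed transfer functions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[-1]
    transfers = _transfer_functions(N, spec)
    spectrum = np.fft.rfft(X, axis=-1)
    return [np.fft.irfft(spectrum * T, n=N, axis=-1) for T in transfers]


def _reflect_extend(X: np.ndarray) -> np.ndarray:
    return np.concatenate([X, X[..., ::-1]], axis=-1)


def decompose(spectrum, spec: WaveletSpec | None = None, sample_id=None) -> MRADecomposition:
    """MRA of one spectrum with the configured boundary rule.

    With ``boundary='reflection'`` the spectrum is mirrored to length 2N and
    the circular transform of the mirrored series is truncated back to N.
    """
    spec = spec or WaveletSpec()
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1:
        raise ValueError("decompose expects a single 1-D spectrum")
    if not np.all(np.isfinite(x)):
        raise ValueError("spectrum contains non-finite values")
    N = x.size
    if N < 2 ** spec.levels:
        raise ValueError(f"signal length {N} shorter than 2^J = {2 ** spec.levels}")
    work = _reflect_extend(x[None, :]) if spec.boundary == "reflection" else x[None, :]
    comps = modwt_mra(work, spec)
    comps = [c[0, :N] for c in comps]
    return MRADecomposition(details=comps[:-1], smooth=comps[-1], sample_id=sample_id)


@dataclass
class WaveletFeatureMatrix:
    """Samples x (scale, wavelength) matrix of MRA component values.

    Columns are ordered scale-major: all wavelengths of D1, then D2, ...,
    then S. Column labels follow ``D{i}_{wavelength}`` / ``S_{wavelength}``.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    scale_labels: list
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        p = len(self.scale_labels) * self.wavelengths.size
        if self.values.shape[1] != p:
            raise ValueError("column count does not match (J+1) x n_wavelengths")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def scale_of(self, column_index: int):
        """Map a column index to its ``(scale_label, wavelength_nm)`` pair."""
        p = self.wavelengths.size
        if not 0 <= column_index < self.n_columns:
            raise IndexError(f"column index {column_index} out of range")
        return self.scale_labels[column_index // p], float(self.wavelengths[column_index % p])

    def index_of(self, scale_label: str, wavelength: float) -> int:
        """Inverse of :meth:`scale_of`."""
        p = self.wavelengths.size
        s = self.scale_labels.index(scale_label)
        w = int(np.searchsorted(self.wavelengths, wavelength))
        if w >= p or self.wavelengths[w] != wavelength:
            raise KeyError(f"wavelength {wavelength} not on the grid")
        return s * p + w

    def column_labels(self) -> list:
        return [f"{s}_{int(w) if w == int(w) else w}"
                for s in self.scale_labels for w in self.wavelengths]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.column_labels())

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="id")


def decompose_library(lib, spec: WaveletSpec | None = None) -> WaveletFeatureMatrix:
    """Decompose every spectrum of an absorbance-mode library.

    Vectorised over samples; returns the feature matrix with one row per
    sample and ``(J+1) * n_wavelengths`` columns.
    """
    spec = spec or WaveletSpec()
    if lib.n_samples == 0:
        raise ValueError("empty spectral library")
    if lib.mode != "absorbance":
        raise ValueError("library must be in absorbance mode (apply to_absorbance first)")
    N = lib.n_wavelengths
    if N < 2 ** spec.levels:
        raise ValueError(f"signal length {N} shorter than 2^J = {2 ** spec.levels}")
    work = _reflect_extend(lib.spectra) if spec.boundary == "reflection" else lib.spectra
    comps = modwt_mra(work, spec)
    mat = np.concatenate([c[:, :N] for c in comps], axis=1)
    return WaveletFeatureMatrix(
        values=mat,
        wavelengths=lib.wavelengths,
        scale_labels=spec.scale_labels,
        sample_ids=list(lib.sample_ids),
    )
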
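"""Generalized two-dimensional correlation spectroscopy (Hilbert-Noda).

Given a perturbation series of m spectra, the dynamic spectra D are the
series minus a reference (conventionally the series mean). The synchronous
map is the covariance-like correlation

    Phi = D^T D / (m - 1)                (symmetric, autopeaks on diagonal)

the asynchronous map weights the series with the Hilbert-Noda matrix N
(N_jj = 0, N_jk = 1/(pi (k - j)) off-diagonal, antisymmetric):

    Psi = D^T N D / (m - 1)              (antisymmetric, zero diagonal)

and the integrated map is their elementwise product I = Phi * Psi.

For the per-sample image pipeline, each sample's r replicate scans form
its perturbation series (m = r), yielding one synchronous, one
asynchronous and one integrated map per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraSet

__all__ = [
    "DynamicSpectra",
    "CorrelationMaps",
    "CosError",
    "hilbert_noda_matrix",
    "dynamic_spectra",
    "synchronous_map",
    "asynchronous_map",
    "integrated_map",
    "correlation_maps",
    "per_sample_maps",
]


class CosError(ValueError):
    """Invalid correlation-spectroscopy input."""


def hilbert_noda_matrix(m: int) -> np.ndarray:
    """The m x m Hilbert-Noda weight matrix.

    Zero on the diagonal, 1/(pi (k - j)) elsewhere; antisymmetric by
    construction.
    """
    if m < 1:
        raise CosError("m must be >= 1")
    j, k = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    with np.errstate(divide="ignore"):
        N = 1.0 / (np.pi * (k - j))
    N[j == k] = 0.0
    return N


@dataclass(frozen=True)
class DynamicSpectra:
    """Mean-centered (or reference-subtracted) perturbation series."""

    matrix: np.ndarray  # [m x n]
    reference: np.ndarray  # [n]
    wavenumbers: np.ndarray

    @property
    def m(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class CorrelationMaps:
    """Synchronous, asynchronous and integrated maps on one grid."""

    sync: np.ndarray
    asyn: np.ndarray
    integrated: np.ndarray
    wavenumbers: np.ndarray
    provenance: str = ""


def dynamic_spectra(
    series: SpectraSet | np.ndarray,
    wavenumbers: np.ndarray | None = None,
    reference: np.ndarray | str = "mean",
) -> DynamicSpectra:
    """Build dynamic spectra from a perturbation series.

    ``reference='mean'`` (the convention) subtracts the series mean, so
    column sums of D vanish and the synchronous diagonal is the
    per-wavenumber variance. ``reference='none'`` uses the raw series
    (exact-equation mode); an explicit spectrum subtracts that spectrum.
    """
    if isinstance(series, SpectraSet):
        mat = series.absorbance
        wavenumbers = series.wavenumbers
    else:
        mat = np.asarray(series, dtype=float)
        if wavenumbers is None:
            wavenumbers = np.arange(mat.shape[1], dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise CosError("perturbation series needs at least 2 records")
    if isinstance(reference, str):
        if reference == "mean":
            ref = mat.mean(axis=0)
        elif reference == "none":
            ref = np.zeros(mat.shape[1])
        else:
            raise CosError(f"unknown reference policy {reference!r}")
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (mat.shape[1],):
            raise CosError("reference spectrum is not on the series grid")
    return DynamicSpectra(mat - ref, ref, np.asarray(wavenumbers, dtype=float))


def _as_matrix(D: DynamicSpectra | np.ndarray) -> np.ndarray:
    mat = D.matrix if isinstance(D, DynamicSpectra) else np.asarray(D, dtype=float)
    if mat.shape[0] < 2:
        raise CosError("correlation maps need m >= 2 perturbation points")
    return mat

def synchronous_map(D: DynamicSpectra | np.ndarray) -> np.ndarray:
    """Phi = D^T D / (m - 1); symmetric with nonnegative diagonal."""
    mat = _as_matrix(D)
    return mat.T @ mat / (mat.shape[0] - 1)


def asynchronous_map(D: DynamicSpectra | np.ndarray) -> np.ndarray:
    """Psi = D^T N D / (m - 1); antisymmetric with zero diagonal."""
    mat = _as_matrix(D)
    N = hilbert_noda_matrix(mat.shape[0])
    return mat.T @ (N @ mat) / (mat.shape[0] - 1)


def integrated_map(sync: np.ndarray, asyn: np.ndarray) -> np.ndarray:
    """Elementwise product I = Phi * Psi (antisymmetric)."""
    sync = np.asarray(sync)
    asyn = np.asarray(asyn)
    if sync.shape != asyn.shape:
        raise CosError(f"shape mismatch: {sync.shape} vs {asyn.shape}")
    return sync * asyn


def correlation_maps(
    series: SpectraSet | np.ndarray,
    wavenumbers: np.ndarray | None = None,
    reference: np.ndarray | str = "mean",
    provenance: str = "",
) -> CorrelationMaps:
    """All three maps of one perturbation series."""
    D = dynamic_spectra(series, wavenumbers, reference)
    sync = synchronous_map(D)
    asyn = asynchronous_map(D)
    return CorrelationMaps(sync, asyn, integrated_map(sync, asyn), D.wavenumbers, provenance)


def per_sample_maps(
    spectra: SpectraSet,
    mode: str = "replicate",
    downsample: int = 4,
) -> dict[str, CorrelationMaps]:
    """One CorrelationMaps per sample (three images per sample downstream).

    mode='replicate': each sample's r >= 2 replicate scans are its
    perturbation series. mode='deviation': the series is the pair
    (sample mean spectrum, global mean spectrum); with m = 2 the
    asynchronous map vanishes identically, so this fallback mode carries
    synchronous information only. ``downsample`` decimates the wavenumber
    grid by an integer factor before the quadratic-cost map computation.
    """
    if downsample < 1 or int(downsample) != downsample:
        raise CosError("downsample must be a positive integer")
    sl = slice(None, None, int(downsample))
    w = spectra.wavenumbers[sl]
    out: dict[str, CorrelationMaps] = {}
    if mode == "replicate":
        if spectra.replicate_index is None or spectra.replicate_count < 2:
            raise CosError("mode='replicate' requires replicate_index with r >= 2")
        for sid in spectra.unique_sample_ids:
            series = spectra.records_of(sid)[:, sl]
            out[sid] = correlation_maps(series, w, provenance=f"{sid}:replicate")
    elif mode == "deviation":
        mean_set = spectra.mean_by_sample()
        global_mean = mean_set.absorbance[:, sl].mean(axis=0)
        for sid in mean_set.unique_sample_ids:
            series = np.vstack([mean_set.records_of(sid)[0, sl], global_mean])
            out[sid] = correlation_maps(series, w, provenance=f"{sid}:deviation")
    else:
        raise CosError(f"unknown mode {mode!r}")
    return out
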
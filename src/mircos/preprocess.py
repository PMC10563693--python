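"""Spectral preprocessing: SNV, MSC, Savitzky-Golay smoothing/derivatives.

The named chains accepted throughout the package are the nine used for
chemometric model comparison: RAW, 1D, 2D, SNV, MSC, SG, SNV+2D, MSC+2D,
SG+2D. 1D/2D are Savitzky-Golay derivatives (window 15 points, polynomial
order 3, derivative order 1/2); SG alone is the same filter used as a
smoother (derivative order 0).

MSC needs a reference spectrum; :class:`ChainTransformer` freezes the
training-set mean as that reference so held-out records are transformed by
the identical operator (no leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet

__all__ = [
    "snv",
    "msc",
    "savitzky_golay",
    "apply_chain",
    "ChainTransformer",
    "PreprocessSpec",
    "Step",
    "parse_chain_name",
    "CHAIN_NAMES",
    "DegenerateRecordError",
    "ParameterError",
]

CHAIN_NAMES = ("RAW", "1D", "2D", "SNV", "MSC", "SG", "SNV+2D", "MSC+2D", "SG+2D")

SG_WINDOW = 15
SG_POLYORDER = 3


class DegenerateRecordError(ValueError):
    """A record cannot be normalized (constant, or zero regression slope)."""


class ParameterError(ValueError):
    """Invalid filter or chain parameters."""


@dataclass(frozen=True)
class Step:
    kind: str  # SNV | MSC | SG
    window: int = SG_WINDOW
    polyorder: int = SG_POLYORDER
    deriv_order: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"SNV", "MSC", "SG"}:
            raise ParameterError(f"unknown step kind {self.kind!r}")
        if self.kind == "SG":
            if self.window % 2 == 0 or self.window <= self.polyorder:
                raise ParameterError(
                    f"SG window must be odd and > polyorder (got {self.window}, {self.polyorder})"
                )
            if not (0 <= self.deriv_order <= self.polyorder):
                raise ParameterError("deriv_order must satisfy 0 <= deriv <= polyorder")


@dataclass(frozen=True)
class PreprocessSpec:
    """An ordered, validated list of preprocessing steps."""

    steps: tuple[Step, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.steps, tuple):
            object.__setattr__(self, "steps", tuple(self.steps))


def parse_chain_name(name: str) -> PreprocessSpec:
    """Map a printed chain name (e.g. ``SNV+2D``) to its step list.

    ``RAW`` is the empty chain; ``1D``/``2D`` are SG derivatives of order
    1/2; ``SG`` is SG smoothing (derivative 0).
    """
    name = name.strip()
    steps: list[Step] = []
    for part in ([] if name.upper() == "RAW" else name.split("+")):
        part = part.strip().upper()
        if part == "SNV":
            steps.append(Step("SNV"))
        elif part == "MSC":
            steps.append(Step("MSC"))
        elif part == "SG":
            steps.append(Step("SG", deriv_order=0))
        elif part == "1D":
            steps.append(Step("SG", deriv_order=1))
        elif part == "2D":
            steps.append(Step("SG", deriv_order=2))
        else:
            raise ParameterError(f"unknown preprocessing name {part!r} in {name!r}")
    return PreprocessSpec(tuple(steps), name=name)


# ---------------------------------------------------------------------- #


def _snv_matrix(mat: np.ndarray, ids) -> np.ndarray:
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise DegenerateRecordError(
            f"constant record cannot be SNV-normalized: {ids[bad[0]]!r}"
        )
    return (mat - mean) / sd


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-record center and scale to unit sd.

    Uses the sample (n-1) standard deviation. Idempotent up to the sd of
    an already-normalized record.
    """
    return spectra.with_absorbance(_snv_matrix(spectra.absorbance, spectra.sample_ids))


def _msc_matrix(mat: np.ndarray, reference: np.ndarray, ids) -> np.ndarray:
    ref = np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise DegenerateRecordError("MSC reference is constant")
    out = np.empty_like(mat)
    for i, x in enumerate(mat):
        b = (x - x.mean()) @ ref_c / denom
        if b == 0:
            raise DegenerateRecordError(f"zero MSC slope for record {ids[i]!r}")
        a = x.mean() - b * ref.mean()
        out[i] = (x - a) / b
    return out


def msc(spectra: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each record x is regressed as x = a + b*ref (OLS) and returned as
    (x - a)/b, exactly inverting any affine distortion of the reference.
    Defaults to the set's own mean spectrum; supply the frozen training
    mean to transform held-out records without refitting the reference.
    """
    ref = spectra.absorbance.mean(axis=0) if reference is None else reference
    return spectra.with_absorbance(
        _msc_matrix(spectra.absorbance, ref, spectra.sample_ids)
    )


def savitzky_golay(
    spectra: SpectraSet,
    window: int = SG_WINDOW,
    polyorder: int = SG_POLYORDER,
    deriv_order: int = 0,
) -> SpectraSet:
    """Savitzky-Golay local-polynomial smoothing or differentiation.

    Derivatives are returned in physical units (per cm^-1 along the stored
    grid direction): the filter spacing is the grid step, so a quadratic
    x(v) = v^2 yields 2v regardless of whether the grid is stored
    ascending or descending. Edge points are evaluated from the one-sided
    polynomial fit.
    """
    Step("SG", window, polyorder, deriv_order)  # validate parameters
    step = spectra.grid_step
    out = savgol_filter(
        spectra.absorbance,
        window_length=window,
        polyorder=polyorder,
        deriv=deriv_order,
        delta=abs(step),
        axis=1,
        mode="interp",
    )
    if step < 0 and deriv_order % 2 == 1:
        out = -out
    return spectra.with_absorbance(out)


# ---------------------------------------------------------------------- #


def apply_chain(
    spectra: SpectraSet,
    spec: PreprocessSpec | str,
    msc_reference: np.ndarray | None = None,
) -> SpectraSet:
    """Apply a preprocessing chain left-to-right.

    ``msc_reference`` overrides the MSC reference (use the training-set
    mean when transforming held-out data); by default each MSC step uses
    the mean of the spectra it is given.
    """
    if isinstance(spec, str):
        spec = parse_chain_name(spec)
    out = spectra
    for step in spec.steps:
        if step.kind == "SNV":
            out = snv(out)
        elif step.kind == "MSC":
            out = msc(out, msc_reference)
        else:
            out = savitzky_golay(out, step.window, step.polyorder, step.deriv_order)
    return out


@dataclass
class ChainTransformer:
    """A chain whose MSC reference is fitted once on training data.

    ``fit`` freezes the training-set mean spectrum as the MSC reference
    (identity for chains without MSC); ``transform`` then applies the same
    operator to any record set, so train and test pass through identical
    preprocessing.
    """

    spec: PreprocessSpec
    msc_reference: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_name(cls, name: str) -> "ChainTransformer":
        return cls(parse_chain_name(name))

    @property
    def needs_reference(self) -> bool:
        return any(s.kind == "MSC" for s in self.spec.steps)

    def fit(self, train: SpectraSet) -> "ChainTransformer":
        if self.needs_reference:
            self.msc_reference = train.absorbance.mean(axis=0)
        return self

    def transform(self, spectra: SpectraSet) -> SpectraSet:
        if self.needs_reference and self.msc_reference is None:
            raise ParameterError("MSC chain must be fitted before transform")
        return apply_chain(spectra, self.spec, self.msc_reference)

    def fit_transform(self, train: SpectraSet) -> SpectraSet:
        return self.fit(train).transform(train)
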
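"""Domain containers for FT-MIR spectral tables and their on-disk formats.

A :class:`SpectraSet` is the currency every stage of the pipeline trades in:
a shared wavenumber grid (cm^-1, conventionally stored descending, e.g.
4000 -> 450), an absorbance matrix with one row per recorded scan, sample
identifiers, two-class labels, and an optional replicate index marking
repeated scans of the same physical sample.

On disk, spectra are a wide CSV (first column ``wavenumber``, one column per
record; replicate records are named ``<sample_id>#<k>``) with a two-column
``sample_id,class`` label sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "GridError",
    "SpectraFormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_labels_csv",
    "write_labels_csv",
]


class GridError(ValueError):
    """Wavenumber grid is non-monotonic, unevenly spaced, or mismatched."""


class SpectraFormatError(ValueError):
    """Malformed spectral table or label sidecar."""


_REL_STEP_TOL = 1e-9


def _check_grid(wavenumbers: np.ndarray) -> None:
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise GridError("wavenumber grid must be 1-D with at least 2 points")
    steps = np.diff(w)
    if not (np.all(steps > 0) or np.all(steps < 0)):
        raise GridError("wavenumber grid must be strictly monotonic")
    mean_step = steps.mean()
    if np.max(np.abs(steps - mean_step)) > abs(mean_step) * 1e-6 + _REL_STEP_TOL:
        raise GridError("wavenumber grid step is not constant")


@dataclass(frozen=True)
class SpectraSet:
    """A set of absorbance records on one wavenumber grid.

    Parameters
    ----------
    wavenumbers : (n_wavenumbers,) array, cm^-1, strictly monotonic.
    absorbance : (n_records, n_wavenumbers) array, absorbance units.
    sample_ids : record-level sample keys; repeated only across replicates.
    labels : class name per record, exactly two distinct classes expected
        by downstream classifiers (e.g. ``wild`` / ``cultivated``).
    replicate_index : optional 1-based replicate number per record; when
        present every sample must carry the same replicate count r >= 2.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    replicate_index: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.replicate_index is not None:
            object.__setattr__(
                self, "replicate_index", tuple(int(k) for k in self.replicate_index)
            )
        if a.ndim != 2:
            raise SpectraFormatError("absorbance must be a 2-D matrix")
        if a.shape[0] > 0:
            _check_grid(w)
            if not np.isfinite(a).all():
                raise SpectraFormatError("absorbance contains non-finite values")
        if a.shape[1] != w.size and a.shape[0] > 0:
            raise SpectraFormatError(
                f"absorbance has {a.shape[1]} columns but the grid has {w.size} points"
            )
        n = a.shape[0]
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise SpectraFormatError("sample_ids/labels length must match record count")
        if self.replicate_index is not None:
            if len(self.replicate_index) != n:
                raise SpectraFormatError("replicate_index length must match record count")
            counts: dict[str, int] = {}
            for sid in self.sample_ids:
                counts[sid] = counts.get(sid, 0) + 1
            r_values = set(counts.values())
            if len(r_values) > 1:
                raise SpectraFormatError(
                    f"unequal replicate counts per sample: {sorted(r_values)}"
                )
            if n > 0 and r_values.pop() < 2:
                raise SpectraFormatError("replicate_index present but replicate count < 2")
        else:
            if len(set(self.sample_ids)) != n:
                raise SpectraFormatError(
                    "duplicate sample_id without replicate markers"
                )

    # ------------------------------------------------------------------ #

    @property
    def n_records(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size

    @property
    def grid_step(self) -> float:
        return float(np.diff(self.wavenumbers).mean())

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))

    @property
    def replicate_count(self) -> int:
        """Replicates per sample (1 when records are unreplicated)."""
        if self.replicate_index is None:
            return 1
        return self.n_records // len(set(self.sample_ids))

    @property
    def unique_sample_ids(self) -> tuple[str, ...]:
        """Sample ids in first-appearance order."""
        seen: dict[str, None] = {}
        for sid in self.sample_ids:
            seen.setdefault(sid)
        return tuple(seen)

    def record_names(self) -> list[str]:
        """Column names for the wide CSV (``id#k`` when replicated)."""
        if self.replicate_index is None:
            return list(self.sample_ids)
        return [f"{sid}#{k}" for sid, k in zip(self.sample_ids, self.replicate_index)]

    def label_of(self, sample_id: str) -> str:
        return self.labels[self.sample_ids.index(sample_id)]

    def select(self, indices: np.ndarray | list[int]) -> "SpectraSet":
        """Row-subset by record indices, preserving order."""
        idx = np.asarray(indices, dtype=int)
        rep = (
            tuple(self.replicate_index[i] for i in idx)
            if self.replicate_index is not None
            else None
        )
        return SpectraSet(
            self.wavenumbers,
            self.absorbance[idx],
            tuple(self.sample_ids[i] for i in idx),
            tuple(self.labels[i] for i in idx),
            rep,
        )

    def select_samples(self, sample_ids: list[str] | tuple[str, ...]) -> "SpectraSet":
        """Subset by sample id; replicates of a sample travel together."""
        wanted = set(sample_ids)
        idx = [i for i, sid in enumerate(self.sample_ids) if sid in wanted]
        missing = wanted - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return self.select(idx)

    def mean_by_sample(self) -> "SpectraSet":
        """Average replicate scans into one record per sample.

        Mirrors the acquisition convention of scanning each sample several
        times and taking the mean as the working spectrum.
        """
        if self.replicate_index is None:
            return self
        order = self.unique_sample_ids
        rows = []
        labels = []
        for sid in order:
            mask = [i for i, s in enumerate(self.sample_ids) if s == sid]
            rows.append(self.absorbance[mask].mean(axis=0))
            labels.append(self.labels[mask[0]])
        return SpectraSet(self.wavenumbers, np.vstack(rows), order, tuple(labels))

    def with_absorbance(self, matrix: np.ndarray) -> "SpectraSet":
        if matrix.shape != self.absorbance.shape:
            raise SpectraFormatError("replacement matrix shape mismatch")
        return replace(self, absorbance=np.asarray(matrix, dtype=float))

    def records_of(self, sample_id: str) -> np.ndarray:
        mask = [i for i, s in enumerate(self.sample_ids) if s == sample_id]
        if not mask:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self.absorbance[mask]


# ---------------------------------------------------------------------- #
# I/O


def _split_record_name(name: str) -> tuple[str, int | None]:
    if "#" in name:
        sid, _, k = name.rpartition("#")
        try:
            return sid, int(k)
        except ValueError:
            return name, None
    return name, None


def read_labels_csv(path: str | Path) -> dict[str, str]:
    """Read the two-column ``sample_id,class`` sidecar."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise SpectraFormatError(f"label file {path} needs columns sample_id,class")
    ids, classes = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise SpectraFormatError(f"duplicate sample_id {dup!r} in label file")
    if classes.isna().any():
        raise SpectraFormatError("empty class in label file")
    return dict(zip(ids, classes))


def write_labels_csv(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "class": list(labels.values())}
    ).to_csv(path, index=False)


def read_spectra_csv(path: str | Path, labels_path: str | Path) -> SpectraSet:
    """Read a wide spectral CSV plus its label sidecar into a SpectraSet.

    The first column is the wavenumber grid; every other column is one
    record, its header the record name (``sample_id`` or ``sample_id#k``).
    Records whose sample_id has no label are rejected.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 1:
        raise SpectraFormatError(f"{path}: empty table")
    try:
        w = df.iloc[:, 0].astype(float).to_numpy()
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavenumber column: {exc}") from exc
    record_names = list(df.columns[1:])
    if record_names:
        _check_grid(w)
    mat = np.empty((len(record_names), w.size))
    for j, name in enumerate(record_names):
        col = pd.to_numeric(df[name], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            raise SpectraFormatError(
                f"{path}: non-numeric or missing value at row {bad[0] + 2}, column {name!r}"
            )
        mat[j] = col

    label_map = read_labels_csv(labels_path)
    sids, reps = [], []
    has_rep = False
    for name in record_names:
        sid, k = _split_record_name(name)
        sids.append(sid)
        reps.append(k)
        has_rep = has_rep or k is not None
    unlabeled = [s for s in sids if s not in label_map]
    if unlabeled:
        raise SpectraFormatError(f"records lacking a label: {sorted(set(unlabeled))}")
    labels = tuple(label_map[s] for s in sids)
    rep_idx = tuple(k if k is not None else 1 for k in reps) if has_rep else None
    return SpectraSet(w, mat, tuple(sids), labels, rep_idx)


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    """Write the wide CSV at 17 significant digits (lossless round-trip)."""
    cols = {"wavenumber": spectra.wavenumbers}
    for name, row in zip(spectra.record_names(), spectra.absorbance):
        cols[name] = row
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
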
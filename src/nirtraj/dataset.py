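"""Spectral dataset container, delimited-text I/O, region cropping and
Kennard-Stone sample-set partitioning.

A :class:`SpectralDataset` is the package's in-memory unit of data: an
``n_samples x n_variables`` absorbance matrix, an ordered spectral axis
(wavenumber in cm^-1 or wavelength in nm), one reference value per sample
(the regressand, e.g. API content in % w/w or chlorogenic acid in mg/mL)
and sample identifiers.

The on-disk dialect is a plain delimited text file, one row per sample:
an identifier column, the reference column (name configurable) and one
numeric column per axis position, the axis value itself serving as the
column header.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectralAxis",
    "SpectralDataset",
    "SplitResult",
    "read_dataset",
    "write_dataset",
    "crop_region",
    "kennard_stone_split",
]

AXIS_UNITS = ("cm-1", "nm")


class DatasetError(ValueError):
    """Structural or parse problem in a spectral dataset."""


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered spectral positions with their physical unit."""

    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise DatasetError("spectral axis needs at least 2 ordered positions")
        diffs = np.diff(values)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise DatasetError("spectral axis must be strictly monotone")
        if self.unit not in AXIS_UNITS:
            raise DatasetError(f"axis unit must be one of {AXIS_UNITS}, got {self.unit!r}")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def ascending(self) -> bool:
        return bool(self.values[1] > self.values[0])


@dataclass
class SpectralDataset:
    """Absorbance matrix + axis + single reference value per sample."""

    spectra: np.ndarray
    axis: SpectralAxis
    reference: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    reference_unit: str = ""
    reference_name: str = "reference"

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.spectra.ndim != 2:
            raise DatasetError("spectra must be a 2-D samples x variables matrix")
        n, p = self.spectra.shape
        if p != len(self.axis):
            raise DatasetError(
                f"axis length {len(self.axis)} != number of variables {p}"
            )
        if self.reference.shape != (n,):
            raise DatasetError(
                f"reference length {self.reference.size} != number of samples {n}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise DatasetError("sample_ids length mismatch")
        if not np.all(np.isfinite(self.spectra)):
            i, j = np.argwhere(~np.isfinite(self.spectra))[0]
            raise DatasetError(f"non-finite absorbance at sample {i}, variable {j}")
        if not np.all(np.isfinite(self.reference)):
            i = int(np.argwhere(~np.isfinite(self.reference))[0])
            raise DatasetError(f"non-finite reference value for sample {i}")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_variables(self) -> int:
        return self.spectra.shape[1]

    def subset(self, indices: np.ndarray) -> "SpectralDataset":
        """Row subset, preserving order of ``indices``."""
        indices = np.asarray(indices, dtype=int)
        return replace(
            self,
            spectra=self.spectra[indices].copy(),
            reference=self.reference[indices].copy(),
            sample_ids=[self.sample_ids[i] for i in indices],
        )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.spectra.tobytes())
        h.update(self.reference.tobytes())
        h.update(self.axis.values.tobytes())
        return h.hexdigest()[:16]


@dataclass
class SplitResult:
    """Kennard-Stone (or any) train/validation partition of a dataset."""

    train: SpectralDataset
    validation: SpectralDataset
    train_indices: np.ndarray
    validation_indices: np.ndarray


def read_dataset(
    path,
    reference_col: str = "reference",
    axis_unit: str = "nm",
    id_col: str | None = "sample_id",
    delimiter: str = ",",
    reference_unit: str = "",
) -> SpectralDataset:
    """Read a delimited text file into a validated :class:`SpectralDataset`.

    Layout: one row per sample; a header row whose spectral columns are the
    numeric axis positions; ``reference_col`` names the regressand column.
    Fails loudly (``DatasetError``) on non-numeric cells, missing reference
    values, or a header that does not parse as a numeric axis.
    """
    frame = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if reference_col not in frame.columns:
        raise DatasetError(f"reference column {reference_col!r} not found in {path}")
    ids: list[str] = []
    if id_col is not None and id_col in frame.columns:
        ids = [str(v) for v in frame[id_col]]
        frame = frame.drop(columns=[id_col])
    reference = frame.pop(reference_col)
    axis_positions = []
    for name in frame.columns:
        try:
            axis_positions.append(float(name))
        except ValueError as exc:
            raise DatasetError(
                f"spectral column header {name!r} is not a numeric axis position"
            ) from exc
    spectra = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(spectra))
    if bad.size:
        i, j = bad[0]
        raise DatasetError(
            f"non-numeric or missing absorbance at row {i}, column {frame.columns[j]!r}"
        )
    ref = pd.to_numeric(reference, errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(ref)):
        i = int(np.argwhere(~np.isfinite(ref))[0])
        raise DatasetError(f"missing or non-numeric reference value at row {i}")
    return SpectralDataset(
        spectra=spectra,
        axis=SpectralAxis(np.array(axis_positions), axis_unit),
        reference=ref,
        sample_ids=ids,
        reference_unit=reference_unit,
        reference_name=reference_col,
    )


def write_dataset(ds: SpectralDataset, path, delimiter: str = ",") -> None:
    """Write the same dialect :func:`read_dataset` reads (round-trips)."""
    # shortest-repr formatting so values round-trip bit-identically
    cells = np.vectorize(lambda v: repr(float(v)), otypes=[object])
    frame = pd.DataFrame(cells(ds.spectra), columns=[repr(float(v)) for v in ds.axis.values])
    frame.insert(0, ds.reference_name, [repr(float(v)) for v in ds.reference])
    frame.insert(0, "sample_id", ds.sample_ids)
    frame.to_csv(path, sep=delimiter, index=False)


def crop_region(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep exactly the variables with axis position in the closed [lo, hi]."""
    if not lo < hi:
        raise DatasetError(f"crop bounds must satisfy lo < hi, got {lo}, {hi}")
    mask = (ds.axis.values >= lo) & (ds.axis.values <= hi)
    if not mask.any():
        raise DatasetError(f"region [{lo}, {hi}] excludes all variables")
    return replace(
        ds,
        spectra=ds.spectra[:, mask].copy(),
        axis=SpectralAxis(ds.axis.values[mask], ds.axis.unit),
    )


def kennard_stone_split(ds: SpectralDataset, n_train: int) -> SplitResult:
    """Deterministic greedy max-min Kennard-Stone partition.

    Seeds with the two mutually most distant spectra (Euclidean distance),
    then repeatedly adds the sample whose minimum distance to the selected
    set is largest. Ties are broken by lowest sample index, so duplicate
    spectra are allowed and the split is fully deterministic.
    """
    n = ds.n_samples
    if not 2 <= n_train < n:
        raise DatasetError(f"n_train must be in [2, {n - 1}], got {n_train}")
    X = ds.spectra
    # squared distances suffice: monotone in the Euclidean distance
    sq = np.sum(X * X, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(D, -np.inf)
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)  # first max: lowest (i, j)
    if i > j:
        i, j = j, i
    selected = [int(i), int(j)]
    np.fill_diagonal(D, np.inf)
    min_dist = np.minimum(D[:, i], D[:, j])
    min_dist[selected] = -np.inf
    while len(selected) < n_train:
        k = int(np.argmax(min_dist))  # argmax returns lowest index on ties
        selected.append(k)
        min_dist = np.minimum(min_dist, D[:, k])
        min_dist[k] = -np.inf
    train_idx = np.array(selected, dtype=int)
    mask = np.ones(n, dtype=bool)
    mask[train_idx] = False
    val_idx = np.flatnonzero(mask)
    return SplitResult(
        train=ds.subset(train_idx),
        validation=ds.subset(val_idx),
        train_indices=train_idx,
        validation_indices=val_idx,
    )
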
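"""Spectral dataset container and I/O.

A :class:`SpectraSet` holds an absorbance matrix (samples x wavelength
channels), its wavelength axis in nm, and optionally a reference
concentration vector and sample identifiers.  Every other module consumes
this container.

CSV layout (comma separator, dot decimal, UTF-8):

* header row: ``id``, one wavelength per channel, optionally ``reference``
* one row per sample: sample id, absorbance values, optional reference value

MAT-file containers (MATLAB v5, as distributed for the public corn
benchmark) are read through :func:`scipy.io.loadmat`; when the container
stores only the matrix, the wavelength axis is synthesized as an arithmetic
sequence from a user-supplied start/step.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io

__all__ = [
    "SpectraSet",
    "SpectraFormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_mat_container",
    "save_pls1_model",
    "load_pls1_model",
    "save_ctai_model",
    "load_ctai_model",
    "save_model_json",
    "load_model_json",
]


class SpectraFormatError(ValueError):
    """Raised when a spectral file or array violates the expected layout."""


@dataclass
class SpectraSet:
    """Absorbance spectra with wavelength axis and optional reference values.

    Parameters
    ----------
    spectra
        ``(n, p)`` absorbance matrix.
    wavelengths
        Strictly increasing length-``p`` vector of wavelengths in nm.
    reference
        Optional length-``n`` vector of reference concentrations
        (property units, e.g. % moisture).
    ids
        Optional length-``n`` sequence of sample labels.
    """

    spectra: np.ndarray
    wavelengths: np.ndarray
    reference: np.ndarray | None = None
    ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.ndim != 2:
            raise SpectraFormatError(
                f"spectra must be 2-D, got ndim={self.spectra.ndim}"
            )
        n, p = self.spectra.shape
        if self.wavelengths.ndim != 1 or self.wavelengths.size != p:
            raise SpectraFormatError(
                f"wavelength axis length {self.wavelengths.size} does not "
                f"match channel count {p}"
            )
        if p > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise SpectraFormatError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.spectra)):
            raise SpectraFormatError("spectra contain non-finite values")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != (n,):
                raise SpectraFormatError(
                    f"reference length {self.reference.size} does not match "
                    f"sample count {n}"
                )
        if self.ids is not None:
            self.ids = [str(i) for i in self.ids]
            if len(self.ids) != n:
                raise SpectraFormatError(
                    f"ids length {len(self.ids)} does not match sample count {n}"
                )

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_channels(self) -> int:
        return self.spectra.shape[1]

    def subset(self, indices) -> "SpectraSet":
        """Return the row subset at ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            spectra=self.spectra[idx],
            wavelengths=self.wavelengths,
            reference=None if self.reference is None else self.reference[idx],
            ids=None if self.ids is None else [self.ids[i] for i in idx],
        )


def _parse_float(token: str, row: int, col: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise SpectraFormatError(
            f"non-numeric cell {token!r} at row {row}, column {col}"
        ) from None


def read_spectra_csv(path: str | Path, reference_file: str | Path | None = None) -> SpectraSet:
    """Read a :class:`SpectraSet` from CSV.

    The first header cell is an id label, the remaining header cells are
    wavelengths, except an optional trailing ``reference`` column.
    ``reference_file`` supports the paired-file layout (one reference
    value per line, aligned with the spectra rows) used by datasets that
    ship concentrations separately.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise SpectraFormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise SpectraFormatError(f"{path}: header must list wavelengths")
    has_ref = header[-1].strip().lower() == "reference"
    wl_cells = header[1 : len(header) - 1 if has_ref else len(header)]
    wavelengths = [
        _parse_float(c, 0, j + 1) for j, c in enumerate(wl_cells)
    ]
    width = len(header)
    ids: list[str] = []
    spectra: list[list[float]] = []
    reference: list[float] = []
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != width:
            raise SpectraFormatError(
                f"{path}: row {i} has {len(row)} cells, expected {width}"
            )
        ids.append(row[0])
        stop = len(row) - 1 if has_ref else len(row)
        spectra.append([_parse_float(c, i, j) for j, c in enumerate(row[1:stop], start=1)])
        if has_ref:
            reference.append(_parse_float(row[-1], i, width - 1))
    ref_vec = np.asarray(reference) if has_ref else None
    if reference_file is not None:
        if has_ref:
            raise SpectraFormatError(
                f"{path}: has an inline reference column and a reference file"
            )
        ref_vec = np.loadtxt(reference_file, dtype=float, ndmin=1)
    return SpectraSet(
        spectra=np.asarray(spectra, dtype=float),
        wavelengths=np.asarray(wavelengths, dtype=float),
        reference=ref_vec,
        ids=ids,
    )


def write_spectra_csv(s: SpectraSet, path: str | Path) -> None:
    """Write ``s`` so that :func:`read_spectra_csv` recovers it exactly."""
    path = Path(path)
    ids = s.ids if s.ids is not None else [str(i) for i in range(s.n_samples)]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = ["id"] + [repr(float(w)) for w in s.wavelengths]
        if s.reference is not None:
            header.append("reference")
        writer.writerow(header)
        for i in range(s.n_samples):
            row = [ids[i]] + [repr(float(v)) for v in s.spectra[i]]
            if s.reference is not None:
                row.append(repr(float(s.reference[i])))
            writer.writerow(row)


def read_mat_container(
    path: str | Path,
    spectra_key: str,
    reference_key: str | None = None,
    *,
    wl_start: float | None = None,
    wl_step: float | None = None,
) -> SpectraSet:
    """Read a MATLAB v5 container holding a 2-D spectral matrix.

    When the container has no wavelength axis, supply ``wl_start`` and
    ``wl_step`` to synthesize an arithmetic grid; otherwise channel indices
    0..p-1 are used.
    """
    contents = scipy.io.loadmat(str(path))
    available = [k for k in contents if not k.startswith("__")]
    if spectra_key not in contents:
        raise KeyError(
            f"key {spectra_key!r} not in container; available: {available}"
        )
    spectra = np.atleast_2d(np.asarray(contents[spectra_key], dtype=float))
    p = spectra.shape[1]
    if wl_start is not None and wl_step is not None:
        wavelengths = wl_start + wl_step * np.arange(p)
    else:
        wavelengths = np.arange(p, dtype=float)
    reference = None
    if reference_key is not None:
        if reference_key not in contents:
            raise KeyError(
                f"key {reference_key!r} not in container; available: {available}"
            )
        reference = np.asarray(contents[reference_key], dtype=float).ravel()
    return SpectraSet(spectra=spectra, wavelengths=wavelengths, reference=reference)


def save_pls1_model(model, directory: str | Path) -> None:
    """Serialize a PLS1 model to a directory of JSON + CSV (diffable).

    ``model.json`` holds the scalars and vectors; the weight and loading
    matrices go to ``W.csv`` and ``P.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "model_type": "pls1",
        "A": model.A,
        "x_mean": model.x_mean,
        "y_mean": model.y_mean,
        "q": model.q,
        "beta": model.beta,
        "rmsec": model.rmsec,
    }
    save_model_json(meta, directory / "model.json")
    np.savetxt(directory / "W.csv", model.W, delimiter=",")
    np.savetxt(directory / "P.csv", model.P, delimiter=",")


def load_pls1_model(directory: str | Path):
    from .pls_core import PLS1Model  # deferred: dataio is imported by pls_core users

    directory = Path(directory)
    meta = load_model_json(directory / "model.json")
    W = np.loadtxt(directory / "W.csv", delimiter=",", ndmin=2)
    P = np.loadtxt(directory / "P.csv", delimiter=",", ndmin=2)
    return PLS1Model(
        x_mean=np.asarray(meta["x_mean"], dtype=float),
        y_mean=float(meta["y_mean"]),
        W=W,
        P=P,
        q=np.asarray(meta["q"], dtype=float),
        beta=np.asarray(meta["beta"], dtype=float),
        A=int(meta["A"]),
        rmsec=float(meta["rmsec"]),
    )


def save_ctai_model(model, directory: str | Path) -> None:
    """Serialize a fitted transfer model: master PLS1 plus the
    per-component regression/normalization statistics and deltas."""
    from dataclasses import asdict

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_pls1_model(model.master, directory / "master_pls1")
    meta = {
        "model_type": "ctai",
        "A": model.A,
        "denorm_reference": model.denorm_reference,
        "delta_theta": model.delta_theta,
        "delta_b": model.delta_b,
        "master_regs": [asdict(r) for r in model.master_regs],
        "slave_regs": [asdict(r) for r in model.slave_regs],
    }
    save_model_json(meta, directory / "transfer.json")


def load_ctai_model(directory: str | Path):
    from .ctai_transfer import ComponentRegression, CTAIModel  # deferred

    directory = Path(directory)
    meta = load_model_json(directory / "transfer.json")
    master = load_pls1_model(directory / "master_pls1")
    return CTAIModel(
        master=master,
        master_regs=[ComponentRegression(**r) for r in meta["master_regs"]],
        slave_regs=[ComponentRegression(**r) for r in meta["slave_regs"]],
        delta_theta=np.asarray(meta["delta_theta"], dtype=float),
        delta_b=np.asarray(meta["delta_b"], dtype=float),
        denorm_reference=meta["denorm_reference"],
    )


def save_model_json(obj: dict, path: str | Path) -> None:
    """Serialize a model's metadata dict as indented JSON (diffable)."""

    def _default(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        raise TypeError(f"not JSON-serializable: {type(x)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def load_model_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
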
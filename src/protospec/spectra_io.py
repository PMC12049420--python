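"""Reading, writing and validating labelled Raman spectral datasets.

Two delimited-text layouts are supported, both comma-separated, UTF-8, with a
mandatory header row:

* ``matrix`` — one row per spectrum; leading columns ``spectrum_id``,
  ``class``, ``subclass``; every remaining column is one wavenumber (the
  header cell is the wavenumber value in cm^-1). All spectra share the grid.
* ``long`` — a spectra table with columns ``spectrum_id``, ``wavenumber_cm1``,
  ``intensity`` plus a manifest table with columns ``spectrum_id``, ``class``,
  ``subclass``, ``specimen_id``. The two files live in a directory (named
  ``spectra.csv`` / ``manifest.csv``), or the manifest sits next to the
  spectra file as ``<stem>_manifest.csv``.

Class and subclass vocabularies are data-driven (ordered by first
appearance); no species names are hardcoded anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "LabeledDataset",
    "SpectraValidationError",
    "read_dataset",
    "write_dataset",
    "aggregate_classes",
]


class SpectraValidationError(ValueError):
    """A dataset or file violates a structural invariant."""


@dataclass
class Spectrum:
    """A single 1-D spectrum: strictly increasing wavenumbers (cm^-1) and
    intensities of equal length, plus free-form metadata (id, specimen, ...)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        name = self.meta.get("id", "<unnamed>")
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectraValidationError(f"spectrum {name!r}: arrays must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise SpectraValidationError(
                f"spectrum {name!r}: {len(self.wavenumbers)} wavenumbers vs "
                f"{len(self.intensities)} intensities")
        if len(self.wavenumbers) < 2:
            raise SpectraValidationError(f"spectrum {name!r}: needs at least 2 points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise SpectraValidationError(
                f"spectrum {name!r}: wavenumbers not strictly increasing")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    @property
    def id(self) -> str:
        return str(self.meta.get("id", ""))


@dataclass
class LabeledDataset:
    """Spectra with one class label each (and an optional subclass).

    ``class_vocab`` is ordered by first appearance. When subclasses are
    present, each subclass must belong to exactly one class.
    """

    spectra: list[Spectrum]
    labels: list[str]
    subclasses: list[str] | None = None
    class_vocab: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.spectra) != len(self.labels):
            raise SpectraValidationError(
                f"{len(self.spectra)} spectra but {len(self.labels)} labels")
        if not self.class_vocab:
            self.class_vocab = list(dict.fromkeys(self.labels))
        unknown = set(self.labels) - set(self.class_vocab)
        if unknown:
            raise SpectraValidationError(f"labels outside class_vocab: {sorted(unknown)}")
        if self.subclasses is not None:
            if len(self.subclasses) != len(self.spectra):
                raise SpectraValidationError("subclass list length mismatch")
            owner: dict[str, str] = {}
            for sub, lab in zip(self.subclasses, self.labels):
                if sub in owner and owner[sub] != lab:
                    raise SpectraValidationError(
                        f"subclass {sub!r} maps to both {owner[sub]!r} and {lab!r}")
                owner[sub] = lab

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.spectra]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_vocab}
        for lab in self.labels:
            counts[lab] += 1
        return counts

    def shared_grid(self) -> np.ndarray | None:
        """The common wavenumber grid, or None if spectra are heterogeneous."""
        grid = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if len(s) != len(grid) or not np.array_equal(s.wavenumbers, grid):
                return None
        return grid

    def intensity_matrix(self) -> np.ndarray:
        if self.shared_grid() is None:
            raise SpectraValidationError(
                "spectra are not on a shared grid; resample first")
        return np.stack([s.intensities for s in self.spectra])

    def summary(self) -> pd.DataFrame:
        rows = [{"class": c, "n_spectra": n} for c, n in self.class_counts().items()]
        return pd.DataFrame(rows)


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def read_dataset(path: str | Path, dialect: str = "matrix") -> LabeledDataset:
    """Load a dataset from disk. ``dialect`` is ``"matrix"`` or ``"long"``."""
    path = Path(path)
    if dialect == "matrix":
        return _read_matrix(path)
    if dialect == "long":
        return _read_long(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_matrix(path: Path) -> LabeledDataset:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"spectrum_id": str, "class": str, "subclass": str})
    except pd.errors.EmptyDataError:
        raise SpectraValidationError(f"{path}: empty file") from None
    if df.empty:
        raise SpectraValidationError(f"{path}: no data rows")
    lead = ["spectrum_id", "class", "subclass"]
    missing = [c for c in lead if c not in df.columns]
    if missing:
        raise SpectraValidationError(f"{path}: missing columns {missing}")
    wn_cols = [c for c in df.columns if c not in lead]
    if len(wn_cols) < 2:
        raise SpectraValidationError(f"{path}: fewer than 2 wavenumber columns")
    try:
        grid = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraValidationError(f"{path}: non-numeric wavenumber header: {exc}")
    if not np.all(np.diff(grid) > 0):
        raise SpectraValidationError(f"{path}: wavenumber header not strictly increasing")
    if df["class"].isna().any():
        bad = df.loc[df["class"].isna(), "spectrum_id"].iloc[0]
        raise SpectraValidationError(f"{path}: missing class label for spectrum {bad!r}")
    values = df[wn_cols].to_numpy(dtype=float)
    spectra = [Spectrum(grid, row, {"id": sid})
               for sid, row in zip(df["spectrum_id"], values)]
    subs = None
    if df["subclass"].notna().any():
        subs = ["" if pd.isna(s) else str(s) for s in df["subclass"]]
    return LabeledDataset(spectra, [str(c) for c in df["class"]], subs)


def _long_paths(path: Path) -> tuple[Path, Path]:
    if path.is_dir():
        return path / "spectra.csv", path / "manifest.csv"
    return path, path.with_name(path.stem + "_manifest.csv")


def _read_long(path: Path) -> LabeledDataset:
    spec_path, man_path = _long_paths(Path(path))
    for p in (spec_path, man_path):
        if not p.exists():
            raise FileNotFoundError(p)
    try:
        spec_df = pd.read_csv(spec_path, dtype={"spectrum_id": str})
        man_df = pd.read_csv(man_path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SpectraValidationError(f"{path}: empty file") from None
    if spec_df.empty:
        raise SpectraValidationError(f"{spec_path}: no data rows")
    for col in ("spectrum_id", "wavenumber_cm1", "intensity"):
        if col not in spec_df.columns:
            raise SpectraValidationError(f"{spec_path}: missing column {col!r}")
    man = man_df.set_index("spectrum_id")
    spectra, labels, subs = [], [], []
    have_sub = "subclass" in man.columns and man["subclass"].notna().any()
    for sid, grp in spec_df.groupby("spectrum_id", sort=False):
        wn = grp["wavenumber_cm1"].to_numpy(dtype=float)
        if not np.all(np.diff(wn) > 0):
            raise SpectraValidationError(
                f"{spec_path}: wavenumbers not strictly increasing for spectrum {sid!r}")
        if sid not in man.index:
            raise SpectraValidationError(f"{man_path}: no manifest row for spectrum {sid!r}")
        row = man.loc[sid]
        meta = {"id": sid}
        if "specimen_id" in man.columns and pd.notna(row.get("specimen_id")):
            meta["specimen_id"] = row["specimen_id"]
        spectra.append(Spectrum(wn, grp["intensity"].to_numpy(dtype=float), meta))
        labels.append(str(row["class"]))
        subs.append("" if not have_sub or pd.isna(row.get("subclass")) else str(row["subclass"]))
    return LabeledDataset(spectra, labels, subs if have_sub else None)


def write_dataset(dataset: LabeledDataset, path: str | Path, dialect: str = "matrix") -> None:
    """Write a dataset; round-trips through :func:`read_dataset` to at least
    9 significant digits."""
    if len(dataset) == 0:
        raise SpectraValidationError("refusing to write an empty dataset")
    path = Path(path)
    subs = dataset.subclasses or [""] * len(dataset)
    if dialect == "matrix":
        grid = dataset.shared_grid()
        if grid is None:
            raise SpectraValidationError(
                "matrix dialect needs a shared wavenumber grid; resample first")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("spectrum_id,class,subclass," + ",".join(_fmt(w) for w in grid) + "\n")
            for spec, lab, sub in zip(dataset.spectra, dataset.labels, subs):
                vals = ",".join(_fmt(v) for v in spec.intensities)
                fh.write(f"{spec.id},{lab},{sub},{vals}\n")
    elif dialect == "long":
        spec_path, man_path = _long_paths(path)
        spec_path.parent.mkdir(parents=True, exist_ok=True)
        with open(spec_path, "w", encoding="utf-8") as fh:
            fh.write("spectrum_id,wavenumber_cm1,intensity\n")
            for spec in dataset.spectra:
                for w, v in zip(spec.wavenumbers, spec.intensities):
                    fh.write(f"{spec.id},{_fmt(w)},{_fmt(v)}\n")
        with open(man_path, "w", encoding="utf-8") as fh:
            fh.write("spectrum_id,class,subclass,specimen_id\n")
            for spec, lab, sub in zip(dataset.spectra, dataset.labels, subs):
                fh.write(f"{spec.id},{lab},{sub},{spec.meta.get('specimen_id', '')}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def aggregate_classes(dataset: LabeledDataset, mapping: dict[str, str]) -> LabeledDataset:
    """Collapse fine-grained labels into aggregated classes.

    ``mapping`` sends each current label to its aggregated class (for example,
    every elephant subclass to a single class). The original labels
    are kept as the subclass annotation of the returned dataset.
    """
    missing = set(dataset.labels) - set(mapping)
    if missing:
        raise SpectraValidationError(f"mapping misses labels: {sorted(missing)}")
    new_labels = [mapping[lab] for lab in dataset.labels]
    return LabeledDataset(dataset.spectra, new_labels, subclasses=list(dataset.labels))
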
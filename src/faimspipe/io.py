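"""Data model and I/O for FAIMS dispersion runs.

A FAIMS (field asymmetric ion mobility spectrometry) measurement of one
urine sample produces, per run, two detected-current grids — one per ion
polarity — over a sweep of compensation voltage (rows, default 512 steps
spanning +6 V to −6 V) by dispersion-field magnitude (columns, default 51
steps).  Each sample is measured three consecutive times ("runs").

This module defines the in-memory containers (:class:`IonMatrix`,
:class:`FAIMSRun`, :class:`SampleRecord`, :class:`FeatureTable`), a
plain-text run-file dialect, the linearisation of a run into a single
feature vector, and run-level combinations (subtraction, averaging).

Linearisation convention
------------------------
The positive-polarity grid is flattened row-major (compensation-voltage
rows, dispersion-field columns), followed by the negative grid, giving
``2 * rows * cols`` features (52,224 at instrument defaults).  Feature
identifiers encode ``(polarity, cv_index, df_index)`` so that every
downstream stage can trace a feature back to its grid cell.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IonMatrix",
    "FAIMSRun",
    "SampleRecord",
    "FeatureTable",
    "FAIMSParseError",
    "DEFAULT_ROWS",
    "DEFAULT_COLS",
    "read_run",
    "write_run",
    "read_metadata",
    "write_metadata",
    "linearise",
    "raw_feature_ids",
    "build_table",
    "combine_subtract",
    "combine_mean",
]

#: Instrument-standard grid: 512 compensation-voltage steps (+6 V to −6 V)
#: by 51 dispersion-field steps, per polarity.
DEFAULT_ROWS = 512
DEFAULT_COLS = 51

_POLARITIES = ("positive", "negative")


class FAIMSParseError(ValueError):
    """Raised when a run file violates the documented dialect."""


@dataclass(frozen=True)
class IonMatrix:
    """One polarity's detected-current grid for a single run.

    Rows index compensation-voltage steps, columns index dispersion-field
    steps.  Values are detector currents in arbitrary units and must be
    finite.
    """

    polarity: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}, got {self.polarity!r}")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"IonMatrix values must be 2-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("IonMatrix values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class FAIMSRun:
    """Both polarities of one consecutive measurement of one sample."""

    sample_id: str
    run_index: int
    positive: IonMatrix
    negative: IonMatrix

    def __post_init__(self) -> None:
        if self.run_index not in (1, 2, 3):
            raise ValueError(f"run_index must be 1, 2 or 3, got {self.run_index}")
        if self.positive.polarity != "positive" or self.negative.polarity != "negative":
            raise ValueError("positive/negative IonMatrix polarity tags are swapped")
        if self.positive.shape != self.negative.shape:
            raise ValueError(
                f"polarity grids differ in shape: {self.positive.shape} vs {self.negative.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.positive.shape


@dataclass(frozen=True)
class SampleRecord:
    """Clinical metadata for one sample: class label and demographics."""

    sample_id: str
    label: str  # "case" | "control"
    sex: str  # "M" | "F"
    age: float  # years
    alcohol: float  # units/week
    bmi: float  # kg/m^2

    def __post_init__(self) -> None:
        if self.label not in ("case", "control"):
            raise ValueError(f"label must be 'case' or 'control', got {self.label!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not self.bmi > 0:
            raise ValueError("bmi must be positive")
        if self.alcohol < 0:
            raise ValueError("alcohol must be non-negative")


@dataclass
class FeatureTable:
    """A samples × features numeric matrix with aligned identifiers.

    ``provenance`` records which pipeline stage produced the table
    (``raw``, ``dwt1``, ``dwt2``, ``selected``, ``pca``, ``demographics``
    or ``combined``).  Alignment between two tables is checked strictly —
    mismatched identifier order is an error, never silently reindexed.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    provenance: str = "raw"
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self._validated:
            return
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureTable values must be finite")
        self._validated = True

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def take_rows(self, indices: Sequence[int]) -> "FeatureTable":
        """Row subset (e.g. a CV fold); skips revalidation for speed."""
        return FeatureTable(
            [self.sample_ids[i] for i in indices],
            self.feature_ids,
            self.values[np.asarray(indices, dtype=int)],
            self.provenance,
            _validated=True,
        )

    def take_features(self, indices: Sequence[int], provenance: str | None = None) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            self.sample_ids,
            [self.feature_ids[i] for i in idx],
            self.values[:, idx],
            provenance or self.provenance,
            _validated=True,
        )

    def select_features(self, ids: Sequence[str], provenance: str | None = None) -> "FeatureTable":
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            idx = [lookup[f] for f in ids]
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown feature id {exc.args[0]!r}") from None
        return self.take_features(idx, provenance)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, provenance: str = "raw") -> "FeatureTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(float), provenance)


# ---------------------------------------------------------------------------
# Run-file dialect
# ---------------------------------------------------------------------------

def write_run(run: FAIMSRun, path: str | Path) -> None:
    """Write a run in the package's plain-text TSV dialect."""
    rows, cols = run.shape
    with open(path, "w") as fh:
        fh.write(f"#sample_id={run.sample_id}\n")
        fh.write(f"#run={run.run_index}\n")
        fh.write(f"#rows={rows}\n")
        fh.write(f"#cols={cols}\n")
        for matrix in (run.positive, run.negative):
            fh.write(f"#polarity={matrix.polarity}\n")
            for row in matrix.values:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_run(path: str | Path) -> FAIMSRun:
    """Read a run file, enforcing the header-declared dimensions.

    Malformed headers, ragged rows or non-numeric cells raise
    :class:`FAIMSParseError` naming the offending line number.
    """
    path = Path(path)
    header: dict[str, str] = {}
    blocks: dict[str, list[list[float]]] = {}
    current: list[list[float]] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise FAIMSParseError(f"{path}:{lineno}: malformed header line {line!r}")
                key, value = line[1:].split("=", 1)
                if key == "polarity":
                    if value not in _POLARITIES:
                        raise FAIMSParseError(f"{path}:{lineno}: unknown polarity {value!r}")
                    if value in blocks:
                        raise FAIMSParseError(f"{path}:{lineno}: duplicate polarity block {value!r}")
                    current = []
                    blocks[value] = current
                else:
                    header[key] = value
                continue
            if current is None:
                raise FAIMSParseError(f"{path}:{lineno}: data before any #polarity header")
            cells = line.split("\t")
            try:
                current.append([float(c) for c in cells])
            except ValueError:
                raise FAIMSParseError(f"{path}:{lineno}: non-numeric cell in row") from None

    for key in ("sample_id", "run", "rows", "cols"):
        if key not in header:
            raise FAIMSParseError(f"{path}: missing #{key}= header")
    try:
        rows, cols, run_index = int(header["rows"]), int(header["cols"]), int(header["run"])
    except ValueError:
        raise FAIMSParseError(f"{path}: non-integer rows/cols/run header") from None

    matrices: dict[str, IonMatrix] = {}
    for polarity in _POLARITIES:
        if polarity not in blocks:
            raise FAIMSParseError(f"{path}: missing #polarity={polarity} block")
        block = blocks[polarity]
        if len(block) != rows:
            raise FAIMSParseError(
                f"{path}: {polarity} block has {len(block)} rows, header declares {rows}"
            )
        widths = {len(r) for r in block}
        if widths != {cols}:
            raise FAIMSParseError(
                f"{path}: {polarity} block has row widths {sorted(widths)}, header declares {cols}"
            )
        matrices[polarity] = IonMatrix(polarity, np.array(block, dtype=float))
    return FAIMSRun(header["sample_id"], run_index, matrices["positive"], matrices["negative"])


_META_COLUMNS = ["sample_id", "label", "sex", "age", "alcohol", "bmi"]


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_META_COLUMNS)
        for r in records:
            writer.writerow([r.sample_id, r.label, r.sex, r.age, r.alcohol, r.bmi])


def read_metadata(path: str | Path) -> list[SampleRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_META_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FAIMSParseError(f"{path}: metadata missing columns {sorted(missing)}")
        for row in reader:
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"],
                    label=row["label"],
                    sex=row["sex"],
                    age=float(row["age"]),
                    alcohol=float(row["alcohol"]),
                    bmi=float(row["bmi"]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Linearisation and table assembly
# ---------------------------------------------------------------------------

def linearise(run: FAIMSRun) -> np.ndarray:
    """Flatten a run into a single feature vector.

    Positive grid first, then negative, each row-major over
    (compensation-voltage row, dispersion-field column).  Length is
    ``2 * rows * cols`` — 52,224 at instrument defaults.
    """
    return np.concatenate([run.positive.values.ravel(), run.negative.values.ravel()])


def raw_feature_ids(rows: int = DEFAULT_ROWS, cols: int = DEFAULT_COLS) -> list[str]:
    """Feature identifiers matching :func:`linearise` order: ``pol:cv:df``."""
    ids = []
    for pol in ("pos", "neg"):
        for r in range(rows):
            base = f"{pol}:cv{r}:df"
            ids.extend(f"{base}{c}" for c in range(cols))
    return ids


def build_table(runs: Iterable[FAIMSRun], run_index: int) -> FeatureTable:
    """Assemble one row per sample from each sample's run ``run_index``.

    Raises if ``run_index`` is out of range or any sample lacks that run;
    the error lists the affected sample identifiers.
    """
    if run_index not in (1, 2, 3):
        raise ValueError(f"run_index must be 1, 2 or 3, got {run_index}")
    by_sample: dict[str, FAIMSRun] = {}
    all_samples: list[str] = []
    for run in runs:
        if run.sample_id not in by_sample and run.sample_id not in all_samples:
            all_samples.append(run.sample_id)
        if run.run_index == run_index:
            by_sample[run.sample_id] = run
    missing = [s for s in all_samples if s not in by_sample]
    if missing:
        raise ValueError(f"samples missing run {run_index}: {missing}")
    if not by_sample:
        raise ValueError("no runs supplied")
    shapes = {by_sample[s].shape for s in all_samples}
    if len(shapes) != 1:
        raise ValueError(f"runs have inconsistent grid shapes: {sorted(shapes)}")
    rows, cols = shapes.pop()
    values = np.stack([linearise(by_sample[s]) for s in all_samples])
    return FeatureTable(all_samples, raw_feature_ids(rows, cols), values, "raw")


def _check_aligned(a: FeatureTable, b: FeatureTable) -> None:
    if a.sample_ids != b.sample_ids:
        raise ValueError("sample_ids differ or are ordered differently")
    if a.feature_ids != b.feature_ids:
        raise ValueError("feature_ids differ or are ordered differently")


def combine_subtract(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Element-wise ``a - b`` of two aligned tables (run subtraction)."""
    _check_aligned(a, b)
    return FeatureTable(a.sample_ids, a.feature_ids, a.values - b.values, "raw", _validated=True)


def combine_mean(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Element-wise mean of ≥2 aligned tables (run ensemble)."""
    if len(tables) < 2:
        raise ValueError("combine_mean needs at least two tables")
    first = tables[0]
    for other in tables[1:]:
        _check_aligned(first, other)
    mean = np.mean([t.values for t in tables], axis=0)
    return FeatureTable(first.sample_ids, first.feature_ids, mean, "raw", _validated=True)
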
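"""Count tables, sample metadata, and expected-ASV references.

The exchange object throughout the package is :class:`AsvTable`, an
integer matrix of amplicon sequence variants (ASVs, rows) by samples
(columns).  Tables are plain TSV with the first header cell literally
``asv_id``; orientation (ASVs as rows) is part of the format contract and
is never auto-detected.  Sample metadata is a four-column TSV
(``sample_id``, ``dilution_round``, ``dna_concentration``,
``sample_type``); the dilution round is empty for negative controls.
Expected-ASV references are one identifier per line with an optional
tab-separated taxon label.

Identifiers are opaque strings matched by exact equality: in a real
experiment an ASV identifier stands in for its exact denoised sequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when a file does not conform to the declared dialect."""


class ValidationError(ValueError):
    """Raised when data violate a type invariant."""


class SampleType(str, enum.Enum):
    DILUTION_SAMPLE = "dilution_sample"
    NEGATIVE_CONTROL = "negative_control"

    @classmethod
    def parse(cls, token: str) -> "SampleType":
        try:
            return cls(token)
        except ValueError:
            allowed = ", ".join(m.value for m in cls)
            raise ValidationError(
                f"unknown sample_type {token!r}; allowed tokens: {allowed}"
            ) from None


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample experimental annotations.

    ``dilution_round`` is the serial-dilution index d (0 = undiluted) and
    is ``None`` for negative controls.  ``dna_concentration`` is the
    spectrophotometer reading in instrument units (ng/µl for a NanoDrop).
    """

    sample_id: str
    dilution_round: int | None
    dna_concentration: float
    sample_type: SampleType

    def __post_init__(self) -> None:
        if self.dna_concentration < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: dna_concentration must be >= 0, "
                f"got {self.dna_concentration}"
            )
        if self.dilution_round is not None and self.dilution_round < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: dilution_round must be >= 0"
            )

    @property
    def is_control(self) -> bool:
        return self.sample_type is SampleType.NEGATIVE_CONTROL


class AsvTable:
    """Non-negative integer count matrix of ASVs (rows) × samples (columns).

    Wraps a :class:`pandas.DataFrame` with unique string row/column labels
    and int64 entries.  Construction validates all invariants; the wrapped
    frame should be treated as read-only.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV identifiers: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        values = counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                    raise ValidationError("counts must be integral")
            if np.any(values < 0):
                raise ValidationError("counts must be non-negative")
        frame = counts.astype(np.int64)
        frame.index = counts.index.astype(str)
        frame.columns = counts.columns.astype(str)
        self._frame = frame

    @classmethod
    def from_arrays(
        cls,
        asv_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray | Sequence[Sequence[int]],
    ) -> "AsvTable":
        matrix = np.asarray(counts)
        if matrix.size == 0:
            matrix = matrix.reshape(len(asv_ids), len(sample_ids))
        return cls(pd.DataFrame(matrix, index=list(asv_ids), columns=list(sample_ids)))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def asv_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def n_asvs(self) -> int:
        return self._frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self._frame.shape[1]

    def sample_sums(self) -> pd.Series:
        """Reads per sample (column sums)."""
        return self._frame.sum(axis=0)

    def column(self, sample_id: str) -> np.ndarray:
        return self._frame[sample_id].to_numpy()

    def subset_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        missing = [s for s in sample_ids if s not in self._frame.columns]
        if missing:
            raise ValidationError(f"unknown sample identifiers: {missing}")
        return AsvTable(self._frame[list(sample_ids)])

    def drop_empty_asvs(self) -> "AsvTable":
        """Drop ASVs with zero counts in every sample."""
        keep = self._frame.sum(axis=1) > 0
        return AsvTable(self._frame.loc[keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AsvTable):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return f"AsvTable({self.n_asvs} ASVs x {self.n_samples} samples)"


@dataclass(frozen=True)
class ExpectedReference:
    """The set of ASV identifiers expected in the mock community."""

    expected_asv_ids: tuple[str, ...]
    taxon_labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.expected_asv_ids:
            raise ValidationError("expected reference must be non-empty")
        if len(set(self.expected_asv_ids)) != len(self.expected_asv_ids):
            raise ValidationError("expected reference contains duplicate identifiers")

    def __contains__(self, asv_id: str) -> bool:
        return asv_id in set(self.expected_asv_ids)

    def __len__(self) -> int:
        return len(self.expected_asv_ids)

    @property
    def id_set(self) -> frozenset[str]:
        return frozenset(self.expected_asv_ids)


# ---------------------------------------------------------------------------
# File I/O (TSV dialect: tab separator, no quoting, "." decimal, UTF-8)
# ---------------------------------------------------------------------------

HEADER_CELL = "asv_id"
METADATA_COLUMNS = ("sample_id", "dilution_round", "dna_concentration", "sample_type")


def read_asv_table(path: str | Path) -> AsvTable:
    """Read an ASV count table from TSV.

    First header cell must be ``asv_id``; remaining header cells are
    sample identifiers; each body row is an ASV identifier followed by
    non-negative integer counts.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (missing header)")
    header = lines[0].split("\t")
    if header[0] != HEADER_CELL:
        raise FormatError(
            f"{path}: first header cell must be {HEADER_CELL!r}, got {header[0]!r}"
        )
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample identifiers {dups}")
    asv_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}, line {lineno}: expected {len(sample_ids) + 1} cells, "
                f"got {len(cells)}"
            )
        asv_ids.append(cells[0])
        row = []
        for col, cell in zip(sample_ids, cells[1:]):
            try:
                value = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}, line {lineno}, sample {col!r}: "
                    f"malformed count {cell!r}"
                ) from None
            if value < 0:
                raise ValidationError(
                    f"{path}, line {lineno}, sample {col!r}: negative count {value}"
                )
            row.append(value)
        rows.append(row)
    if len(set(asv_ids)) != len(asv_ids):
        dups = sorted({a for a in asv_ids if asv_ids.count(a) > 1})
        raise ValidationError(f"{path}: duplicate ASV identifiers {dups}")
    matrix = np.asarray(rows, dtype=np.int64).reshape(len(asv_ids), len(sample_ids))
    return AsvTable.from_arrays(asv_ids, sample_ids, matrix)


def write_asv_table(table: AsvTable, path: str | Path) -> None:
    """Write a count table as TSV; round-trips exactly through read_asv_table."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join([HEADER_CELL, *table.sample_ids]) + "\n")
        matrix = table.frame.to_numpy()
        for asv_id, row in zip(table.asv_ids, matrix):
            fh.write("\t".join([asv_id, *(str(int(v)) for v in row)]) + "\n")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata from a four-column TSV."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (missing header)")
    header = tuple(lines[0].split("\t"))
    if header != METADATA_COLUMNS:
        raise FormatError(
            f"{path}: header must be {list(METADATA_COLUMNS)}, got {list(header)}"
        )
    records: list[SampleMetadata] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != 4:
            raise FormatError(f"{path}, line {lineno}: expected 4 cells, got {len(cells)}")
        sample_id, dil, conc, stype = cells
        if sample_id in seen:
            raise ValidationError(f"{path}, line {lineno}: duplicate sample_id {sample_id!r}")
        seen.add(sample_id)
        dilution_round: int | None
        if dil.strip() in ("", "-", "–", "NA"):
            dilution_round = None
        else:
            try:
                dilution_round = int(dil)
            except ValueError:
                raise FormatError(
                    f"{path}, line {lineno}: malformed dilution_round {dil!r}"
                ) from None
        try:
            concentration = float(conc)
        except ValueError:
            raise FormatError(
                f"{path}, line {lineno}: malformed dna_concentration {conc!r}"
            ) from None
        records.append(
            SampleMetadata(
                sample_id=sample_id,
                dilution_round=dilution_round,
                dna_concentration=concentration,
                sample_type=SampleType.parse(stype),
            )
        )
    return records


def write_metadata(records: Iterable[SampleMetadata], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(METADATA_COLUMNS) + "\n")
        for rec in records:
            dil = "" if rec.dilution_round is None else str(rec.dilution_round)
            fh.write(
                "\t".join(
                    [rec.sample_id, dil, repr(rec.dna_concentration), rec.sample_type.value]
                )
                + "\n"
            )


def read_reference(path: str | Path) -> ExpectedReference:
    """Read an expected-ASV reference: one id per line, optional taxon label."""
    path = Path(path)
    ids: list[str] = []
    labels: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh.read().splitlines():
            if not line.strip():
                continue
            cells = line.split("\t")
            ids.append(cells[0])
            if len(cells) > 1 and cells[1]:
                labels[cells[0]] = cells[1]
    return ExpectedReference(tuple(ids), labels or None)


def write_reference(reference: ExpectedReference, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for asv_id in reference.expected_asv_ids:
            label = (reference.taxon_labels or {}).get(asv_id)
            fh.write(asv_id + (f"\t{label}" if label else "") + "\n")


def metadata_by_id(records: Iterable[SampleMetadata]) -> dict[str, SampleMetadata]:
    return {rec.sample_id: rec for rec in records}


def to_relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Convert counts to per-sample proportions (columns sum to 1).

    Raises :class:`ValidationError` naming the first zero-read sample.
    """
    sums = table.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(
            f"cannot compute relative abundance for zero-read sample "
            f"{zero.index[0]!r}"
        )
    return table.frame / sums
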
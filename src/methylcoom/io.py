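"""Typed containers and readers/writers for methylation-array tables.

The pipeline consumes five kinds of input: a beta-value matrix (CpG probes
x samples, fractions in [0, 1]), a probe annotation table (genomic position
plus SNP-overlap and sex-chromosome flags), a sample sheet assigning samples
to reference subpopulations (with an ordinal along the naive->mature axis)
or to the tumor cohort, expression matrices, and BED-like genomic region
sets.  All tabular formats are delimited text with a header row; interval
files are BED3/BED6 (0-based half-open).  Probe positions are 1-based, the
array-manifest convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ProbeAnnotation",
    "SampleSheet",
    "GenomicRegionSet",
    "ExpressionMatrix",
    "load_beta_matrix",
    "save_beta_matrix",
    "load_annotation",
    "load_sample_sheet",
    "load_regions",
    "save_regions",
    "load_expression",
    "filter_probes",
]

_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        if delimiter not in ("\t", ","):
            raise FormatError(
                f"unsupported delimiter {delimiter!r}: only tab and comma are recognized"
            )
        return delimiter
    with open(path) as fh:
        header = fh.readline()
    # auto-detection is deliberately limited to tab and comma
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class BetaMatrix:
    """Methylation fractions per (probe, sample); NaN marks missing cells.

    ``data`` is a float DataFrame indexed by probe id with one column per
    sample.  Every non-missing value lies in [0, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "probe id")
        _check_unique(self.data.columns, "sample id")
        vals = self.data.to_numpy()
        bad = np.argwhere(~np.isnan(vals) & ((vals < 0.0) | (vals > 1.0)))
        if bad.size:
            r, c = bad[0]
            raise FormatError(
                f"beta value {vals[r, c]!r} outside [0, 1] at probe "
                f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probes if p not in self.data.index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:5]}")
        return BetaMatrix(self.data.loc[list(probes)])

    def select_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.data[list(samples)])


@dataclass
class ExpressionMatrix:
    """Normalized expression (RPKM / rlog / RPM) per (feature, sample)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "feature id")
        _check_unique(self.data.columns, "sample id")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ProbeAnnotation:
    """Genomic location and filter flags per probe (positions 1-based)."""

    table: pd.DataFrame  # columns: chrom, pos, snp, sex_chrom; index probe_id

    def __post_init__(self) -> None:
        req = {"chrom", "pos", "snp", "sex_chrom"}
        missing = req - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "probe id")
        if (self.table["pos"] < 1).any():
            bad = self.table.index[self.table["pos"] < 1][0]
            raise FormatError(f"probe {bad!r} has position < 1")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class SampleSheet:
    """Sample roles: reference subpopulations (ordered naive->mature) or tumor."""

    table: pd.DataFrame  # columns: role, subpopulation, ordinal; index sample_id

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample id")
        bad_role = set(self.table["role"]) - {"reference", "tumor"}
        if bad_role:
            raise FormatError(f"unknown sample roles: {sorted(bad_role)}")
        ref = self.table[self.table["role"] == "reference"]
        if ref["subpopulation"].isna().any():
            raise FormatError("reference sample without subpopulation label")
        if ref["ordinal"].isna().any():
            raise FormatError("reference sample without subpopulation ordinal")

    @property
    def reference_samples(self) -> list[str]:
        return list(self.table.index[self.table["role"] == "reference"])

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.table.index[self.table["role"] == "tumor"])

    def subpopulations(self) -> list[str]:
        """Subpopulation labels ordered by their naive->mature ordinal."""
        ref = self.table[self.table["role"] == "reference"]
        order = (
            ref[["subpopulation", "ordinal"]]
            .drop_duplicates()
            .sort_values("ordinal")
        )
        if order["subpopulation"].duplicated().any():
            raise FormatError("subpopulation mapped to more than one ordinal")
        return list(order["subpopulation"])

    def samples_of(self, subpopulation: str) -> list[str]:
        ref = self.table[self.table["role"] == "reference"]
        return list(ref.index[ref["subpopulation"] == subpopulation])

    def validate_for_fitting(self) -> None:
        subs = self.subpopulations()
        if len(subs) < 2:
            raise FormatError("model fitting needs at least 2 subpopulations")
        for s in subs:
            if len(self.samples_of(s)) < 2:
                raise FormatError(f"subpopulation {s!r} has fewer than 2 samples")


@dataclass
class GenomicRegionSet:
    """A named set of genomic intervals, 0-based half-open."""

    name: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: chrom, start, end, and optionally label, strand

    def __post_init__(self) -> None:
        if len(self.table):
            bad = self.table["start"] >= self.table["end"]
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                row = self.table.iloc[i]
                raise FormatError(
                    f"region set {self.name!r}: start >= end at interval "
                    f"{row['chrom']}:{row['start']}-{row['end']} (row {i + 1})"
                )

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers / writers


def load_beta_matrix(path: str | Path, delimiter: str | None = None) -> BetaMatrix:
    """Read a delimited probe x sample table of beta values.

    First column holds probe ids; empty cells become missing.  Values outside
    [0, 1] and duplicate probe ids are rejected with coordinates.
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric beta value {bad.iloc[0]!r} at probe "
                    f"{bad.index[0]!r}, sample {col!r}"
                )
            df[col] = pd.to_numeric(df[col])
    return BetaMatrix(df)


def save_beta_matrix(matrix: BetaMatrix | pd.DataFrame, path: str | Path) -> None:
    df = matrix.data if isinstance(matrix, BetaMatrix) else matrix
    df.to_csv(path, sep="\t", index_label="probe_id", float_format="%.12g")


def load_expression(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric expression value {bad.iloc[0]!r} for feature "
                    f"{bad.index[0]!r}, sample {col!r}"
                )
            df[col] = pd.to_numeric(df[col])
    return ExpressionMatrix(df)


def save_expression(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    df = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t", index_label="feature_id", float_format="%.12g")


_TRUE = {"1", "true", "True", "TRUE", "yes"}


def _to_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).isin(_TRUE)


def load_annotation(path: str | Path, delimiter: str | None = None) -> ProbeAnnotation:
    """Read a probe annotation TSV: probe_id, chrom, pos[, snp[, sex_chrom]].

    A missing ``sex_chrom`` column is derived from the chromosome name.
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype={"probe_id": str, "chrom": str})
    df = df.set_index("probe_id")
    if "snp" not in df.columns:
        df["snp"] = False
    df["snp"] = _to_bool(df["snp"])
    if "sex_chrom" in df.columns:
        df["sex_chrom"] = _to_bool(df["sex_chrom"])
    else:
        df["sex_chrom"] = df["chrom"].isin(_SEX_CHROMS)
    df["pos"] = df["pos"].astype(int)
    return ProbeAnnotation(df[["chrom", "pos", "snp", "sex_chrom"]])


def save_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="probe_id")


def load_sample_sheet(path: str | Path, delimiter: str | None = None) -> SampleSheet:
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    df = df.set_index("sample_id")
    if "subpopulation" not in df.columns:
        df["subpopulation"] = pd.NA
    if "ordinal" not in df.columns:
        df["ordinal"] = pd.NA
    df["ordinal"] = pd.to_numeric(df["ordinal"], errors="coerce")
    return SampleSheet(df[["role", "subpopulation", "ordinal"]])


def save_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index_label="sample_id")


def load_regions(path: str | Path, name: str | None = None) -> GenomicRegionSet:
    """Read a BED3/BED6 file (0-based half-open) into a region set."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path.name}:{lineno}: fewer than 3 BED fields")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path.name}:{lineno}: start {start} >= end {end}"
                )
            label = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, label, strand))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "strand"])
    return GenomicRegionSet(name or path.stem, table)


def save_regions(regions: GenomicRegionSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in regions.table.itertuples(index=False):
            label = getattr(row, "label", "") or "."
            strand = getattr(row, "strand", ".") or "."
            w.writerow([row.chrom, row.start, row.end, label, 0, strand])


# ---------------------------------------------------------------------------
# probe filtering


def filter_probes(matrix: BetaMatrix, annotation: ProbeAnnotation) -> BetaMatrix:
    """Drop probes overlapping SNPs or located on sex chromosomes.

    Every probe of the matrix must be annotated; the sample set is unchanged
    and probe order is preserved.  Idempotent.
    """
    ann = annotation.table
    missing = [p for p in matrix.probe_ids if p not in ann.index]
    if missing:
        raise FormatError(
            f"{len(missing)} matrix probes missing from annotation, e.g. {missing[:5]}"
        )
    flags = ann.loc[matrix.probe_ids]
    keep = ~(flags["snp"] | flags["sex_chrom"])
    return BetaMatrix(matrix.data.loc[keep.to_numpy()])
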